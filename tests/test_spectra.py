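"""mzML round-tripping, centroiding, XICs and top-3 MS2 selection."""

import numpy as np
import pytest

import fragmode as fm
from fragmode.spectra import Run, RunFormatError, Spectrum, centroided

from conftest import make_planted_spec


# ---------------------------------------------------------------------------
# Run model and mzML I/O

def test_spectrum_invariants():
    with pytest.raises(RunFormatError):
        Spectrum(1, 1, 0.0, np.array([1.0, 2.0]), np.array([1.0]))
    with pytest.raises(RunFormatError, match="7"):
        Spectrum(7, 2, 0.0, np.array([1.0]), np.array([1.0]))  # MS2, no precursor
    with pytest.raises(RunFormatError):
        Run([Spectrum(1, 1, 5.0, np.empty(0), np.empty(0)),
             Spectrum(2, 1, 4.0, np.empty(0), np.empty(0))])


def test_mzml_roundtrip(tmp_path):
    spec = make_planted_spec(residual_precursor_frac=0.1)
    run = fm.simulate_run(spec)
    path = tmp_path / "fixture.mzML"
    fm.write_mzml(run, str(path))
    run2 = fm.read_run(str(path))
    assert len(run2.scans) == len(run.scans)
    for a, b in zip(run.scans, run2.scans):
        assert b.scan_number == a.scan_number
        assert b.ms_level == a.ms_level
        assert b.rt == pytest.approx(a.rt, abs=1e-6)
        assert np.allclose(a.mz, b.mz)
        assert np.allclose(a.intensity, b.intensity)
        if a.ms_level == 2:
            assert b.frag_mode == a.frag_mode
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-6)


def test_roundtrip_preserves_eight_frag_modes(tmp_path):
    # 3 HCD + 5 UVPD reaction times
    modes = tuple(fm.FragMode("HCD", ce) for ce in (20, 35, 60)) + tuple(
        fm.FragMode("UVPD", t) for t in (25, 50, 100, 200, 400)
    )
    spec = make_planted_spec(modes=modes)
    path = tmp_path / "modes.mzML"
    fm.write_mzml(fm.simulate_run(spec), str(path))
    run = fm.read_run(str(path))
    assert len(set(run.frag_modes())) == 8


def test_read_malformed_file(tmp_path):
    bad = tmp_path / "bad.mzML"
    bad.write_text("<mzML><spectrum></mzML>")
    with pytest.raises(RunFormatError):
        fm.read_run(str(bad))


# ---------------------------------------------------------------------------
# Centroiding

def _gaussian_profile(center, sigma=0.01, height=1000.0, step=0.002, width=6):
    mz = np.arange(center - width * sigma, center + width * sigma, step)
    return mz, height * np.exp(-0.5 * ((mz - center) / sigma) ** 2)


def test_centroid_single_gaussian():
    mz, inten = _gaussian_profile(100.05)
    cmz, cint = fm.centroid_spectrum(mz, inten)
    assert cmz.size == 1
    assert cmz[0] == pytest.approx(100.05, abs=1e-3)
    assert cint[0] == pytest.approx(inten.max(), rel=1e-6)


def test_centroid_two_separated_gaussians():
    m1, i1 = _gaussian_profile(100.05)
    m2, i2 = _gaussian_profile(100.60)
    mz = np.concatenate([m1, m2])
    inten = np.concatenate([i1, i2])
    cmz, _ = fm.centroid_spectrum(mz, inten)
    assert cmz.size == 2
    assert cmz == pytest.approx([100.05, 100.60], abs=1e-3)


def test_centroid_flat_and_empty():
    mz = np.linspace(100, 101, 50)
    assert fm.centroid_spectrum(mz, np.zeros(50))[0].size == 0
    assert fm.centroid_spectrum(np.empty(0), np.empty(0))[0].size == 0


def test_centroid_idempotent_on_stick_spectra():
    cmz = np.array([70.04, 112.05, 261.15])
    cint = np.array([300.0, 200.0, 100.0])
    out_mz, out_int = fm.centroid_spectrum(cmz, cint)
    assert np.allclose(out_mz, cmz)
    assert np.allclose(out_int, cint)


def test_centroid_count_bounded_by_points():
    rng = np.random.default_rng(0)
    mz = np.sort(rng.uniform(100, 110, 200))
    inten = rng.uniform(0, 100, 200)
    cmz, _ = fm.centroid_spectrum(mz, inten)
    assert cmz.size <= 200


def test_profile_run_centroids_near_planted_mz():
    spec = make_planted_spec(profile=True)
    run = fm.simulate_run(spec)
    sp = centroided(run.ms_scans(2)[0])
    planted = sorted(f.mz for f in spec.fragments if str(run.ms_scans(2)[0].frag_mode)
                     in dict(f.intensity_by_mode))
    for target in planted:
        assert np.min(np.abs(sp.mz - target)) < 2e-3


# ---------------------------------------------------------------------------
# XIC / apex / AUC

@pytest.fixture()
def gaussian_run():
    spec = make_planted_spec()
    return spec, fm.simulate_run(spec)


def test_xic_apex_recovers_planted_rt(gaussian_run):
    spec, run = gaussian_run
    x = fm.xic(run, spec.precursor_mz)
    rt, inten = x.apex()
    assert abs(rt - spec.apex_rt) <= spec.ms1_interval
    assert inten == pytest.approx(spec.precursor_intensity, rel=1e-6)


def test_xic_auc_close_to_analytic_gaussian(gaussian_run):
    spec, run = gaussian_run
    x = fm.xic(run, spec.precursor_mz)
    analytic = spec.precursor_intensity * spec.peak_width * np.sqrt(2 * np.pi)
    assert x.auc() == pytest.approx(analytic, rel=0.05)


def test_xic_linearity_and_zero(gaussian_run):
    spec, run = gaussian_run
    x = fm.xic(run, spec.precursor_mz)
    doubled = fm.XIC(x.target_mz, x.tol_ppm, x.rt, 2 * x.intensity)
    assert doubled.auc() == pytest.approx(2 * x.auc(), rel=1e-9)
    empty = fm.xic(run, 777.7)
    assert empty.auc() == 0.0


def test_xic_requires_positive_tol(gaussian_run):
    _, run = gaussian_run
    with pytest.raises(ValueError):
        fm.xic(run, 100.0, tol_ppm=0.0)


def test_apex_undefined_for_empty_level():
    run = Run([Spectrum(1, 2, 0.0, np.array([100.0]), np.array([1.0]),
                        precursor_mz=200.0, frag_mode=fm.FragMode("HCD", 35))])
    x = fm.xic(run, 100.0, ms_level=1)
    with pytest.raises(ValueError):
        x.apex()


# ---------------------------------------------------------------------------
# Top-3 MS2 selection

def test_select_top_ms2_three_per_mode(gaussian_run):
    spec, run = gaussian_run
    x = fm.xic(run, spec.precursor_mz)
    top = fm.select_top_ms2(run, spec.precursor_mz, x, n=3)
    assert set(top) == set(spec.modes)
    for scans in top.values():
        assert len(scans) == 3
        # the selected scans hug the apex: they carry the three highest
        # master intensities among candidates, which peak at the apex RT
        for s in scans:
            assert abs(s.rt - spec.apex_rt) <= 2 * spec.ms1_interval


def test_select_top_ms2_excludes_off_tolerance_precursor(gaussian_run):
    spec, run = gaussian_run
    x = fm.xic(run, spec.precursor_mz)
    top = fm.select_top_ms2(run, spec.precursor_mz + 0.5, x, n=3)
    assert top == {}


def test_select_top_ms2_fewer_when_unavailable(gaussian_run):
    spec, run = gaussian_run
    x = fm.xic(run, spec.precursor_mz)
    # keep only one MS2 scan per mode near the apex
    apex_scans = [s for s in run.scans
                  if s.ms_level == 1 or abs(s.rt - spec.apex_rt) < spec.ms1_interval / 2]
    small = Run(apex_scans)
    top = fm.select_top_ms2(small, spec.precursor_mz, fm.xic(small, spec.precursor_mz))
    assert all(len(v) == 1 for v in top.values())


def test_select_top_ms2_validates_n(gaussian_run):
    spec, run = gaussian_run
    x = fm.xic(run, spec.precursor_mz)
    with pytest.raises(ValueError):
        fm.select_top_ms2(run, spec.precursor_mz, x, n=0)
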
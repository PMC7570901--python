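"""Peak-to-ion matching, the three scores, error statistics, mode comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fragmode as fm
from fragmode.annotate import classify_compound
from fragmode.chem import ChargeConfig as CC
from fragmode.fragment import PredictedIon
from fragmode.spectra import FragMode, Spectrum


def ion(mz, formula=(("C", 1), ("H", 4)), cfg=CC.M_PLUS, depth=1):
    return PredictedIon(formula=formula, cfg=cfg, mz=mz, depth=depth)


def stick(mz, intensity, scan=1, prec=300.0):
    mz = np.atleast_1d(np.asarray(mz, dtype=float))
    intensity = np.atleast_1d(np.asarray(intensity, dtype=float))
    return Spectrum(scan, 2, 10.0, mz, intensity, precursor_mz=prec,
                    frag_mode=FragMode("HCD", 35))


# ---------------------------------------------------------------------------
# Precursor removal

def test_remove_precursor_strips_window():
    sp = stick([100.0, 299.9, 300.0, 300.1, 400.0], [1, 2, 3, 4, 5])
    out = fm.remove_precursor(sp, 300.0, tol=0.5)
    assert list(out.mz) == [100.0, 400.0]


def test_remove_precursor_requires_positive_tol():
    with pytest.raises(ValueError):
        fm.remove_precursor(stick([100.0], [1.0]), 300.0, tol=0.0)


def test_remove_precursor_idempotent():
    sp = stick([100.0, 300.0, 400.0], [1, 2, 3])
    once = fm.remove_precursor(sp, 300.0)
    twice = fm.remove_precursor(once, 300.0)
    assert np.array_equal(once.mz, twice.mz)


# ---------------------------------------------------------------------------
# Matching

def test_match_within_both_cutoffs():
    matches = fm.match_fragments(stick([70.0401], [10.0]), [ion(70.0400)])
    assert len(matches) == 1
    assert matches[0].error_ppm == pytest.approx(1.43, abs=0.05)
    assert matches[0].error_da == pytest.approx(0.0001, abs=1e-6)


def test_match_rejected_beyond_abs_cutoff():
    assert fm.match_fragments(stick([70.10], [10.0]), [ion(70.0400)]) == []


def test_match_rejected_beyond_ppm_cutoff():
    # 0.004 Da at 200 m/z is 20 ppm: inside the Da cutoff, outside ppm
    assert fm.match_fragments(stick([200.004], [1.0]), [ion(200.0)]) == []


def test_match_tie_breaks_to_lower_mz():
    ions = [ion(99.9995), ion(100.0005)]
    matches = fm.match_fragments(stick([100.000], [1.0]), ions)
    assert len(matches) == 1
    assert matches[0].ion.mz == 99.9995


def test_match_each_peak_once_ordered():
    ions = [ion(100.0), ion(100.5), ion(101.0)]
    sp = stick([100.0005, 100.5001, 100.9995], [1, 3, 2])
    matches = fm.match_fragments(sp, ions)
    assert [m.ion.mz for m in matches] == [100.0, 100.5, 101.0]
    assert [m.peak_mz for m in matches] == sorted(m.peak_mz for m in matches)


def test_match_against_exhaustive_oracle():
    """Binary-search matching equals O(n*m) exhaustive nearest-ion search."""
    rng = np.random.default_rng(17)
    for _ in range(25):
        ion_mzs = np.sort(rng.uniform(50, 500, rng.integers(1, 40)))
        ions = [ion(v) for v in ion_mzs]
        peaks = np.sort(rng.uniform(50, 500, rng.integers(1, 60)))
        # mix in near-hits
        near = ion_mzs[rng.integers(0, len(ion_mzs), 10)] * (
            1 + rng.normal(0, 4e-6, 10)
        )
        peaks = np.sort(np.concatenate([peaks, near]))
        sp = stick(peaks, np.ones_like(peaks))
        got = fm.match_fragments(sp, ions, ppm_cutoff=10, abs_cutoff=0.02)
        expected = []
        for p in peaks:
            errs = np.abs(p - ion_mzs)
            j = int(np.argmin(errs))  # argmin takes first (lower m/z) on ties
            if errs[j] <= 0.02 and errs[j] / ion_mzs[j] * 1e6 <= 10:
                expected.append((p, ion_mzs[j]))
        assert [(m.peak_mz, m.ion.mz) for m in got] == expected


@given(st.floats(1.0, 10.0), st.floats(0.001, 0.02))
@settings(max_examples=30, deadline=None)
def test_tightening_cutoffs_never_gains_matches(ppm, da):
    rng = np.random.default_rng(5)
    ion_mzs = np.sort(rng.uniform(50, 500, 30))
    ions = [ion(v) for v in ion_mzs]
    peaks = np.sort(ion_mzs * (1 + rng.normal(0, 6e-6, 30)))
    sp = stick(peaks, np.ones_like(peaks))
    loose = fm.match_fragments(sp, ions, ppm_cutoff=10, abs_cutoff=0.02)
    tight = fm.match_fragments(sp, ions, ppm_cutoff=ppm, abs_cutoff=da)
    assert len(tight) <= len(loose)


# ---------------------------------------------------------------------------
# Scores

def test_scores_direct_formula():
    ions = [ion(float(100 + i)) for i in range(20)]
    sp = stick([100.0, 101.0, 102.0, 103.0, 104.0], np.ones(5))
    matches = fm.match_fragments(sp, ions)
    s = fm.compute_scores(matches, sp, ions, precursor_intensity=1000.0)
    assert s.n_matched == s.n_exp == 5
    assert s.score1 == pytest.approx(0.25)
    assert s.score2 == pytest.approx(1.0)


def test_scores_no_matches():
    sp = stick([100.0], [50.0])
    s = fm.compute_scores([], sp, [ion(400.0)], precursor_intensity=100.0)
    assert (s.score1, s.score2, s.score3) == (0.0, 0.0, 0.0)


def test_score3_planted_intensities():
    ions = [ion(100.0), ion(200.0), ion(300.5)]
    sp = stick([100.0, 200.0, 300.5], [100.0, 200.0, 300.0])
    matches = fm.match_fragments(sp, ions)
    s = fm.compute_scores(matches, sp, ions, precursor_intensity=6000.0)
    assert s.score3 == pytest.approx(0.1)


def test_score_edge_cases_flagged():
    empty = stick(np.empty(0), np.empty(0))
    s = fm.compute_scores([], empty, [], precursor_intensity=10.0)
    assert s.score1 == 0.0 and s.score2 == 0.0
    assert "no_theoretical_ions" in s.flags
    assert "no_experimental_peaks" in s.flags
    with pytest.raises(ValueError):
        fm.compute_scores([], empty, [], precursor_intensity=0.0)


def test_score_bounds_random_inputs():
    rng = np.random.default_rng(23)
    for _ in range(20):
        ion_mzs = np.sort(rng.uniform(50, 500, rng.integers(1, 30)))
        ions = [ion(v) for v in ion_mzs]
        peaks = np.sort(rng.uniform(50, 500, rng.integers(1, 30)))
        sp = stick(peaks, rng.uniform(0, 100, peaks.size))
        matches = fm.match_fragments(sp, ions)
        s = fm.compute_scores(matches, sp, ions, precursor_intensity=rng.uniform(1, 100))
        assert 0 <= s.score1 <= 1
        assert 0 <= s.score2 <= 1
        assert s.score3 >= 0
        assert s.n_matched <= min(s.n_exp, s.n_theor)


# ---------------------------------------------------------------------------
# Error statistics

def test_error_stats_recovers_simulated_sd():
    rng = np.random.default_rng(31)
    n = 500
    ion_mz0 = 200.0
    ppm_err = rng.normal(0, 5.0, n)
    matches = [
        fm.AnnotationMatch(
            peak_mz=ion_mz0 * (1 + e * 1e-6), peak_intensity=1.0, ion=ion(ion_mz0),
            error_da=ion_mz0 * e * 1e-6, error_ppm=e,
        )
        for e in ppm_err
    ]
    stats = fm.mass_error_stats(matches)
    assert stats.fitted
    assert 4.3 <= stats.ppm_fit[1] <= 5.7


def test_error_stats_single_match_no_fit():
    stats = fm.mass_error_stats(
        [fm.AnnotationMatch(100.0, 1.0, ion(100.0), 0.0, 0.0)]
    )
    assert not stats.fitted
    assert stats.ppm_fit is None
    assert stats.errors_ppm.size == 1


def test_error_stats_zero_errors_zero_sd():
    matches = [fm.AnnotationMatch(100.0, 1.0, ion(100.0), 0.0, 0.0) for _ in range(5)]
    stats = fm.mass_error_stats(matches)
    assert stats.ppm_fit[1] == 0.0
    assert stats.da_fit[1] == 0.0


# ---------------------------------------------------------------------------
# Mode comparison

def scoreset(score3, n_matched):
    return fm.ScoreSet(0.1, 0.5, score3, n_exp=4, n_matched=n_matched, n_theor=10,
                       precursor_intensity=100.0)


def test_classification_rule_four_groups():
    hcd, uvpd = FragMode("HCD", 35), FragMode("UVPD", 50)
    assert classify_compound({hcd: scoreset(0.5, 3), uvpd: scoreset(0.5, 3)}) == \
        "good fragmentation with both"
    assert classify_compound({hcd: scoreset(0.5, 3), uvpd: scoreset(0.0, 0)}) == \
        "preference for HCD"
    assert classify_compound({hcd: scoreset(0.0, 0), uvpd: scoreset(0.5, 3)}) == \
        "preference for UVPD"
    assert classify_compound({hcd: scoreset(0.0, 0), uvpd: scoreset(0.0, 1)}) == \
        "poor fragmentation with both"


def test_compare_modes_tables_and_conservation():
    hcd, uvpd = FragMode("HCD", 35), FragMode("UVPD", 50)
    m1 = fm.AnnotationMatch(100.0, 40.0, ion(100.0, cfg=CC.M_PLUS), 0.0, 0.0)
    m2 = fm.AnnotationMatch(150.0, 60.0, ion(150.0, cfg=CC.M_PLUS_H), 0.0, 0.0)
    results = {
        "cmpdA": {
            hcd: (scoreset(0.0, 0), []),
            uvpd: (scoreset(0.5, 2), [m1, m2]),
        }
    }
    tables = fm.compare_modes(results)
    groups = dict(zip(tables["groups"]["compound"], tables["groups"]["group"]))
    assert groups["cmpdA"] == "preference for UVPD"
    ints = tables["intensities"]
    uv = ints[ints["mode"] == str(uvpd)]
    assert uv["summed_intensity"].sum() == pytest.approx(100.0)
    freqs = tables["frequencies"]
    assert freqs["n_annotated"].sum() == 2
    assert set(tables["scores"].columns) >= {"score1", "score2", "score3"}


def test_compare_modes_no_matches_is_poor():
    hcd = FragMode("HCD", 35)
    tables = fm.compare_modes({"x": {hcd: (scoreset(0.0, 0), [])}})
    assert tables["groups"]["group"].iloc[0] == "poor fragmentation with both"
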
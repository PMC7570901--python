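"""Synthetic LC-HRMS/MS run generator.

Emulates the acquisition design used for the fragmentation-mode
comparison: MS1 full scans over 100-800 m/z, MS2 scans over 50-500 m/z,
HCD events at collision energies 20/35/60 and UVPD events at reaction
times 25-800 ms.  A compound elutes as a chromatographic Gaussian; each
MS2 event near the apex carries planted fragment peaks at their
theoretical ion m/z, perturbed by seeded Gaussian ppm jitter and
multiplicative intensity noise.  Runs can be produced in centroid or
profile mode (Gaussian peak shapes in m/z) and are fully reproducible
under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import ChargeConfig, formula_from_smiles, ion_mz, parse_formula
from .spectra import FragMode, Run, Spectrum

__all__ = [
    "PlantedFragment",
    "FixtureSpec",
    "DEFAULT_HCD_ENERGIES",
    "DEFAULT_UVPD_TIMES",
    "default_modes",
    "simulate_run",
    "planted_fingerprints",
]

logger = logging.getLogger(__name__)

DEFAULT_HCD_ENERGIES: Tuple[float, ...] = (20.0, 35.0, 60.0)
DEFAULT_UVPD_TIMES: Tuple[float, ...] = (25.0, 50.0, 100.0, 200.0, 400.0, 800.0)


def default_modes() -> Tuple[FragMode, ...]:
    """The standard acquisition's fragmentation-mode cycle (3 HCD + 6 UVPD)."""
    return tuple(FragMode("HCD", ce) for ce in DEFAULT_HCD_ENERGIES) + tuple(
        FragMode("UVPD", t) for t in DEFAULT_UVPD_TIMES
    )


@dataclass(frozen=True)
class PlantedFragment:
    """A fragment planted into the MS2 scans of selected modes.

    ``intensity_by_mode`` maps the string form of a :class:`FragMode`
    (e.g. ``"UVPD@50ms"``) to the fragment's relative intensity in that
    mode; modes absent from the map receive no peak.
    """

    formula: str
    cfg: ChargeConfig
    intensity_by_mode: Tuple[Tuple[str, float], ...]

    @property
    def mz(self) -> float:
        return ion_mz(parse_formula(self.formula), self.cfg)


@dataclass
class FixtureSpec:
    """Full description of one synthetic single-compound run."""

    smiles: str
    polarity: str = "positive"
    fragments: Tuple[PlantedFragment, ...] = ()
    apex_rt: float = 10.0  # minutes
    peak_width: float = 0.15  # chromatographic Gaussian sigma, minutes
    precursor_intensity: float = 1e6
    rt_start: float = 8.0
    rt_end: float = 12.0
    ms1_interval: float = 0.05  # minutes between MS1 scans
    ms1_range: Tuple[float, float] = (100.0, 800.0)
    ms2_range: Tuple[float, float] = (50.0, 500.0)
    modes: Tuple[FragMode, ...] = field(default_factory=default_modes)
    baseline: float = 0.0
    mz_jitter_ppm: float = 0.0
    intensity_cv: float = 0.0
    residual_precursor_frac: float = 0.0  # precursor carried into MS2 spectra
    profile: bool = False
    profile_sigma_mz: float = 0.01
    profile_step_mz: float = 0.0025
    seed: int = 0

    @property
    def precursor_cfg(self) -> ChargeConfig:
        return (
            ChargeConfig.M_PLUS_H if self.polarity == "positive" else ChargeConfig.M_MINUS_H
        )

    @property
    def precursor_mz(self) -> float:
        return ion_mz(formula_from_smiles(self.smiles), self.precursor_cfg)

    def to_json(self) -> str:
        d = asdict(self)
        d["fragments"] = [
            {
                "formula": f.formula,
                "cfg": f.cfg.name,
                "intensity_by_mode": dict(f.intensity_by_mode),
            }
            for f in self.fragments
        ]
        d["modes"] = [{"technique": m.technique, "energy": m.energy} for m in self.modes]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        d = json.loads(text)
        d["fragments"] = tuple(
            PlantedFragment(
                formula=f["formula"],
                cfg=ChargeConfig[f["cfg"]],
                intensity_by_mode=tuple(f["intensity_by_mode"].items()),
            )
            for f in d.get("fragments", ())
        )
        d["modes"] = tuple(FragMode(m["technique"], m["energy"]) for m in d.get("modes", ()))
        for key in ("ms1_range", "ms2_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _profile_peaks(
    centers: np.ndarray, heights: np.ndarray, lo: float, hi: float,
    sigma: float, step: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render stick peaks as sampled Gaussians on a regular m/z grid."""
    if centers.size == 0:
        return np.empty(0), np.empty(0)
    grid_parts = []
    for c in centers:
        a = max(lo, c - 5 * sigma)
        b = min(hi, c + 5 * sigma)
        grid_parts.append(np.arange(a, b + step, step))
    grid = np.unique(np.concatenate(grid_parts))
    y = np.zeros_like(grid)
    for c, h in zip(centers, heights):
        y += h * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    keep = y > 0
    return grid[keep], y[keep]


def simulate_run(spec: FixtureSpec) -> Run:
    """Generate a synthetic :class:`Run` from a fixture description.

    MS1 scans sample the compound's chromatographic Gaussian at the
    theoretical precursor m/z; after each MS1 scan inside the elution
    window, one MS2 scan per fragmentation mode is emitted carrying the
    planted fragments (with per-mode intensities scaled by the precursor's
    current elution factor).  Planted fragments outside the MS2 range are
    dropped with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    prec_mz = spec.precursor_mz
    lo2, hi2 = spec.ms2_range

    frag_table: List[Tuple[float, Dict[str, float]]] = []
    for f in spec.fragments:
        if not lo2 <= f.mz <= hi2:
            logger.warning(
                "planted fragment %s %s at m/z %.4f outside MS2 range; dropped",
                f.formula, f.cfg.name, f.mz,
            )
            continue
        frag_table.append((f.mz, dict(f.intensity_by_mode)))

    scans: List[Spectrum] = []
    scan_number = 0
    n_ms1 = int(round((spec.rt_end - spec.rt_start) / spec.ms1_interval)) + 1

    def jitter(mz: float) -> float:
        if spec.mz_jitter_ppm <= 0:
            return mz
        return mz * (1.0 + rng.normal(0.0, spec.mz_jitter_ppm) * 1e-6)

    def noisy(i: float) -> float:
        if spec.intensity_cv <= 0:
            return i
        return max(i * (1.0 + rng.normal(0.0, spec.intensity_cv)), 0.0)

    for k in range(n_ms1):
        rt = spec.rt_start + k * spec.ms1_interval
        scan_number += 1
        elution = np.exp(-0.5 * ((rt - spec.apex_rt) / spec.peak_width) ** 2)
        prec_int = noisy(spec.precursor_intensity * elution)
        centers, heights = [], []
        if prec_int > spec.baseline and spec.ms1_range[0] <= prec_mz <= spec.ms1_range[1]:
            centers.append(jitter(prec_mz))
            heights.append(prec_int)
        cmz = np.asarray(centers)
        cint = np.asarray(heights)
        if spec.profile:
            pmz, pint = _profile_peaks(
                cmz, cint, *spec.ms1_range, spec.profile_sigma_mz, spec.profile_step_mz
            )
            scans.append(Spectrum(scan_number, 1, rt, pmz, pint, is_profile=True))
        else:
            order = np.argsort(cmz)
            scans.append(Spectrum(scan_number, 1, rt, cmz[order], cint[order]))

        # MS2 events only while the compound actually elutes
        if elution < 0.01:
            continue
        for mode in spec.modes:
            scan_number += 1
            centers, heights = [], []
            for mz0, by_mode in frag_table:
                rel = by_mode.get(str(mode), 0.0)
                if rel <= 0:
                    continue
                centers.append(jitter(mz0))
                heights.append(noisy(rel * spec.precursor_intensity * elution))
            if spec.residual_precursor_frac > 0 and lo2 <= prec_mz <= hi2:
                centers.append(jitter(prec_mz))
                heights.append(noisy(spec.residual_precursor_frac * prec_int))
            cmz = np.asarray(centers, dtype=np.float64)
            cint = np.asarray(heights, dtype=np.float64)
            if spec.profile and cmz.size:
                pmz, pint = _profile_peaks(
                    cmz, cint, lo2, hi2, spec.profile_sigma_mz, spec.profile_step_mz
                )
                scans.append(
                    Spectrum(scan_number, 2, rt, pmz, pint, is_profile=True,
                             precursor_mz=prec_mz, frag_mode=mode)
                )
            else:
                order = np.argsort(cmz) if cmz.size else np.empty(0, dtype=int)
                scans.append(
                    Spectrum(scan_number, 2, rt, cmz[order], cint[order],
                             precursor_mz=prec_mz, frag_mode=mode)
                )
    return Run(scans=scans, source=f"synthetic:{spec.smiles}")


def planted_fingerprints(
    n_templates: int = 5,
    per_cluster: int = 20,
    n_bits: int = 1024,
    template_bits: int = 60,
    flip_prob: float = 0.02,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Synthetic fingerprints drawn from well-separated bit templates.

    Each of ``n_templates`` clusters has a random template with
    ``template_bits`` set bits (disjointly sampled so clusters are well
    separated); members copy their template and then flip every bit
    independently with probability ``flip_prob``.  Returns ``(fps,
    labels)`` where labels are the planted cluster ids (0-based).  Used to
    validate clustering and SOM behavior against a known ground truth.
    """
    rng = np.random.default_rng(seed)
    positions = rng.permutation(n_bits)
    templates = np.zeros((n_templates, n_bits), dtype=np.uint8)
    for t in range(n_templates):
        idx = positions[t * template_bits:(t + 1) * template_bits]
        templates[t, idx] = 1
    fps = np.repeat(templates, per_cluster, axis=0)
    labels = np.repeat(np.arange(n_templates), per_cluster)
    flips = rng.random(fps.shape) < flip_prob
    fps = np.where(flips, 1 - fps, fps).astype(np.uint8)
    return fps, labels
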
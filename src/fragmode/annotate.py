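"""Fragment annotation of MS2 peaks and fragmentation-quality scoring.

Experimental MS2 peaks are matched to in-silico predicted ions under a
combined relative (ppm) and absolute (Da) mass tolerance — both must hold.
Three scores summarize how well a compound fragmented in a given mode:

* Score 1 = matched experimental fragments / theoretical fragments
* Score 2 = matched experimental fragments / experimental fragments
* Score 3 = summed matched-fragment intensity / MS1 precursor intensity

Score 3 is not clamped: fragment intensities are compared against a single
precursor intensity and can exceed it.  Mass-error distributions are
summarized with a maximum-likelihood normal fit, and per-compound-per-mode
tables support the qualitative four-group comparison of two fragmentation
techniques (poor with both / HCD preference / UVPD preference / good with
both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .fragment import PredictedIon
from .spectra import FragMode, Spectrum

__all__ = [
    "AnnotationMatch",
    "ScoreSet",
    "ErrorStats",
    "DEFAULT_PPM_CUTOFF",
    "DEFAULT_ABS_CUTOFF",
    "remove_precursor",
    "match_fragments",
    "compute_scores",
    "mass_error_stats",
    "classify_compound",
    "compare_modes",
]

logger = logging.getLogger(__name__)

DEFAULT_PPM_CUTOFF = 10.0  # ppm
DEFAULT_ABS_CUTOFF = 0.02  # Da
LOOSE_ABS_CUTOFF = 1.0  # Da; coarse pre-refinement matching mode


@dataclass(frozen=True)
class AnnotationMatch:
    """One experimental peak matched to its best predicted ion."""

    peak_mz: float
    peak_intensity: float
    ion: PredictedIon
    error_da: float  # signed, observed - theoretical
    error_ppm: float


@dataclass
class ScoreSet:
    """The three fragmentation-quality scores for one MS2 spectrum."""

    score1: float
    score2: float
    score3: float
    n_exp: int
    n_matched: int
    n_theor: int
    precursor_intensity: float
    flags: Tuple[str, ...] = ()


def remove_precursor(spectrum: Spectrum, precursor_mz: float, tol: float = 0.5) -> Spectrum:
    """Strip peaks within ``precursor_mz`` +- ``tol`` Da from an MS2 spectrum."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    keep = np.abs(spectrum.mz - precursor_mz) > tol
    from dataclasses import replace

    return replace(spectrum, mz=spectrum.mz[keep], intensity=spectrum.intensity[keep])


def match_fragments(
    spectrum: Spectrum,
    ions: Sequence[PredictedIon],
    ppm_cutoff: float = DEFAULT_PPM_CUTOFF,
    abs_cutoff: float = DEFAULT_ABS_CUTOFF,
) -> List[AnnotationMatch]:
    """Match each experimental peak to its nearest predicted ion.

    A peak is annotated with the minimum-|error| ion satisfying both the
    relative (ppm) and absolute (Da) cutoffs simultaneously; unmatched
    peaks are omitted.  Equidistant ions break ties toward the lower
    theoretical m/z; output is ordered by peak m/z.
    """
    if ppm_cutoff <= 0 or abs_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    if not ions:
        return []
    ion_mzs = np.array([i.mz for i in ions])
    order = np.argsort(ion_mzs, kind="stable")
    ion_mzs = ion_mzs[order]
    ions_sorted = [ions[i] for i in order]
    out: List[AnnotationMatch] = []
    for mz, inten in zip(spectrum.mz, spectrum.intensity):
        j = int(np.searchsorted(ion_mzs, mz))
        best: Optional[int] = None
        best_err = np.inf
        for cand in (j - 1, j):
            if 0 <= cand < ion_mzs.size:
                err = abs(mz - ion_mzs[cand])
                # strict < keeps the lower-m/z ion on exact ties
                if err < best_err:
                    best_err = err
                    best = cand
        if best is None:
            continue
        error_da = float(mz - ion_mzs[best])
        error_ppm = error_da / ion_mzs[best] * 1e6
        if abs(error_da) <= abs_cutoff and abs(error_ppm) <= ppm_cutoff:
            out.append(
                AnnotationMatch(
                    peak_mz=float(mz),
                    peak_intensity=float(inten),
                    ion=ions_sorted[best],
                    error_da=error_da,
                    error_ppm=float(error_ppm),
                )
            )
    out.sort(key=lambda m: m.peak_mz)
    return out


def compute_scores(
    matches: Sequence[AnnotationMatch],
    spectrum: Spectrum,
    ions: Sequence[PredictedIon],
    precursor_intensity: float,
) -> ScoreSet:
    """Scores 1–3 for one annotated MS2 spectrum.

    ``spectrum`` should already have the precursor signal removed when that
    option is active, so that ``n_exp`` counts genuine fragment peaks.
    """
    n_exp = int(spectrum.mz.size)
    n_matched = len(matches)
    n_theor = len(ions)
    flags: List[str] = []
    if n_theor == 0:
        score1 = 0.0
        flags.append("no_theoretical_ions")
    else:
        score1 = n_matched / n_theor
    if n_exp == 0:
        score2 = 0.0
        flags.append("no_experimental_peaks")
    else:
        score2 = n_matched / n_exp
    if precursor_intensity <= 0:
        raise ValueError("score 3 undefined: precursor intensity must be positive")
    score3 = float(sum(m.peak_intensity for m in matches)) / precursor_intensity
    return ScoreSet(
        score1=score1,
        score2=score2,
        score3=score3,
        n_exp=n_exp,
        n_matched=n_matched,
        n_theor=n_theor,
        precursor_intensity=precursor_intensity,
        flags=tuple(flags),
    )


@dataclass
class ErrorStats:
    """Mass-error distribution summary with an ML normal fit."""

    errors_ppm: np.ndarray
    errors_da: np.ndarray
    ppm_fit: Optional[Tuple[float, float]]  # (mean, sd)
    da_fit: Optional[Tuple[float, float]]
    ppm_hist: Tuple[np.ndarray, np.ndarray]
    da_hist: Tuple[np.ndarray, np.ndarray]
    fitted: bool


def mass_error_stats(matches: Sequence[AnnotationMatch], bins: int = 30) -> ErrorStats:
    """Histogram + maximum-likelihood normal fit of ppm and Da errors.

    With fewer than two matches the arrays are still returned but the fit
    is skipped (``fitted`` False).
    """
    ppm = np.array([m.error_ppm for m in matches], dtype=np.float64)
    da = np.array([m.error_da for m in matches], dtype=np.float64)
    fitted = ppm.size >= 2
    ppm_fit = da_fit = None
    if fitted:
        # MLE of a normal: sample mean and sqrt of the biased variance
        ppm_fit = tuple(map(float, stats.norm.fit(ppm)))
        da_fit = tuple(map(float, stats.norm.fit(da)))
    ppm_hist = np.histogram(ppm, bins=bins) if ppm.size else (np.empty(0), np.empty(0))
    da_hist = np.histogram(da, bins=bins) if da.size else (np.empty(0), np.empty(0))
    return ErrorStats(
        errors_ppm=ppm, errors_da=da, ppm_fit=ppm_fit, da_fit=da_fit,
        ppm_hist=ppm_hist, da_hist=da_hist, fitted=fitted,
    )


def classify_compound(
    mode_scores: Mapping[FragMode, ScoreSet],
    score3_threshold: float = 0.01,
    min_matched: int = 2,
) -> str:
    """Assign one of the four qualitative fragmentation groups.

    A technique "fragments well" when the best of its modes reaches both
    ``score3 >= score3_threshold`` and ``n_matched >= min_matched``.  The
    two booleans (HCD, UVPD) give: good fragmentation with both, a
    preference for one technique, or poor fragmentation with both.
    """

    def good(tech: str) -> bool:
        sets = [s for m, s in mode_scores.items() if m.technique == tech]
        return any(s.score3 >= score3_threshold and s.n_matched >= min_matched for s in sets)

    hcd, uvpd = good("HCD"), good("UVPD")
    if hcd and uvpd:
        return "good fragmentation with both"
    if hcd:
        return "preference for HCD"
    if uvpd:
        return "preference for UVPD"
    return "poor fragmentation with both"


def compare_modes(
    results: Mapping[str, Mapping[FragMode, Tuple[ScoreSet, Sequence[AnnotationMatch]]]],
    score3_threshold: float = 0.01,
    min_matched: int = 2,
) -> Dict[str, pd.DataFrame]:
    """Per-compound-per-mode summary tables across fragmentation modes.

    ``results`` maps compound -> mode -> (scores, matches).  Returns tidy
    frames: ``scores`` (the three scores and counts per compound x mode),
    ``intensities`` (summed matched intensity stacked by charge-config ion
    type), ``frequencies`` (annotated-fragment counts per ion type) and
    ``groups`` (the four-way classification per compound).
    """
    score_rows, int_rows, freq_rows, group_rows = [], [], [], []
    for compound, by_mode in results.items():
        for mode, (scores, matches) in by_mode.items():
            score_rows.append(
                {
                    "compound": compound,
                    "mode": str(mode),
                    "technique": mode.technique,
                    "energy": mode.energy,
                    "score1": scores.score1,
                    "score2": scores.score2,
                    "score3": scores.score3,
                    "n_exp": scores.n_exp,
                    "n_matched": scores.n_matched,
                    "n_theor": scores.n_theor,
                }
            )
            by_type: Dict[str, float] = {}
            freq: Dict[str, int] = {}
            for m in matches:
                ion_type = m.ion.cfg.name
                by_type[ion_type] = by_type.get(ion_type, 0.0) + m.peak_intensity
                freq[ion_type] = freq.get(ion_type, 0) + 1
            for ion_type in sorted(set(by_type) | set(freq)):
                int_rows.append(
                    {
                        "compound": compound,
                        "mode": str(mode),
                        "ion_type": ion_type,
                        "summed_intensity": by_type.get(ion_type, 0.0),
                    }
                )
                freq_rows.append(
                    {
                        "compound": compound,
                        "mode": str(mode),
                        "ion_type": ion_type,
                        "n_annotated": freq.get(ion_type, 0),
                    }
                )
        group_rows.append(
            {
                "compound": compound,
                "group": classify_compound(
                    {m: s for m, (s, _) in by_mode.items()},
                    score3_threshold=score3_threshold,
                    min_matched=min_matched,
                ),
            }
        )
    return {
        "scores": pd.DataFrame(score_rows),
        "intensities": pd.DataFrame(int_rows),
        "frequencies": pd.DataFrame(freq_rows),
        "groups": pd.DataFrame(group_rows),
    }
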
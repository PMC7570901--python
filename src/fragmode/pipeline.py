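"""End-to-end workflow orchestration.

For every compound x run: predict fragment ions from the SMILES, extract
the precursor XIC and its apex, pick the top-3 MS2 scans per
fragmentation mode near the apex, annotate their peaks against the
predicted ions under ppm/Da tolerances, compute the three scores, and
emit tidy CSV summaries (scores, stacked matched intensities, ion-type
frequencies, four-group classification).  Compounds or runs that cannot
be processed are skipped with a structured log record, mirroring the
accounting of undetected compounds in a real acquisition campaign.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import annotate as _annotate
from . import fragment as _fragment
from . import spectra as _spectra
from .annotate import DEFAULT_ABS_CUTOFF, DEFAULT_PPM_CUTOFF, ScoreSet
from .chem import ChargeConfig, FormulaError, formula_from_smiles, ion_mz
from .spectra import FragMode, Run, RunFormatError

__all__ = ["WorkflowConfig", "WorkflowResult", "run_workflow", "load_compounds"]

logger = logging.getLogger(__name__)

PPM_RANGE = (1.0, 100.0)
ABS_RANGE = (1e-4, 0.5)


@dataclass
class WorkflowConfig:
    """Configuration of one workflow invocation."""

    compounds_csv: str
    run_paths: Tuple[str, ...]
    output_dir: str = "fragmode_out"
    ppm_cutoff: float = DEFAULT_PPM_CUTOFF
    abs_cutoff: float = DEFAULT_ABS_CUTOFF
    remove_precursor: bool = True
    precursor_removal_tol: float = 0.5  # Da
    tree_depth: int = 2
    top_n: int = 3
    seed: int = 0
    allow_out_of_range_cutoffs: bool = False

    def __post_init__(self) -> None:
        if not self.allow_out_of_range_cutoffs:
            if not PPM_RANGE[0] <= self.ppm_cutoff <= PPM_RANGE[1]:
                raise ValueError(
                    f"ppm cutoff {self.ppm_cutoff} outside {PPM_RANGE}; "
                    "set allow_out_of_range_cutoffs to override"
                )
            if not ABS_RANGE[0] <= self.abs_cutoff <= ABS_RANGE[1]:
                raise ValueError(
                    f"absolute cutoff {self.abs_cutoff} outside {ABS_RANGE}; "
                    "set allow_out_of_range_cutoffs to override"
                )

    @classmethod
    def from_json(cls, path: str) -> "WorkflowConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["run_paths"] = tuple(d.get("run_paths", ()))
        return cls(**d)


@dataclass
class WorkflowResult:
    """Outputs of :func:`run_workflow`."""

    tables: Dict[str, pd.DataFrame]
    score_sets: Dict[Tuple[str, str], Dict[FragMode, ScoreSet]]  # (compound, run)
    dropped: List[Dict[str, str]]
    n_hard_errors: int


def load_compounds(path: str) -> pd.DataFrame:
    """Read a compound list CSV/TSV with name, SMILES and polarity columns."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("name", "smiles", "polarity") if c not in cols]
    if missing:
        raise ValueError(f"compound list {path} missing column(s): {missing}")
    out = df.rename(columns={cols["name"]: "name", cols["smiles"]: "smiles",
                             cols["polarity"]: "polarity"})
    return out[["name", "smiles", "polarity"]]


def _process_compound_run(
    name: str,
    smiles: str,
    polarity: str,
    run: Run,
    cfg: WorkflowConfig,
) -> Tuple[Dict[FragMode, Tuple[ScoreSet, list]], Dict[str, float]]:
    ions = _fragment.predicted_ion_table(smiles, polarity, cfg.tree_depth)
    prec_cfg = ChargeConfig.M_PLUS_H if polarity == "positive" else ChargeConfig.M_MINUS_H
    prec_mz = ion_mz(formula_from_smiles(smiles), prec_cfg)
    cxic = _spectra.xic(run, prec_mz, tol_ppm=cfg.ppm_cutoff)
    apex_rt, apex_int = cxic.apex()
    if apex_int <= 0:
        raise RunFormatError(f"{name}: precursor {prec_mz:.4f} not detected in run")
    top = _spectra.select_top_ms2(run, prec_mz, cxic, n=cfg.top_n, tol_ppm=cfg.ppm_cutoff)
    per_mode: Dict[FragMode, Tuple[ScoreSet, list]] = {}
    for mode, scans in top.items():
        mode_matches: list = []
        best: Optional[ScoreSet] = None
        for sp in scans:
            c = _spectra.centroided(sp)
            if cfg.remove_precursor:
                c = _annotate.remove_precursor(c, prec_mz, cfg.precursor_removal_tol)
            matches = _annotate.match_fragments(
                c, ions, ppm_cutoff=cfg.ppm_cutoff, abs_cutoff=cfg.abs_cutoff
            )
            master = max(cxic.intensity_at(sp.rt), 1e-12)
            scores = _annotate.compute_scores(matches, c, ions, master)
            if best is None or scores.score3 > best.score3:
                best = scores
                mode_matches = matches
        if best is not None:
            per_mode[mode] = (best, mode_matches)
    meta = {"precursor_mz": prec_mz, "apex_rt": apex_rt, "apex_intensity": apex_int,
            "xic_auc": cxic.auc()}
    return per_mode, meta


def run_workflow(cfg: WorkflowConfig) -> WorkflowResult:
    """Execute the full annotation workflow and write CSV outputs.

    Returns the result bundle; ``n_hard_errors`` counts runs/compounds that
    failed for structural reasons (callers may exit non-zero on it).
    Outputs are deterministic for identical config and inputs.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    compounds = load_compounds(cfg.compounds_csv)
    dropped: List[Dict[str, str]] = []
    n_hard = 0

    runs: List[Tuple[str, Run]] = []
    for path in cfg.run_paths:
        try:
            runs.append((str(path), _spectra.read_run(path)))
        except RunFormatError as exc:
            logger.error("skipping run %s: %s", path, exc)
            dropped.append({"item": str(path), "kind": "run", "reason": str(exc)})
            n_hard += 1

    results: Dict[str, Dict[FragMode, Tuple[ScoreSet, list]]] = {}
    score_sets: Dict[Tuple[str, str], Dict[FragMode, ScoreSet]] = {}
    meta_rows: List[Dict[str, object]] = []
    for _, row in compounds.iterrows():
        name, smiles, polarity = row["name"], row["smiles"], row["polarity"]
        for run_path, run in runs:
            try:
                per_mode, meta = _process_compound_run(name, smiles, polarity, run, cfg)
            except (FormulaError, RunFormatError, ValueError) as exc:
                logger.warning("dropped %s on %s: %s", name, run_path, exc)
                dropped.append({"item": str(name), "kind": "compound",
                                "run": run_path, "reason": str(exc)})
                continue
            merged = results.setdefault(name, {})
            for mode, pair in per_mode.items():
                if mode not in merged or pair[0].score3 > merged[mode][0].score3:
                    merged[mode] = pair
            score_sets[(name, run_path)] = {m: s for m, (s, _) in per_mode.items()}
            meta_rows.append({"compound": name, "run": run_path, **meta})

    tables = _annotate.compare_modes(results) if results else {
        "scores": pd.DataFrame(), "intensities": pd.DataFrame(),
        "frequencies": pd.DataFrame(), "groups": pd.DataFrame(),
    }
    tables["data"] = pd.DataFrame(meta_rows)
    tables["dropped"] = pd.DataFrame(dropped)
    for key, frame in tables.items():
        frame.to_csv(out_dir / f"{key}.csv", index=False)
    if not len(compounds):
        logger.warning("empty compound list: no work done")
    return WorkflowResult(
        tables=tables, score_sets=score_sets, dropped=dropped, n_hard_errors=n_hard
    )
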
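"""Combinatorial bond-dissociation fragment enumeration and predicted-ion tables.

MetFrag-style in-silico fragmentation: no fragmentation rules, only
systematic deletion of covalent bonds between heavy atoms.  At tree depth 1
every single bond deletion is applied to the parent; at depth 2 one further
deletion is applied to each depth-1 structure.  Deleting a non-ring bond
splits the molecule into two fragments; deleting a ring bond yields a
connected ring-opened intermediate with the parent formula, which is kept
only as a substrate for the next round of cleavage.  Hydrogens stay with
the heavy atom they are bonded to; hydrogen rearrangement is represented
afterwards by the six charge configurations (±0/1/2 H per polarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from rdkit import Chem

from .chem import (
    ChargeConfig,
    FormulaError,
    format_formula,
    formula_from_smiles,
    ion_mz,
    mol_from_smiles,
)

__all__ = [
    "FragmentStructure",
    "PredictedIon",
    "enumerate_fragments",
    "predicted_ion_table",
    "ion_table_frame",
]


@dataclass(frozen=True)
class FragmentStructure:
    """A connected substructure of the parent reachable by bond deletions.

    ``atoms`` indexes heavy atoms of the parent molecule; ``formula`` counts
    those atoms plus their attached hydrogens.  ``bonds_broken`` records the
    parent bond indices deleted on the path that produced this structure.
    A structure whose atom set equals the full parent is a ring-opened
    intermediate (same formula as the parent).
    """

    atoms: FrozenSet[int]
    formula: Tuple[Tuple[str, int], ...]
    depth: int
    bonds_broken: Tuple[int, ...]

    @property
    def formula_dict(self) -> Dict[str, int]:
        return dict(self.formula)

    @property
    def formula_str(self) -> str:
        return format_formula(self.formula_dict)


@dataclass(frozen=True)
class PredictedIon:
    """A theoretical singly charged ion for one fragment formula."""

    formula: Tuple[Tuple[str, int], ...]
    cfg: ChargeConfig
    mz: float
    depth: int

    @property
    def formula_dict(self) -> Dict[str, int]:
        return dict(self.formula)

    @property
    def formula_str(self) -> str:
        return format_formula(self.formula_dict)


def _atom_formula(mol: Chem.Mol, atoms: Iterable[int]) -> Tuple[Tuple[str, int], ...]:
    counts: Dict[str, int] = {}
    for idx in atoms:
        atom = mol.GetAtomWithIdx(idx)
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        n_h = atom.GetTotalNumHs()
        if n_h:
            counts["H"] = counts.get("H", 0) + n_h
    return tuple(sorted(counts.items()))


def _components(
    atoms: FrozenSet[int], adjacency: Mapping[int, Sequence[Tuple[int, int]]],
    dead_bonds: FrozenSet[int],
) -> List[FrozenSet[int]]:
    """Connected components of the subgraph on ``atoms`` minus ``dead_bonds``."""
    seen: set[int] = set()
    comps: List[FrozenSet[int]] = []
    for start in atoms:
        if start in seen:
            continue
        stack = [start]
        comp = set()
        while stack:
            a = stack.pop()
            if a in comp:
                continue
            comp.add(a)
            for nbr, bond_idx in adjacency[a]:
                if nbr in atoms and bond_idx not in dead_bonds and nbr not in comp:
                    stack.append(nbr)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def enumerate_fragments(
    mol_or_smiles: "Chem.Mol | str", max_depth: int = 2
) -> List[FragmentStructure]:
    """Enumerate fragment structures by combinatorial bond dissociation.

    Parameters
    ----------
    mol_or_smiles:
        Parent molecule (RDKit mol or SMILES).  Only bonds between heavy
        atoms are breakable; bonds to hydrogen are never broken.
    max_depth:
        Number of successive bond-deletion rounds, 1 or 2.

    Returns
    -------
    Deduplicated list of :class:`FragmentStructure` (unique heavy-atom
    subsets, keeping the smallest depth at which each subset appears).
    Ring-opened whole-molecule intermediates are included in the returned
    list (flagged by ``atoms`` equal to the full parent set) so callers can
    distinguish them from mass-reduced fragments.
    """
    if max_depth not in (1, 2):
        raise ValueError(f"max_depth must be 1 or 2, got {max_depth}")
    mol = mol_from_smiles(mol_or_smiles) if isinstance(mol_or_smiles, str) else mol_or_smiles

    n_atoms = mol.GetNumAtoms()
    adjacency: Dict[int, List[Tuple[int, int]]] = {i: [] for i in range(n_atoms)}
    for bond in mol.GetBonds():
        a, b, idx = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), bond.GetIdx()
        adjacency[a].append((b, idx))
        adjacency[b].append((a, idx))

    all_atoms = frozenset(range(n_atoms))
    best: Dict[FrozenSet[int], FragmentStructure] = {}

    def bonds_within(atoms: FrozenSet[int], dead: FrozenSet[int]) -> List[int]:
        out = []
        for bond in mol.GetBonds():
            idx = bond.GetIdx()
            if idx in dead:
                continue
            if bond.GetBeginAtomIdx() in atoms and bond.GetEndAtomIdx() in atoms:
                out.append(idx)
        return out

    # Depth-1 structures; ring-opened intermediates kept (with their broken
    # bond) as substrates for depth 2 even though their atom sets collide.
    frontier: List[FragmentStructure] = []
    for bond_idx in bonds_within(all_atoms, frozenset()):
        dead = frozenset([bond_idx])
        for comp in _components(all_atoms, adjacency, dead):
            struct = FragmentStructure(
                atoms=comp,
                formula=_atom_formula(mol, comp),
                depth=1,
                bonds_broken=(bond_idx,),
            )
            frontier.append(struct)
            if comp not in best:
                best[comp] = struct

    if max_depth >= 2:
        for parent_struct in frontier:
            dead0 = frozenset(parent_struct.bonds_broken)
            for bond_idx in bonds_within(parent_struct.atoms, dead0):
                dead = dead0 | {bond_idx}
                for comp in _components(parent_struct.atoms, adjacency, dead):
                    if comp in best:
                        continue
                    best[comp] = FragmentStructure(
                        atoms=comp,
                        formula=_atom_formula(mol, comp),
                        depth=2,
                        bonds_broken=parent_struct.bonds_broken + (bond_idx,),
                    )

    return sorted(
        best.values(), key=lambda s: (s.depth, len(s.atoms), sorted(s.atoms))
    )


def predicted_ion_table(
    smiles: str,
    polarity: str,
    max_depth: int = 2,
) -> List[PredictedIon]:
    """Derive the predicted-ion table for one compound and polarity.

    Every unique fragment formula (mass-reduced structures only) plus the
    intact parent is combined with the three polarity-appropriate charge
    configurations; configurations that would remove more hydrogens than the
    formula carries are skipped.  Ions are deduplicated by (formula, config)
    keeping the smallest tree depth, and sorted by m/z.
    """
    mol = mol_from_smiles(smiles)
    parent_formula = tuple(sorted(formula_from_smiles(smiles).items()))
    n_heavy = mol.GetNumAtoms()

    # formula -> smallest depth seen; parent counts as depth 0
    formulas: Dict[Tuple[Tuple[str, int], ...], int] = {parent_formula: 0}
    for struct in enumerate_fragments(mol, max_depth):
        if len(struct.atoms) == n_heavy:
            continue  # ring-opened intermediate: indistinguishable from parent by m/z
        if struct.formula not in formulas or struct.depth < formulas[struct.formula]:
            formulas.setdefault(struct.formula, struct.depth)
            formulas[struct.formula] = min(formulas[struct.formula], struct.depth)

    configs = ChargeConfig.for_polarity(polarity)
    ions: Dict[Tuple[Tuple[Tuple[str, int], ...], ChargeConfig], PredictedIon] = {}
    for formula, depth in formulas.items():
        fdict = dict(formula)
        for cfg in configs:
            try:
                mz = ion_mz(fdict, cfg)
            except FormulaError:
                continue  # infeasible hydrogen removal
            key = (formula, cfg)
            if key not in ions or depth < ions[key].depth:
                ions[key] = PredictedIon(formula=formula, cfg=cfg, mz=mz, depth=depth)
    return sorted(ions.values(), key=lambda i: (i.mz, i.cfg.name))


def ion_table_frame(
    compound: str, smiles: str, ions: Sequence[PredictedIon]
) -> pd.DataFrame:
    """Serialize predicted ions into the tidy CSV layout."""
    return pd.DataFrame(
        {
            "compound": compound,
            "smiles": smiles,
            "depth": [i.depth for i in ions],
            "formula": [i.formula_str for i in ions],
            "charge_config": [i.cfg.name for i in ions],
            "mz": [i.mz for i in ions],
        }
    )
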
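"""Molecular formulas, monoisotopic masses and ion m/z under charge configurations.

Small-molecule MS2 annotation needs exact theoretical masses for neutral
fragment formulas and for the singly charged species derived from them.
Six charge configurations are supported: the radical/even-electron cations
[M]+, [M+H]+, [M+2H]+ in positive mode and the anions [M]-, [M-H]-, [M-2H]-
in negative mode.  m/z values account for the electron mass, which matters
at the 10 ppm matching tolerances typical of Orbitrap data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, Mapping

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "ChargeConfig",
    "FormulaError",
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "formula_from_smiles",
    "mol_from_smiles",
    "ion_mz",
    "nominal_mz",
    "add_hydrogens",
]

# Monoisotopic atomic masses, Da (IUPAC/CODATA, 6 decimals).
ELEMENT_MASSES: Dict[str, float] = {
    "H": 1.007825,
    "C": 12.0,
    "N": 14.003074,
    "O": 15.994915,
    "F": 18.998403,
    "Na": 22.989769,
    "P": 30.973762,
    "S": 31.972071,
    "Cl": 34.968853,
    "Br": 78.918338,
    "I": 126.904473,
}

PROTON_MASS = 1.007276  # Da
ELECTRON_MASS = 0.000549  # Da


class FormulaError(ValueError):
    """Raised for malformed or chemically infeasible formula input."""


class ChargeConfig(Enum):
    """Hydrogen/charge variants applied to a neutral fragment formula.

    Each member carries ``(delta_h, charge)``: the number of hydrogen atoms
    added to (or removed from) the neutral formula and the resulting unit
    charge.  Fragments produced by homolytic bond cleavage keep their
    hydrogens as attached in the parent; hydrogen rearrangement during
    dissociation is approximated entirely by these configurations.
    """

    M_PLUS = (0, +1)
    M_PLUS_H = (+1, +1)
    M_PLUS_2H = (+2, +1)
    M_MINUS = (0, -1)
    M_MINUS_H = (-1, -1)
    M_MINUS_2H = (-2, -1)

    @property
    def delta_h(self) -> int:
        return self.value[0]

    @property
    def charge(self) -> int:
        return self.value[1]

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    @classmethod
    def for_polarity(cls, polarity: str) -> tuple["ChargeConfig", ...]:
        """The three configurations applicable in one ionization mode."""
        if polarity == "positive":
            return (cls.M_PLUS, cls.M_PLUS_H, cls.M_PLUS_2H)
        if polarity == "negative":
            return (cls.M_MINUS, cls.M_MINUS_H, cls.M_MINUS_2H)
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Dict[str, int]:
    """Parse a Hill-notation formula string such as ``"C6H9Cl2O3"``.

    Returns a mapping element symbol -> count.  Unknown element symbols and
    empty formulas raise :class:`FormulaError`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    counts: Dict[str, int] = {}
    pos = 0
    text = text.strip()
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Format element counts in Hill order (C, H, then alphabetical)."""
    _validate(counts)
    parts = []
    symbols = sorted(counts, key=lambda s: (s != "C", s != "H", s))
    for sym in symbols:
        n = counts[sym]
        if n:
            parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def _validate(counts: Mapping[str, int]) -> None:
    if not counts or sum(counts.values()) < 1:
        raise FormulaError("formula must contain at least one atom")
    for sym, n in counts.items():
        if sym not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {sym!r}")
        if n < 0:
            raise FormulaError(f"negative count for {sym}")


def monoisotopic_mass(counts: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da of a neutral formula (sum of atomic masses)."""
    _validate(counts)
    return sum(ELEMENT_MASSES[sym] * n for sym, n in counts.items())


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES into an RDKit molecule, raising a structured error."""
    if not smiles or not smiles.strip():
        raise FormulaError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FormulaError(f"unparsable SMILES: {smiles!r}")
    return mol


def formula_from_smiles(smiles: str) -> Dict[str, int]:
    """Neutral molecular formula (implicit hydrogens included) from SMILES."""
    mol = mol_from_smiles(smiles)
    counts: Dict[str, int] = {}
    n_h = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "H":
            n_h += 1
        else:
            counts[sym] = counts.get(sym, 0) + 1
        n_h += atom.GetTotalNumHs()
    if n_h:
        counts["H"] = counts.get("H", 0) + n_h
    _validate(counts)
    return counts


def add_hydrogens(counts: Mapping[str, int], delta_h: int) -> Dict[str, int]:
    """Shift the hydrogen count of a neutral formula by ``delta_h`` atoms.

    Raises :class:`FormulaError` when the shift would drive H negative
    (an infeasible configuration for that fragment).
    """
    _validate(counts)
    new = dict(counts)
    h = new.get("H", 0) + delta_h
    if h < 0:
        raise FormulaError(
            f"configuration removes {-delta_h} H from formula with "
            f"{counts.get('H', 0)} H: {format_formula(counts)}"
        )
    if h == 0:
        new.pop("H", None)
    else:
        new["H"] = h
    if not new:
        raise FormulaError("no atoms left after hydrogen adjustment")
    return new


def ion_mz(counts: Mapping[str, int], cfg: ChargeConfig) -> float:
    """Theoretical m/z of a neutral formula under one charge configuration.

    m/z = monoisotopic mass + delta_h * m(H) - charge * m(e), |charge| = 1.
    For ``M_PLUS_H`` this equals the neutral mass plus the proton mass.
    """
    mass = monoisotopic_mass(counts)
    if cfg.delta_h < 0 and counts.get("H", 0) < -cfg.delta_h:
        raise FormulaError(
            f"{cfg.name} infeasible for {format_formula(counts)}: "
            f"would remove more hydrogens than present"
        )
    return mass + cfg.delta_h * ELEMENT_MASSES["H"] - cfg.charge * ELECTRON_MASS


def nominal_mz(mz: float) -> int:
    """Nominal (integer) m/z: round half-up, as printed in annotation prose."""
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    return int(mz + 0.5)
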
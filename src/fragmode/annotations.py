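"""Reference fragment annotations for the three model compounds.

Triadimenol (a fungicide, positive mode), gemfibrozil (a lipid-lowering
pharmaceutical, negative mode) and sucralose (an artificial sweetener,
negative mode) are the model organic micro-pollutants whose HCD and UVPD
fragment annotations anchor the workflow: each entry records a neutral
fragment formula, an optional neutral hydrogen shift applied before
ionization (the bracketed "-H"/"-2H" of the written annotation) and the
charge configuration, together with the nominal m/z at which the fragment
was observed.

Four further reported annotations for these compounds print a nominal m/z
one unit away from what their stated formula and charge configuration
compute to ([C8H14N3O+H]+ "at 168", and the sucralose dichloro species
"at 196/197/198"); being internally inconsistent, they are excluded here
rather than forced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .chem import ChargeConfig, add_hydrogens, ion_mz, nominal_mz, parse_formula

__all__ = [
    "AnnotatedFragment",
    "MODEL_COMPOUNDS",
    "ANNOTATED_FRAGMENTS",
    "SECONDARY_ANNOTATIONS",
    "annotation_mz",
]

#: SMILES and ionization polarity of the three model compounds
#: (sucralose is 4,1',6'-trichlorogalactosucrose, C12H19Cl3O8).
MODEL_COMPOUNDS: Dict[str, Tuple[str, str]] = {
    "triadimenol": ("CC(C)(C)C(O)C(Oc1ccc(Cl)cc1)n1cncn1", "positive"),
    "gemfibrozil": ("Cc1ccc(C)c(OCCCC(C)(C)C(=O)O)c1", "negative"),
    "sucralose": ("OCC1OC(OC2(CCl)OC(CCl)C(O)C2O)C(Cl)C(O)C1O", "negative"),
}


@dataclass(frozen=True)
class AnnotatedFragment:
    """One reported fragment annotation.

    ``h_shift`` is the number of hydrogen atoms removed from the neutral
    formula before the charge configuration is applied, so that e.g.
    "[C6H10O4-2H]-H(-)" is formula C6H10O4, h_shift -2, cfg M_MINUS_H.
    """

    compound: str
    formula: str
    h_shift: int
    cfg: ChargeConfig
    nominal: int
    technique: str  # technique(s) under which the fragment was reported


def annotation_mz(a: AnnotatedFragment) -> float:
    """Theoretical m/z of an annotated fragment species."""
    counts = parse_formula(a.formula)
    if a.h_shift:
        counts = add_hydrogens(counts, a.h_shift)
    return ion_mz(counts, a.cfg)


C = ChargeConfig

#: The twelve internally consistent primary annotations.
ANNOTATED_FRAGMENTS: Tuple[AnnotatedFragment, ...] = (
    AnnotatedFragment("triadimenol", "C2H2N3", 0, C.M_PLUS_2H, 70, "HCD+UVPD"),
    AnnotatedFragment("triadimenol", "C6H12O", -1, C.M_PLUS, 99, "HCD+UVPD"),
    AnnotatedFragment("triadimenol", "C7H5ClO", 0, C.M_PLUS_H, 141, "HCD+UVPD"),
    AnnotatedFragment("triadimenol", "C4H5N3O", 0, C.M_PLUS_H, 112, "UVPD"),
    AnnotatedFragment("triadimenol", "C14H18N3O2", 0, C.M_PLUS_H, 261, "UVPD"),
    AnnotatedFragment("triadimenol", "C12H16ClO2", 0, C.M_PLUS, 227, "UVPD"),
    AnnotatedFragment("gemfibrozil", "C8H9O", 0, C.M_MINUS, 121, "HCD+UVPD"),
    AnnotatedFragment("gemfibrozil", "C7H13O2", 0, C.M_MINUS_2H, 127, "HCD+UVPD"),
    AnnotatedFragment("sucralose", "C2H4O2", 0, C.M_MINUS_H, 59, "HCD"),
    AnnotatedFragment("sucralose", "C6H10O4", -2, C.M_MINUS_H, 143, "HCD+UVPD"),
    AnnotatedFragment("sucralose", "C4H7O3", 0, C.M_MINUS_2H, 101, "HCD+UVPD"),
    AnnotatedFragment("sucralose", "C6H10O5", -2, C.M_MINUS_H, 159, "UVPD"),
)

#: Further consistent annotations (kept separate from the primary twelve).
SECONDARY_ANNOTATIONS: Tuple[AnnotatedFragment, ...] = (
    AnnotatedFragment("sucralose", "C3H5O2", 0, C.M_MINUS_2H, 71, "HCD"),
    AnnotatedFragment("sucralose", "C3H5O2", 0, C.M_MINUS, 73, "HCD"),
    AnnotatedFragment("sucralose", "C3H5O3", 0, C.M_MINUS_2H, 87, "HCD"),
    AnnotatedFragment("sucralose", "C6H10O4", 0, C.M_MINUS_2H, 144, "UVPD"),
    AnnotatedFragment("sucralose", "C6H10ClO5", 0, C.M_MINUS_2H, 195, "UVPD"),
)
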
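"""Shared fixtures: model-compound tables and synthetic run builders."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

import fragmode as fm
from fragmode.chem import ChargeConfig as CC


@pytest.fixture(scope="session")
def predicted_tables():
    """Depth-2 predicted-ion tables for the three model compounds."""
    return {
        name: fm.predicted_ion_table(smi, pol, 2)
        for name, (smi, pol) in fm.MODEL_COMPOUNDS.items()
    }


def make_planted_spec(seed: int = 0, **overrides) -> fm.FixtureSpec:
    """A triadimenol run with three planted fragments of known identity.

    Intensities relative to the precursor: the triazolyl cation fragment
    (70 m/z) in every mode, the UVPD-specific 112 m/z fragment in UVPD
    modes only, and the dehalogenated 261 m/z species in long-reaction-time
    UVPD modes.
    """
    modes = fm.default_modes()
    uvpd = tuple(m for m in modes if m.technique == "UVPD")
    fragments = (
        fm.PlantedFragment(
            "C2H2N3", CC.M_PLUS_2H, tuple((str(m), 0.30) for m in modes)
        ),
        fm.PlantedFragment(
            "C4H5N3O", CC.M_PLUS_H, tuple((str(m), 0.20) for m in uvpd)
        ),
        fm.PlantedFragment(
            "C14H18N3O2", CC.M_PLUS_H,
            tuple((str(m), 0.10) for m in uvpd if m.energy >= 200),
        ),
    )
    kwargs = dict(
        smiles=fm.MODEL_COMPOUNDS["triadimenol"][0],
        polarity="positive",
        fragments=fragments,
        seed=seed,
    )
    kwargs.update(overrides)
    return fm.FixtureSpec(**kwargs)


@pytest.fixture()
def planted_spec() -> fm.FixtureSpec:
    return make_planted_spec()


def random_acyclic_smiles(rng: np.random.Generator, n_heavy: int) -> str:
    """A random acyclic molecule: a uniform random tree over heavy atoms."""
    symbols = ["C", "C", "C", "N", "O", "S"]  # carbon-biased draw
    capacity = {"C": 4, "N": 3, "O": 2, "S": 2}
    mol = Chem.RWMol()
    free = []
    for k in range(n_heavy):
        sym = symbols[rng.integers(len(symbols))]
        if k == n_heavy - 1 and n_heavy > 1 and not free:
            sym = "C"
        mol.AddAtom(Chem.Atom(sym))
        free.append(capacity[sym])
    for i in range(1, n_heavy):
        candidates = [j for j in range(i) if free[j] > 0]
        j = int(candidates[rng.integers(len(candidates))])
        mol.AddBond(i, j, Chem.BondType.SINGLE)
        free[j] -= 1
        free[i] -= 1
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return Chem.MolToSmiles(m)
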
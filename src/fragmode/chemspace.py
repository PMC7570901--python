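"""Compound selection in chemical space: fingerprints, clustering, SOM.

To pick a structurally diverse panel of compounds for fragmentation
experiments, every candidate is encoded as a 1024-bit path-based
(extended) fingerprint, pairwise Tanimoto distances are computed, k-means
is run on the distance matrix (each compound's distance row is its feature
vector) with the number of clusters chosen by the elbow method, and a
10x10 self-organizing map serves as an independent check that the
clusters separate in fingerprint space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from sklearn.cluster import KMeans

from .chem import mol_from_smiles

__all__ = [
    "FINGERPRINT_BITS",
    "extended_fingerprint",
    "fingerprint_matrix",
    "tanimoto_distance_matrix",
    "elbow_select_k",
    "kmeans_clusters",
    "kmedoids_clusters",
    "ClusterModel",
    "SOMModel",
    "train_som",
    "map_compounds",
]

logger = logging.getLogger(__name__)

FINGERPRINT_BITS = 1024


def extended_fingerprint(smiles: str, n_bits: int = FINGERPRINT_BITS) -> np.ndarray:
    """1024-bit extended (path-based) fingerprint of a molecule.

    Deterministic for identical canonical structures: two SMILES spellings
    of the same molecule give identical bit vectors.
    """
    mol = mol_from_smiles(smiles)
    bv = Chem.RDKFingerprint(mol, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_matrix(smiles_list: Sequence[str]) -> np.ndarray:
    """Stack fingerprints row-wise into an (n, 1024) binary matrix."""
    return np.vstack([extended_fingerprint(s) for s in smiles_list])


def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto distances 1 - |i AND j| / |i OR j|.

    ``fps`` is an (n, bits) 0/1 matrix, n >= 2.  A pair of all-zero
    fingerprints is treated as identical (distance 0) and logged.
    """
    fps = np.asarray(fps)
    if fps.ndim != 2 or fps.shape[0] < 2:
        raise ValueError("need at least two fingerprints")
    f = fps.astype(np.float64)
    inter = f @ f.T
    card = f.sum(axis=1)
    union = card[:, None] + card[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    if (union == 0).any():
        logger.warning("all-zero fingerprint pair(s): distance defined as 0")
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 1.0)


@dataclass
class ClusterModel:
    """k-means (or k-medoids) result over Tanimoto distance space."""

    k: int
    assignments: np.ndarray  # cluster id per compound, 1..k
    wcss: float
    wcss_curve: Dict[int, float] = field(default_factory=dict)
    method: str = "kmeans"


def _kmeans_wcss(dm: np.ndarray, k: int, seed: int, n_init: int) -> Tuple[np.ndarray, float]:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(dm)
    return labels + 1, float(km.inertia_)


def elbow_select_k(
    dm: np.ndarray,
    k_range: Sequence[int] = range(2, 16),
    seed: int = 0,
    n_init: int = 10,
) -> Tuple[int, Dict[int, float]]:
    """Choose k by the elbow of the within-cluster sum-of-squares curve.

    k-means is fit for each candidate k on the distance-matrix rows; the
    elbow is the candidate of maximum discrete curvature, located as the
    point farthest from the chord joining the normalized WCSS curve's
    endpoints (kneedle-style criterion).  Returns (k, WCSS curve).
    """
    dm = np.asarray(dm, dtype=np.float64)
    n = dm.shape[0]
    ks = sorted(int(k) for k in k_range)
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, n-1]={n - 1}")
    curve: Dict[int, float] = {}
    for k in ks:
        _, wcss = _kmeans_wcss(dm, k, seed, n_init)
        curve[k] = wcss
    if len(ks) == 1:
        return ks[0], curve

    w = np.array([curve[k] for k in ks])
    if np.any(np.diff(w) > 1e-9 * max(w.max(), 1.0)):
        warnings.warn("WCSS curve not monotone non-increasing; elbow may be unstable")
    # normalize both axes to [0, 1] and take the max distance from the chord
    x = (np.array(ks, float) - ks[0]) / max(ks[-1] - ks[0], 1)
    span = w[0] - w[-1]
    y = (w - w[-1]) / span if span > 0 else np.zeros_like(w)
    # distance from point (x, y) to the line through (0, 1) and (1, 0)
    dist = (1.0 - x - y) / np.sqrt(2.0)
    best = int(np.argmax(np.abs(dist)))
    return ks[best], curve


def kmeans_clusters(
    dm: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> ClusterModel:
    """k-means over the Tanimoto distance matrix.

    Each compound is embedded as its row of the distance matrix (what
    coercing a ``dist`` object into k-means computes); multiple seeded
    restarts are run and the best-WCSS solution kept.
    """
    dm = np.asarray(dm, dtype=np.float64)
    n = dm.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n={n}, got {k}")
    labels, wcss = _kmeans_wcss(dm, k, seed, n_init)
    return ClusterModel(k=k, assignments=labels, wcss=wcss, method="kmeans")


def kmedoids_clusters(dm: np.ndarray, k: int, seed: int = 0, n_init: int = 5) -> ClusterModel:
    """PAM-style k-medoids directly on the distance matrix (comparison mode)."""
    dm = np.asarray(dm, dtype=np.float64)
    n = dm.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n={n}, got {k}")
    rng = np.random.default_rng(seed)
    best_cost = np.inf
    best_labels: Optional[np.ndarray] = None
    for _ in range(n_init):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(100):
            labels = np.argmin(dm[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                if members.size == 0:
                    new_medoids[c] = rng.integers(n)
                    continue
                costs = dm[np.ix_(members, members)].sum(axis=0)
                new_medoids[c] = members[int(np.argmin(costs))]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        labels = np.argmin(dm[:, medoids], axis=1)
        cost = dm[np.arange(n), medoids[labels]].sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    assert best_labels is not None
    return ClusterModel(k=k, assignments=best_labels + 1, wcss=float(best_cost), method="kmedoids")


@dataclass
class SOMModel:
    """A trained rectangular self-organizing map over fingerprint space."""

    codebook: np.ndarray  # (rows, cols, dim)
    grid: Tuple[int, int]
    epochs: int
    learning_rate: Tuple[float, float]
    seed: int


def train_som(
    fps: np.ndarray,
    grid: Tuple[int, int] = (10, 10),
    epochs: Optional[int] = None,
    learning_rate: Tuple[float, float] = (0.05, 0.01),
    seed: int = 0,
) -> SOMModel:
    """Train a self-organizing map on fingerprint vectors.

    Rectangular ``grid`` (default 10x10 = 100 nodes), Gaussian neighborhood
    whose radius decays linearly from half the grid diagonal to 1, learning
    rate decaying linearly between the two given values.  ``epochs``
    defaults to 100 x n presentation steps.  Fully deterministic under a
    fixed seed.
    """
    fps = np.asarray(fps, dtype=np.float64)
    if fps.ndim != 2 or fps.shape[0] < 1:
        raise ValueError("need at least one fingerprint")
    n, dim = fps.shape
    rows, cols = grid
    if epochs is None:
        epochs = 100 * n
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(seed)
    codebook = rng.random((rows, cols, dim))
    coords = np.stack(np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij"), axis=-1)

    lr0, lr1 = learning_rate
    sigma0 = max(rows, cols) / 2.0
    order = rng.integers(0, n, size=epochs)
    for t, idx in enumerate(order):
        frac = t / max(epochs - 1, 1)
        lr = lr0 + (lr1 - lr0) * frac
        sigma = max(sigma0 + (1.0 - sigma0) * frac, 0.5)
        x = fps[idx]
        dists = np.linalg.norm(codebook - x, axis=-1)
        bmu = np.unravel_index(np.argmin(dists), dists.shape)
        grid_d2 = ((coords - np.array(bmu)) ** 2).sum(axis=-1)
        h = np.exp(-grid_d2 / (2.0 * sigma**2))
        codebook += lr * h[..., None] * (x - codebook)
    return SOMModel(
        codebook=codebook, grid=grid, epochs=epochs, learning_rate=learning_rate, seed=seed
    )


def map_compounds(model: SOMModel, fps: np.ndarray) -> np.ndarray:
    """Best-matching-unit grid coordinates, shape (n, 2), per compound."""
    fps = np.asarray(fps, dtype=np.float64)
    flat = model.codebook.reshape(-1, model.codebook.shape[-1])
    out = np.empty((fps.shape[0], 2), dtype=np.int64)
    for i, x in enumerate(fps):
        j = int(np.argmin(np.linalg.norm(flat - x, axis=1)))
        out[i] = divmod(j, model.grid[1])
    return out
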
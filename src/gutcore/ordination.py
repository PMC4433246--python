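"""Principal coordinates analysis and Procrustes comparison of
ordinations.

PCoA is classical metric scaling: double-centre the squared distance
matrix, eigendecompose, keep axes in decreasing-eigenvalue order and
scale them by the square roots of the (positive) eigenvalues.  Negative
eigenvalues -- the signature of a non-Euclidean distance -- are reported
untouched rather than corrected away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from skbio import DistanceMatrix


@dataclass
class OrdinationResult:
    samples: pd.DataFrame          # ids x axes, eigenvalue-ordered
    eigenvalues: np.ndarray        # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only
    negative_eigenvalues: np.ndarray


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0))
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    axes = [f"PC{k + 1}" for k in range(coords.shape[1])]
    pos_sum = eigvals[positive].sum()
    prop = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return OrdinationResult(
        samples=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
        negative_eigenvalues=eigvals[eigvals < -tol],
    )


@dataclass
class ProcrustesResult:
    m2: float
    p_value: float
    permutations: int


def _disparity(a: np.ndarray, b: np.ndarray) -> float:
    _, _, d = _scipy_procrustes(a, b)
    return float(d)


def procrustes_test(
    coords_a: pd.DataFrame,
    coords_b: pd.DataFrame,
    permutations: int = 1000,
    seed_or_rng=0,
) -> ProcrustesResult:
    """Optimal superimposition of B onto A with a Monte-Carlo test.

    M^2 is the normalized residual sum of squares after translation,
    rotation and scaling (0 = identical configurations, 1 = no shared
    structure).  Significance: permute the row assignment of B and count
    permuted M^2 values at or below the observed one; p = (b+1)/(B+1).
    """
    common = [s for s in coords_a.index if s in set(coords_b.index)]
    if len(common) != len(coords_a.index) or len(common) != len(coords_b.index):
        raise ValueError("ordinations must cover the same sample ids")
    if len(common) < 3:
        raise ValueError("need at least 3 samples for a Procrustes test")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    k = min(coords_a.shape[1], coords_b.shape[1])
    a = coords_a.loc[common].to_numpy(dtype=float)[:, :k]
    b = coords_b.loc[common].to_numpy(dtype=float)[:, :k]
    m2 = _disparity(a, b)
    hits = 0
    n = len(common)
    for _ in range(permutations):
        perm = rng.permutation(n)
        if _disparity(a, b[perm]) <= m2 + 1e-12:
            hits += 1
    return ProcrustesResult(
        m2=m2, p_value=(hits + 1) / (permutations + 1), permutations=permutations
    )
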
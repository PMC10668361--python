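"""Community ecology statistics: Bray-Curtis, PCoA, PERMANOVA.

PERMANOVA is implemented directly from the sum-of-squares partition of the
squared distance matrix so that permutation scheme, p-value convention
(observed statistic included, ``+1`` in numerator and denominator) and
seeding are fully under the caller's control.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from asvnet.feature_table import FeatureTable


class EcologyError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        mat = self.data.to_numpy(dtype=float)
        if mat.shape[0] != mat.shape[1]:
            raise EcologyError("distance matrix must be square")
        if not np.allclose(mat, mat.T, atol=1e-10):
            raise EcologyError("distance matrix must be symmetric")
        if not np.allclose(np.diag(mat), 0.0, atol=1e-10):
            raise EcologyError("distance matrix diagonal must be zero")
        if np.any(mat < -1e-12):
            raise EcologyError("distances must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, sample_ids: list[str]) -> "DistanceMatrix":
        return DistanceMatrix(self.data.loc[sample_ids, sample_ids])


@dataclass(frozen=True)
class PermanovaResult:
    F: float
    R2: float
    p: float
    n_perm: int
    seed: int | None


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    if table.n_samples < 2:
        raise EcologyError("need at least two samples")
    totals = table.sample_totals()
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise EcologyError(f"all-zero sample(s): {zero}")
    mat = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(
        pd.DataFrame(mat, index=table.data.index, columns=table.data.index)
    )


def pcoa(dm: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates: eigendecomposition of the double-centered
    ``-0.5 * D**2`` matrix.

    Returns coordinates for the positive-eigenvalue axes (sorted by
    descending eigenvalue) and the full eigenvalue spectrum; negative
    eigenvalues are reported but never embedded.
    """
    d2 = dm.values ** 2
    n = d2.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > 1e-10
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    columns = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=dm.data.index, columns=columns), eigvals


def _permanova_ss(d2: np.ndarray, group_indices: list[np.ndarray]) -> float:
    """Within-group sum of squares: sum over groups of within-pair d^2 / n_g."""
    ss_within = 0.0
    for idx in group_indices:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * len(idx))
    return ss_within


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA with a permutation p-value.

    ``SS_total = sum_{i<j} d_ij^2 / n``; within-group SS analogous per
    group; pseudo-F uses (k-1, n-k) degrees of freedom;
    ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)``.
    """
    labels = pd.Series(labels, index=dm.data.index).astype(str)
    n = len(labels)
    groups = labels.unique()
    k = len(groups)
    if k < 2:
        raise EcologyError("need at least two groups")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise EcologyError(f"groups with fewer than 2 samples: {small}")

    d2 = dm.values ** 2
    ss_total = d2.sum() / (2.0 * n)
    codes = labels.map({g: i for i, g in enumerate(groups)}).to_numpy()

    def f_stat(code_vec: np.ndarray) -> float:
        idx = [np.where(code_vec == g)[0] for g in range(k)]
        ss_within = _permanova_ss(d2, idx)
        ss_between = ss_total - ss_within
        if ss_within == 0:  # perfect separation
            return np.inf
        return (ss_between / (k - 1)) / (ss_within / (n - k))

    f_obs = f_stat(codes)
    idx_obs = [np.where(codes == g)[0] for g in range(k)]
    ss_within_obs = _permanova_ss(d2, idx_obs)
    r2 = (ss_total - ss_within_obs) / ss_total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(codes)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return PermanovaResult(F=float(f_obs), R2=float(r2), p=float(p),
                           n_perm=n_perm, seed=seed)


def permanova_pairwise(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """One-way PERMANOVA for every unordered pair of groups.

    No multiplicity correction is applied: each pair is reported raw.
    """
    labels = pd.Series(labels, index=dm.data.index).astype(str)
    rows = []
    for g1, g2 in combinations(sorted(labels.unique()), 2):
        ids = labels[labels.isin([g1, g2])].index.tolist()
        sub = dm.subset(ids)
        res = permanova(sub, labels.loc[ids], n_perm=n_perm, seed=seed)
        rows.append({"group_a": g1, "group_b": g2, "F": res.F, "R2": res.R2,
                     "p": res.p, "n_perm": n_perm, "seed": seed})
    return pd.DataFrame(rows)


def percent_change(baseline: float, value: float) -> int:
    """Percent decrease from baseline, rounded to the nearest integer.

    ``100 * (1 - value / baseline)``; negative results indicate an increase.
    """
    if baseline <= 0:
        raise EcologyError("baseline must be positive")
    return int(round(100.0 * (1.0 - value / baseline)))
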
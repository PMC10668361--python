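"""Synthetic grouped ASV count tables with planted correlation structure.

The generator uses a Gaussian copula: a latent multivariate normal with a
block correlation matrix (planted modules, plus designated connector taxa
correlated with foreign modules) is pushed through log-normal marginal
quantiles, closed to relative abundances, and sampled as multinomial counts
at Poisson library sizes.  Because all downstream statistics are rank- or
distance-based, the marginal family is immaterial; what matters is the
controllable rank correlation, which for a Gaussian copula with latent
correlation ``rho`` converges to ``(6/pi) * arcsin(rho/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from asvnet.feature_table import FeatureTable, SampleMetadata


class SyntheticSpecError(ValueError):
    """Invalid generator specification."""


@dataclass
class SyntheticSpec:
    """Specification for a grouped count table with planted structure.

    ``module_sizes`` partitions the first ``sum(module_sizes)`` ASVs into
    correlation blocks; the remaining ASVs are uncorrelated background.
    ``connector_asvs`` maps ASV indices to the foreign module ids they are
    additionally correlated with (at ``rho_cross``).  ``effect_asvs`` have
    their mean abundance multiplied by ``effect_size`` in ``effect_group``.
    """

    n_samples_per_group: int = 10
    group_names: list[str] = field(default_factory=lambda: ["LT", "LTB", "HT", "HTB"])
    n_asvs: int = 300
    module_sizes: list[int] = field(default_factory=list)
    rho_within: float = 0.85
    connector_asvs: list[tuple[int, list[int]]] = field(default_factory=list)
    rho_cross: float = 0.75
    effect_asvs: list[int] = field(default_factory=list)
    effect_group: str | None = None
    effect_size: float = 1.0
    base_logmean: float = 0.0
    base_logsd: float = 1.0
    depth_mean: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1 or self.n_asvs < 1:
            raise SyntheticSpecError("need at least one sample and one ASV")
        if sum(self.module_sizes) > self.n_asvs:
            raise SyntheticSpecError("module sizes sum exceeds n_asvs")
        if any(s < 1 for s in self.module_sizes):
            raise SyntheticSpecError("module sizes must be positive")
        if not 0 <= self.rho_within < 1:
            raise SyntheticSpecError("rho_within must lie in [0, 1)")
        if not 0 <= self.rho_cross < 1:
            raise SyntheticSpecError("rho_cross must lie in [0, 1)")
        if self.effect_size <= 0:
            raise SyntheticSpecError("effect_size must be positive")
        if self.depth_mean <= 0:
            raise SyntheticSpecError("depth_mean must be positive")
        if len(set(self.group_names)) != len(self.group_names):
            raise SyntheticSpecError("duplicate group names")
        if self.effect_group is not None and self.effect_group not in self.group_names:
            raise SyntheticSpecError(f"unknown effect group {self.effect_group!r}")
        n_modules = len(self.module_sizes)
        for asv, foreign in self.connector_asvs:
            if not 0 <= asv < self.n_asvs:
                raise SyntheticSpecError(f"connector ASV index {asv} out of range")
            for m in foreign:
                if not 0 <= m < n_modules:
                    raise SyntheticSpecError(f"unknown foreign module {m}")
            if self.module_of(asv) in foreign:
                raise SyntheticSpecError(
                    f"connector {asv} lists its own module as foreign"
                )
        for asv in self.effect_asvs:
            if not 0 <= asv < self.n_asvs:
                raise SyntheticSpecError(f"effect ASV index {asv} out of range")

    @property
    def asv_ids(self) -> list[str]:
        width = max(4, len(str(self.n_asvs)))
        return [f"ASV{i:0{width}d}" for i in range(self.n_asvs)]

    def module_of(self, asv_index: int) -> int | None:
        """Planted module id for an ASV index, or None for background."""
        offset = 0
        for mid, size in enumerate(self.module_sizes):
            if offset <= asv_index < offset + size:
                return mid
            offset += size
        return None

    def module_members(self, module_id: int) -> list[int]:
        offset = sum(self.module_sizes[:module_id])
        return list(range(offset, offset + self.module_sizes[module_id]))


@dataclass
class GroundTruth:
    """Planted structure actually used for a generated table."""

    module_of: dict[str, str]          # asv id -> module label or "none"
    connector_set: set[str]
    differential_set: set[str]
    latent_correlation: pd.DataFrame   # symmetric, unit diagonal

    def __post_init__(self) -> None:
        mat = self.latent_correlation.to_numpy()
        if not np.allclose(mat, mat.T, atol=1e-10):
            raise SyntheticSpecError("latent correlation must be symmetric")
        if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
            raise SyntheticSpecError("latent correlation must have unit diagonal")


def nearest_psd(matrix: np.ndarray, eig_floor: float = 0.0) -> np.ndarray:
    """Clip negative eigenvalues to ``eig_floor`` and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(matrix)
    vals = np.clip(vals, eig_floor, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def build_latent_correlation(spec: SyntheticSpec) -> np.ndarray:
    """Block latent correlation matrix implied by a spec.

    ``rho_within`` inside each module block, ``rho_cross`` between every
    connector and all members of its foreign modules, zero elsewhere, unit
    diagonal.  Projected to the nearest PSD matrix (eigenvalue clipping)
    when the raw construction has eigenvalues below -1e-10.
    """
    n = spec.n_asvs
    corr = np.zeros((n, n))
    for mid in range(len(spec.module_sizes)):
        members = spec.module_members(mid)
        for i in members:
            for j in members:
                if i != j:
                    corr[i, j] = spec.rho_within
    for asv, foreign in spec.connector_asvs:
        for mid in foreign:
            for j in spec.module_members(mid):
                if j != asv:
                    corr[asv, j] = spec.rho_cross
                    corr[j, asv] = spec.rho_cross
    np.fill_diagonal(corr, 1.0)
    min_eig = np.linalg.eigvalsh(corr).min()
    if min_eig < -1e-10:
        corr = nearest_psd(corr)
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise SyntheticSpecError("latent correlation not PSD after repair")
    return corr


def ground_truth(spec: SyntheticSpec) -> GroundTruth:
    """Materialize the planted structure (module map, connectors, effects)."""
    ids = spec.asv_ids
    module_map = {}
    for i, asv in enumerate(ids):
        mid = spec.module_of(i)
        module_map[asv] = "none" if mid is None else f"M{mid}"
    corr = build_latent_correlation(spec)
    return GroundTruth(
        module_of=module_map,
        connector_set={ids[a] for a, _ in spec.connector_asvs},
        differential_set={ids[a] for a in spec.effect_asvs},
        latent_correlation=pd.DataFrame(corr, index=ids, columns=ids),
    )


def gaussian_copula_spearman(rho: float) -> float:
    """Population Spearman correlation induced by latent Gaussian ``rho``."""
    return (6.0 / np.pi) * np.arcsin(rho / 2.0)


def sample_counts(
    spec: SyntheticSpec, truth: GroundTruth | None = None
) -> tuple[FeatureTable, SampleMetadata]:
    """Draw a grouped count table from the copula model.

    Per sample: latent MVN scores with the planted correlation -> log-normal
    quantile map (mean shifted by ``log(effect_size)`` for effect ASVs in
    the effect group) -> closure to relative abundances -> multinomial
    counts at a Poisson(``depth_mean``) library size.  Deterministic under
    ``spec.seed``.
    """
    if truth is None:
        truth = ground_truth(spec)
    corr = truth.latent_correlation.to_numpy()
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-8:
        raise SyntheticSpecError("latent correlation matrix is not PSD")
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))

    rng = np.random.default_rng(spec.seed)
    ids = spec.asv_ids
    rows, sample_ids, meta_rows = [], [], []
    for group in spec.group_names:
        mu = np.full(spec.n_asvs, spec.base_logmean)
        if spec.effect_group == group:
            mu[spec.effect_asvs] += np.log(spec.effect_size)
        for rep in range(spec.n_samples_per_group):
            z = factor @ rng.standard_normal(spec.n_asvs)
            abundance = np.exp(mu + spec.base_logsd * z)
            rel = abundance / abundance.sum()
            depth = rng.poisson(spec.depth_mean)
            rows.append(rng.multinomial(depth, rel))
            sid = f"{group}_s{rep + 1:02d}"
            sample_ids.append(sid)
            meta_rows.append(_group_metadata(group))
    table = FeatureTable(pd.DataFrame(rows, index=sample_ids, columns=ids))
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    return table, SampleMetadata(meta)


def _group_metadata(group: str) -> dict[str, str]:
    """Heuristic metadata columns for LT/LTB/HT/HTB-style group labels."""
    temperature = treatment = "NA"
    if group.upper().startswith("L"):
        temperature = "27C"
    elif group.upper().startswith("H"):
        temperature = "31C"
    if temperature != "NA":
        treatment = "bacteria" if group.upper().endswith("B") else "placebo"
    return {"group": group, "timepoint": "T2T3",
            "temperature": temperature, "treatment": treatment}


# ---------------------------------------------------------------------------
# Ground-truth export / import
# ---------------------------------------------------------------------------

def export_truth(truth: GroundTruth, directory) -> None:
    """Write module map, connector set and differential set as TSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    modules = pd.DataFrame(
        {"asv": list(truth.module_of), "module": list(truth.module_of.values())}
    )
    modules.to_csv(directory / "truth_modules.tsv", sep="\t", index=False)
    pd.DataFrame({"asv": sorted(truth.connector_set)}).to_csv(
        directory / "truth_connectors.tsv", sep="\t", index=False
    )
    pd.DataFrame({"asv": sorted(truth.differential_set)}).to_csv(
        directory / "truth_differential.tsv", sep="\t", index=False
    )
    corr = truth.latent_correlation.copy()
    corr.index.name = "asv"
    corr.to_csv(directory / "truth_latent_correlation.tsv", sep="\t")


def load_truth(directory) -> GroundTruth:
    directory = Path(directory)
    modules = pd.read_csv(directory / "truth_modules.tsv", sep="\t", dtype=str)
    connectors = pd.read_csv(directory / "truth_connectors.tsv", sep="\t", dtype=str)
    differential = pd.read_csv(directory / "truth_differential.tsv", sep="\t", dtype=str)
    corr = pd.read_csv(
        directory / "truth_latent_correlation.tsv", sep="\t", index_col=0
    )
    return GroundTruth(
        module_of=dict(zip(modules["asv"], modules["module"])),
        connector_set=set(connectors["asv"].dropna()),
        differential_set=set(differential["asv"].dropna()),
        latent_correlation=corr,
    )
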
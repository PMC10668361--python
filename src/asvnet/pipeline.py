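"""End-to-end pipeline: filters -> PERMANOVA -> per-group networks ->
topology/nulls -> node roles -> cross-network KS comparisons.

Everything is driven by a :class:`PipelineConfig`; all stochastic stages
draw their seeds deterministically from the master seed by stable hashing
of stage names, so re-running with the same config reproduces every output
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from asvnet import feature_table as ft
from asvnet import ecology, network, roles, synthetic, topology
from asvnet._util import derive_seed, logger


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds; defaults are the standard ones
    (0.005% abundance, 30% prevalence, |rho| > 0.7, p < 0.05, Zi 2.5,
    Pi 0.62, 999 permutations, 1000 random graphs, 10,000 bootstraps)."""

    table_path: str = ""
    metadata_path: str = ""
    output_dir: str = "results"
    group_column: str = "group"
    network_groups: list[str] = field(default_factory=list)  # empty = all groups
    min_relative_abundance: float = 0.00005
    min_prevalence: float = 0.30
    rho_threshold: float = 0.7
    p_threshold: float = 0.05
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62
    n_perm: int = 999
    n_random: int = 1000
    n_boot: int = 10_000
    rarefaction_depth: int | None = None  # None = minimum sample total
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value, lo, hi in [
            ("min_relative_abundance", self.min_relative_abundance, 0, 1),
            ("min_prevalence", self.min_prevalence, 0, 1),
            ("rho_threshold", self.rho_threshold, 0, 1),
            ("p_threshold", self.p_threshold, 0, 1),
        ]:
            if not lo <= value <= hi:
                raise PipelineError(f"{name} must lie in [{lo}, {hi}]")
        if min(self.n_perm, self.n_random, self.n_boot) < 1:
            raise PipelineError("n_perm, n_random and n_boot must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a result bundle of paths/objects.

    Stages: load -> abundance filter -> rarefy -> Bray-Curtis + PCoA +
    pairwise PERMANOVA on the whole design -> per-group prevalence filter,
    Spearman network, topology with E-R baseline, node roles -> KS
    comparisons for every network pair x {degree, betweenness, closeness}.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}

    def stage_seed(name: str) -> int:
        s = derive_seed(config.seed, name)
        log["stages"].setdefault(name, {})["seed"] = s
        return s

    # ---- load ------------------------------------------------------------
    try:
        table = ft.read_feature_table(config.table_path)
        metadata = ft.read_metadata(config.metadata_path)
        metadata.check_covers(table)
    except Exception as exc:
        raise PipelineError(f"stage load: {exc}") from exc
    groups = metadata.groups().loc[table.sample_ids]
    network_groups = config.network_groups or sorted(groups.unique())
    unknown = set(network_groups) - set(groups.unique())
    if unknown:
        raise PipelineError(f"stage config: unknown groups {sorted(unknown)}")

    # ---- abundance filter + rarefaction ----------------------------------
    filtered = ft.filter_min_relative_abundance(
        table, config.min_relative_abundance)
    log["stages"]["abundance_filter"] = {
        "asvs_in": table.n_asvs, "asvs_out": filtered.n_asvs}
    depth = config.rarefaction_depth or ft.default_rarefaction_depth(filtered)
    rarefied = ft.rarefy(filtered, depth, seed=stage_seed("rarefy"))
    log["stages"]["rarefy"].update({
        "depth": depth, "samples_in": filtered.n_samples,
        "samples_out": rarefied.n_samples})
    ft.write_feature_table(rarefied, out / "filtered_table.tsv")

    # ---- community comparison -------------------------------------------
    dm = ecology.bray_curtis(rarefied)
    dm_df = dm.data.copy()
    dm_df.index.name = "sample_id"
    dm_df.to_csv(out / "distance_matrix.tsv", sep="\t")
    coords, eigvals = ecology.pcoa(dm)
    coords.index.name = "sample_id"
    coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    rarefied_groups = groups.loc[rarefied.sample_ids]
    permanova_table = ecology.permanova_pairwise(
        dm, rarefied_groups, n_perm=config.n_perm,
        seed=stage_seed("permanova"))
    permanova_table.to_csv(out / "permanova_pairwise.tsv", sep="\t", index=False)

    # ---- per-group networks ----------------------------------------------
    summaries, role_tables, attrs, connector_rows = {}, {}, {}, []
    for group in network_groups:
        sample_ids = rarefied_groups[rarefied_groups == group].index.tolist()
        sub = ft.FeatureTable(rarefied.data.loc[sample_ids])
        prevalent = ft.filter_prevalence(sub, config.min_prevalence)
        log["stages"][f"network:{group}"] = {
            "samples": len(sample_ids),
            "asvs_in": sub.n_asvs, "asvs_prevalent": prevalent.n_asvs}
        graph, edges = network.network_from_table(
            prevalent, config.rho_threshold, config.p_threshold)
        log["stages"][f"network:{group}"].update({
            "nodes": graph.number_of_nodes(), "edges": graph.number_of_edges()})
        network.export_network(graph,
                               graphml_path=out / f"network_{group}.graphml",
                               edges_path=out / f"edges_{group}.csv")
        if graph.number_of_nodes() == 0:
            logger.warning("network %s is empty; skipping topology/roles", group)
            continue
        partition = roles.detect_modules(graph)
        role_table = roles.node_role_table(graph, partition)
        role_table.to_csv(out / f"node_roles_{group}.csv")
        role_tables[group] = role_table
        summary = topology.network_metrics(graph, partition)
        topology.attach_er_baseline(summary, n_random=config.n_random,
                                    seed=stage_seed(f"er:{group}"))
        summaries[group] = summary
        attrs[group] = topology.node_attributes(graph)
        counts = roles.role_counts(role_table)
        connector_rows.append({"network": group, **counts.to_dict()})

    if summaries:
        topo = pd.DataFrame(
            {g: s.as_dict() for g, s in summaries.items()}).T
        topo.index.name = "network"
        topo.to_csv(out / "topology_summary.tsv", sep="\t")
    pd.DataFrame(connector_rows).to_csv(
        out / "role_counts.tsv", sep="\t", index=False)

    # ---- cross-network KS comparisons ------------------------------------
    ks_rows = []
    for g1, g2 in combinations(sorted(attrs), 2):
        for attribute in ("degree", "betweenness", "closeness"):
            comp = topology.ks_bootstrap_compare(
                attrs[g1][attribute].to_numpy(),
                attrs[g2][attribute].to_numpy(),
                attribute=attribute, n_boot=config.n_boot,
                seed=stage_seed(f"ks:{g1}:{g2}:{attribute}"))
            ks_rows.append({"network_a": g1, "network_b": g2,
                            **comp.as_dict()})
    ks_table = pd.DataFrame(ks_rows)
    ks_table.to_csv(out / "ks_comparisons.tsv", sep="\t", index=False)

    with open(out / "pipeline_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)

    return {
        "table": rarefied,
        "distance_matrix": dm,
        "pcoa": coords,
        "pcoa_eigenvalues": eigvals,
        "permanova": permanova_table,
        "topology": summaries,
        "roles": role_tables,
        "node_attributes": attrs,
        "ks": ks_table,
        "log": log,
        "output_dir": str(out),
    }


def make_demo(seed: int, directory) -> Path:
    """Generate the demo fixture: 4 groups x 10 samples, 300 ASVs,
    3 planted modules, 2 connectors, one group effect.

    Writes the count table, metadata, ground truth and a scaled-down
    config (small null ensembles/bootstraps so the demo runs in seconds).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = synthetic.SyntheticSpec(
        n_samples_per_group=10,
        group_names=["LT", "LTB", "HT", "HTB"],
        n_asvs=300,
        module_sizes=[10, 8, 8],
        rho_within=0.85,
        connector_asvs=[(26, [0, 1]), (27, [1, 2])],
        rho_cross=0.6,
        effect_asvs=list(range(40, 100)),
        effect_group="HT",
        effect_size=4.0,
        base_logmean=0.0,
        base_logsd=1.0,
        depth_mean=10_000,
        seed=seed,
    )
    truth = synthetic.ground_truth(spec)
    table, metadata = synthetic.sample_counts(spec, truth)
    ft.write_feature_table(table, directory / "table.tsv")
    ft.write_metadata(metadata, directory / "metadata.tsv")
    synthetic.export_truth(truth, directory / "truth")
    config = PipelineConfig(
        table_path=str(directory / "table.tsv"),
        metadata_path=str(directory / "metadata.tsv"),
        output_dir=str(directory / "results"),
        n_perm=199,
        n_random=50,
        n_boot=500,
        seed=seed,
    )
    config.to_yaml(directory / "config.yaml")
    return directory
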
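"""Module detection and Zi-Pi node-role classification.

Nodes are partitioned by deterministic greedy modularity maximization
(Clauset-Newman-Moore) and classified by within-module connectivity
``Zi = (k_is - mean_ks) / sd_ks`` (population standard deviation; ``Zi = 0``
when the module's within-degree spread is zero) and the participation
coefficient ``Pi = 1 - sum_s (k_s / k)^2``.  Roles follow the four-way
scheme: network hub (Zi > 2.5, Pi > 0.62), module hub (Zi > 2.5,
Pi < 0.62), connector (Zi < 2.5, Pi > 0.62), peripheral otherwise; exact
boundary values fall to the lower category.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from asvnet._util import logger

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

ROLE_NETWORK_HUB = "network hub"
ROLE_MODULE_HUB = "module hub"
ROLE_CONNECTOR = "connector"
ROLE_PERIPHERAL = "peripheral"


class RolesError(ValueError):
    pass


@dataclass(frozen=True)
class ModulePartition:
    """Node -> module id assignment plus its modularity Q."""

    module_of: dict
    modularity: float

    @property
    def modules(self) -> dict:
        out: dict = {}
        for node, mid in self.module_of.items():
            out.setdefault(mid, set()).add(node)
        return out

    def as_sets(self) -> list[set]:
        return [members for _, members in sorted(self.modules.items())]


def detect_modules(graph: nx.Graph) -> ModulePartition:
    """Greedy (Clauset-Newman-Moore) modularity maximization.

    Deterministic for a fixed node/edge insertion order; module ids are
    assigned by (descending size, lexicographically smallest member) so
    labels are stable across runs.
    """
    if graph.number_of_nodes() == 0:
        raise RolesError("empty network")
    if graph.number_of_edges() == 0:
        communities = [{n} for n in sorted(graph.nodes)]
    else:
        communities = [
            set(c) for c in nx.community.greedy_modularity_communities(graph)
        ]
    communities.sort(key=lambda c: (-len(c), min(map(str, c))))
    module_of = {node: mid for mid, members in enumerate(communities)
                 for node in members}
    q = nx.community.modularity(graph, communities) if graph.number_of_edges() else 0.0
    return ModulePartition(module_of=module_of, modularity=float(q))


def module_degree_stats(graph: nx.Graph, partition: ModulePartition) -> pd.DataFrame:
    """Per-node degree decomposition over modules.

    Columns: ``degree``, ``k_within`` (links into the node's own module)
    and ``k_to_module`` (dict module id -> link count; sums to degree).
    """
    rows = []
    for node in graph.nodes:
        own = partition.module_of[node]
        k_to_module: dict = {}
        for nbr in graph.neighbors(node):
            mid = partition.module_of[nbr]
            k_to_module[mid] = k_to_module.get(mid, 0) + 1
        rows.append({
            "node": node,
            "module": own,
            "degree": graph.degree(node),
            "k_within": k_to_module.get(own, 0),
            "k_to_module": k_to_module,
        })
    return pd.DataFrame(rows).set_index("node")


def within_module_z(stats: pd.DataFrame) -> pd.Series:
    """Zi: z-score of within-module degree against the node's module.

    Uses the population standard deviation; a module whose members all have
    the same within-degree yields Zi = 0 for every member.
    """
    zi = pd.Series(0.0, index=stats.index)
    for _, members in stats.groupby("module"):
        k_within = members["k_within"].to_numpy(dtype=float)
        mean, sd = k_within.mean(), k_within.std(ddof=0)
        if sd > 0:
            zi.loc[members.index] = (k_within - mean) / sd
    return zi.rename("Zi")


def participation(stats: pd.DataFrame) -> pd.Series:
    """Pi = 1 - sum over modules of (links-to-module / degree)^2."""
    values = {}
    for node, row in stats.iterrows():
        k = row["degree"]
        if k == 0:
            raise RolesError(f"isolated node {node!r} in role computation")
        values[node] = 1.0 - sum((ks / k) ** 2 for ks in row["k_to_module"].values())
    return pd.Series(values, name="Pi")


def classify_roles(zi: pd.Series, pi: pd.Series) -> pd.Series:
    """Four-way role labels from strict Zi/Pi thresholds.

    Values exactly on a threshold go to the lower category (the defining
    inequalities are strict on both sides, leaving equality undefined);
    such boundary nodes are logged.
    """
    roles = {}
    for node in zi.index:
        z, p = zi[node], pi[node]
        if z == ZI_THRESHOLD or p == PI_THRESHOLD:
            logger.info("node %s on role boundary (Zi=%g, Pi=%g); "
                        "assigned to lower category", node, z, p)
        high_z = z > ZI_THRESHOLD
        high_p = p > PI_THRESHOLD
        if high_z and high_p:
            roles[node] = ROLE_NETWORK_HUB
        elif high_z:
            roles[node] = ROLE_MODULE_HUB
        elif high_p:
            roles[node] = ROLE_CONNECTOR
        else:
            roles[node] = ROLE_PERIPHERAL
    return pd.Series(roles, name="role")


def node_role_table(
    graph: nx.Graph, partition: ModulePartition | None = None
) -> pd.DataFrame:
    """Full per-node role table: module, Zi, Pi, role."""
    if partition is None:
        partition = detect_modules(graph)
    stats = module_degree_stats(graph, partition)
    zi = within_module_z(stats)
    pi = participation(stats)
    roles = classify_roles(zi, pi)
    out = pd.DataFrame({
        "module": stats["module"],
        "degree": stats["degree"],
        "Zi": zi,
        "Pi": pi,
        "role": roles,
    })
    out.index.name = "asv"
    return out.sort_index()


def role_counts(role_table: pd.DataFrame) -> pd.Series:
    all_roles = [ROLE_NETWORK_HUB, ROLE_MODULE_HUB, ROLE_CONNECTOR, ROLE_PERIPHERAL]
    counts = role_table["role"].value_counts()
    return counts.reindex(all_roles, fill_value=0).astype(np.int64)
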
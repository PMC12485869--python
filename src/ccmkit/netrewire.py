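"""Comparative network rewiring: feature integration, per-node edit
scores between two condition networks, LFC weighting and nomination.

A condition network is a set of typed directed edges
``(source, relation, target)`` as emitted by causal-network inference in
SIF form.  The rewiring score of a node is the number of incident edges
that would need to be added or removed to transform its connectivity in
one condition into the other — the size of the symmetric difference of
its incident-edge sets.  Edge identity includes the relation label and
orientation, so a change from activation to inhibition counts as one
removal plus one addition.

Scores are weighted by the node's log-fold change (LFC) under the
condition of interest (negatives clipped to 0 by default, prioritising
nodes both highly rewired and upregulated), and the top-``n`` nodes are
nominated under a deterministic tie-break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .simkit import ConditionNetwork

log = logging.getLogger(__name__)

__all__ = [
    "ConditionNetwork", "RewiringScore", "integrate_features", "read_sif",
    "write_sif", "rewiring_score", "weighted_rewiring", "nominate_top_nodes",
    "to_networkx",
]


@dataclass(frozen=True)
class RewiringScore:
    node: str
    raw_rewiring: int            # incident-edge symmetric-difference size
    degree_union: int
    normalized_rewiring: float   # raw / union (0 when union empty)
    lfc: float = float("nan")
    weighted_score: float = float("nan")
    rank: int | None = None


def integrate_features(features: pd.DataFrame, lfc_threshold: float = 1.0,
                       use_absolute: bool = False) -> pd.DataFrame:
    """Merge multi-assay features with proteomic precedence, then filter.

    For nodes reported by both assays the protein record is kept and the
    transcript record discarded; records must then have
    ``lfc >= lfc_threshold`` (or ``|lfc| >=`` with ``use_absolute``).
    Conflicting duplicate records within one assay raise.
    """
    required = {"node", "assay", "lfc"}
    if not required.issubset(features.columns):
        raise ValueError(f"feature table needs columns {sorted(required)}")
    if features.empty:
        return features.copy()
    keys = [c for c in ("node", "assay", "condition") if c in features.columns]
    dup = features.duplicated(subset=keys, keep=False)
    if dup.any():
        conflicting = features[dup].groupby(keys)["lfc"].nunique()
        if (conflicting > 1).any():
            bad = conflicting[conflicting > 1].index[0]
            raise ValueError(f"conflicting duplicate feature records for {bad}")
        features = features.drop_duplicates(subset=keys)

    group = [c for c in ("node", "condition") if c in features.columns]
    def pick(sub: pd.DataFrame) -> pd.DataFrame:
        protein = sub[sub["assay"] == "protein"]
        return protein if not protein.empty else sub
    kept = features.groupby(group, group_keys=False)[features.columns.tolist()].apply(pick)
    lfc = kept["lfc"].abs() if use_absolute else kept["lfc"]
    return kept[lfc >= lfc_threshold].reset_index(drop=True)


def read_sif(path, condition: str | None = None) -> ConditionNetwork:
    """Parse a SIF edge list (3 whitespace-delimited tokens per line).

    Blank and ``#`` lines are skipped; duplicate triples are collapsed
    with a log entry; a line without exactly 3 tokens raises with its
    line number.
    """
    path = Path(path)
    edges = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tokens "
                                 f"(source relation target), got {len(tokens)}")
            e = tuple(tokens)
            if e in edges:
                n_dup += 1
            edges.add(e)
    if n_dup:
        log.warning("read_sif(%s): collapsed %d duplicate edge line(s)", path, n_dup)
    return ConditionNetwork(condition or path.stem, frozenset(edges))


def write_sif(net: ConditionNetwork, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for s, rel, t in sorted(net.edges):
            fh.write(f"{s}\t{rel}\t{t}\n")
    return path


def rewiring_score(net_a: ConditionNetwork, net_b: ConditionNetwork,
                   node: str) -> RewiringScore:
    """Edge-edit distance of one node's connectivity between two networks.

    ``raw_rewiring`` is the size of the symmetric difference of the
    node's incident-edge sets; ``degree_union`` the size of their union.
    A node present in only one network scores its full degree there.
    """
    if node not in net_a.nodes and node not in net_b.nodes:
        raise KeyError(f"node {node!r} absent from both networks")
    inc_a = net_a.incident_edges(node)
    inc_b = net_b.incident_edges(node)
    raw = len(inc_a ^ inc_b)
    union = len(inc_a | inc_b)
    return RewiringScore(node=node, raw_rewiring=raw, degree_union=union,
                         normalized_rewiring=raw / union if union else 0.0)


def weighted_rewiring(net_a: ConditionNetwork, net_b: ConditionNetwork,
                      lfc, weighting: str = "clipped") -> pd.DataFrame:
    """Score every node of either network and rank by LFC-weighted rewiring.

    ``lfc`` maps node -> log-fold change under the condition of interest
    (a mapping, Series, or feature DataFrame with ``node``/``lfc``
    columns); nodes without an LFC are weighted 0 and logged.
    Weightings: ``clipped`` (default) ``raw * max(lfc, 0)``; ``signed``
    ``raw * lfc``; ``normalized`` ``normalized_rewiring * max(lfc, 0)``.
    Ties break by raw rewiring, then node name.
    """
    if weighting not in ("clipped", "signed", "normalized"):
        raise ValueError("weighting must be 'clipped', 'signed' or 'normalized'")
    if isinstance(lfc, pd.DataFrame):
        lfc = lfc.set_index("node")["lfc"]
    lfc = dict(pd.Series(lfc, dtype=float))

    nodes = sorted(net_a.nodes | net_b.nodes)
    missing = [n for n in nodes if n not in lfc]
    if missing:
        log.info("weighted_rewiring: %d node(s) without LFC treated as 0", len(missing))

    rows = []
    for node in nodes:
        rs = rewiring_score(net_a, net_b, node)
        node_lfc = float(lfc.get(node, 0.0))
        if weighting == "clipped":
            w = rs.raw_rewiring * max(node_lfc, 0.0)
        elif weighting == "signed":
            w = rs.raw_rewiring * node_lfc
        else:
            w = rs.normalized_rewiring * max(node_lfc, 0.0)
        rows.append({"node": node, "raw_rewiring": rs.raw_rewiring,
                     "degree_union": rs.degree_union,
                     "normalized_rewiring": rs.normalized_rewiring,
                     "lfc": node_lfc, "weighted_score": w})
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["weighted_score", "raw_rewiring", "node"],
        ascending=[False, False, True], kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = range(1, len(table) + 1)
    return table


def nominate_top_nodes(ranked: pd.DataFrame, n: int = 14) -> list[str]:
    """The first ``n`` nodes of a ranked rewiring table (warns if short)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(ranked):
        log.warning("nominate_top_nodes: requested %d of %d nodes; returning all",
                    n, len(ranked))
    return ranked["node"].head(n).tolist()


def to_networkx(net: ConditionNetwork):
    """Export a ConditionNetwork as a networkx MultiDiGraph (for viewers)."""
    import networkx as nx

    g = nx.MultiDiGraph(condition=net.condition)
    for s, rel, t in sorted(net.edges):
        g.add_edge(s, t, relation=rel)
    return g
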
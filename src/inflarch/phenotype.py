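"""Marker normalization and phenotype assignment.

Cell phenotypes follow the murine myeloid gating used for zymosan-induced
paw inflammation: macrophages are F4-80+ SiglecF- and split by
costimulatory/scavenger markers into M1-like (CD86+ CD206-), M0
(CD86+ CD206+) and M2-like (CD86- CD206+); neutrophils are Ly6G+,
eosinophils SiglecF+, dendritic cells CD11c+ F4-80-.  Gates are applied
on z-scored mean intensities with a configurable "+" threshold
(default z > 0).  A k-nearest-neighbour/modularity clustering is offered
as an annotation-free alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GatingRule",
    "ClusteringParams",
    "DEFAULT_GATING_RULES",
    "RESERVED_COLUMNS",
    "marker_columns",
    "zscore_normalize",
    "assign_phenotypes",
    "cluster_cells",
    "load_rules_yaml",
    "save_rules_yaml",
]

RESERVED_COLUMNS = ("cell_id", "x", "y", "area", "phenotype")


@dataclass(frozen=True)
class GatingRule:
    """Required marker signs defining one phenotype.

    Rules are evaluated in ascending ``priority``; the first rule whose
    pattern matches wins.
    """

    phenotype: str
    required: Mapping[str, str]
    priority: int

    def __post_init__(self) -> None:
        bad = {s for s in self.required.values() if s not in {"+", "-"}}
        if bad:
            raise ValueError(f"marker signs must be '+' or '-', got {bad}")


DEFAULT_GATING_RULES: tuple[GatingRule, ...] = (
    GatingRule("neutrophil", {"Ly6G": "+", "F4-80": "-"}, priority=1),
    GatingRule("eosinophil", {"SiglecF": "+"}, priority=2),
    GatingRule("M1-like", {"SiglecF": "-", "F4-80": "+", "CD86": "+", "CD206": "-"}, priority=3),
    GatingRule("M0", {"SiglecF": "-", "F4-80": "+", "CD86": "+", "CD206": "+"}, priority=4),
    GatingRule("M2-like", {"SiglecF": "-", "F4-80": "+", "CD86": "-", "CD206": "+"}, priority=5),
    # the DC gate is a placeholder convention (CD11c+ non-macrophage)
    GatingRule("DC", {"CD11c": "+", "F4-80": "-"}, priority=6),
)


@dataclass(frozen=True)
class ClusteringParams:
    """Neighbourhood-graph community detection settings (15 <= k <= 30
    mirrors typical cytometry practice)."""

    k: int = 20
    resolution: float = 0.8
    seed: int = 0


def marker_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in RESERVED_COLUMNS]


def zscore_normalize(
    table: pd.DataFrame, markers: Sequence[str] | None = None
) -> pd.DataFrame:
    """Z-score each marker column over all cells.

    Uses the population standard deviation; markers with zero spread map
    to all-zero columns.  Requires at least two cells.
    """
    if len(table) < 2:
        raise ValueError("z-score normalization needs at least 2 cells")
    markers = list(markers) if markers is not None else marker_columns(table)
    out = table.copy()
    for m in markers:
        x = table[m].to_numpy(dtype=np.float64)
        sd = x.std(ddof=0)
        out[m] = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
    return out


def assign_phenotypes(
    table: pd.DataFrame,
    rules: Iterable[GatingRule] = DEFAULT_GATING_RULES,
    threshold: float = 0.0,
) -> pd.Series:
    """Assign a phenotype label per cell from gating rules on z-scores.

    A marker counts as "+" iff its z-score exceeds ``threshold``.  Rules
    are tried in priority order and the first full match wins; cells
    matching no rule are labelled ``"other"``.
    """
    rules = sorted(rules, key=lambda r: r.priority)
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("rule priorities must be unique")
    markers = marker_columns(table)
    for rule in rules:
        unknown = [m for m in rule.required if m not in markers]
        if unknown:
            raise ValueError(f"rule {rule.phenotype!r} references unknown markers {unknown}")

    positive = {m: table[m].to_numpy(dtype=np.float64) > threshold for m in markers}
    labels = np.full(len(table), "other", dtype=object)
    unassigned = np.ones(len(table), dtype=bool)
    for rule in rules:
        match = unassigned.copy()
        for marker, sign in rule.required.items():
            match &= positive[marker] if sign == "+" else ~positive[marker]
        labels[match] = rule.phenotype
        unassigned &= ~match
    return pd.Series(labels, index=table.index, name="phenotype")


def cluster_cells(
    table: pd.DataFrame,
    params: ClusteringParams = ClusteringParams(),
    markers: Sequence[str] | None = None,
) -> np.ndarray:
    """Cluster cells on their marker vectors.

    Builds a symmetrised k-nearest-neighbour graph (Euclidean distance on
    the marker matrix), weights each edge by the Jaccard overlap of the
    two cells' neighbourhoods (shared-neighbour weighting sharpens the
    boundaries between marker populations) and partitions the graph with
    greedy modularity maximisation.  Deterministic for a given table and
    parameters.
    """
    import networkx as nx
    from sklearn.neighbors import kneighbors_graph

    markers = list(markers) if markers is not None else marker_columns(table)
    X = table[markers].to_numpy(dtype=np.float64)
    n = len(X)
    if n <= params.k:
        raise ValueError(f"need more than k={params.k} cells, got {n}")
    adj = kneighbors_graph(X, n_neighbors=params.k, mode="connectivity", include_self=False)
    adj = adj.maximum(adj.T).tolil()
    neighbourhoods = [set(adj.rows[i]) | {i} for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    coo = adj.tocoo()
    for i, j in zip(coo.row, coo.col):
        if i < j:
            shared = len(neighbourhoods[i] & neighbourhoods[j])
            union = len(neighbourhoods[i] | neighbourhoods[j])
            if shared:
                g.add_edge(int(i), int(j), weight=shared / union)
    communities = nx.community.greedy_modularity_communities(
        g, weight="weight", resolution=params.resolution
    )
    ids = np.empty(n, dtype=np.int64)
    for cid, members in enumerate(sorted(communities, key=min)):
        ids[list(members)] = cid
    return ids


def load_rules_yaml(path) -> list[GatingRule]:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        GatingRule(entry["phenotype"], dict(entry["markers"]), int(entry["priority"]))
        for entry in raw
    ]


def save_rules_yaml(rules: Iterable[GatingRule], path) -> None:
    import yaml

    payload = [
        {"phenotype": r.phenotype, "markers": dict(r.required), "priority": r.priority}
        for r in rules
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
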
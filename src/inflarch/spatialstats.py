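"""Permutation-based neighborhood statistics on tissue cell maps.

Two objects are *neighbors* when their boundaries lie within a pixel
threshold (default 4 px) of each other.  For a pair of cell types the
observed number of neighbor pairs is compared to a null distribution
obtained by shuffling phenotype labels over the fixed cell positions
(zymosan particles are immobile reference objects and are never
shuffled).  The mid-p likelihood

    L = (#{count_perm < count_obs} + 0.5 * #{count_perm = count_obs}) / n_perm

is mapped to a relative distance ``d = 2 * (1 - L)``: 0 means the two
types are direct neighbors far more often than chance, 1 is the neutral
expectation, and 2 means they avoid each other entirely.  The relative
distance between zymosan and M2-like macrophages measures how far the
anti-inflammatory ring sits from the pathogen and is used as the size of
the pro-inflammatory (PI) region.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .synthdata import CellMap, ZYMOSAN_LABEL

__all__ = [
    "InteractionResult",
    "DistanceMap",
    "DualNetwork",
    "build_adjacency",
    "adjacency_from_mask",
    "interaction_likelihood",
    "distance_map",
    "pi_region_size",
    "percent_of_control",
    "dual_network",
]


@dataclass
class InteractionResult:
    """Observed adjacency count, permutation null summary and the
    resulting likelihood/relative distance for one type pair."""

    type_a: str
    type_b: str
    count_obs: int
    n_perm: int
    perm_mean: float
    perm_sd: float
    n_less: int
    n_ties: int
    L: float
    d: float
    seed: int | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.L <= 1.0 and 0.0 <= self.d <= 2.0


@dataclass
class DistanceMap:
    """Relative distances from one anchor type to each phenotype."""

    center: str
    entries: dict[str, InteractionResult]
    absent: list[str]
    n_perm: int
    seed: int | None = None

    @property
    def distances(self) -> dict[str, float]:
        return {p: r.d for p, r in self.entries.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "phenotype": p,
                "d": r.d,
                "L": r.L,
                "count_obs": r.count_obs,
                "perm_mean": r.perm_mean,
                "perm_sd": r.perm_sd,
                "n_perm": r.n_perm,
                "seed": r.seed,
            }
            for p, r in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class DualNetwork:
    """Phenotypes positioned by their relative distances to two anchors."""

    center_a: str
    center_b: str
    graph: nx.Graph = field(repr=False)
    link_threshold: float = 0.5

    def coordinates(self) -> dict[str, tuple[float, float]]:
        return {
            n: (self.graph.nodes[n]["d_to_a"], self.graph.nodes[n]["d_to_b"])
            for n in self.graph.nodes
        }

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def _cell_nodes(graph: nx.Graph) -> list:
    return [n for n, a in graph.nodes(data=True) if a.get("kind") != "zymosan"]


def build_adjacency(source, threshold_px: float = 4.0) -> nx.Graph:
    """Build the neighbor graph at a boundary-to-boundary pixel threshold.

    ``source`` is either a :class:`~inflarch.synthdata.CellMap` (point
    mode: objects are disks, two objects are linked when their center
    distance minus both radii is at most the threshold) or a 2-D integer
    label mask (pixel mode, see :func:`adjacency_from_mask`).  Zymosan
    objects participate as nodes labelled ``"zymosan"``.
    """
    if threshold_px < 0:
        raise ValueError("threshold_px must be >= 0")
    if isinstance(source, np.ndarray):
        return adjacency_from_mask(source, threshold_px)
    if not isinstance(source, CellMap):
        raise TypeError("source must be a CellMap or a 2-D label mask")

    cells = source.cells
    zym = source.zymosan
    n_obj = len(cells) + len(zym)
    if n_obj < 1:
        raise ValueError("need at least one object to build an adjacency graph")

    g = nx.Graph(threshold_px=threshold_px)
    xy = []
    radii = []
    keys = []
    for row in cells.itertuples(index=False):
        key = ("cell", int(row.cell_id))
        r = math.sqrt(row.area / math.pi)
        g.add_node(key, kind="cell", label=row.phenotype, x=float(row.x), y=float(row.y))
        keys.append(key)
        xy.append((row.x, row.y))
        radii.append(r)
    for row in zym.itertuples(index=False):
        key = ("zymosan", int(row.object_id))
        g.add_node(key, kind="zymosan", label=ZYMOSAN_LABEL, x=float(row.x), y=float(row.y))
        keys.append(key)
        xy.append((row.x, row.y))
        radii.append(float(row.radius))

    if len(keys) >= 2:
        xy_arr = np.asarray(xy, dtype=float)
        radii_arr = np.asarray(radii, dtype=float)
        reach = threshold_px + 2.0 * radii_arr.max()
        tree = cKDTree(xy_arr)
        for i, j in tree.query_pairs(r=reach):
            gap = float(np.hypot(*(xy_arr[i] - xy_arr[j]))) - radii_arr[i] - radii_arr[j]
            if gap <= threshold_px:
                g.add_edge(keys[i], keys[j])
    return g


def adjacency_from_mask(
    labels: np.ndarray,
    threshold_px: float = 4.0,
    zymosan_mask: np.ndarray | None = None,
    cell_labels: dict[int, str] | None = None,
) -> nx.Graph:
    """Neighbor graph from a label image.

    Pixels are unit squares; two objects are linked when some pair of
    their pixels has center distance at most ``threshold_px + 1`` (i.e.
    boundary gap at most the threshold: a 4 px gap links, a 5 px gap does
    not).  ``zymosan_mask`` may supply additional immobile reference
    objects; ``cell_labels`` maps mask labels to phenotype names.
    """
    if threshold_px < 0:
        raise ValueError("threshold_px must be >= 0")
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label mask must be 2-D")

    coords = []
    node_of_pixel = []
    g = nx.Graph(threshold_px=threshold_px)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        key = ("cell", int(lab))
        ys, xs = np.nonzero(labels == lab)
        cx, cy = float(xs.mean()), float(ys.mean())
        name = cell_labels.get(int(lab)) if cell_labels else None
        g.add_node(key, kind="cell", label=name or f"cell_{int(lab)}", x=cx, y=cy)
        coords.append(np.column_stack([xs, ys]))
        node_of_pixel.append(np.full(len(xs), len(g.nodes) - 1))
    if zymosan_mask is not None:
        zymosan_mask = np.asarray(zymosan_mask)
        if zymosan_mask.shape != labels.shape:
            raise ValueError("zymosan mask shape must match label mask")
        for lab in np.unique(zymosan_mask):
            if lab == 0:
                continue
            key = ("zymosan", int(lab))
            ys, xs = np.nonzero(zymosan_mask == lab)
            g.add_node(
                key, kind="zymosan", label=ZYMOSAN_LABEL, x=float(xs.mean()), y=float(ys.mean())
            )
            coords.append(np.column_stack([xs, ys]))
            node_of_pixel.append(np.full(len(xs), len(g.nodes) - 1))
    if len(g.nodes) < 1:
        raise ValueError("label mask contains no objects")

    nodes = list(g.nodes)
    if len(nodes) >= 2:
        all_xy = np.concatenate(coords).astype(float)
        owner = np.concatenate(node_of_pixel)
        tree = cKDTree(all_xy)
        pairs = tree.query_pairs(r=threshold_px + 1.0, output_type="ndarray")
        if len(pairs):
            a, b = owner[pairs[:, 0]], owner[pairs[:, 1]]
            for i, j in set(zip(a.tolist(), b.tolist())):
                if i != j:
                    g.add_edge(nodes[i], nodes[j])
    return g


def interaction_likelihood(
    graph: nx.Graph,
    type_a: str,
    type_b: str,
    n_perm: int = 1000,
    seed: int | None = None,
    labels: dict | None = None,
) -> InteractionResult:
    """Permutation-null likelihood and relative distance for a type pair.

    The observed count of unordered edges joining ``type_a`` and
    ``type_b`` endpoints is compared against ``n_perm`` random
    reassignments of the cell phenotype labels over the fixed cell
    positions; zymosan reference objects keep their identity.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    nodes = list(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    if labels is None:
        labels = {n: graph.nodes[n].get("label") for n in nodes}
    all_labels = np.array([labels[n] for n in nodes], dtype=object)
    for t in (type_a, type_b):
        if t not in set(all_labels):
            raise ValueError(f"type {t!r} absent from the labelled objects")

    cell_pos = np.array(
        [i for i, n in enumerate(nodes) if graph.nodes[n].get("kind") != "zymosan"]
    )
    edges = np.array([[idx[u], idx[v]] for u, v in graph.edges], dtype=np.int64)

    def count(lab: np.ndarray) -> int:
        if len(edges) == 0:
            return 0
        la, lb = lab[edges[:, 0]], lab[edges[:, 1]]
        if type_a == type_b:
            return int(np.count_nonzero((la == type_a) & (lb == type_a)))
        return int(
            np.count_nonzero(((la == type_a) & (lb == type_b)) | ((la == type_b) & (lb == type_a)))
        )

    count_obs = count(all_labels)

    unique_cell_labels = set(all_labels[cell_pos]) if len(cell_pos) else set()
    if len(unique_cell_labels) <= 1:
        warnings.warn("degenerate null: all cells share one label; L=0.5, d=1")
        return InteractionResult(
            type_a, type_b, count_obs, n_perm, float(count_obs), 0.0,
            0, n_perm, 0.5, 1.0, seed,
        )

    rng = np.random.default_rng(seed)
    perm_counts = np.empty(n_perm, dtype=np.int64)
    work = all_labels.copy()
    cell_lab = all_labels[cell_pos]
    for p in range(n_perm):
        work[cell_pos] = cell_lab[rng.permutation(len(cell_pos))]
        perm_counts[p] = count(work)

    n_less = int(np.count_nonzero(perm_counts < count_obs))
    n_ties = int(np.count_nonzero(perm_counts == count_obs))
    L = (n_less + 0.5 * n_ties) / n_perm
    return InteractionResult(
        type_a=type_a,
        type_b=type_b,
        count_obs=count_obs,
        n_perm=n_perm,
        perm_mean=float(perm_counts.mean()),
        perm_sd=float(perm_counts.std()),
        n_less=n_less,
        n_ties=n_ties,
        L=float(L),
        d=float(2.0 * (1.0 - L)),
        seed=seed,
    )


def _as_graph(source, threshold_px: float) -> nx.Graph:
    if isinstance(source, nx.Graph):
        return source
    return build_adjacency(source, threshold_px=threshold_px)


def distance_map(
    source,
    center: str = ZYMOSAN_LABEL,
    phenotypes: list[str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    threshold_px: float = 4.0,
) -> DistanceMap:
    """Relative distance from ``center`` to every phenotype on the map.

    ``source`` is a cell map, label mask or prebuilt adjacency graph.
    Phenotypes requested but absent from the map are reported in
    ``absent`` rather than given a score.
    """
    graph = _as_graph(source, threshold_px)
    present = {a.get("label") for _, a in graph.nodes(data=True)}
    if center not in present:
        raise ValueError(f"center type {center!r} absent from the map")
    if phenotypes is None:
        phenotypes = sorted(
            {a["label"] for _, a in graph.nodes(data=True) if a.get("kind") != "zymosan"}
            - {center}
        )
    entries: dict[str, InteractionResult] = {}
    absent: list[str] = []
    children = np.random.SeedSequence(seed).spawn(len(phenotypes))
    for phen, child in zip(phenotypes, children):
        if phen not in present:
            absent.append(phen)
            continue
        sub_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        entries[phen] = interaction_likelihood(
            graph, center, phen, n_perm=n_perm, seed=sub_seed
        )
    return DistanceMap(center=center, entries=entries, absent=absent, n_perm=n_perm, seed=seed)


def pi_region_size(dm: DistanceMap, m2_label: str = "M2-like") -> float:
    """Size of the PI region: relative distance from the map's center
    (zymosan) to the M2-like macrophages that delimit the AI ring."""
    if m2_label in dm.absent or m2_label not in dm.entries:
        raise ValueError(f"{m2_label!r} missing from the distance map")
    return dm.entries[m2_label].d


def percent_of_control(d_intervention: float, d_control: float) -> float:
    """PI-region size of an intervention as percent of its control."""
    if d_control <= 0:
        raise ValueError("control relative distance must be positive")
    return 100.0 * d_intervention / d_control


def dual_network(
    source,
    center_a: str = ZYMOSAN_LABEL,
    center_b: str = "M2-like",
    n_perm: int = 500,
    seed: int | None = None,
    link_threshold: float = 0.5,
    threshold_px: float = 4.0,
) -> DualNetwork:
    """Dual-centered neighborhood network.

    Every phenotype becomes a node placed at its relative distances to
    the two anchor types (self-distance is 0 by convention); phenotype
    pairs whose mutual relative distance is at most ``link_threshold``
    are connected.
    """
    if center_a == center_b:
        raise ValueError("the two centers must differ")
    graph = _as_graph(source, threshold_px)
    present = {a.get("label") for _, a in graph.nodes(data=True)}
    for c in (center_a, center_b):
        if c not in present:
            raise ValueError(f"center type {c!r} absent from the map")
    phenos = sorted(
        {a["label"] for _, a in graph.nodes(data=True) if a.get("kind") != "zymosan"}
    )
    ss = np.random.SeedSequence(seed)

    def sub_seed(child) -> int:
        return int(child.generate_state(1)[0] & 0x7FFFFFFF)

    net = nx.Graph(center_a=center_a, center_b=center_b)
    children = iter(ss.spawn(2 * len(phenos) + len(phenos) * (len(phenos) - 1) // 2))
    for p in phenos:
        d_a = 0.0 if p == center_a else interaction_likelihood(
            graph, center_a, p, n_perm=n_perm, seed=sub_seed(next(children))
        ).d
        d_b = 0.0 if p == center_b else interaction_likelihood(
            graph, center_b, p, n_perm=n_perm, seed=sub_seed(next(children))
        ).d
        net.add_node(p, d_to_a=float(d_a), d_to_b=float(d_b), x=float(d_a), y=float(d_b))
    for i, p in enumerate(phenos):
        for q in phenos[i + 1:]:
            d_pq = interaction_likelihood(
                graph, p, q, n_perm=n_perm, seed=sub_seed(next(children))
            ).d
            if d_pq <= link_threshold:
                net.add_edge(p, q, d=float(d_pq))
    return DualNetwork(center_a=center_a, center_b=center_b, graph=net, link_threshold=link_threshold)
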
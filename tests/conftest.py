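"""Shared fixtures: one default synthetic tissue map (expensive pieces are
session-scoped and reused read-only) and small constructed cell maps."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from inflarch import spatialstats as ss
from inflarch import synthdata as sd


@pytest.fixture(scope="session")
def default_config() -> sd.SyntheticTissueConfig:
    return sd.SyntheticTissueConfig(seed=11)


@pytest.fixture(scope="session")
def default_map(default_config) -> sd.CellMap:
    return sd.generate_tissue_map(default_config)


@pytest.fixture(scope="session")
def default_graph(default_map):
    return ss.build_adjacency(default_map)


@pytest.fixture(scope="session")
def rendered_stack(default_map) -> np.ndarray:
    return sd.render_channels(default_map)


def make_point_map(
    cells: list[tuple[float, float, str]],
    zymosan: list[tuple[float, float, float]] = (),
    field: tuple[int, int] = (256, 256),
    cell_radius: float = 4.0,
) -> sd.CellMap:
    """Small hand-built cell map (point mode) for constructed scenarios."""
    area = math.pi * cell_radius**2
    cell_df = pd.DataFrame(
        [
            {"cell_id": i + 1, "x": x, "y": y, "area": area, "phenotype": p}
            for i, (x, y, p) in enumerate(cells)
        ],
        columns=["cell_id", "x", "y", "area", "phenotype"],
    )
    zym_df = pd.DataFrame(
        [
            {"object_id": i + 1, "x": x, "y": y, "radius": r}
            for i, (x, y, r) in enumerate(zymosan)
        ],
        columns=["object_id", "x", "y", "radius"],
    )
    return sd.CellMap(cell_df, zym_df, field, cell_radius, [])


def make_enrichment_map(n_near: int = 5, n_far: int = 60) -> sd.CellMap:
    """One central zymosan particle, ``n_near`` type-A cells touching it and
    ``n_far`` type-B cells far away (>10 px boundary gap)."""
    cx, cy, rz, rc = 128.0, 128.0, 10.0, 4.0
    cells = []
    for i in range(n_near):
        ang = 2 * math.pi * i / n_near
        r = rz + rc + 1.0  # boundary gap 1 px <= 4
        cells.append((cx + r * math.cos(ang), cy + r * math.sin(ang), "A"))
    rng = np.random.default_rng(42)
    placed = 0
    while placed < n_far:
        x = rng.uniform(5, 250)
        y = rng.uniform(5, 250)
        if math.hypot(x - cx, y - cy) < rz + rc + 30:
            continue
        if any(math.hypot(x - u, y - v) < 1.0 for u, v, _ in cells):
            continue
        cells.append((x, y, "B"))
        placed += 1
    return make_point_map(cells, zymosan=[(cx, cy, rz)])


@pytest.fixture(scope="session")
def enrichment_map() -> sd.CellMap:
    return make_enrichment_map()


def make_pwl_exact(
    group_means: dict[str, dict[float, float]],
    animal_offsets: tuple[float, ...] = (-0.5, -0.3, -0.1, 0.1, 0.3, 0.5),
    cutoff: float = 20.0,
) -> "sd.PWLDataset":
    """PWL dataset whose cell means equal ``group_means`` exactly.

    Each animal carries a constant offset across all timepoints, so every
    cell has positive within-cell variance while all cell means (and hence
    all ANOVA contrasts) are exactly the designed values.
    """
    from inflarch.resolution import PWLDataset

    rows = []
    for group, means in group_means.items():
        for a, off in enumerate(animal_offsets):
            for t, mu in means.items():
                rows.append((f"{group}_{a + 1}", group, float(t), mu + off))
    return PWLDataset(
        pd.DataFrame(rows, columns=["animal", "group", "timepoint_h", "latency_s"]),
        cutoff_s=cutoff,
    )
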
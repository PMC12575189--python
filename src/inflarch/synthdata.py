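"""Synthetic tissue maps and paw-withdrawal-latency time courses.

Zymosan-induced inflammation organises into three concentric zones around
the immobile pathogen particles: a zymosan-containing core (covering
roughly 30 % of a typical imaging field) rich in neutrophils, a
pro-inflammatory (PI) ring dominated by M1-like macrophages, and an outer
anti-inflammatory (AI) ring dominated by M2-like macrophages.  This
module generates cell maps with that architecture -- including per-cell
marker-intensity vectors and optional rendered channel images -- plus
Hargreaves-style paw-withdrawal-latency (PWL) trajectories, so that every
downstream stage of the pipeline can be exercised without microscope or
animal data.

Regions are modelled as concentric annuli around the field centre; real
lesions are irregular, but all downstream statistics are geometry
agnostic, so the idealised shape only affects plausibility, not the
contracts being tested.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .resolution import PWLDataset

__all__ = [
    "REGIONS",
    "DEFAULT_MARKER_PANEL",
    "DEFAULT_DENSITIES",
    "PHENOTYPE_POSITIVE_MARKERS",
    "SyntheticTissueConfig",
    "CellMap",
    "PWLConfig",
    "GroupEffect",
    "generate_tissue_map",
    "generate_pwl",
    "render_label_mask",
    "render_channels",
]

REGIONS = ("core", "pi", "ai", "outside")

DEFAULT_MARKER_PANEL = [
    "nuclei",
    "CD45",
    "Ly6G",
    "SiglecF",
    "F4-80",
    "CD86",
    "CD206",
    "CD11c",
]

# markers expressed ("+") by each phenotype; all other panel markers sit at
# background level.  nuclei and CD45 are positive on every cell.
PHENOTYPE_POSITIVE_MARKERS: dict[str, tuple[str, ...]] = {
    "neutrophil": ("nuclei", "CD45", "Ly6G"),
    "eosinophil": ("nuclei", "CD45", "SiglecF"),
    "M1-like": ("nuclei", "CD45", "F4-80", "CD86"),
    "M0": ("nuclei", "CD45", "F4-80", "CD86", "CD206"),
    "M2-like": ("nuclei", "CD45", "F4-80", "CD206"),
    "DC": ("nuclei", "CD45", "CD11c"),
}

# expected cells per 10^4 px^2, per phenotype and region.  Neutrophils and
# M1-like macrophages populate core/PI, M2-like macrophages the AI ring.
DEFAULT_DENSITIES: dict[str, dict[str, float]] = {
    "neutrophil": {"core": 8.0, "pi": 2.0, "ai": 0.5, "outside": 0.2},
    "M1-like": {"core": 3.0, "pi": 8.0, "ai": 1.0, "outside": 0.2},
    "M0": {"core": 0.5, "pi": 2.0, "ai": 2.0, "outside": 0.2},
    "M2-like": {"core": 0.0, "pi": 0.3, "ai": 8.0, "outside": 0.4},
    "eosinophil": {"core": 0.2, "pi": 1.0, "ai": 2.0, "outside": 0.3},
    "DC": {"core": 0.2, "pi": 1.5, "ai": 1.5, "outside": 0.3},
}

ZYMOSAN_LABEL = "zymosan"
_MAX_PLACEMENT_RETRIES = 10_000


@dataclass
class SyntheticTissueConfig:
    """Geometry, densities and marker model of a synthetic tissue map.

    ``r_core`` defaults to the radius whose disk covers
    ``core_area_fraction`` of the field; ``r_pi``/``r_ai`` default to
    fixed-width rings outside it.  ``ring_offsets`` translates the
    sampling annulus of individual phenotypes radially (negative =
    inward), which is how interventions that displace the AI ring are
    emulated; densities remain defined on the unshifted regions.
    """

    field_size: tuple[int, int] = (512, 512)
    core_area_fraction: float = 0.30
    r_core: float | None = None
    r_pi: float | None = None
    r_ai: float | None = None
    densities: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(d) for p, d in DEFAULT_DENSITIES.items()}
    )
    ring_offsets: dict[str, float] = field(default_factory=dict)
    n_zymosan: int = 60
    zymosan_radius_px: float = 5.0
    cell_radius_px: float = 4.0
    marker_panel: list[str] = field(default_factory=lambda: list(DEFAULT_MARKER_PANEL))
    marker_means: dict[str, dict[str, float]] | None = None
    positive_mean: float = 100.0
    background_fraction: float = 0.05
    marker_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size
        if self.r_core is None:
            self.r_core = math.sqrt(self.core_area_fraction * h * w / math.pi)
        if self.r_pi is None:
            self.r_pi = self.r_core * 1.27
        if self.r_ai is None:
            self.r_ai = self.r_pi * 1.25
        if not (0 < self.r_core < self.r_pi < self.r_ai <= min(h, w) / 2):
            raise ValueError(
                "radii must satisfy 0 < r_core < r_pi < r_ai <= min(field_size)/2; "
                f"got {self.r_core:.1f}, {self.r_pi:.1f}, {self.r_ai:.1f}"
            )
        for phen, per_region in self.densities.items():
            for region, d in per_region.items():
                if region not in REGIONS:
                    raise ValueError(f"unknown region {region!r} for {phen!r}")
                if d < 0:
                    raise ValueError(f"negative density for {phen!r}/{region!r}")
        if self.marker_means is None:
            bg = self.background_fraction * self.positive_mean
            self.marker_means = {
                phen: {
                    m: (self.positive_mean if m in PHENOTYPE_POSITIVE_MARKERS.get(phen, ()) else bg)
                    for m in self.marker_panel
                }
                for phen in self.densities
            }
        for phen in self.densities:
            if phen not in self.marker_means:
                raise ValueError(f"no marker means for phenotype {phen!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def region_area(self, region: str) -> float:
        h, w = self.field_size
        areas = {
            "core": math.pi * self.r_core**2,
            "pi": math.pi * (self.r_pi**2 - self.r_core**2),
            "ai": math.pi * (self.r_ai**2 - self.r_pi**2),
            "outside": h * w - math.pi * self.r_ai**2,
        }
        return areas[region]


@dataclass
class CellMap:
    """Per-cell records plus zymosan reference objects for one field.

    ``cells`` columns: ``cell_id, x, y, area, phenotype, <marker...>``
    with 0-based pixel coordinates (x = column, y = row, origin
    top-left).  Zymosan particles are immobile reference objects and are
    never counted as cells.
    """

    cells: pd.DataFrame
    zymosan: pd.DataFrame
    field_size: tuple[int, int]
    cell_radius_px: float
    marker_panel: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = self.cells["cell_id"]
        if ids.duplicated().any():
            raise ValueError("cell_ids must be unique")
        h, w = self.field_size
        if len(self.cells):
            x, y = self.cells["x"].to_numpy(), self.cells["y"].to_numpy()
            if np.any((x < 0) | (x >= w) | (y < 0) | (y >= h)):
                raise ValueError("cell coordinates outside field")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def phenotype_counts(self) -> pd.Series:
        return self.cells["phenotype"].value_counts()

    def phenotype_proportions(self) -> pd.Series:
        return self.cells["phenotype"].value_counts(normalize=True)

    def to_csv(self, cells_path, zymosan_path) -> None:
        self.cells.to_csv(cells_path, index=False)
        self.zymosan.to_csv(zymosan_path, index=False)

    @classmethod
    def from_csv(
        cls,
        cells_path,
        zymosan_path=None,
        field_size: tuple[int, int] = (512, 512),
        cell_radius_px: float = 4.0,
    ) -> "CellMap":
        cells = pd.read_csv(cells_path)
        if zymosan_path is not None:
            zym = pd.read_csv(zymosan_path)
        else:
            zym = pd.DataFrame(columns=["object_id", "x", "y", "radius"])
        reserved = {"cell_id", "x", "y", "area", "phenotype"}
        panel = [c for c in cells.columns if c not in reserved]
        return cls(cells, zym, field_size, cell_radius_px, panel)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


def _sample_annulus(
    rng: np.random.Generator, center: tuple[float, float], r_in: float, r_out: float
) -> tuple[float, float]:
    r = math.sqrt(rng.uniform(r_in**2, r_out**2))
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return center[0] + r * math.cos(theta), center[1] + r * math.sin(theta)


def _sample_outside(
    rng: np.random.Generator,
    center: tuple[float, float],
    r_ai: float,
    field_size: tuple[int, int],
    margin: float,
) -> tuple[float, float]:
    h, w = field_size
    for _ in range(_MAX_PLACEMENT_RETRIES):
        x = rng.uniform(margin, w - 1 - margin)
        y = rng.uniform(margin, h - 1 - margin)
        if math.hypot(x - center[0], y - center[1]) > r_ai:
            return x, y
    raise RuntimeError("could not sample a point outside the AI ring")


def generate_tissue_map(config: SyntheticTissueConfig) -> CellMap:
    """Sample a cell map with the concentric core/PI/AI architecture.

    Zymosan particles are placed uniformly in the core first; per
    phenotype and region, a Poisson count (density x region area / 10^4)
    of cells is drawn and placed uniformly in the (optionally offset)
    region annulus, with a minimum centre spacing of 1.5 cell radii and no
    overlap with zymosan particles, enforced by rejection sampling.
    Identical config + seed yields identical output.
    """
    h, w = config.field_size
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    seed = config.seed

    zrng = _rng(seed, 0)
    zym_rows = []
    zr = config.zymosan_radius_px
    for i in range(config.n_zymosan):
        for _ in range(_MAX_PLACEMENT_RETRIES):
            x, y = _sample_annulus(zrng, center, 0.0, max(config.r_core - zr, zr))
            if all(math.hypot(x - r[1], y - r[2]) >= 2 * zr for r in zym_rows):
                zym_rows.append((i + 1, x, y, zr))
                break
        else:
            raise RuntimeError("could not place zymosan particle without overlap")
    zym = pd.DataFrame(zym_rows, columns=["object_id", "x", "y", "radius"])

    cr = config.cell_radius_px
    min_spacing = 1.5 * cr
    placed_xy: list[tuple[float, float]] = []
    rows: list[tuple] = []
    phenotypes = sorted(config.densities)
    for pi_idx, phen in enumerate(phenotypes):
        offset = float(config.ring_offsets.get(phen, 0.0))
        n_cells_ph = 0
        marker_rows_start = len(rows)
        for ri, region in enumerate(REGIONS):
            density = config.densities[phen].get(region, 0.0)
            if density <= 0:
                continue
            lam = density * config.region_area(region) / 1e4
            rng = _rng(seed, 1, pi_idx, ri)
            n = int(rng.poisson(lam))
            bounds = {
                "core": (0.0, config.r_core),
                "pi": (config.r_core, config.r_pi),
                "ai": (config.r_pi, config.r_ai),
            }
            for _ in range(n):
                for _try in range(_MAX_PLACEMENT_RETRIES):
                    if region == "outside":
                        x, y = _sample_outside(rng, center, config.r_ai, config.field_size, cr)
                    else:
                        r_in, r_out = bounds[region]
                        r_in = max(0.0, r_in + offset)
                        r_out = max(r_in + 1.0, r_out + offset)
                        x, y = _sample_annulus(rng, center, r_in, r_out)
                        if not (cr <= x <= w - 1 - cr and cr <= y <= h - 1 - cr):
                            continue
                    if placed_xy:
                        arr = np.asarray(placed_xy)
                        if np.min(np.hypot(arr[:, 0] - x, arr[:, 1] - y)) < min_spacing:
                            continue
                    if len(zym) and np.min(
                        np.hypot(zym["x"].to_numpy() - x, zym["y"].to_numpy() - y)
                    ) < (cr + zr):
                        continue
                    placed_xy.append((x, y))
                    rows.append((x, y, phen))
                    n_cells_ph += 1
                    break
                else:
                    raise RuntimeError(
                        f"could not place {phen!r} cell in {region!r} after "
                        f"{_MAX_PLACEMENT_RETRIES} retries (field too crowded)"
                    )
        # marker vectors per phenotype, drawn after all its placements
        mrng = _rng(seed, 2, pi_idx)
        means = np.array([config.marker_means[phen][m] for m in config.marker_panel])
        if config.marker_cv > 0:
            sigma = math.sqrt(math.log(1.0 + config.marker_cv**2))
            mu = np.log(means) - sigma**2 / 2.0
            intensities = mrng.lognormal(mean=mu, sigma=sigma, size=(n_cells_ph, len(means)))
        else:
            intensities = np.tile(means, (n_cells_ph, 1))
        for j in range(n_cells_ph):
            x, y, p = rows[marker_rows_start + j]
            rows[marker_rows_start + j] = (x, y, p, intensities[j])

    area = math.pi * cr**2
    records = []
    for cid, (x, y, phen, markers) in enumerate(rows, start=1):
        records.append([cid, x, y, area, phen, *markers])
    cells = pd.DataFrame(
        records, columns=["cell_id", "x", "y", "area", "phenotype", *config.marker_panel]
    )
    if cells.empty:
        cells = pd.DataFrame(
            columns=["cell_id", "x", "y", "area", "phenotype", *config.marker_panel]
        )
    return CellMap(
        cells=cells,
        zymosan=zym,
        field_size=config.field_size,
        cell_radius_px=cr,
        marker_panel=list(config.marker_panel),
        provenance=f"{config.config_hash()}:{seed}",
    )


def _paint_disk(img: np.ndarray, x: float, y: float, radius: float, value: float) -> None:
    from skimage.draw import disk

    rr, cc = disk((y, x), radius, shape=img.shape)
    img[rr, cc] = np.maximum(img[rr, cc], value)


def render_label_mask(cellmap: CellMap, radius: float | None = None) -> np.ndarray:
    """Render cells as labelled disks (32-bit label image; 0 = background)."""
    from skimage.draw import disk

    mask = np.zeros(cellmap.field_size, dtype=np.int32)
    r = radius if radius is not None else cellmap.cell_radius_px
    for row in cellmap.cells.itertuples():
        rr, cc = disk((row.y, row.x), r, shape=mask.shape)
        mask[rr, cc] = row.cell_id
    return mask


def render_channels(
    cellmap: CellMap,
    nucleus_radius: float | None = None,
) -> np.ndarray:
    """Render per-marker channel images (H x W x C, aligned to the panel).

    Each cell is painted as a disk carrying its marker intensity; the
    nuclear channel uses a smaller disk (half the cell radius by default)
    so that nuclei of neighbouring cells stay separable for segmentation.
    Overlaps take the maximum.
    """
    h, w = cellmap.field_size
    c = len(cellmap.marker_panel)
    stack = np.zeros((h, w, c), dtype=np.float64)
    r_cell = cellmap.cell_radius_px
    r_nuc = nucleus_radius if nucleus_radius is not None else max(1.0, r_cell / 2.0)
    xs = cellmap.cells["x"].to_numpy(float)
    ys = cellmap.cells["y"].to_numpy(float)
    for ci, marker in enumerate(cellmap.marker_panel):
        radius = r_nuc if marker == "nuclei" else r_cell
        values = cellmap.cells[marker].to_numpy(float)
        for x, y, v in zip(xs, ys, values):
            _paint_disk(stack[:, :, ci], x, y, radius, v)
    return stack


# ---------------------------------------------------------------------------
# paw-withdrawal latencies


@dataclass(frozen=True)
class PWLConfig:
    """Shared settings of a synthetic Hargreaves experiment."""

    n_per_group: int = 6
    timepoints_h: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0, 96.0)
    baseline_s: float = 10.0
    cutoff_s: float = 20.0
    drop_s: float = 6.0
    noise_sd_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_s <= self.cutoff_s:
            raise ValueError("baseline must lie in (0, cutoff]")
        required = {0.0, 24.0, 48.0, 72.0}
        if not required <= set(float(t) for t in self.timepoints_h):
            raise ValueError("timepoints must include 0, 24, 48 and 72 h")


@dataclass(frozen=True)
class GroupEffect:
    """Per-group deviation from the shared trajectory.

    ``shift_s`` may be a constant (applied at 24-72 h) or a mapping
    ``timepoint -> shift`` for timepoint-specific offsets.
    """

    drop_s: float | None = None
    recovery_h: float | None = None
    shift_s: float | Mapping[float, float] = 0.0


def _trajectory(
    t: float,
    baseline: float,
    drop: float,
    recovery_h: float,
    shift: float | Mapping[float, float],
) -> float:
    if t <= 0:
        lat = baseline
    elif t >= recovery_h:
        lat = baseline
    else:
        lat = baseline - drop * (recovery_h - t) / (recovery_h - 24.0)
    if isinstance(shift, Mapping):
        lat += float(shift.get(t, 0.0))
    elif 24.0 <= t <= 72.0:
        lat += float(shift)
    return lat


def generate_pwl(
    config: PWLConfig,
    group_effects: Mapping[str, GroupEffect],
) -> PWLDataset:
    """Generate per-animal PWL trajectories for the configured groups.

    Latency starts at baseline, drops by ``drop_s`` at 24 h and relaxes
    linearly back to baseline at the group's recovery hour; Gaussian
    residual noise is added per record and values are clipped to
    ``(0, cutoff_s]``.

    Noise is *yoked* across groups (common random numbers per animal
    index and timepoint): groups with identical effects produce identical
    trajectories, and group contrasts equal the designed effects exactly.
    """
    if not group_effects:
        raise ValueError("group_effects must name at least one group")
    resolved = {}
    for group, eff in group_effects.items():
        drop = eff.drop_s if eff.drop_s is not None else config.drop_s
        rec = eff.recovery_h if eff.recovery_h is not None else max(config.timepoints_h)
        if float(rec) not in [float(t) for t in config.timepoints_h]:
            raise ValueError(
                f"recovery_h={rec} for group {group!r} is not an observed timepoint"
            )
        resolved[group] = (drop, float(rec), eff.shift_s)
    timepoints = [float(t) for t in config.timepoints_h]
    records = []
    for a in range(config.n_per_group):
        rng = _rng(config.seed, 3, a)
        noise = (
            rng.normal(0.0, config.noise_sd_s, size=len(timepoints))
            if config.noise_sd_s > 0
            else np.zeros(len(timepoints))
        )
        for group in sorted(resolved):
            drop, rec, shift = resolved[group]
            for ti, t in enumerate(timepoints):
                lat = _trajectory(t, config.baseline_s, drop, rec, shift) + noise[ti]
                lat = min(max(lat, 0.01), config.cutoff_s)
                records.append((f"{group}_{a + 1}", group, t, lat))
    df = pd.DataFrame(records, columns=["animal", "group", "timepoint_h", "latency_s"])
    return PWLDataset(df, cutoff_s=config.cutoff_s)
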
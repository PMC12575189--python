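"""Resolution scoring of thermal hypersensitivity time courses.

The resolution of zymosan-induced inflammation is read out behaviourally:
paw-withdrawal latencies (PWL, Hargreaves test, 20 s cutoff) drop after
zymosan injection and climb back to baseline as the inflammation resolves.
An intervention is scored against its control with two components:

* **Score 1** — at each scoring timepoint (24, 48, 72 h) the intervention
  group is contrasted against control (two-way ANOVA over group x time on
  the post-injection records, Bonferroni-adjusted contrasts).  A
  significant increase of PWL toward baseline scores +1, a significant
  decrease scores -1, no change scores 0.
* **Score 2** — each group's return-to-baseline time is found (one-way
  ANOVA across timepoints within the group, Bonferroni contrasts against
  the 0 h baseline).  Every full day the intervention returns earlier
  than control adds +2; every day later adds -2.

The final resolution score is the sum of both components.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "PWLDataset",
    "ScoringConfig",
    "ResolutionScoreResult",
    "NEVER_RETURNED",
    "score1",
    "days_to_baseline",
    "score2",
    "resolution_score",
]

#: Sentinel returned by :func:`days_to_baseline` when a group's PWL stays
#: significantly different from baseline through the last observed timepoint.
NEVER_RETURNED = math.inf

REQUIRED_COLUMNS = ("animal", "group", "timepoint_h", "latency_s")


@dataclass
class PWLDataset:
    """Longitudinal paw-withdrawal latencies, one record per animal/timepoint.

    Parameters
    ----------
    records
        Table with columns ``animal``, ``group``, ``timepoint_h``,
        ``latency_s``.  Every animal must carry a 0 h baseline record and
        latencies must lie in ``(0, cutoff_s]``.
    cutoff_s
        Hargreaves cutoff in seconds (heat source switched off).
    """

    records: pd.DataFrame
    cutoff_s: float = 20.0

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"PWL table misses required columns: {missing}")
        df = self.records
        lat = df["latency_s"].to_numpy(float)
        if np.any(lat <= 0) or np.any(lat > self.cutoff_s):
            raise ValueError(f"latencies must lie in (0, {self.cutoff_s}]")
        by_animal = df.groupby("animal")["timepoint_h"].apply(set)
        without_baseline = [a for a, tps in by_animal.items() if 0 not in tps]
        if without_baseline:
            raise ValueError(f"animals without 0 h baseline record: {without_baseline}")

    @property
    def timepoints_h(self) -> list[float]:
        return sorted(self.records["timepoint_h"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.records["group"].unique())

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cutoff_s: float = 20.0) -> "PWLDataset":
        return cls(pd.read_csv(path), cutoff_s=cutoff_s)


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the resolution score."""

    score_timepoints_h: tuple[float, ...] = (24.0, 48.0, 72.0)
    alpha: float = 0.05
    per_day_points: int = 2
    day_h: float = 24.0
    control: str = "control"
    intervention: str = "intervention"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ResolutionScoreResult:
    score1_by_timepoint: dict[float, int]
    score1_total: int
    days_to_baseline: dict[str, float]
    score2: int
    total: int
    anova_table: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "score1_by_timepoint": {str(k): v for k, v in self.score1_by_timepoint.items()},
            "score1_total": self.score1_total,
            "days_to_baseline": {
                g: (None if math.isinf(v) else v) for g, v in self.days_to_baseline.items()
            },
            "score2": self.score2,
            "total": self.total,
        }


def _check_cells_nondegenerate(df: pd.DataFrame) -> None:
    """Raise if any (group, timepoint) cell has zero within-cell variance."""
    for (g, t), sub in df.groupby(["group", "timepoint_h"]):
        if len(sub) >= 2 and float(np.var(sub["latency_s"].to_numpy())) == 0.0:
            raise ValueError(
                f"zero within-group variance in cell (group={g!r}, timepoint={t} h)"
            )


def score1(data: PWLDataset, cfg: ScoringConfig = ScoringConfig()) -> dict[float, int]:
    """Per-timepoint intervention-vs-control scoring of PWL changes.

    Fits a two-way ANOVA (group, time and interaction) on the
    post-injection records, then contrasts intervention against control at
    each scoring timepoint using the pooled residual variance with
    Bonferroni correction over the scoring timepoints.  Returns a map
    ``timepoint -> {-1, 0, +1}`` where +1 means the intervention raised
    PWL toward baseline.
    """
    df = data.records[data.records["timepoint_h"] > 0].copy()
    for g in (cfg.control, cfg.intervention):
        if g not in set(df["group"]):
            raise ValueError(f"group {g!r} absent from dataset")
    for t in cfg.score_timepoints_h:
        for g in (cfg.control, cfg.intervention):
            if df[(df["group"] == g) & (df["timepoint_h"] == t)].empty:
                raise ValueError(f"no records for group {g!r} at {t} h")
    df = df[df["group"].isin([cfg.control, cfg.intervention])]
    _check_cells_nondegenerate(df)

    model = smf.ols("latency_s ~ C(group) * C(timepoint_h)", data=df).fit()
    mse = float(model.mse_resid)
    dof = int(model.df_resid)

    m = len(cfg.score_timepoints_h)
    scores: dict[float, int] = {}
    for t in cfg.score_timepoints_h:
        ci = df[(df["group"] == cfg.intervention) & (df["timepoint_h"] == t)]["latency_s"]
        cc = df[(df["group"] == cfg.control) & (df["timepoint_h"] == t)]["latency_s"]
        diff = float(ci.mean() - cc.mean())
        se = math.sqrt(mse * (1.0 / len(ci) + 1.0 / len(cc))) if mse > 0 else 0.0
        if se == 0.0:
            p_adj = 0.0 if diff != 0.0 else 1.0
        else:
            tval = diff / se
            p = 2.0 * stats.t.sf(abs(tval), dof)
            p_adj = min(1.0, p * m)
        if p_adj < cfg.alpha and diff != 0.0:
            scores[t] = 1 if diff > 0 else -1
        else:
            scores[t] = 0
    return scores


def days_to_baseline(
    data: PWLDataset, group: str, cfg: ScoringConfig = ScoringConfig()
) -> float:
    """Hours until the group's PWL has returned to its own 0 h baseline.

    One-way ANOVA across timepoints within the group; each post-injection
    timepoint is contrasted against baseline (pooled residual variance,
    Bonferroni over the post-injection timepoints).  Returns the earliest
    post-injection timepoint from which the contrast is non-significant at
    that timepoint *and all later ones*; ``NEVER_RETURNED`` (+inf) if the
    last timepoint is still significantly different from baseline.
    """
    sub = data.records[data.records["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} absent from dataset")
    tps = sorted(sub["timepoint_h"].unique())
    if 0 not in tps:
        raise ValueError(f"group {group!r} has no 0 h baseline records")
    post = [t for t in tps if t > 0]
    if len(post) < 2:
        raise ValueError("need at least two post-injection timepoints")

    cells = {t: sub[sub["timepoint_h"] == t]["latency_s"].to_numpy(float) for t in tps}
    n_total = sum(len(v) for v in cells.values())
    sse = sum(float(np.sum((v - v.mean()) ** 2)) for v in cells.values())
    dof = n_total - len(tps)
    mse = sse / dof if dof > 0 else 0.0

    base = cells[0]
    m = len(post)
    significant: dict[float, bool] = {}
    for t in post:
        v = cells[t]
        diff = float(v.mean() - base.mean())
        se = math.sqrt(mse * (1.0 / len(v) + 1.0 / len(base))) if mse > 0 else 0.0
        if se == 0.0:
            p_adj = 0.0 if diff != 0.0 else 1.0
        else:
            p = 2.0 * stats.t.sf(abs(diff / se), dof)
            p_adj = min(1.0, p * m)
        significant[t] = p_adj < cfg.alpha
    for i, t in enumerate(post):
        if not any(significant[u] for u in post[i:]):
            return float(t)
    return NEVER_RETURNED


def score2(
    days_control: float,
    days_intervention: float,
    cfg: ScoringConfig = ScoringConfig(),
    horizon_h: float | None = None,
) -> int:
    """Return-to-baseline component: +/- ``per_day_points`` per full day.

    A group that never returns within the observation window
    (``NEVER_RETURNED``) is scored as if it returned one day after
    ``horizon_h``, the last observed timepoint; fractional day gaps are
    truncated toward zero.
    """
    if math.isinf(days_control) and math.isinf(days_intervention):
        warnings.warn("neither group returned to baseline; score 2 set to 0")
        return 0
    if math.isinf(days_control) or math.isinf(days_intervention):
        if horizon_h is None:
            raise ValueError(
                "a group never returned to baseline; pass horizon_h (last observed "
                "timepoint) so the open-ended recovery can be scored"
            )
        effective = horizon_h + cfg.day_h
        days_control = effective if math.isinf(days_control) else days_control
        days_intervention = effective if math.isinf(days_intervention) else days_intervention
    gap_days = (days_control - days_intervention) / cfg.day_h
    return cfg.per_day_points * math.trunc(gap_days)


def resolution_score(
    data: PWLDataset, cfg: ScoringConfig = ScoringConfig()
) -> ResolutionScoreResult:
    """Full resolution score: Score 1 summed over timepoints plus Score 2."""
    s1 = score1(data, cfg)
    days = {
        cfg.control: days_to_baseline(data, cfg.control, cfg),
        cfg.intervention: days_to_baseline(data, cfg.intervention, cfg),
    }
    horizon = max(data.timepoints_h)
    s2 = score2(days[cfg.control], days[cfg.intervention], cfg, horizon_h=horizon)
    post = data.records[data.records["timepoint_h"] > 0]
    post = post[post["group"].isin([cfg.control, cfg.intervention])]
    model = smf.ols("latency_s ~ C(group) * C(timepoint_h)", data=post).fit()
    table = sm.stats.anova_lm(model, typ=2)
    s1_total = int(sum(s1.values()))
    return ResolutionScoreResult(
        score1_by_timepoint=s1,
        score1_total=s1_total,
        days_to_baseline=days,
        score2=int(s2),
        total=s1_total + int(s2),
        anova_table=table,
    )
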
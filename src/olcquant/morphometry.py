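"""Sheath morphometry: group comparisons and per-fish stability.

Measurements are one row per sheath: the length (longitudinal extent)
and width (lateral extent) of each ensheathed area, for an identified
cell in one fish at one day post fertilization.  Group comparisons use
the cell as the unit of analysis: sheath values are averaged per cell
first, then cell averages are compared across classes with a Welch
two-sample t test.  Stability of a cell followed across days in the
same fish is assessed with a one-way ANOVA of its sheath measurements
grouped by day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, sem, ttest_ind

__all__ = [
    "GroupComparison",
    "StabilityResult",
    "group_compare",
    "stability_test",
    "stability_by_fish",
    "max_projection_count",
]

_FIELD_COLUMNS = {"length": "length_um", "width": "width_um"}


@dataclass
class GroupComparison:
    """Welch comparison of per-cell sheath averages between two classes."""

    field: str
    classes: tuple[str, str]
    means: dict[str, float]     # um, mean of per-cell averages
    sems: dict[str, float]      # um
    n_cells: dict[str, int]
    t: float
    p: float
    unit: str = "cell"          # cell (default) | sheath


@dataclass
class StabilityResult:
    """One-way ANOVA of one fish's sheath measurements across days."""

    fish_id: str
    field: str
    day_means: dict[int, float]
    day_n: dict[int, int]
    f_statistic: float
    p: float
    degenerate: bool = False    # zero variance both between and within days


def _field_column(field: str) -> str:
    try:
        return _FIELD_COLUMNS[field]
    except KeyError:
        raise ValueError(f"field must be 'length' or 'width', got {field!r}") from None


def group_compare(
    measurements: pd.DataFrame, field: str = "length", unit: str = "cell"
) -> GroupComparison:
    """Compare sheath ``length`` or ``width`` between the two cell classes.

    With ``unit="cell"`` (default) sheath values are averaged per cell
    before the Welch test, so each cell contributes one observation;
    ``unit="sheath"`` pools raw sheath values instead.
    """
    col = _field_column(field)
    if unit not in ("cell", "sheath"):
        raise ValueError(f"unit must be 'cell' or 'sheath', got {unit!r}")
    classes = sorted(measurements["cell_class"].unique())
    if len(classes) != 2:
        raise ValueError(
            f"group comparison needs exactly two cell classes, found {classes}"
        )
    samples: dict[str, np.ndarray] = {}
    for cls in classes:
        sub = measurements[measurements["cell_class"] == cls]
        if unit == "cell":
            vals = sub.groupby(["fish_id", "cell_id"])[col].mean().to_numpy()
        else:
            vals = sub[col].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"class {cls!r} has fewer than two observations")
        samples[cls] = vals
    a, b = (samples[c] for c in classes)
    t, p = ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        field=field,
        classes=(classes[0], classes[1]),
        means={c: float(samples[c].mean()) for c in classes},
        sems={c: float(sem(samples[c])) for c in classes},
        n_cells={c: int(len(samples[c])) for c in classes},
        t=float(t),
        p=float(p),
        unit=unit,
    )


def stability_test(measurements: pd.DataFrame, field: str = "length") -> StabilityResult:
    """One-way ANOVA of one fish's sheath measurements grouped by day.

    Requires a single fish, at least two days and at least two sheath
    measurements per day.  A dataset with zero variance both between
    and within days is flagged degenerate and reported as F = 0, p = 1
    (perfect stability); zero within-day variance with distinct day
    means yields F = inf, p = 0.
    """
    col = _field_column(field)
    fish = measurements["fish_id"].unique()
    if len(fish) != 1:
        raise ValueError(
            f"stability_test analyzes one fish at a time, found {sorted(map(str, fish))}"
        )
    days = sorted(measurements["day"].unique())
    if len(days) < 2:
        raise ValueError("stability test needs measurements from >= 2 days")
    groups = []
    for d in days:
        vals = measurements.loc[measurements["day"] == d, col].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"day {d} has fewer than two sheath measurements")
        groups.append(vals)
    allvals = np.concatenate(groups)
    grand = allvals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0.0 and ssb == 0.0:
        f_stat, p, degenerate = 0.0, 1.0, True
    elif ssw == 0.0:
        f_stat, p, degenerate = float("inf"), 0.0, False
    else:
        f_stat, p = f_oneway(*groups)
        f_stat, p, degenerate = float(f_stat), float(p), False
    return StabilityResult(
        fish_id=str(fish[0]),
        field=field,
        day_means={int(d): float(g.mean()) for d, g in zip(days, groups)},
        day_n={int(d): int(len(g)) for d, g in zip(days, groups)},
        f_statistic=f_stat,
        p=p,
        degenerate=degenerate,
    )


def stability_by_fish(
    measurements: pd.DataFrame, field: str = "length"
) -> dict[str, StabilityResult]:
    """Run :func:`stability_test` separately for every fish in the table."""
    return {
        str(fid): stability_test(sub, field)
        for fid, sub in measurements.groupby("fish_id", sort=True)
    }


def max_projection_count(counts: pd.DataFrame) -> pd.Series:
    """Maximum number of extended projections per cell, from a per-frame
    count table with columns ``cell_id``, ``frame``, ``n_projections``."""
    if counts.empty:
        raise ValueError("no projection counts supplied")
    if (counts["n_projections"] < 0).any():
        raise ValueError("projection counts must be non-negative")
    out = counts.groupby("cell_id", sort=True)["n_projections"].max()
    out.name = "max_projections"
    return out
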
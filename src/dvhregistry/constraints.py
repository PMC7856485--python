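"""Median-based organ-at-risk constraint derivation.

Given a historical cohort treated under one prescription scheme, the planning
constraint for organ o at dose threshold t is the cohort median of VtGy(o):
half of past acceptable plans met it, so it is an achievable yet demanding
initial optimization goal for new plans.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ingest import CANONICAL_ORGANS
from .registry import Cohort, Registry, RegistryError

__all__ = [
    "ConstraintTable",
    "CohortDoseSummary",
    "derive_constraints",
    "summarize_cohort_doses",
    "render_constraint_table",
    "DEFAULT_CONSTRAINT_THRESHOLDS",
]

#: Constraint-table dose columns (Gy).  15 Gy is a monitoring endpoint but not
#: a constraint column by default; both lists are configurable.
DEFAULT_CONSTRAINT_THRESHOLDS = (5.0, 10.0, 20.0)


@dataclass(frozen=True)
class ConstraintTable:
    """Organ x threshold grid of median relative-volume constraints (%).

    ``n_per_organ`` records how many cohort plans contributed to each row;
    ``saturated`` flags organs whose median V at the two lowest thresholds is
    100 % (the constraint carries no planning information there).
    """

    rx_dose: float
    rx_fractions: int
    thresholds: tuple[float, ...]
    rows: dict[str, dict[float, float]]
    cohort_name: str
    n_per_organ: dict[str, int] = field(default_factory=dict)
    excluded: tuple[str, ...] = ()
    saturated: tuple[str, ...] = ()


@dataclass(frozen=True)
class CohortDoseSummary:
    """Per-organ mean / median / SD of the cohort's Dmean values (Gy)."""

    organ: str
    n: int
    mean: float
    median: float
    sd: float  # nan when n == 1: undefined, never 0 by convention


def derive_constraints(
    registry: Registry,
    cohort: Cohort | str,
    organs: tuple[str, ...] = CANONICAL_ORGANS,
    thresholds: tuple[float, ...] = DEFAULT_CONSTRAINT_THRESHOLDS,
) -> ConstraintTable:
    """Median VtGy per organ over a cohort, at each constraint threshold.

    The median of an even-sized sample is the mean of its two central order
    statistics.  Organs absent from every plan are excluded and reported,
    never silently dropped.  Full float precision is kept here; rounding is a
    display concern of :func:`render_constraint_table`.
    """
    if isinstance(cohort, str):
        cohort = registry.get_cohort(cohort)
    if len(cohort) == 0:
        raise RegistryError(f"cohort {cohort.name!r} is empty")
    thresholds = tuple(sorted(float(t) for t in thresholds))

    rows: dict[str, dict[float, float]] = {}
    n_per_organ: dict[str, int] = {}
    excluded: list[str] = []
    saturated: list[str] = []
    for organ in organs:
        per_threshold: dict[float, float] = {}
        n_organ = 0
        try:
            for t in thresholds:
                sample, _skipped = registry.cohort_metric_sample(
                    cohort, organ, f"v{t:g}"
                )
                per_threshold[t] = float(np.median(sample))
                n_organ = len(sample)
        except RegistryError:
            excluded.append(organ)
            continue
        rows[organ] = per_threshold
        n_per_organ[organ] = n_organ
        low = sorted(thresholds)[:2]
        if len(low) == 2 and all(_round_half_up(per_threshold[t]) >= 100 for t in low):
            saturated.append(organ)

    any_plan = registry.load_plan(cohort.serials[0])
    return ConstraintTable(
        rx_dose=any_plan.meta.rx_dose,
        rx_fractions=any_plan.meta.rx_fractions,
        thresholds=thresholds,
        rows=rows,
        cohort_name=cohort.name,
        n_per_organ=n_per_organ,
        excluded=tuple(excluded),
        saturated=tuple(saturated),
    )


def summarize_cohort_doses(
    registry: Registry,
    cohort: Cohort | str,
    organs: tuple[str, ...] = CANONICAL_ORGANS,
) -> list[CohortDoseSummary]:
    """Population mean, median and SD (n-1 denominator) of Dmean per organ.

    The SD of a single-plan sample is undefined and reported as NaN.
    """
    if isinstance(cohort, str):
        cohort = registry.get_cohort(cohort)
    out = []
    for organ in organs:
        sample, _ = registry.cohort_metric_sample(cohort, organ, "d_mean")
        arr = np.asarray(sample)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
        out.append(
            CohortDoseSummary(
                organ=organ,
                n=arr.size,
                mean=float(arr.mean()),
                median=float(np.median(arr)),
                sd=sd,
            )
        )
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def render_constraint_table(table: ConstraintTable, path: str | Path) -> None:
    """Write the constraint table as CSV, one organ per row.

    Values are rounded half-up to integer percent for display, mirroring how
    such tables are circulated on planning sheets; the registry keeps full
    precision.  Output is deterministic: same cohort, byte-identical file.
    """
    path = Path(path)
    header = ["organ"] + [f"V{t:g}Gy" for t in table.thresholds]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for organ in table.rows:
            writer.writerow(
                [organ] + [_round_half_up(table.rows[organ][t]) for t in table.thresholds]
            )


def constraint_table_yaml(table: ConstraintTable, path: str | Path) -> None:
    """Optional YAML export, e.g. for planning-sheet templating."""
    payload = {
        organ: {f"V{t:g}": _round_half_up(v) for t, v in cells.items()}
        for organ, cells in table.rows.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
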
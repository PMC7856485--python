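"""Pre/post cohort monitoring of planning practice.

Two cohorts of plans (before and after a planning intervention, e.g. the
introduction of constraint guidance) are compared per organ across eight
dosimetric endpoints (V5Gy, V10Gy, V15Gy, V20Gy, Dmean, Dmedian, Dmin, Dmax)
by two complementary routes:

* a two-tailed Mann-Whitney U test per organ-endpoint cell -- nonparametric,
  appropriate for small, non-normal dosimetric samples; exact enumeration of
  the null U distribution for small tie-free samples, tie-corrected normal
  approximation with continuity correction otherwise;
* a Welch t-based confidence interval on the difference of cohort means,
  whose verdict (interval excludes zero) cross-checks the rank test.

Each cell is classified into five change categories combining significance
and direction, and the fraction of cells on which the two routes agree
summarizes their consistency.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import stats

from .dvh_core import CumulativeDVH, v_at_dose
from .registry import ENDPOINTS, Cohort, Registry, RegistryError

__all__ = [
    "MeanDVH",
    "DistributionSummary",
    "EndpointTestResult",
    "ComparisonGrid",
    "TimelinePoint",
    "Timeline",
    "CATEGORIES",
    "population_mean_dvh",
    "distribution_summary",
    "mann_whitney_u",
    "mean_diff_ci",
    "classify_change",
    "compare_cohorts",
    "agreement_fraction",
    "percent_change_of_median",
    "timeline",
    "render_report",
]

#: The five change categories, mirroring a green/light-green/yellow/orange/red
#: traffic-light display.
CATEGORIES = (
    "significant_reduction",
    "nonsignificant_reduction",
    "no_change",
    "nonsignificant_increase",
    "significant_increase",
)

#: Below this exact-enumeration limit on n_pre + n_post (and with no ties),
#: the Mann-Whitney p-value is computed from the full null distribution of U.
EXACT_LIMIT = 20


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeanDVH:
    """Population-mean DVH of a cohort on a common dose grid.

    ``sem_rel_volume`` is the standard uncertainty of the mean, sd/sqrt(n)
    with the n-1 denominator; it is NaN everywhere when n == 1.
    """

    dose_edges: np.ndarray
    mean_rel_volume: np.ndarray
    sem_rel_volume: np.ndarray
    n: int


@dataclass(frozen=True)
class DistributionSummary:
    """Location and spread of one endpoint sample (typically Dmean, in Gy)."""

    n: int
    mean: float
    median: float
    sd: float
    q1: float
    q3: float
    iqr: float
    ci95_low: float
    ci95_high: float


@dataclass(frozen=True)
class EndpointTestResult:
    """One organ-endpoint cell of the comparison grid."""

    organ: str
    endpoint: str
    n_pre: int
    n_post: int
    u_statistic: float
    p_value: float
    mean_diff: float  # post - pre, endpoint units
    ci95_low: float
    ci95_high: float
    direction: str  # "reduction" | "increase" | "none"
    category: str  # one of CATEGORIES

    @property
    def mw_significant(self) -> bool:
        return self.p_value < 0.05

    @property
    def ci_significant(self) -> bool:
        return not (self.ci95_low <= 0.0 <= self.ci95_high)


@dataclass(frozen=True)
class ComparisonGrid:
    """Organ x endpoint matrix of test results at one significance level."""

    results: tuple[EndpointTestResult, ...]
    alpha: float
    organs: tuple[str, ...]
    endpoints: tuple[str, ...]
    missing_organs: tuple[str, ...] = ()

    @property
    def n_evaluations(self) -> int:
        return len(self.results)

    def cell(self, organ: str, endpoint: str) -> EndpointTestResult:
        for r in self.results:
            if r.organ == organ and r.endpoint == endpoint:
                return r
        raise KeyError((organ, endpoint))


@dataclass(frozen=True)
class TimelinePoint:
    """Mean (and SD, undefined at n == 1) of Dmean for one treatment year."""

    year: int
    n: int
    mean_of_dmean: float
    sd: float  # NaN when n == 1


@dataclass(frozen=True)
class Timeline:
    points: tuple[TimelinePoint, ...]
    median_pre: float  # median of all Dmean before the first split year
    median_post: float  # median of all Dmean from the second split year on
    split_years: tuple[int, int]


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------


def population_mean_dvh(
    registry: Registry,
    cohort: Cohort | str,
    organ: str,
    common_grid: np.ndarray,
) -> MeanDVH:
    """Per-edge mean and standard uncertainty of a cohort's DVHs.

    Every curve is resampled onto ``common_grid`` by the same linear
    interpolation that serves VxGy lookups, then averaged edge-wise.
    """
    if isinstance(cohort, str):
        cohort = registry.get_cohort(cohort)
    if len(cohort) == 0:
        raise RegistryError(f"cohort {cohort.name!r} is empty")
    grid = np.asarray(common_grid, dtype=float)
    curves = []
    for serial in cohort.serials:
        plan = registry.load_plan(serial)
        if organ not in plan.dvhs:
            continue
        dvh = plan.dvhs[organ]
        curves.append([v_at_dose(dvh, float(d)) for d in grid])
    if not curves:
        raise RegistryError(f"organ {organ!r} absent from cohort {cohort.name!r}")
    arr = np.asarray(curves)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    if n >= 2:
        sem = arr.std(axis=0, ddof=1) / math.sqrt(n)
    else:
        sem = np.full(grid.shape, np.nan)
    return MeanDVH(grid, mean, sem, n)


def distribution_summary(sample) -> DistributionSummary:
    """Mean/median, SD, quartiles and the t-based 95 % CI of the mean.

    Quartiles use linear interpolation of order statistics (the convention in
    which {1,2,3,4} has q1 = 1.75 and q3 = 3.25).  SD and CI are undefined
    (NaN) for a single observation.
    """
    arr = np.asarray(sample, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    n = arr.size
    mean = float(arr.mean())
    q1, med, q3 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    if n > 1:
        sd = float(arr.std(ddof=1))
        half = float(stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
        lo, hi = mean - half, mean + half
    else:
        sd = lo = hi = math.nan
    return DistributionSummary(n, mean, med, sd, q1, q3, q3 - q1, lo, hi)


@lru_cache(maxsize=64)
def _exact_u_cdf(n1: int, n2: int) -> np.ndarray:
    """Null CDF of the Mann-Whitney U statistic for tie-free samples.

    Entry u is P(U <= u) under random assignment of the n1+n2 distinct ranks.
    Computed by the subset-sum recurrence: counts[k][s] = number of k-subsets
    of {1..n} with rank sum s.
    """
    n = n1 + n2
    max_sum = n1 * n + 1
    counts = np.zeros((n1 + 1, max_sum), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            counts[k, rank:] += counts[k - 1, :-rank]
    offset = n1 * (n1 + 1) // 2  # U1 = ranksum - n1(n1+1)/2
    pmf = counts[n1, offset : offset + n1 * n2 + 1]
    pmf /= pmf.sum()
    return np.cumsum(pmf)


def mann_whitney_u(
    pre_sample, post_sample, exact_limit: int = EXACT_LIMIT
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns ``(U, p)`` with U = min(U1, U2).

    Ranks use midranks for ties.  For tie-free samples with combined size at
    most ``exact_limit`` the p-value is exact, 2 P(U <= u) from the full null
    distribution (capped at 1); otherwise a normal approximation with tie
    correction and continuity correction is used.  Samples that are entirely
    tied give p = 1.
    """
    x = np.asarray(pre_sample, dtype=float)
    y = np.asarray(post_sample, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if not has_ties and n1 + n2 <= exact_limit:
        cdf = _exact_u_cdf(n1, n2)
        p = min(1.0, 2.0 * float(cdf[int(round(u))]))
        return u, p

    n = n1 + n2
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma_sq <= 0:
        return u, 1.0  # all observations tied
    mu = n1 * n2 / 2.0
    z = (u - mu + 0.5) / math.sqrt(sigma_sq)  # U = min side, continuity toward mu
    p = min(1.0, 2.0 * float(stats.norm.cdf(z)))
    return u, p


def mean_diff_ci(
    pre_sample, post_sample, confidence: float = 0.95, pooled: bool = False
) -> tuple[float, float, float]:
    """Difference of means (post - pre) with its t-based confidence interval.

    By default the Welch construction: standard uncertainty
    sqrt(s1^2/n1 + s2^2/n2) and Welch-Satterthwaite degrees of freedom.
    ``pooled=True`` switches to the equal-variance construction.  Two samples
    with zero combined variance give a degenerate zero-width interval.
    """
    x = np.asarray(pre_sample, dtype=float)
    y = np.asarray(post_sample, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    n1, n2 = x.size, y.size
    diff = float(y.mean() - x.mean())
    v1, v2 = float(x.var(ddof=1)), float(y.var(ddof=1))
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        su = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        su = math.sqrt(v1 / n1 + v2 / n2)
        if su > 0:
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        else:
            df = n1 + n2 - 2
    if su == 0.0:
        return diff, diff, diff  # degenerate: both samples constant
    half = float(stats.t.ppf((1 + confidence) / 2, df)) * su
    return diff, diff - half, diff + half


def classify_change(
    p_value: float, mean_diff: float, alpha: float = 0.05, tol: float = 1e-9
) -> str:
    """Five-way change category from significance and direction.

    A difference within ``tol`` of zero is "no change" regardless of p;
    otherwise the sign of (post - pre) sets reduction vs increase, and
    p < alpha sets significant vs nonsignificant.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if abs(mean_diff) <= tol:
        return "no_change"
    direction = "reduction" if mean_diff < 0 else "increase"
    sig = "significant" if p_value < alpha else "nonsignificant"
    return f"{sig}_{direction}"


# ---------------------------------------------------------------------------
# Grid-level analysis
# ---------------------------------------------------------------------------


def compare_samples(
    organ: str,
    endpoint: str,
    pre: list[float],
    post: list[float],
    alpha: float = 0.05,
    tol: float = 1e-9,
) -> EndpointTestResult:
    """One grid cell from raw endpoint samples (pre and post cohorts)."""
    u, p = mann_whitney_u(pre, post)
    diff, lo, hi = mean_diff_ci(pre, post)
    category = classify_change(p, diff, alpha=alpha, tol=tol)
    direction = (
        "none" if abs(diff) <= tol else ("reduction" if diff < 0 else "increase")
    )
    return EndpointTestResult(
        organ=organ,
        endpoint=endpoint,
        n_pre=len(pre),
        n_post=len(post),
        u_statistic=u,
        p_value=p,
        mean_diff=diff,
        ci95_low=lo,
        ci95_high=hi,
        direction=direction,
        category=category,
    )


def compare_plan_cohorts(
    pre_plans,
    post_plans,
    organs: tuple[str, ...],
    endpoints: tuple[str, ...] = ENDPOINTS,
    alpha: float = 0.05,
) -> ComparisonGrid:
    """Organ x endpoint grid straight from in-memory plan records.

    Same analysis as :func:`compare_cohorts` without a registry round trip;
    convenient for simulation studies.  Plans lacking an organ are skipped
    per cell; organs absent from either whole cohort are excluded.
    """
    from .dvh_core import extract_metrics

    results = []
    kept, missing = [], []
    for organ in organs:
        pre_any = any(organ in p.dvhs for p in pre_plans)
        post_any = any(organ in p.dvhs for p in post_plans)
        if not (pre_any and post_any):
            missing.append(organ)
            continue
        kept.append(organ)
        # metrics are extracted once per plan, then sliced per endpoint
        pre_metrics = [
            extract_metrics(p.dvhs[organ]) for p in pre_plans if organ in p.dvhs
        ]
        post_metrics = [
            extract_metrics(p.dvhs[organ]) for p in post_plans if organ in p.dvhs
        ]
        for ep in endpoints:
            pre = [m.endpoint(ep) for m in pre_metrics]
            post = [m.endpoint(ep) for m in post_metrics]
            results.append(compare_samples(organ, ep, pre, post, alpha=alpha))
    return ComparisonGrid(
        results=tuple(results),
        alpha=alpha,
        organs=tuple(kept),
        endpoints=tuple(endpoints),
        missing_organs=tuple(missing),
    )


def compare_cohorts(
    registry: Registry,
    cohort_pre: Cohort | str,
    cohort_post: Cohort | str,
    organs: tuple[str, ...],
    endpoints: tuple[str, ...] = ENDPOINTS,
    alpha: float = 0.05,
) -> ComparisonGrid:
    """Full organ x endpoint comparison of two cohorts.

    Organs missing from either cohort are excluded from the grid and listed
    in ``missing_organs``; the evaluation count is |kept organs| x |endpoints|.
    """
    if isinstance(cohort_pre, str):
        cohort_pre = registry.get_cohort(cohort_pre)
    if isinstance(cohort_post, str):
        cohort_post = registry.get_cohort(cohort_post)
    if len(cohort_pre) == 0 or len(cohort_post) == 0:
        raise RegistryError("both cohorts must be non-empty")

    results = []
    kept: list[str] = []
    missing: list[str] = []
    for organ in organs:
        try:
            samples = {
                ep: (
                    registry.cohort_metric_sample(cohort_pre, organ, ep)[0],
                    registry.cohort_metric_sample(cohort_post, organ, ep)[0],
                )
                for ep in endpoints
            }
        except RegistryError:
            missing.append(organ)
            continue
        kept.append(organ)
        for ep in endpoints:
            pre, post = samples[ep]
            results.append(compare_samples(organ, ep, pre, post, alpha=alpha))
    return ComparisonGrid(
        results=tuple(results),
        alpha=alpha,
        organs=tuple(kept),
        endpoints=tuple(endpoints),
        missing_organs=tuple(missing),
    )


def agreement_fraction(
    grid: ComparisonGrid,
) -> tuple[int, int, float, list[EndpointTestResult]]:
    """Consistency between the rank-test and CI significance verdicts.

    A cell agrees when (p < alpha) and (CI excludes 0) give the same verdict.
    Returns ``(n_agree, n_total, fraction, disagreements)``.
    """
    if grid.n_evaluations == 0:
        raise ValueError("empty comparison grid")
    disagreements = [
        r for r in grid.results if (r.p_value < grid.alpha) != r.ci_significant
    ]
    n_total = grid.n_evaluations
    n_agree = n_total - len(disagreements)
    return n_agree, n_total, n_agree / n_total, disagreements


def percent_change_of_median(pre_sample, post_sample) -> float:
    """Percent reduction of the sample median, positive when post < pre."""
    m_pre = float(np.median(np.asarray(pre_sample, dtype=float)))
    m_post = float(np.median(np.asarray(post_sample, dtype=float)))
    if m_pre == 0:
        raise ValueError("pre-cohort median is zero; percent change undefined")
    return 100.0 * (m_pre - m_post) / m_pre


def timeline(
    registry: Registry,
    cohorts: list[Cohort | str] | None,
    organ: str,
    split_years: tuple[int, int],
) -> Timeline:
    """Yearly trend of Dmean for one organ, with reference medians.

    Plans are grouped by treatment year; each point carries the group mean
    and SD (undefined for single-plan years).  The reference medians are the
    median Dmean over all plans before the first split year (the
    intervention) and from the second split year on (e.g. a technique
    change).  ``cohorts=None`` uses every plan in the registry.
    """
    if cohorts is None:
        serials = registry.serials()
    else:
        serials = []
        for c in cohorts:
            c = registry.get_cohort(c) if isinstance(c, str) else c
            serials.extend(c.serials)
    values: list[tuple[int, float]] = []
    for serial in serials:
        try:
            metrics = registry.plan_metrics(serial, organ)
        except RegistryError:
            continue
        values.append((registry.plan_year(serial), metrics.d_mean))
    if not values:
        raise RegistryError(f"organ {organ!r} absent from the selected plans")

    by_year: dict[int, list[float]] = {}
    for year, v in values:
        by_year.setdefault(year, []).append(v)
    points = []
    for year in sorted(by_year):
        arr = np.asarray(by_year[year])
        sd = float(arr.std(ddof=1)) if arr.size > 1 else math.nan
        points.append(TimelinePoint(year, arr.size, float(arr.mean()), sd))

    pre_vals = [v for y, v in values if y < split_years[0]]
    post_vals = [v for y, v in values if y >= split_years[1]]
    median_pre = float(np.median(pre_vals)) if pre_vals else math.nan
    median_post = float(np.median(post_vals)) if post_vals else math.nan
    return Timeline(tuple(points), median_pre, median_post, tuple(split_years))


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def write_results_csv(grid: ComparisonGrid, path: str | Path) -> None:
    """Machine-readable grid: one row per organ-endpoint cell."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "organ",
                "endpoint",
                "n_pre",
                "n_post",
                "u",
                "p",
                "mean_diff",
                "ci_low",
                "ci_high",
                "direction",
                "category",
                "agree_mw_ci",
            ]
        )
        for r in grid.results:
            writer.writerow(
                [
                    r.organ,
                    r.endpoint,
                    r.n_pre,
                    r.n_post,
                    repr(r.u_statistic),
                    repr(r.p_value),
                    repr(r.mean_diff),
                    repr(r.ci95_low),
                    repr(r.ci95_high),
                    r.direction,
                    r.category,
                    int((r.p_value < grid.alpha) == r.ci_significant),
                ]
            )


def render_report(
    out_dir: str | Path,
    grid: ComparisonGrid,
    summaries: dict[str, tuple[DistributionSummary, DistributionSummary]] | None = None,
    mean_dvhs: dict[str, tuple[MeanDVH, MeanDVH]] | None = None,
    timelines: dict[str, Timeline] | None = None,
    dmean_samples: dict[str, tuple[list[float], list[float]]] | None = None,
) -> list[Path]:
    """Write the results CSV and static plot files into ``out_dir``.

    Produces a category heat-map of the grid, population-mean DVH bands,
    violin-style Dmean distribution plots and yearly timelines, as static
    figures.  Returns the list of files written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = out / "comparison_results.csv"
    write_results_csv(grid, csv_path)
    written.append(csv_path)

    # category heat-map
    colors = {
        "significant_reduction": "#1a9850",
        "nonsignificant_reduction": "#a6d96a",
        "no_change": "#ffffbf",
        "nonsignificant_increase": "#fdae61",
        "significant_increase": "#d73027",
    }
    organs, endpoints = grid.organs, grid.endpoints
    if organs:
        img = np.zeros((len(organs), len(endpoints), 3))
        for i, organ in enumerate(organs):
            for j, ep in enumerate(endpoints):
                hexc = colors[grid.cell(organ, ep).category].lstrip("#")
                img[i, j] = [int(hexc[k : k + 2], 16) / 255 for k in (0, 2, 4)]
        fig, ax = plt.subplots(figsize=(1.2 * len(endpoints), 0.6 * len(organs) + 1))
        ax.imshow(img, aspect="auto")
        ax.set_xticks(range(len(endpoints)), endpoints)
        ax.set_yticks(range(len(organs)), organs)
        ax.set_title("Change categories (pre vs post)")
        fig.tight_layout()
        p = out / "category_grid.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

    if mean_dvhs:
        for organ, (pre, post) in mean_dvhs.items():
            fig, ax = plt.subplots(figsize=(5, 3.5))
            for mdvh, label, color in ((pre, "pre", "C0"), (post, "post", "C1")):
                ax.plot(mdvh.dose_edges, mdvh.mean_rel_volume, color=color, label=label)
                if mdvh.n >= 2:
                    ax.fill_between(
                        mdvh.dose_edges,
                        mdvh.mean_rel_volume - mdvh.sem_rel_volume,
                        mdvh.mean_rel_volume + mdvh.sem_rel_volume,
                        color=color,
                        alpha=0.3,
                    )
            ax.set_xlabel("Dose (Gy)")
            ax.set_ylabel("Relative volume (%)")
            ax.set_title(f"Population-mean DVH: {organ}")
            ax.legend()
            fig.tight_layout()
            p = out / f"mean_dvh_{organ}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)

    if dmean_samples:
        organs_v = list(dmean_samples)
        fig, ax = plt.subplots(figsize=(max(6, 1.1 * len(organs_v)), 4))
        pos = np.arange(len(organs_v), dtype=float)
        pre_data = [dmean_samples[o][0] for o in organs_v]
        post_data = [dmean_samples[o][1] for o in organs_v]
        vp1 = ax.violinplot(pre_data, positions=pos - 0.18, widths=0.32)
        vp2 = ax.violinplot(post_data, positions=pos + 0.18, widths=0.32)
        for body in vp1["bodies"]:
            body.set_facecolor("C0")
        for body in vp2["bodies"]:
            body.set_facecolor("C1")
        ax.set_xticks(pos, organs_v, rotation=45, ha="right")
        ax.set_ylabel("Dmean (Gy)")
        ax.set_title("Dmean distributions (pre: blue, post: orange)")
        fig.tight_layout()
        p = out / "dmean_violins.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

    if timelines:
        for organ, tl in timelines.items():
            fig, ax = plt.subplots(figsize=(5.5, 3.5))
            years = [pt.year for pt in tl.points]
            means = [pt.mean_of_dmean for pt in tl.points]
            errs = [0.0 if math.isnan(pt.sd) else pt.sd for pt in tl.points]
            ax.errorbar(years, means, yerr=errs, fmt="ko-", capsize=3)
            ax.axvline(tl.split_years[0], color="red", lw=1)
            ax.axvline(tl.split_years[1], color="green", lw=1)
            if not math.isnan(tl.median_pre):
                ax.axhline(tl.median_pre, color="blue", lw=1, ls="--")
            if not math.isnan(tl.median_post):
                ax.axhline(tl.median_post, color="cyan", lw=1, ls="--")
            ax.set_xlabel("Treatment year")
            ax.set_ylabel("Mean of Dmean (Gy)")
            ax.set_title(f"Yearly trend: {organ}")
            fig.tight_layout()
            p = out / f"timeline_{organ}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)

    return written
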
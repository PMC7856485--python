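"""Seeded synthetic cohorts with the structure the monitoring analysis assumes.

No public dataset of per-patient craniospinal-irradiation DVHs exists, so the
generator emulates one: per patient and organ, a cumulative DVH from a
truncated-logistic family whose midpoint dose d50 varies across patients
(lognormal, so it stays positive), with an injectable multiplicative
post-intervention reduction of d50 for chosen organs.  Organs far from the
spinal target (lungs, kidneys, liver, heart, stomach) get low d50 profiles;
organs adjacent to it (esophagus, trachea, thyroid) get high ones -- the
dichotomy that drives which endpoints can plausibly improve.

The family is, for patient i with midpoint ``m = d50_i``:

    V(d) = 100                                          for d <= d_low
    V(d) = 100 * (f(d) - f(d_high)) / (f(d_low) - f(d_high))   otherwise,

with ``f(d) = 1 / (1 + exp((d - m)/slope))``, ``d_low = low_frac * m`` and
``d_high = m + tail * slope``.  The low-dose plateau models the nonzero
scatter floor every organ receives, and the truncation pins V to exactly 0 at
a finite, patient-specific maximum dose; both scale with ``m`` so that every
one of the eight monitored endpoints, Dmin and Dmax included, is a continuous
patient-level quantity.  V(t) is closed-form, monotone in ``m``, so cohort
medians of VtGy have analytic references for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .dvh_core import CumulativeDVH, DoseGrid, StructureMask
from .ingest import PlanMetadata, PlanRecord

__all__ = [
    "OrganProfile",
    "StudyConfig",
    "DEFAULT_PROFILES",
    "analytic_v_at",
    "generate_patient_dvh",
    "generate_cohorts",
    "generate_dose_grid_case",
]


@dataclass(frozen=True)
class OrganProfile:
    """Population-level DVH shape for one organ.

    ``d50`` is the dose (Gy) at which half the organ volume is covered,
    ``slope`` the logistic steepness (Gy), ``effect`` the multiplicative
    factor applied to d50 in the post-intervention cohort (1.0 = no change,
    0.5 = halved).  ``volume_range`` bounds the uniformly drawn organ volume
    (cm^3).
    """

    name: str
    d50: float
    slope: float
    near_target: bool = False
    effect: float = 1.0
    volume_range: tuple[float, float] = (50.0, 300.0)
    low_frac: float = 0.2
    tail: float = 12.0

    def __post_init__(self) -> None:
        if not self.d50 > 0 or not self.slope > 0:
            raise ValueError("d50 and slope must be positive")
        if not 0 < self.effect <= 1.5:
            raise ValueError("effect must lie in (0, 1.5]")


#: Default ten-organ study: distant organs with low d50 (doses fall off away
#: from the spinal target), near-target organs with high d50 and a high dose
#: floor (their whole volume sits close to the 36 Gy target axis).  The
#: parameters are calibrated so the family curve at the population d50
#: reproduces the V5/V10/V20 pattern of a historical craniospinal constraint
#: table: hearts near full coverage at 5 Gy but spared at 20 Gy, esophagus
#: and trachea saturated (100 %/100 %) at 5 and 10 Gy with V20 in the
#: 20-35 % range, thyroid saturated at 5 Gy only.  Pediatric-scale volumes.
DEFAULT_PROFILES: tuple[OrganProfile, ...] = (
    OrganProfile("heart", d50=8.3, slope=1.4, volume_range=(150.0, 400.0)),
    OrganProfile("left_lung", d50=5.2, slope=2.0, volume_range=(300.0, 900.0)),
    OrganProfile("right_lung", d50=6.4, slope=2.2, volume_range=(350.0, 1000.0)),
    OrganProfile("left_kidney", d50=5.8, slope=1.9, volume_range=(50.0, 150.0)),
    OrganProfile("right_kidney", d50=6.6, slope=1.7, volume_range=(50.0, 150.0)),
    OrganProfile("liver", d50=5.8, slope=2.5, volume_range=(400.0, 1200.0)),
    OrganProfile("stomach", d50=7.0, slope=2.0, low_frac=0.72, volume_range=(100.0, 400.0)),
    OrganProfile(
        "esophagus", d50=16.5, slope=4.0, low_frac=0.68, near_target=True,
        volume_range=(10.0, 40.0),
    ),
    OrganProfile(
        "trachea", d50=14.0, slope=3.5, low_frac=0.79, near_target=True,
        volume_range=(10.0, 30.0),
    ),
    OrganProfile(
        "thyroid", d50=13.5, slope=1.9, low_frac=0.42, near_target=True,
        volume_range=(5.0, 20.0),
    ),
)


@dataclass(frozen=True)
class StudyConfig:
    """One synthetic pre/post study.

    Defaults mirror the monitored clinical setting: 10 pre-intervention and
    9 post-intervention plans of 36 Gy in 20 fractions, pre years 2009-2014
    (TomoTherapy) and post years 2015-2019 (IMRT), 12 % inter-patient
    coefficient of variation on d50.
    """

    n_pre: int = 10
    n_post: int = 9
    profiles: tuple[OrganProfile, ...] = DEFAULT_PROFILES
    inter_patient_cv: float = 0.12
    rx_dose: float = 36.0
    rx_fractions: int = 20
    pre_years: tuple[int, int] = (2009, 2014)
    post_years: tuple[int, int] = (2015, 2019)
    pre_technique: str = "TomoTherapy"
    post_technique: str = "IMRT"
    bin_width: float = 0.1
    seed: int = 20141201

    def __post_init__(self) -> None:
        if self.n_pre < 1 or self.n_post < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.inter_patient_cv < 0:
            raise ValueError("inter_patient_cv must be >= 0")

    def with_effects(self, effects: dict[str, float]) -> "StudyConfig":
        """Copy of the config with per-organ post-intervention effects set."""
        profiles = tuple(
            replace(p, effect=effects.get(p.name, p.effect)) for p in self.profiles
        )
        return replace(self, profiles=profiles)


def analytic_v_at(
    threshold: float,
    d50: float,
    slope: float,
    low_frac: float = 0.2,
    tail: float = 12.0,
) -> float:
    """Closed-form V(threshold) (%) of the truncated-logistic family."""
    d_low = low_frac * d50
    d_high = d50 + tail * slope
    if threshold <= d_low:
        return 100.0
    if threshold >= d_high:
        return 0.0

    def f(d: float) -> float:
        return 1.0 / (1.0 + np.exp((d - d50) / slope))

    return 100.0 * (f(threshold) - f(d_high)) / (f(d_low) - f(d_high))


def generate_patient_dvh(
    profile: OrganProfile,
    d50_multiplier: float,
    volume_cc: float,
    bin_width: float = 0.1,
) -> CumulativeDVH:
    """One patient's cumulative DVH from the profile's curve family."""
    m = profile.d50 * d50_multiplier * profile.effect
    d_low = profile.low_frac * m
    d_high = m + profile.tail * profile.slope
    n_edges = int(np.floor(d_high / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    f = 1.0 / (1.0 + np.exp((edges - m) / profile.slope))
    f_low = 1.0 / (1.0 + np.exp((d_low - m) / profile.slope))
    f_high = 1.0 / (1.0 + np.exp((d_high - m) / profile.slope))
    rel = 100.0 * (f - f_high) / (f_low - f_high)
    rel[edges <= d_low] = 100.0
    rel = np.clip(rel, 0.0, 100.0)
    rel[-1] = 0.0
    rel = np.minimum.accumulate(rel)
    return CumulativeDVH(edges, rel, float(volume_cc))


def _lognormal_multipliers(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-median lognormal multipliers with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, size))


def generate_cohorts(config: StudyConfig) -> tuple[list[PlanRecord], list[PlanRecord]]:
    """Draw the pre- and post-intervention cohorts of a synthetic study.

    Per patient, one lognormal d50 multiplier per organ; post-cohort organs
    additionally scaled by their profile's ``effect``.  Treatment years are
    spread evenly over the configured ranges.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)

    def build(n: int, years: tuple[int, int], technique: str, tag: str, post: bool):
        plans = []
        year_span = list(range(years[0], years[1] + 1))
        for i in range(n):
            dvhs = {}
            for profile in config.profiles:
                p = profile if post else replace(profile, effect=1.0)
                mult = _lognormal_multipliers(rng, config.inter_patient_cv, 1)[0]
                volume = rng.uniform(*profile.volume_range)
                dvhs[profile.name] = generate_patient_dvh(
                    p, mult, volume, config.bin_width
                )
            meta = PlanMetadata(
                source_id=f"{tag}-{i + 1:03d}",
                rx_dose=config.rx_dose,
                rx_fractions=config.rx_fractions,
                technique=technique,
                treatment_year=year_span[i * len(year_span) // n],
            )
            plans.append(PlanRecord(meta=meta, dvhs=dvhs))
        return plans

    pre = build(config.n_pre, config.pre_years, config.pre_technique, "pre", post=False)
    post = build(
        config.n_post, config.post_years, config.post_technique, "post", post=True
    )
    return pre, post


def write_study(
    config: StudyConfig, out_dir: str | Path, write_config: bool = True
) -> tuple[Path, Path]:
    """Emit the study through the public exchange format (two CSV files).

    Optionally writes the generating configuration alongside as YAML for
    provenance.  Returns the (pre, post) CSV paths.
    """
    from .ingest import write_dvh_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pre, post = generate_cohorts(config)
    pre_path = out / "cohort_pre.csv"
    post_path = out / "cohort_post.csv"
    write_dvh_csv(pre, pre_path)
    write_dvh_csv(post, post_path)
    if write_config:
        payload = {
            "n_pre": config.n_pre,
            "n_post": config.n_post,
            "inter_patient_cv": config.inter_patient_cv,
            "rx_dose": config.rx_dose,
            "rx_fractions": config.rx_fractions,
            "pre_years": list(config.pre_years),
            "post_years": list(config.post_years),
            "seed": config.seed,
            "profiles": [
                {
                    "name": p.name,
                    "d50": p.d50,
                    "slope": p.slope,
                    "near_target": p.near_target,
                    "effect": p.effect,
                }
                for p in config.profiles
            ],
        }
        with open(out / "study_config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
    return pre_path, post_path


def generate_dose_grid_case(
    seed: int | None = None, shape: tuple[int, int, int] = (12, 12, 12)
) -> tuple[DoseGrid, dict[str, StructureMask]]:
    """A small 3-D dose grid plus masks for DICOM-free DVH testing.

    Without a seed: a linear 0-to-20 Gy dose ramp along the z axis, with a
    full-volume mask ("everything"), an axis-aligned box and a centered
    ellipsoid -- shapes whose cumulative DVHs have closed forms.  With a
    seed: smooth random dose values on the same masks, for comparison against
    brute-force voxel counting.
    """
    nz, ny, nx = shape
    z = np.arange(nz)
    if seed is None:
        values = np.broadcast_to(
            (20.0 * z / max(nz - 1, 1))[:, None, None], shape
        ).copy()
    else:
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.0, 30.0, shape)
    grid = DoseGrid(values, spacing=(2.0, 2.0, 2.0))

    full = np.ones(shape, dtype=bool)
    box = np.zeros(shape, dtype=bool)
    box[nz // 4 : 3 * nz // 4, ny // 4 : 3 * ny // 4, nx // 4 : 3 * nx // 4] = True
    zz, yy, xx = np.meshgrid(
        z - (nz - 1) / 2,
        np.arange(ny) - (ny - 1) / 2,
        np.arange(nx) - (nx - 1) / 2,
        indexing="ij",
    )
    ellipsoid = (zz / (nz / 2.5)) ** 2 + (yy / (ny / 3)) ** 2 + (
        xx / (nx / 3)
    ) ** 2 <= 1.0
    masks = {
        "everything": StructureMask("everything", full),
        "box": StructureMask("box", box),
        "ellipsoid": StructureMask("ellipsoid", ellipsoid),
    }
    return grid, masks
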
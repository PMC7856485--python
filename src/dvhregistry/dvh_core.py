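"""Cumulative dose-volume histograms and the dosimetric endpoints derived from them.

A cumulative DVH gives, for each dose level d, the relative volume (%) of a
structure receiving at least d.  Everything downstream of raw dose data --
constraint derivation, cohort monitoring, reporting -- consumes the
:class:`CumulativeDVH` produced (or imported) here, together with the standard
endpoint set V5Gy/V10Gy/V15Gy/V20Gy and Dmean/Dmedian/Dmin/Dmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseGrid",
    "StructureMask",
    "CumulativeDVH",
    "DoseMetrics",
    "DvhError",
    "DEFAULT_V_THRESHOLDS",
    "DEFAULT_BIN_WIDTH",
    "compute_cumulative_dvh",
    "v_at_dose",
    "dose_at_volume",
    "extract_metrics",
]

#: Default dose thresholds (Gy) for the VxGy endpoints.
DEFAULT_V_THRESHOLDS = (5.0, 10.0, 15.0, 20.0)

#: Default DVH sampling step (Gy).  Fine enough that binning error is far
#: below the integer-percent precision at which constraints are reported.
DEFAULT_BIN_WIDTH = 0.1


class DvhError(ValueError):
    """Invalid DVH input (empty structure, shape mismatch, bad curve)."""


@dataclass(frozen=True)
class DoseGrid:
    """A 3-D absorbed-dose distribution.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Absorbed dose per voxel in Gy; all values must be >= 0.
    spacing : tuple of float
        Voxel size along each axis in mm, strictly positive.
    origin : tuple of float
        Physical position (mm) of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or values.size == 0:
            raise DvhError("dose grid must be a non-empty 3-D array")
        if np.any(values < 0):
            raise DvhError("absorbed dose must be non-negative")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise DvhError("voxel spacing must be strictly positive on all axes")
        object.__setattr__(self, "values", values)

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3 (spacing is in mm)."""
        sz, sy, sx = self.spacing
        return sz * sy * sx / 1000.0


@dataclass(frozen=True)
class StructureMask:
    """Boolean voxel mask of one structure, congruent with a :class:`DoseGrid`."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)

    def volume_cc(self, grid: DoseGrid) -> float:
        """Structure volume: voxel count times voxel volume (cm^3)."""
        if self.mask.shape != grid.values.shape:
            raise DvhError(
                f"grid/mask mismatch for {self.name!r}: "
                f"{grid.values.shape} vs {self.mask.shape}"
            )
        return float(self.mask.sum()) * grid.voxel_volume_cc


@dataclass(frozen=True)
class CumulativeDVH:
    """One structure's cumulative dose-volume curve.

    ``rel_volume[i]`` is the percentage of the structure receiving at least
    ``dose_edges[i]`` Gy.  The curve starts at (0 Gy, 100 %), is non-increasing,
    and reaches 0 % at or above the maximum structure dose.  The absolute-volume
    curve is derived on demand as ``rel_volume / 100 * organ_volume_cc``.
    """

    dose_edges: np.ndarray
    rel_volume: np.ndarray
    organ_volume_cc: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.dose_edges, dtype=float)
        rel = np.asarray(self.rel_volume, dtype=float)
        if edges.ndim != 1 or edges.shape != rel.shape or edges.size < 2:
            raise DvhError("dose_edges and rel_volume must be 1-D, equal length >= 2")
        if edges[0] != 0.0 or np.any(np.diff(edges) <= 0):
            raise DvhError("dose_edges must start at 0 and be strictly increasing")
        if rel[0] != 100.0:
            raise DvhError("relative volume at 0 Gy must be 100 %")
        if np.any(np.diff(rel) > 1e-9):
            raise DvhError("cumulative DVH must be non-increasing")
        if abs(rel[-1]) > 1e-9:
            raise DvhError("cumulative DVH must reach 0 % at its last sample")
        if np.any(rel < -1e-9) or np.any(rel > 100.0 + 1e-9):
            raise DvhError("relative volume must lie in [0, 100] %")
        if not self.organ_volume_cc > 0:
            raise DvhError("organ volume must be positive")
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "rel_volume", rel)

    def abs_volume(self) -> np.ndarray:
        """Absolute-volume curve (cm^3) implied by the relative one."""
        return self.rel_volume / 100.0 * self.organ_volume_cc


@dataclass(frozen=True)
class DoseMetrics:
    """The endpoint set extracted from one DVH (all doses in Gy, volumes in %)."""

    d_mean: float
    d_median: float
    d_min: float
    d_max: float
    v_at: dict[float, float] = field(default_factory=dict)

    def endpoint(self, name: str) -> float:
        """Look up an endpoint by its conventional name, e.g. ``'v5'`` or ``'d_mean'``."""
        if name.startswith("v"):
            return self.v_at[float(name[1:])]
        return getattr(self, name)


def compute_cumulative_dvh(
    grid: DoseGrid, structure: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH
) -> CumulativeDVH:
    """Bin masked voxel doses into a cumulative DVH.

    The curve is sampled at edges 0, ``bin_width``, 2*``bin_width``, ... up to
    the first edge strictly beyond the maximum masked dose, so the final sample
    is exactly 0 %.  At each edge d the value is 100 times the fraction of
    masked voxels with dose >= d.
    """
    if bin_width <= 0:
        raise DvhError("bin_width must be positive")
    if structure.mask.shape != grid.values.shape:
        raise DvhError(
            f"grid/mask mismatch for {structure.name!r}: "
            f"{grid.values.shape} vs {structure.mask.shape}"
        )
    doses = grid.values[structure.mask]
    if doses.size == 0:
        raise DvhError(f"empty structure {structure.name!r}")

    d_max = float(doses.max())
    n_edges = int(np.floor(d_max / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    doses_sorted = np.sort(doses)
    # voxels with dose >= edge, via binary search on the sorted dose list
    n_ge = doses.size - np.searchsorted(doses_sorted, edges, side="left")
    rel = 100.0 * n_ge / doses.size
    return CumulativeDVH(edges, rel, structure.volume_cc(grid))


def v_at_dose(dvh: CumulativeDVH, threshold: float) -> float:
    """Relative volume (%) receiving at least ``threshold`` Gy.

    Linear interpolation between the bracketing curve samples; 0 % beyond the
    last sample.
    """
    if threshold < 0:
        raise DvhError("dose threshold must be non-negative")
    return float(np.interp(threshold, dvh.dose_edges, dvh.rel_volume, right=0.0))


def dose_at_volume(dvh: CumulativeDVH, rel_volume: float) -> float:
    """Smallest dose (Gy) at which the curve has fallen to ``rel_volume`` %.

    Defined as the crossing point of the interpolated curve with the requested
    level, approached from above: the curve segment after the last sample whose
    volume exceeds the level is interpolated linearly.  When no sample exceeds
    the level (a request of 100 %), the dose at which the curve first leaves
    its top plateau is returned, so ``dose_at_volume(dvh, 100)`` is Dmin and
    ``dose_at_volume(dvh, 0)`` is Dmax.
    """
    if not 0.0 <= rel_volume <= 100.0:
        raise DvhError("requested relative volume must lie in [0, 100] %")
    rel = dvh.rel_volume
    edges = dvh.dose_edges
    above = np.nonzero(rel > rel_volume)[0]
    if above.size == 0:
        # level at (or above) the global top: end of the leading plateau
        plateau = np.nonzero(rel >= rel[0])[0]
        return float(edges[plateau[-1]])
    i = int(above[-1])
    if i == len(rel) - 1:
        return float(edges[-1])
    v0, v1 = rel[i], rel[i + 1]
    d0, d1 = edges[i], edges[i + 1]
    return float(d0 + (v0 - rel_volume) / (v0 - v1) * (d1 - d0))


def extract_metrics(
    dvh: CumulativeDVH, thresholds: tuple[float, ...] = DEFAULT_V_THRESHOLDS
) -> DoseMetrics:
    """All standard endpoints of one DVH.

    Dmean is the area under the relative curve divided by 100 (trapezoidal
    rule), i.e. the mean of the implied differential dose distribution.
    Dmedian, Dmin and Dmax are inverse lookups at 50 %, 100 % and 0 %.
    """
    if any(t < 0 for t in thresholds):
        raise DvhError("V-thresholds must be non-negative")
    d_mean = float(np.trapezoid(dvh.rel_volume, dvh.dose_edges)) / 100.0
    return DoseMetrics(
        d_mean=d_mean,
        d_median=dose_at_volume(dvh, 50.0),
        d_min=dose_at_volume(dvh, 100.0),
        d_max=dose_at_volume(dvh, 0.0),
        v_at={float(t): v_at_dose(dvh, t) for t in thresholds},
    )
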
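"""Plan ingestion: DICOM-RT and tabular DVH imports, prescription filtering,
and structure-name normalization.

This is the "filtered, anonymized, renamed" stage in front of the registry.
Two input routes produce the same in-memory :class:`PlanRecord`:

* ``read_dicom_plan`` -- an RT-DOSE / RT-STRUCT pair, from which DVHs are
  computed on the dose grid;
* ``read_dvh_csv`` -- the DVH-exchange CSV dialect, for plans whose curves
  were exported from a treatment planning system.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dvh_core import (
    CumulativeDVH,
    DoseGrid,
    DvhError,
    StructureMask,
    compute_cumulative_dvh,
)

__all__ = [
    "PlanMetadata",
    "PlanRecord",
    "NameMap",
    "IngestError",
    "CANONICAL_ORGANS",
    "CSV_COLUMNS",
    "read_dicom_plan",
    "read_dvh_csv",
    "write_dvh_csv",
    "filter_by_prescription",
    "normalize_names",
]

#: The ten organs at risk tracked by default: bilateral lungs, both kidneys,
#: liver, heart, stomach, esophagus, trachea and thyroid gland.
CANONICAL_ORGANS = (
    "heart",
    "left_lung",
    "right_lung",
    "left_kidney",
    "right_kidney",
    "liver",
    "stomach",
    "esophagus",
    "trachea",
    "thyroid",
)

CSV_COLUMNS = [
    "plan_id",
    "rx_dose_gy",
    "rx_fractions",
    "technique",
    "treatment_year",
    "organ",
    "organ_volume_cc",
    "dose_gy",
    "rel_volume_pct",
]


class IngestError(ValueError):
    """Unreadable or invalid plan input."""


@dataclass(frozen=True)
class PlanMetadata:
    """Plan-level metadata; ``source_id`` is discarded at registry insertion."""

    source_id: str
    rx_dose: float
    rx_fractions: int
    technique: str = "unknown"
    treatment_year: int = 0

    def __post_init__(self) -> None:
        if not self.rx_dose > 0:
            raise IngestError("prescription dose must be positive")
        if self.rx_fractions < 1:
            raise IngestError("fraction count must be >= 1")
        if self.treatment_year and not 1900 <= self.treatment_year <= 2999:
            raise IngestError(f"implausible treatment year {self.treatment_year}")


@dataclass(frozen=True)
class PlanRecord:
    """One treatment plan: metadata plus one cumulative DVH per structure.

    ``serial`` is None until the registry assigns its anonymized index.
    ``unmapped`` lists structures whose raw names matched no normalization rule.
    """

    meta: PlanMetadata
    dvhs: dict[str, CumulativeDVH]
    serial: int | None = None
    unmapped: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class NameMap:
    """Ordered structure-renaming rules: glob pattern(s) -> canonical organ name.

    Patterns are matched case-insensitively against raw structure labels;
    the first matching rule wins.  Each canonical name appears in exactly one
    rule (a rule may carry several alternative patterns).
    """

    rules: tuple[tuple[tuple[str, ...], str], ...]

    def __post_init__(self) -> None:
        canon = [c for _, c in self.rules]
        if len(set(canon)) != len(canon):
            raise IngestError("canonical names must be unique within a name map")

    def lookup(self, raw_name: str) -> str | None:
        low = raw_name.lower().strip()
        for patterns, canonical in self.rules:
            if any(fnmatch.fnmatch(low, p.lower()) for p in patterns):
                return canonical
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NameMap":
        with open(path, encoding="utf-8") as fh:
            entries = yaml.safe_load(fh)
        return cls.from_entries(entries)

    @classmethod
    def from_entries(cls, entries: list[dict]) -> "NameMap":
        rules = []
        for e in entries:
            pat = e["pattern"]
            patterns = tuple([pat] if isinstance(pat, str) else pat)
            rules.append((patterns, str(e["canonical"])))
        return cls(tuple(rules))

    @classmethod
    def default(cls) -> "NameMap":
        """The shipped map covering the ten default organs at risk."""
        text = resources.files("dvhregistry").joinpath("data/default_name_map.yaml")
        return cls.from_entries(yaml.safe_load(text.read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# DICOM-RT route
# ---------------------------------------------------------------------------


def _dose_grid_from_rtdose(ds) -> DoseGrid:
    if getattr(ds, "Modality", "") != "RTDOSE" or not hasattr(ds, "PixelData"):
        raise IngestError("file is not an RT-DOSE object with a dose grid")
    values = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(np.diff(offsets).mean()) if offsets.size > 1 else 1.0
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values, spacing=(abs(dz), row_sp, col_sp), origin=origin)


def _structure_masks(struct_ds, dose_ds, grid: DoseGrid) -> dict[str, StructureMask]:
    from matplotlib.path import Path as MplPath

    dose_for = getattr(dose_ds, "FrameOfReferenceUID", None)
    struct_for = None
    for item in getattr(struct_ds, "ReferencedFrameOfReferenceSequence", []):
        struct_for = getattr(item, "FrameOfReferenceUID", None)
    if dose_for and struct_for and dose_for != struct_for:
        raise IngestError("RT-DOSE and RT-STRUCT reference different frames of reference")

    roi_names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(struct_ds, "StructureSetROISequence", [])
    }
    if not roi_names:
        raise IngestError("RT-STRUCT contains no structures")

    nz, ny, nx = grid.values.shape
    ox, oy, oz = grid.origin
    dz, dy, dx = grid.spacing
    z_slices = oz + np.arange(nz) * dz
    px, py = np.meshgrid(ox + np.arange(nx) * dx, oy + np.arange(ny) * dy)
    pixel_centers = np.column_stack([px.ravel(), py.ravel()])

    masks: dict[str, StructureMask] = {}
    for roi in getattr(struct_ds, "ROIContourSequence", []):
        name = roi_names.get(int(roi.ReferencedROINumber))
        if name is None:
            continue
        mask = np.zeros(grid.values.shape, dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            if pts.shape[0] < 3:
                continue
            k = int(np.argmin(np.abs(z_slices - pts[0, 2])))
            if abs(z_slices[k] - pts[0, 2]) > dz / 2 + 1e-6:
                continue  # contour plane outside the dose grid
            inside = MplPath(pts[:, :2]).contains_points(pixel_centers)
            mask[k] |= inside.reshape(ny, nx)
        if mask.any():
            masks[name] = StructureMask(name, mask)
    if not masks:
        raise IngestError("no contours intersect the dose grid")
    return masks


def read_dicom_plan(
    rtdose_path: str | Path,
    rtstruct_path: str | Path,
    meta: PlanMetadata,
    bin_width: float = 0.1,
) -> PlanRecord:
    """Compute one cumulative DVH per contoured structure of a DICOM-RT pair.

    Contours are rasterized onto the dose grid (nearest dose slice, polygon
    fill over pixel centers); structures must already live on the dose grid's
    frame of reference.  Structure names pass through raw -- normalization is
    a separate, explicit step.
    """
    import pydicom

    try:
        dose_ds = pydicom.dcmread(str(rtdose_path))
        struct_ds = pydicom.dcmread(str(rtstruct_path))
    except Exception as exc:  # pydicom raises a mix of types
        raise IngestError(f"cannot parse DICOM input: {exc}") from exc
    grid = _dose_grid_from_rtdose(dose_ds)
    masks = _structure_masks(struct_ds, dose_ds, grid)
    dvhs = {
        name: compute_cumulative_dvh(grid, m, bin_width) for name, m in masks.items()
    }
    return PlanRecord(meta=meta, dvhs=dvhs)


# ---------------------------------------------------------------------------
# DVH-exchange CSV route
# ---------------------------------------------------------------------------


def read_dvh_csv(path: str | Path) -> list[PlanRecord]:
    """Parse the DVH-exchange CSV dialect into plan records.

    Long format, one row per curve sample; samples for one (plan, organ) must
    be dose-sorted and satisfy the cumulative-DVH invariants.  Parse errors
    name the offending plan and organ.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise IngestError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing columns {missing}")

    plans: list[PlanRecord] = []
    for plan_id, plan_df in df.groupby("plan_id", sort=False):
        first = plan_df.iloc[0]
        meta = PlanMetadata(
            source_id=str(plan_id),
            rx_dose=float(first["rx_dose_gy"]),
            rx_fractions=int(first["rx_fractions"]),
            technique=str(first["technique"]),
            treatment_year=int(first["treatment_year"]),
        )
        dvhs: dict[str, CumulativeDVH] = {}
        for organ, curve in plan_df.groupby("organ", sort=False):
            dose = curve["dose_gy"].to_numpy(dtype=float)
            rel = curve["rel_volume_pct"].to_numpy(dtype=float)
            try:
                dvhs[str(organ)] = CumulativeDVH(
                    dose, rel, float(curve["organ_volume_cc"].iloc[0])
                )
            except DvhError as exc:
                row = int(curve.index[0]) + 2  # 1-based, after the header row
                raise IngestError(
                    f"{path}: invalid curve for plan {plan_id!r} organ {organ!r} "
                    f"(rows from {row}): {exc}"
                ) from exc
        plans.append(PlanRecord(meta=meta, dvhs=dvhs))
    return plans


def write_dvh_csv(plans: list[PlanRecord], path: str | Path) -> None:
    """Inverse of :func:`read_dvh_csv`; curves keep full float precision."""
    rows = []
    for plan in plans:
        pid = plan.meta.source_id if plan.serial is None else str(plan.serial)
        for organ, dvh in plan.dvhs.items():
            for d, v in zip(dvh.dose_edges, dvh.rel_volume):
                rows.append(
                    (
                        pid,
                        plan.meta.rx_dose,
                        plan.meta.rx_fractions,
                        plan.meta.technique,
                        plan.meta.treatment_year,
                        organ,
                        dvh.organ_volume_cc,
                        d,
                        v,
                    )
                )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


# ---------------------------------------------------------------------------
# Filtering and renaming
# ---------------------------------------------------------------------------


def filter_by_prescription(
    plans: list[PlanRecord], rx_dose: float, rx_fractions: int
) -> list[PlanRecord]:
    """Keep plans matching one named prescription scheme exactly.

    Dose matches within 0.01 Gy and the fraction count exactly; order is
    preserved.  Mixed exports are expected, so an empty result is legal.
    """
    return [
        p
        for p in plans
        if abs(p.meta.rx_dose - rx_dose) <= 0.01 and p.meta.rx_fractions == rx_fractions
    ]


def normalize_names(plan: PlanRecord, name_map: NameMap) -> PlanRecord:
    """Rename structures to canonical organ names; labels only, never numerics.

    Unmatched structures are retained under their raw name and flagged in
    ``unmapped``.  Two raw structures resolving to one canonical name within a
    plan is a collision error.
    """
    dvhs: dict[str, CumulativeDVH] = {}
    unmapped: set[str] = set()
    resolved_from: dict[str, str] = {}
    for raw, dvh in plan.dvhs.items():
        canonical = name_map.lookup(raw)
        if canonical is None:
            unmapped.add(raw)
            canonical = raw
        elif canonical in resolved_from:
            raise IngestError(
                f"name collision: {resolved_from[canonical]!r} and {raw!r} "
                f"both map to {canonical!r}"
            )
        else:
            resolved_from[canonical] = raw
        if canonical in dvhs:
            raise IngestError(f"duplicate structure name {canonical!r} in plan")
        dvhs[canonical] = dvh
    return replace(plan, dvhs=dvhs, unmapped=frozenset(unmapped))
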
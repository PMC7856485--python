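"""Persistent anonymized plan registry backed by a single SQLite file.

Plans enter through :meth:`Registry.insert_plan`, which drops the original
source identifier, assigns a monotone serial index, and caches the standard
endpoint metrics alongside the full curves.  Named cohorts group serials for
the downstream constraint-derivation and monitoring analyses.  The relational
schema is documented in ``docs/schema.md``.
"""

from __future__ import annotations

import hashlib
import sqlite3
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dvh_core import CumulativeDVH, DoseMetrics, extract_metrics
from .ingest import PlanMetadata, PlanRecord

__all__ = ["Registry", "Cohort", "RegistryError", "ENDPOINTS"]

#: The eight monitored dosimetric endpoints, in canonical order.
ENDPOINTS = ("v5", "v10", "v15", "v20", "d_mean", "d_median", "d_min", "d_max")

_SCHEMA = """
CREATE TABLE IF NOT EXISTS plans (
    serial INTEGER PRIMARY KEY AUTOINCREMENT,
    content_hash TEXT UNIQUE NOT NULL,
    rx_dose REAL NOT NULL,
    rx_fractions INTEGER NOT NULL,
    technique TEXT NOT NULL,
    treatment_year INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS structures (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    plan_serial INTEGER NOT NULL REFERENCES plans(serial),
    organ TEXT NOT NULL,
    organ_volume_cc REAL NOT NULL,
    unmapped INTEGER NOT NULL DEFAULT 0,
    d_mean REAL, d_median REAL, d_min REAL, d_max REAL,
    UNIQUE(plan_serial, organ)
);
CREATE TABLE IF NOT EXISTS dvh_points (
    structure_id INTEGER NOT NULL REFERENCES structures(id),
    idx INTEGER NOT NULL,
    dose_gy REAL NOT NULL,
    rel_volume_pct REAL NOT NULL,
    PRIMARY KEY (structure_id, idx)
);
CREATE TABLE IF NOT EXISTS metric_v_at (
    structure_id INTEGER NOT NULL REFERENCES structures(id),
    threshold_gy REAL NOT NULL,
    rel_volume_pct REAL NOT NULL,
    PRIMARY KEY (structure_id, threshold_gy)
);
CREATE TABLE IF NOT EXISTS cohorts (
    name TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS cohort_members (
    cohort TEXT NOT NULL REFERENCES cohorts(name),
    ord INTEGER NOT NULL,
    serial INTEGER NOT NULL REFERENCES plans(serial),
    PRIMARY KEY (cohort, ord)
);
CREATE TABLE IF NOT EXISTS source_links (
    source_hash TEXT PRIMARY KEY,
    serial INTEGER NOT NULL REFERENCES plans(serial)
);
"""


class RegistryError(ValueError):
    """Invalid registry operation (unknown serial, empty sample, ...)."""


@dataclass(frozen=True)
class Cohort:
    """A named, ordered set of plan serials."""

    name: str
    serials: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.serials)) != len(self.serials):
            raise RegistryError(f"cohort {self.name!r} contains duplicate serials")

    def __len__(self) -> int:
        return len(self.serials)


def _content_hash(plan: PlanRecord) -> str:
    """Hash of the plan's dosimetric content; deliberately excludes source_id."""
    h = hashlib.sha256()
    m = plan.meta
    h.update(f"{m.rx_dose!r}|{m.rx_fractions}|{m.technique}|{m.treatment_year}".encode())
    for organ in sorted(plan.dvhs):
        dvh = plan.dvhs[organ]
        h.update(organ.encode())
        h.update(np.ascontiguousarray(dvh.dose_edges).tobytes())
        h.update(np.ascontiguousarray(dvh.rel_volume).tobytes())
        h.update(f"{dvh.organ_volume_cc!r}".encode())
    return h.hexdigest()


class Registry:
    """Single-file relational store of anonymized plans and named cohorts.

    Parameters
    ----------
    path : str or Path
        SQLite database file; ``":memory:"`` gives an ephemeral registry.
    v_thresholds : tuple of float
        Dose thresholds (Gy) cached as VxGy metrics at insertion time.
    """

    def __init__(
        self,
        path: str | Path = ":memory:",
        v_thresholds: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0),
    ) -> None:
        self.path = str(path)
        self.v_thresholds = tuple(float(t) for t in v_thresholds)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Registry":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- plans --------------------------------------------------------------

    def insert_plan(self, plan: PlanRecord, keep_source_link: bool = False) -> int:
        """Insert a plan, returning its registry serial.

        The source identifier never reaches the database.  Re-inserting a plan
        with identical dosimetric content returns the existing serial and
        warns instead of duplicating.  With ``keep_source_link`` a salted hash
        of the source identifier is stored in a separate table the user may
        drop, preserving re-identification only for whoever holds the salt.
        """
        chash = _content_hash(plan)
        cur = self._conn.execute(
            "SELECT serial FROM plans WHERE content_hash = ?", (chash,)
        )
        row = cur.fetchone()
        if row is not None:
            warnings.warn(
                f"duplicate plan content; returning existing serial {row[0]}",
                stacklevel=2,
            )
            return int(row[0])

        m = plan.meta
        cur = self._conn.execute(
            "INSERT INTO plans (content_hash, rx_dose, rx_fractions, technique,"
            " treatment_year) VALUES (?,?,?,?,?)",
            (chash, m.rx_dose, m.rx_fractions, m.technique, m.treatment_year),
        )
        serial = int(cur.lastrowid)
        for organ, dvh in plan.dvhs.items():
            metrics = extract_metrics(dvh, self.v_thresholds)
            cur = self._conn.execute(
                "INSERT INTO structures (plan_serial, organ, organ_volume_cc,"
                " unmapped, d_mean, d_median, d_min, d_max) VALUES (?,?,?,?,?,?,?,?)",
                (
                    serial,
                    organ,
                    dvh.organ_volume_cc,
                    int(organ in plan.unmapped),
                    metrics.d_mean,
                    metrics.d_median,
                    metrics.d_min,
                    metrics.d_max,
                ),
            )
            sid = cur.lastrowid
            self._conn.executemany(
                "INSERT INTO dvh_points (structure_id, idx, dose_gy, rel_volume_pct)"
                " VALUES (?,?,?,?)",
                [
                    (sid, i, float(d), float(v))
                    for i, (d, v) in enumerate(zip(dvh.dose_edges, dvh.rel_volume))
                ],
            )
            self._conn.executemany(
                "INSERT INTO metric_v_at (structure_id, threshold_gy, rel_volume_pct)"
                " VALUES (?,?,?)",
                [(sid, t, metrics.v_at[t]) for t in self.v_thresholds],
            )
        if keep_source_link:
            link = hashlib.sha256(f"dvhr-link|{m.source_id}".encode()).hexdigest()
            self._conn.execute(
                "INSERT OR REPLACE INTO source_links (source_hash, serial) VALUES (?,?)",
                (link, serial),
            )
        self._conn.commit()
        return serial

    def serials(self) -> list[int]:
        return [
            int(r[0])
            for r in self._conn.execute("SELECT serial FROM plans ORDER BY serial")
        ]

    def load_plan(self, serial: int) -> PlanRecord:
        """Reconstruct a full plan record (anonymized metadata) from storage."""
        row = self._conn.execute(
            "SELECT rx_dose, rx_fractions, technique, treatment_year FROM plans"
            " WHERE serial = ?",
            (serial,),
        ).fetchone()
        if row is None:
            raise RegistryError(f"unknown serial {serial}")
        meta = PlanMetadata(
            source_id=f"serial:{serial}",
            rx_dose=row[0],
            rx_fractions=row[1],
            technique=row[2],
            treatment_year=row[3],
        )
        dvhs: dict[str, CumulativeDVH] = {}
        unmapped = set()
        for sid, organ, vol, unm in self._conn.execute(
            "SELECT id, organ, organ_volume_cc, unmapped FROM structures"
            " WHERE plan_serial = ? ORDER BY id",
            (serial,),
        ).fetchall():
            pts = self._conn.execute(
                "SELECT dose_gy, rel_volume_pct FROM dvh_points"
                " WHERE structure_id = ? ORDER BY idx",
                (sid,),
            ).fetchall()
            arr = np.asarray(pts, dtype=float)
            dvhs[organ] = CumulativeDVH(arr[:, 0], arr[:, 1], vol)
            if unm:
                unmapped.add(organ)
        return PlanRecord(
            meta=meta, dvhs=dvhs, serial=serial, unmapped=frozenset(unmapped)
        )

    def plan_metrics(self, serial: int, organ: str) -> DoseMetrics:
        """Cached endpoint metrics for one structure of one plan."""
        row = self._conn.execute(
            "SELECT id, d_mean, d_median, d_min, d_max FROM structures"
            " WHERE plan_serial = ? AND organ = ?",
            (serial, organ),
        ).fetchone()
        if row is None:
            raise RegistryError(f"serial {serial} has no structure {organ!r}")
        sid, d_mean, d_median, d_min, d_max = row
        v_at = {
            float(t): float(v)
            for t, v in self._conn.execute(
                "SELECT threshold_gy, rel_volume_pct FROM metric_v_at"
                " WHERE structure_id = ?",
                (sid,),
            )
        }
        return DoseMetrics(d_mean, d_median, d_min, d_max, v_at)

    def plan_year(self, serial: int) -> int:
        row = self._conn.execute(
            "SELECT treatment_year FROM plans WHERE serial = ?", (serial,)
        ).fetchone()
        if row is None:
            raise RegistryError(f"unknown serial {serial}")
        return int(row[0])

    # -- cohorts ------------------------------------------------------------

    def define_cohort(self, name: str, serials: list[int]) -> Cohort:
        """Persist a named ordered cohort; redefining a name replaces it."""
        known = set(self.serials())
        unknown = [s for s in serials if s not in known]
        if unknown:
            raise RegistryError(f"cohort {name!r} references unknown serials {unknown}")
        cohort = Cohort(name, tuple(int(s) for s in serials))
        self._conn.execute("DELETE FROM cohort_members WHERE cohort = ?", (name,))
        self._conn.execute("INSERT OR REPLACE INTO cohorts (name) VALUES (?)", (name,))
        self._conn.executemany(
            "INSERT INTO cohort_members (cohort, ord, serial) VALUES (?,?,?)",
            [(name, i, s) for i, s in enumerate(cohort.serials)],
        )
        self._conn.commit()
        return cohort

    def get_cohort(self, name: str) -> Cohort:
        rows = self._conn.execute(
            "SELECT serial FROM cohort_members WHERE cohort = ? ORDER BY ord", (name,)
        ).fetchall()
        if not rows and not self._conn.execute(
            "SELECT 1 FROM cohorts WHERE name = ?", (name,)
        ).fetchone():
            raise RegistryError(f"unknown cohort {name!r}")
        return Cohort(name, tuple(int(r[0]) for r in rows))

    def cohort_metric_sample(
        self, cohort: Cohort | str, organ: str, endpoint: str
    ) -> tuple[list[float], list[int]]:
        """Per-plan endpoint values for one organ, in cohort order.

        Returns ``(values, skipped_serials)``.  Plans lacking the organ are
        skipped and reported, never imputed.  An organ absent from every plan
        is an error.
        """
        if isinstance(cohort, str):
            cohort = self.get_cohort(cohort)
        endpoint = endpoint.lower()
        if endpoint not in ENDPOINTS:
            # any cached VxGy threshold is addressable as "v<threshold>"
            try:
                is_v = endpoint.startswith("v") and float(endpoint[1:]) >= 0
            except ValueError:
                is_v = False
            if not is_v:
                raise RegistryError(
                    f"unknown endpoint {endpoint!r}; one of {ENDPOINTS}"
                )
        values: list[float] = []
        skipped: list[int] = []
        for serial in cohort.serials:
            try:
                metrics = self.plan_metrics(serial, organ)
            except RegistryError:
                skipped.append(serial)
                continue
            values.append(float(metrics.endpoint(endpoint)))
        if not values:
            raise RegistryError(
                f"organ {organ!r} absent from every plan of cohort {cohort.name!r}"
            )
        return values, skipped

    def organs(self) -> list[str]:
        """Distinct organ names present anywhere in the registry."""
        return [
            r[0]
            for r in self._conn.execute(
                "SELECT DISTINCT organ FROM structures ORDER BY organ"
            )
        ]
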
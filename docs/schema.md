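# Registry schema

Single SQLite file. All floats are stored as 8-byte IEEE `REAL`, so curves
round-trip bit-for-bit.

## Tables

### plans
| column | type | notes |
| --- | --- | --- |
| serial | INTEGER PK | monotone anonymized index, assigned at insertion |
| content_hash | TEXT UNIQUE | SHA-256 of the dosimetric content (metadata minus source id, plus every curve); used for duplicate detection |
| rx_dose | REAL | prescription dose (Gy) |
| rx_fractions | INTEGER | fraction count |
| technique | TEXT | delivery technique label |
| treatment_year | INTEGER | calendar year |

The original source identifier is never written to any table.

### structures
| column | type | notes |
| --- | --- | --- |
| id | INTEGER PK | |
| plan_serial | INTEGER FK plans | |
| organ | TEXT | canonical (or raw, if unmapped) structure name; unique per plan |
| organ_volume_cc | REAL | structure volume (cm³) |
| unmapped | INTEGER | 1 if the name matched no normalization rule |
| d_mean, d_median, d_min, d_max | REAL | cached endpoint metrics (Gy), regenerable from the stored curve |

### dvh_points
| column | type | notes |
| --- | --- | --- |
| structure_id | INTEGER FK structures | |
| idx | INTEGER | sample index, 0-based |
| dose_gy | REAL | dose edge |
| rel_volume_pct | REAL | cumulative relative volume at that edge |

Full curves are stored; absolute-volume points are derived on demand as
`rel_volume_pct / 100 * organ_volume_cc`.

### metric_v_at
Cached VxGy values, one row per structure and threshold (default thresholds
5, 10, 15, 20 Gy; configurable at registry creation).

### cohorts / cohort_members
`cohorts(name)` and `cohort_members(cohort, ord, serial)` — named, ordered
plan groups. Redefining a cohort name replaces its membership.

### source_links
Optional: `source_hash` (salted SHA-256 of the source identifier) → serial.
Only written when insertion is asked to keep a re-identification link; the
table may be dropped to sever it.

## Interchange

Any plan can be exported back to the DVH-exchange CSV
(`plan_id, rx_dose_gy, rx_fractions, technique, treatment_year, organ,
organ_volume_cc, dose_gy, rel_volume_pct`, long format, dose-sorted per
organ, full float precision).
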
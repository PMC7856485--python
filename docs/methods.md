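# Methods

## The problem

Craniospinal irradiation (CSI) treats the whole brain and spinal axis, so
many organs at risk (OARs) — lungs, kidneys, liver, heart, stomach,
esophagus, trachea, thyroid — receive appreciable dose. Published organ
tolerances for pediatric CSI are scarce, and a center treating only a few
such patients per year has no natural baseline against which to judge a new
plan. This package implements a dose–volume-histogram registry for that
setting: historical plans are stored anonymized, median dose–volume values of
an accepted historical cohort become prospective planning constraints, and
planning practice is monitored by statistically comparing cohorts treated
before and after the constraints entered use.

## DVH representation and endpoints

A cumulative DVH gives, for each dose level d, the relative volume V(d) (%)
of a structure receiving at least d. Curves are sampled on a uniform dose
grid of configurable step (default **0.1 Gy** — fine enough that binning
error is far below the integer-percent precision at which constraints are
circulated), start at (0 Gy, 100 %), are non-increasing, and end at exactly
0 %. Between samples the curve is interpolated linearly; this single
interpolation serves the VxGy lookups, the inverse lookup, and the
resampling used by population-mean DVHs, so imported (curve-only) and
computed (voxel-based) DVHs go through one code path.

The monitored endpoint set is V5Gy, V10Gy, V15Gy, V20Gy, Dmean, Dmedian,
Dmin, Dmax:

- **VxGy** — interpolated V(x).
- **Dmean** — area under the relative curve divided by 100 (trapezoidal
  rule), i.e. the mean of the implied differential dose distribution.
- **Dmedian / Dmin / Dmax** — inverse lookups at 50 %, 100 % and 0 %. The
  inverse is defined as the crossing point of the interpolated curve with
  the requested level approached from above; at 100 % this yields the dose
  at which the curve first leaves its top plateau, and at 0 % the dose at
  which it reaches zero. On a curve with a flat segment at exactly the
  requested level the lower dose end is returned.

Binning makes every curve-derived metric accurate to one bin width, the
tolerance used throughout the tests.

## Constraint derivation

For a historical cohort treated under one prescription scheme (the shipped
default filter is 36 Gy in 20 fractions, matched within 0.01 Gy and an exact
fraction count), the constraint for organ o at threshold t is the **cohort
median of Vt(o)**; the median of an even-sized sample is the mean of the two
central order statistics. A median constraint is achievable by construction
(half of past accepted plans met it) yet demanding enough to discourage
drift. Tables are rendered with half-up rounding to integer percent — the
precision at which such tables are circulated on planning sheets — while the
registry keeps full float precision.

Organ inclusion is an explicit list (default: the ten OARs above), not an
automatic rule; an advisory flag marks included organs whose rendered median
V at the two lowest thresholds is 100 %/100 %, where the constraint carries
no planning information.

## Cohort monitoring

Each organ–endpoint cell of the pre/post comparison is evaluated twice:

1. **Mann–Whitney U test**, two-tailed, U = min(U1, U2) from rank sums with
   midranks for ties. For tie-free samples with combined n ≤ 20 the p-value
   is exact: the null distribution of U is built by the subset-sum
   recurrence over rank assignments and p = 2·P(U ≤ u), capped at 1. (The
   default limit keeps the 10-vs-9 study scale exact; C(19,10) ≈ 92 000
   assignments is trivially enumerable.) With ties, or beyond the limit, a
   normal approximation with tie correction and continuity correction is
   used; fully tied samples give p = 1. The rank test is appropriate here
   because dosimetric endpoint samples are small and not normally
   distributed.
2. **Welch t interval** on the difference of cohort means (post − pre):
   standard uncertainty √(s₁²/n₁ + s₂²/n₂), Welch–Satterthwaite degrees of
   freedom, 95 % by default. Welch rather than pooled variance because
   pre/post cohort spreads visibly differ in this setting; a pooled mode
   exists behind a flag. Two constant samples give a degenerate zero-width
   interval at the observed difference.

The two verdicts (p < α vs interval excludes 0) are compared per cell; the
**agreement fraction** summarizes their consistency, and disagreements are
listed by organ and endpoint. No multiple-testing correction is applied by
default — each cell is tested at per-test α = 0.05, matching how such
monitoring grids are read cell-by-cell; a Holm-correction flag would be a
natural extension but is deliberately not silently enabled.

Each cell is classified into five categories by combining significance with
the sign of the mean difference: significant/nonsignificant reduction,
no change, nonsignificant/significant increase. A difference within tol
(default 10⁻⁹ endpoint units) of zero counts as "no change" regardless of p;
the tolerance exists only to make the partition total, since a continuous
difference is never exactly zero.

Supporting summaries: population-mean DVHs with the standard uncertainty of
the mean (sd/√n, n−1 denominator; undefined at n = 1) on a common 0.1 Gy
grid; distribution summaries of Dmean (quartiles by linear interpolation of
order statistics — the convention under which {1,2,3,4} has Q1 = 1.75);
percent change of the cohort median (positive = reduction); and yearly
timelines of mean Dmean with reference medians before/after user-supplied
split years, so that improvements that began before a technique change can
be distinguished from those caused by it. Single-plan year groups report an
undefined (not zero) SD.

## Registry and anonymization

A single-file SQLite store (tables `plans`, `structures`, `dvh_points`,
`metric_v_at`, `cohorts`, `cohort_members`; see `docs/schema.md`). Plans are
keyed by a registry-assigned monotone serial; the original source identifier
is dropped before anything touches disk, and re-identification is possible
only through an optional, separately stored salted-hash link table the user
may delete. Re-inserting dosimetrically identical content returns the
existing serial with a warning. Full curves are stored (every derived point
is regenerable from them); endpoint metrics are cached per structure and are
regenerable from the stored curves. Cohort sampling skips plans lacking the
requested organ and reports them — values are never imputed.

## Synthetic studies

Real per-patient CSI dosimetry is not publicly available, so the generator
produces studies with the structure the analysis assumes. Per patient i and
organ, a cumulative DVH from a truncated-logistic family: V(d) = 100 up to a
dose floor d_low, then 100·(f(d) − f(d_high))/(f(d_low) − f(d_high)) with
f(d) = 1/(1 + exp((d − m)/slope)), m = d50·effect·lognormal multiplier. The
floor (d_low = low_frac·m) models the scatter dose every organ receives;
the truncation (d_high = m + 12·slope) pins V to exactly 0 at a finite
maximum dose. Both scale with the patient's m, so all eight endpoints —
Dmin and Dmax included — are continuous patient-level quantities, as in real
DVHs. The lognormal multiplier (unit median, default CV 12 %) keeps d50
positive; V(t) is closed-form and monotone in m, giving analytic references
for the derived medians.

Defaults are the monitored clinical scale: 10 pre / 9 post plans of 36 Gy in
20 fractions, pre years 2009–2014 (TomoTherapy), post years 2015–2019
(IMRT). The ten organ profiles are calibrated so the family curve at the
population d50 reproduces the V5/V10/V20 pattern of a published CSI
constraint table — distant organs (heart V5 ≈ 92 %, V20 ≈ 0) versus
near-target organs with a high dose floor (esophagus and trachea saturated
at 5 and 10 Gy with V20 in the 20–35 % range, thyroid saturated at 5 Gy
only). A post-intervention dose reduction is injected per organ as a
multiplicative factor on d50 (`effect`), leaving near-target organs
untouched by default.

What the generator does **not** emulate: anatomical correlation between
organs of one patient (multipliers are drawn independently per organ),
technique-specific curve shapes, re-planning or re-treatment structure, and
measurement noise on exported curves. Passing tests therefore demonstrate
the correctness and calibration of the machinery on data with the assumed
structure, not clinical conclusions about any real cohort.

## Problem sizes and numerical choices

Replicated validations run at the study scale (19 plans × 10 organs):
2000 replicates for the type-I calibration of the grid (per-cell rejection
rate under the null, which lands slightly below the nominal 0.05 because the
exact test is conservative at small n and saturated cells cannot reject),
200 replicates for effect recovery, 2000 for Welch coverage. Oracle
equivalence checks use ~100 random dose grids of a few hundred voxels and
exhaustive rank-assignment enumeration up to combined n = 10. All stochastic
paths take explicit seeds (package default 20141201) and are bit-reproducible;
the end-to-end CLI pipeline produces byte-identical CSVs across runs.

## Known limitations

- Structure masks must already live on the dose grid; resampling/registration
  between grids is out of scope, as are dose calculation, contouring and
  biological dose models (EQD2/NTCP).
- DICOM-RT contour rasterization fills closed planar polygons on the nearest
  dose slice by pixel-center inclusion; holes (XOR contours) and oblique
  orientations are not supported.
- The DVH-exchange CSV is the only supported tabular dialect; vendor export
  formats vary and are not parsed.
- The registry is single-user, file-based storage; there is no access
  control or concurrent-writer support.
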
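# Methods

## Scoring model

A lesion (primary bladder tumor, right or left pelvic-node metastasis) is
scored on a fixed panel of seven markers: uroplakin (UPK), GATA3, CK5, CK14,
CK18, CK20, CD44.  Each marker carries a percent of positive tumor cells
(0–100, real-valued) and an ordinal intensity (0, 1+, 2+, 3+), with the
invariant *intensity 0 ⇔ percent 0*.  Percent positivity also maps onto the
conventional reporting bands 0 / 1–10 / 11–50 / 51–80 / >80, each inclusive
of its upper endpoint (10 → "1–10", 10.5 → "11–50").  Intensity is carried
through validation and I/O but is never used quantitatively: the subtype
calls and all downstream statistics read only the percent scale, which is
why the simulator derives intensity deterministically from percent
(0 → 0, (0,33] → 1+, (33,66] → 2+, >66 → 3+).

Two expression cutoffs exist and are deliberately distinct parameters:

- **summary positivity** (default 1%, "any staining") for per-marker
  positivity rates — a marker counts as expressed when percent ≥ cutoff;
- **classification cutoff** (default 20%) for the two-marker algorithm and
  cluster labeling.

Both comparisons are ≥, so a lesion exactly at the cutoff is positive.

## Two-marker classification

The classifier reads CK20 and CK18 only: luminal = both ≥ cutoff, mixed =
only CK18, basal = neither.  The fourth quadrant (CK20+/CK18−) has no label
in the luminal/basal/mixed scheme, so the algorithm carries an explicit
**unclassified** reject state rather than forcing a call; rejected lesions
stay in every denominator and occupy a genuine fourth row/column of the
concordance tables.  CK5/GATA3 status at the same cutoff is attached as an
annotation (`CK5±/GATA3±`) and never alters the major call.  Consequences
that the tests assert: the four quadrants map one-to-one onto the four
calls at every cutoff, and the set of cutoffs yielding "luminal" for a
fixed lesion is exactly the interval (0, min(CK20, CK18)].

## Bootstrap cluster support

Patients are clustered on correlation distance (1 − Pearson r between
7-marker percent vectors) with average linkage (UPGMA).  UPGMA is
implemented directly so that (a) tie-breaks are deterministic — among
equally close pairs, the pair whose clusters have the lexicographically
smallest representative leaf labels merges first — and (b) every bootstrap
tree exposes exact member sets; scipy's average linkage serves as an
independent oracle in the tests.

Multiscale bootstrap: the **marker axis** is resampled with replacement
(the feature axis is the sampling axis when clustering patients) at
relative sizes r ∈ {0.5, 0.6, …, 1.4} (resample size round(r·m), m = 7),
`nboot` = 1000 resamples per scale.  A node's BP_r is the fraction of
resampled trees containing an identical member set.  With
ψ(r) = Φ⁻¹(1 − BP_r), weighted least squares fits ψ(r) ≈ v√r + c/√r, with
binomial-information weights nboot·φ(ψ)²/(BP(1−BP)) and BP clipped to
[1/(nboot+1), nboot/(nboot+1)]; then AU = 1 − Φ(v − c) and the smoothed
BP = 1 − Φ(v + c).  It follows analytically that AU = BP when c = 0 and
AU > BP when c > 0; both are asserted.

Edge policy: nodes whose BP is 0 or 1 at *every* scale are pinned to AU 0/1
with a "pinned" flag (the root is always pinned to 1); a node with fewer
than two scales strictly inside (0,1) falls back to its scale-1 BP with a
"degenerate" flag and a warning.  During bootstrap reclustering a patient
whose resampled marker vector is constant is treated as uncorrelated with
everyone (distance 1) instead of aborting the resample.

Significant clusters are the **maximal non-root** nodes with AU ≥ α
(default 0.95); nested significant nodes are absorbed; patients outside
every selected cluster are "unassigned" and are excluded (with a logged
warning) from cluster-based survival analysis.  The root is excluded
because its support is trivially 1, so including it would make the maximal
significant set always equal {root}.

A structural note on small panels: with 7 markers, a resample falls
entirely inside one subtype's positive-marker set with probability ≈
(4/7)⁷ ≈ 2%, leaving near-constant profiles whose correlations are noise.
Scale-1 BP of even perfectly separated blocks therefore saturates around
0.98 unless every marker is informative; AU, which extrapolates across
scales, still reaches ≥ 0.95 for planted subtypes (asserted on a planted
20-patient, two-subtype cohort).

## Concordance

Paired subtype calls cross-classify into a 4×4 table (rows = primary,
columns = metastasis).  Per-row stability = 100 × diagonal / row sum;
rows with no observations report NaN rather than 0.  The transition matrix
P(node subtype | primary subtype) is the row-normalized table; 95%
confidence intervals are percentile bootstrap over patients (default 2000
resamples, seeded).  The bundled reference cohort inherits a quirk of the
published counts it transcribes: the cross-classification covers all 38
primaries against one designated nodal call per patient although only 23
patients had unilateral disease (see the `reference` module docstring);
the pipeline additionally writes the clean unilateral-only (n = 23) and
bilateral paired (n = 15) tables.

## Survival

PFS runs from cystectomy to detected progression (or death, whichever
first) or right-censor; OS to death or right-censor; months.
`pfs_time ≤ os_time` is validated.  Estimation and the unweighted k-group
log-rank test are delegated to lifelines; Greenwood variance is assembled
from the KM event table as S(t)²·Σ d/(n(n−d)).  Ties between an event and
a censoring at the same time keep the censored subject at risk (standard
convention).  The test's 5%-level type-I error is asserted to lie in
[0.03, 0.07] over 1,000 null replicates.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes; its defaults
transcribe the motivating study's printed distributions:

| parameter | default | source |
| --- | --- | --- |
| subtype mixture | 11/38, 10/38, 16/38, 1/38 (luminal, basal, mixed, unclassified) | printed subtype counts |
| nodal pattern | P(unilateral) = 23/38, right-sided share 11/23 | printed nodal split |
| transition matrix | row frequencies of the printed cross-classification (e.g. luminal row 10/11, 1/11, 0, 0) | printed concordance |
| marker percents | expressed ~ 100·Beta(8,2) (mean 80%), silent ~ 100·Beta(1,20) (mean ≈ 4.8%) | chosen so the 20% cutoff misreads a marker in ~1% of lesions; the per-patient two-marker call recovers the latent subtype ≈ 99% of the time |
| PFS hazards /month | basal 0.03 < mixed 0.05 < luminal 0.08 (unclassified 0.05) | ordering reflects the reported better progression-free prognosis of basal tumors; magnitudes are free choices |
| OS hazards /month | basal 0.025, mixed/unclassified 0.035, luminal 0.05 | same rationale |
| censoring | uniform on (0, 60] months, independent | typical 5-year follow-up window |

Markers are conditionally independent given the subtype — a documented
simplification: real panels correlate beyond subtype (shared fixation,
staining batches, intratumoral heterogeneity), so passing recovery tests
show the pipeline is correct under the model, not that real cohorts are
this clean.  The latent "unclassified" pattern is simulated as CK20
expressed, CK18 silent — the only pattern the classifier rejects.

Randomness: each patient consumes an independent substream keyed by
(seed, patient index), so enlarging a cohort never perturbs existing
patients; the censoring time is window·u with u drawn before scaling, so
widening the follow-up window on a fixed seed can only convert censorings
into events (asserted).  Survival draws use the composite-event
convention: the PFS event time is min(progression, death).

## Reference cohort

`reference.reference_cohort()` is a deterministic, fully synthetic
38-patient reconstruction: per-patient marker percents are representative
template values (e.g. luminal primaries CK20 = 60, CK18 = 70) with
per-patient overrides chosen so that the printed per-marker positivity
counts (GATA3 36/38, CK18 35/38, CK5 34/38, UPK 10/38), the subtype split
(11/10/16/1), the pooled concordance counts, the bilateral marginals
(8 luminal / 7 mixed per side) and the nodal split (23/15, 11 right-only /
12 left-only) all reproduce exactly.  Survival times are deterministic
synthetic patterns carrying the printed event totals (13 progressions,
23 deaths); the published source reports no KM medians or p-values, so no
survival quantity of the reference cohort is treated as a published value.

## Problem sizes used by the tests

The suite runs planted-cluster bootstrap support at n = 20 patients with
nboot = 1000 (and smaller nboot for smoke tests), UPGMA-vs-scipy agreement
on 100 random matrices at n ≤ 6, log-rank calibration over 1,000
two-arm replicates of 60 subjects, transition-matrix recovery at n = 2,000
and mixture recovery at n = 10,000 simulated patients — sizes at which the
binomial/multinomial Monte-Carlo error is comfortably inside the asserted
tolerances (e.g. mixture share SE ≈ 0.45 points at n = 10,000 against a
±1.5-point band).

## Known limitations

- No intensity-weighted scores (H-score style composites are out of scope).
- No molecular (transcriptomic) subtype mapping; the labels are IHC-level.
- Marker independence given subtype in the simulator (see above).
- The AU fit assumes the signed-distance/curvature model holds across the
  scale grid; with only 7 markers the scale grid spans resample sizes 4–10,
  so curvature estimates are coarse for weakly supported nodes (flagged
  "degenerate" when fewer than two scales are informative).
- Wilcoxon/Peto-weighted log-rank variants and Cox regression are not
  implemented.
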
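# Methods

This note documents the models, conventions and design choices behind
`phenoprint`, in the spirit of a statistical software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Temporal images

A patient's record over the year before an index diagnosis is encoded
as a matrix `A ∈ [0,1]^{F×53}`. Columns are week offsets −52…0; week
0 is the index week. Rows are defined by a *feature registry*
(default F = 84; fully replaceable via a YAML file, in which case all
downstream shapes follow the registry's size).

**Week binning.** Weeks are 7-day blocks anchored at the index date
and counted outward: an event 1–6 days before the index is week 0,
7–13 days before is week −1, 350 days before is week −50. Days 0–6
after the index also fall in week 0, so late-in-week index events are
not lost. Events outside −52…0 are dropped and logged. (Equivalently:
the bin is the day difference divided by 7, truncated toward zero.)

**Binary rows** (hospitalization, diagnosis groups, procedure groups,
symptom groups) record presence. A hospitalization marks every week
its admission–discharge interval overlaps — a judgment call, since the
alternative (admission week only) is equally defensible; marking the
full interval preserves duration information, which is part of what
the images are meant to capture.

**Lab rows** score `min(|value − μ|/(3σ), 1)`: 0 at the cohort mean,
linear in |z|, saturating at 3 SD. The linear-in-|z| form with a 3σ
cap is the simplest monotone map with the required endpoints (0 at the
mean, 1 far away); a percentile-based map would be a reasonable
alternative and the cap is configurable. μ and σ default to shipped
conventional values per lab and are normally refitted from the cohort
(`fit_lab_standardizer`, sample mean and SD; a zero-variance cohort is
an error).

**Vital rows** score 0 inside a normal range, 1 at or beyond an
extreme bound, and linearly in between, per side; one-sided vitals
(pain score) disable the irrelevant side. Default ranges are
conventional adult values (e.g. pulse 60–100 normal, 30/180 extreme)
and are carried in the registry, overridable.

**Symptom rows** are set by case-insensitive whole-word keyword
matching against note text, with 24 symptom groups whose keyword lists
are distilled from standard clinical rating instruments (depression,
mania, sleep, psychosis, drug-induced movement disorders, suicide
risk). Negation is *not* handled: "denies anxiety" flags anxiety.
This is a deliberate floor on NLP complexity; treat symptom rows as
"symptom mentioned", not "symptom asserted".

**Aggregation.** Same-week duplicates combine by max (OR for binary
rows). Consequently encoding is order-invariant and monotone: adding
an event never lowers a pixel.

## The registry

The default 84-row layout: row 1 hospitalization; rows 2–22 the ICD-9
mental-disorders chapter (290–319) expanded one level into 21
subgroups; rows 23–38 the 16 remaining ICD-9 chapters in code order
(digestive, 520–579, lands on row 30); rows 39–45 the seven CPT
categories (HCPCS level II matched by letter-prefix); rows 46–55 the
ten highest-volume labs; rows 56–60 five vitals; rows 61–84 the
symptom groups. Code lookup is total and overlap-checked at load: an
ICD code resolves by its three-digit stem, a five-digit numeric code
by CPT range, and any unclaimed code raises (or is dropped with a log
entry, per policy). A `medication_class` group is supported for
custom registries but not present in the default rows.

## Temporal blurring

`B(i,j) = max_{j−h ≤ k ≤ j+h} A(i,k)·exp(−(k−j)²/d)` with defaults
h = 10, d = 10, implemented literally (d is not interpreted as 2σ²).
The window truncates at the matrix edges; no padding. Structural
properties (all tested): B ≥ A elementwise, monotone in A, range- and
shape-preserving, translation-equivariant away from boundaries. A
deliberately naive triple-loop oracle ships alongside the vectorized
implementation and the two are compared elementwise at 1e−12 on random
matrices.

## Clustering

Euclidean distance on row-major flattened blurred images, all pixels
equally weighted. Lloyd's algorithm with greedy k-means++
initialization (2 + ⌊ln k⌋ candidates per seed, lowest potential
kept), 10 independent restarts by default, best SSE returned;
deterministic given (data, k, seed, restarts). Nearest-centroid ties
break to the lowest centroid index; an emptied cluster is reseeded
from the farthest point; iteration stops when assignments are stable
or relative SSE improvement < 1e−8 (max 300 iterations). The
per-iteration SSE path of the winning restart is retained and is
non-increasing by construction — this observability is why the loop is
in-house; an independent library implementation serves as a
cross-check oracle in the tests, and plain (non-greedy) k-means++ was
rejected after it demonstrably missed low-mass clusters near the
origin of blurred-image space.

Because k-means labels are arbitrary, fitted clusters are relabeled
1…k by ascending centroid mean pixel mass, so label 1 is always the
least-active ("least prodrome") cluster and is the default reference
for outcome comparisons.

**Choosing k.** `sse_scan` fits each k in 2…20 independently (no warm
starts) under the same seed policy. `suggest_elbow` returns the k
range bracketing the maximum second difference of SSE(k) — an "elbow
area", not a point — and a flat curve returns the full range with a
warning. The choice of k is explicitly left to the analyst; the elbow
is advisory.

**Fingerprints** are pixelwise means of members' *original* images
(not blurred): blurring exists only to make distances behave. The
size-weighted mean of all fingerprints therefore equals the cohort
mean image exactly, which the tests assert at 1e−12.

## Outcomes and comparison

Per cluster: death rate, any-hospitalization rate, mean (sample SD)
hospitalization count, mean (sample SD) total LOS days, psychosis
rate, the event-level share of hospitalizations due to mental illness,
and among hospitalized patients the share with ≥1 mental-illness
admission. Cross-cluster significance uses the uncorrected Pearson
chi-square (binary) and one-way ANOVA (continuous) — ANOVA is applied
to skewed counts and LOS without transformation, mirroring common
practice in this literature; with heavy skew its p-values should be
read qualitatively. Effect sizes use the two standard standardized-
difference formulas (binary and continuous, above), reported as
integer percent (half away from zero) with the conventional ≥10%
flag. Degenerate comparisons (both proportions 0 or 1, both SDs zero)
raise rather than returning infinities; degenerate test tables are
skipped with a warning.

The published eight-cluster group statistics bundled in
`phenoprint.reference` reproduce the published integer ASD grid cell
for cell, with one exception: one proportion pair is printed at a
precision (one decimal percent) that cannot round back to its printed
ASD (the computed value is 14.4 against a printed 15). The test suite
asserts the printed value and documents the discrepancy rather than
special-casing it.

## Synthetic cohorts

The generator plants archetypes, each defined by: onset week;
intensity profile (none / constant / ramp / early-then-fade, the last
fading to 15% of peak); amplitude; a map of active feature rows to
weekly event probabilities; and outcome parameters. Weekly events are
independent Bernoulli draws at (row probability × weekly intensity);
graded features draw abnormal raw values (labs: a ±(0.5 + |N(0,1.5)|)
SD excursion; vitals: uniform over the abnormal band); every patient
receives the index-week mood-disorder diagnosis that defines week 0.
Hospitalization events span 1–3 week bins. All draws flow from one
seeded generator: identical spec + seed ⇒ bit-identical cohort.

One-year outcomes per archetype: death and psychosis are Bernoulli;
hospitalization counts are negative binomial (the published count SDs
exceed their means, so a Poisson would be underdispersed — dispersion
is set as r = m²/(sd²−m) from the published mean/SD pairs); total LOS
sums per-stay lognormal durations (floored at a quarter day);
mental-illness admissions are binomial within the count.

The default eight-archetype suite mirrors the qualitative taxonomy of
the published clusters — no prodrome, late-onset short (intense at
onset), two ramps of different length, early-fading, and three
early-persistent variants (mild, comorbidity-dominated, intense) —
with outcome parameters set to the published per-cluster statistics.
Each archetype owns a disjoint block of feature rows; block widths and
event probabilities are balanced so the planted clusters carry
comparable blurred-image mass (a short prodrome gets a wider block
than a year-long one). This balance is a design requirement, not a
cosmetic choice: with strongly unequal planted masses the SSE curve
bends smoothly and the max-curvature elbow settles below the true
cluster count even when recovery is perfect. A `separation` dial in
(0, 1] weakens each archetype's own rows and adds shared background
rows as it decreases, for studying recovery degradation.

**What the generator does not emulate:** realistic ICD code
frequencies, correlated comorbidity structure, free-text notes
(symptom events are emitted as structured records; the keyword matcher
is tested on literal fixtures), informative missingness, or
care-seeking dynamics. Passing recovery tests therefore demonstrate
that the pipeline's machinery is correct and that its statistics
behave as designed under known truth — not that eight clusters, or any
particular clusters, exist in real cohorts. The published real-cohort
cluster memberships are not reproducible in principle (the data are
withheld and the original initialization/seed are unreported), and are
not a validation surface here.

## Problem sizes and numerics

The validation suite runs the full pipeline at 8 × 100 patients
(k scan 2…20, 10 restarts each) and the outcome-rate recovery at
8 × 2000 patients — sizes at which every planted effect used in an
assertion is separated from its acceptance boundary by at least three
standard errors, while the whole suite stays in the tens of seconds.
Distances use the expanded-inner-product form with a clamp at zero;
SSE comparisons in tests use relative tolerances of 1e−9 to 1e−12;
exact identities (fingerprint weighted mean, blur dominance) are
asserted at 1e−12 or exactly. Determinism everywhere reduces to a
single integer seed.

## Known limitations

- Keyword symptom matching has no negation or context handling.
- ICD-9 only; ICD-10 would need a new registry and range logic.
- The default registry's row ordering beyond the anchored rows
  (1, 30, the 2–22 and 61–84 blocks) is a package convention, not a
  reconstruction of any particular production schema.
- ANOVA on heavily skewed LOS distributions is reported untransformed.
- The elbow suggestion is a curvature heuristic; on real data the SSE
  curve may have no usable elbow (the function then says so).
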
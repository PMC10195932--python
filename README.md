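# phenoprint

Temporal phenotype fingerprinting of clinical prodromes from
longitudinal EHR-style event data.

## The problem

Many psychiatric disorders — bipolar disorder is the motivating case —
are preceded by a heterogeneous *prodrome*: months of early symptoms,
comorbid diagnoses and abnormal labs before the first characteristic
episode is diagnosed. Because the prodrome varies so much between
patients, single-symptom analyses describe it poorly. `phenoprint`
instead treats each patient's pre-diagnosis year as an image and asks
an unsupervised question: *what distinct prodromal phenotypes exist,
and do they carry different prognoses?*

It is aimed at clinical informaticians and epidemiologists who have
per-patient event streams (diagnoses, procedures, labs, vitals,
hospitalizations, note-derived symptom flags) and one-year outcome
data, and want a reproducible clustering-plus-comparison pipeline.

## The method

1. **Temporal images.** Each patient becomes a matrix
   `A ∈ [0,1]^{84×53}`: 84 feature rows (a configurable registry:
   hospitalization, 21 mental-disorder ICD-9 subgroups, 16 other ICD-9
   chapters, 7 CPT groups, 10 labs, 5 vitals, 24 symptom-keyword
   groups) by 53 weekly columns (weeks −52…0 relative to the index
   diagnosis). Binary rows record presence; lab/vital rows carry a
   graded abnormality score in [0,1] (0 at the population mean /
   normal range, 1 at ≥3 SD or the extreme bound).

2. **Temporal blurring.** Before clustering, each image is blurred
   along time with a max-Gaussian kernel:

   `B(i,j) = max_{j−10 ≤ k ≤ j+10} A(i,k) · exp(−(k−j)²/10)`

   so two patients with the same feature a few weeks apart look
   similar under Euclidean distance, rather than maximally different.

3. **Clustering.** K-means (seeded greedy k-means++, 10 restarts,
   best SSE kept) on the flattened blurred images; the SSE curve is
   scanned over k = 2…20 and the "elbow area" (maximum discrete
   curvature of SSE(k)) is reported as advisory guidance — the final k
   is an analyst decision. Each cluster's *fingerprint* is the
   pixelwise mean of its members' original (unblurred) images.

4. **Outcomes.** Per-cluster one-year mortality, hospitalization rate,
   number of hospitalizations, length of stay and psychosis are
   compared across clusters (chi-square / one-way ANOVA) and against a
   reference cluster with the absolute standardized difference

   `d = |p₁−p₂| / √((p₁(1−p₁)+p₂(1−p₂))/2)` (binary) or
   `d = |m₁−m₂| / √((s₁²+s₂²)/2)` (continuous),

   with ASD ≥ 10% flagging a meaningful difference.

Because real EHR cohorts of this kind cannot be redistributed, the
package ships a synthetic-cohort generator that plants eight prodromal
archetypes (onset week, intensity trajectory, feature mix, outcome
rates) so the whole pipeline can be validated end to end against known
ground truth.

## Worked example

```python
import phenoprint as pp
from sklearn.metrics import adjusted_rand_score

specs = pp.default_archetypes(n_patients=50, separation=1.0)
cohort = pp.generate(specs, seed=1)
stack = pp.encode_cohort(cohort.events, patients=cohort.patients)
blurred = pp.blur_stack(stack)
model = pp.kmeans_fit(blurred, k=8, seed=1, n_restarts=10)

truth = [cohort.true_labels[p] for p in model.patient_ids]
print("ARI vs planted archetypes:",
      round(adjusted_rand_score(truth, model.labels), 3))

summary = pp.summarize_outcomes(cohort.outcomes, model.assignments)
asd, tests = pp.compare_clusters(summary, cohort.outcomes, model.assignments)
print(tests.round(3).to_string(index=False))
```

prints

```
ARI vs planted archetypes: 1.0
      outcome_name       test  statistic  p_value  dof
             death chi-square      4.082    0.770    7
   hospitalization chi-square     56.997    0.000    7
         psychosis chi-square     15.117    0.035    7
n_hospitalizations      anova      5.873    0.000    7
    length_of_stay      anova      4.823    0.000    7
```

The clustering recovers the eight planted archetypes exactly
(ARI = 1.0). Hospitalization-related outcomes differ strongly across
the recovered clusters — the generator plants different count and LOS
laws per archetype — while the death-rate signal is too weak to reach
significance at 50 patients per cluster (planted death rates are
0.8–4.6%), exactly the situation the ASD flag is designed for:
`pp.asd_binary(0.046, 0.013)` → `19.6`, i.e. a 20% standardized
difference that a large-n chi-square would trivially call significant
and a small-n one would miss.

A shell interface mirrors the library:
`phenoprint simulate|encode|blur|sse-scan|cluster|fingerprints|outcomes|run-all`
(see `phenoprint --help`); `run-all` takes a YAML config and writes
all artifacts plus a checksummed manifest.

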
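"""Published reference statistics for the eight prodromal phenotype clusters.

The original fingerprinting analysis of 20,000 VA bipolar-disorder
patients reported per-cluster one-year outcome summaries (death rate,
hospitalization rate, number of hospitalizations, length of stay) and
two mental-illness hospitalization proportions, together with integer
ASD percentages of each cluster against reference Cluster 1.  The
patient-level data are not public, but the published group statistics
are sufficient inputs for the standardized-difference formulas, so
they serve as the module's numeric ground truth: feeding them through
:func:`phenoprint.outcomes.asd_binary` / :func:`asd_continuous` should
recover the published integer ASDs.

All proportions here are stored as fractions in [0, 1]; published
percentages were divided by 100.
"""

from __future__ import annotations

import pandas as pd

from .outcomes import asd_binary, asd_continuous, round_asd

__all__ = [
    "reference_cluster_summary",
    "published_asd",
    "computed_asd",
    "REFERENCE_LABEL",
]

REFERENCE_LABEL = 1

# cluster -> (n, death rate, hospitalization rate, mean #hosp, sd #hosp,
#             mean LOS days, sd LOS days,
#             share of hospitalizations due to mental illness,
#             share of hospitalized patients with >=1 mental-illness stay)
_SUMMARY = {
    1: (4077, 0.013, 0.279, 0.5, 1.1, 11.1, 35.1, 0.730, 0.773),
    2: (1386, 0.021, 0.361, 0.8, 1.4, 14.5, 39.3, 0.718, 0.772),
    3: (1906, 0.008, 0.273, 0.5, 1.1, 9.3, 30.4, 0.772, 0.785),
    4: (2105, 0.014, 0.276, 0.6, 1.3, 10.2, 34.0, 0.662, 0.710),
    5: (3874, 0.010, 0.135, 0.2, 0.7, 4.0, 21.3, 0.639, 0.689),
    6: (1617, 0.046, 0.351, 0.7, 1.4, 9.4, 32.2, 0.353, 0.445),
    7: (3634, 0.014, 0.200, 0.3, 0.9, 5.9, 26.0, 0.578, 0.607),
    8: (1401, 0.026, 0.511, 1.4, 2.2, 22.8, 52.9, 0.641, 0.721),
}

# published integer ASD percentages vs Cluster 1, by outcome
_PUBLISHED_ASD = {
    "death": {2: 6, 3: 5, 4: 1, 5: 3, 6: 20, 7: 1, 8: 9},
    "hospitalization": {2: 18, 3: 1, 4: 1, 5: 36, 6: 16, 7: 19, 8: 49},
    "n_hospitalizations": {2: 24, 3: 0, 4: 8, 5: 33, 6: 16, 7: 20, 8: 52},
    "length_of_stay": {2: 9, 3: 5, 4: 3, 5: 24, 6: 5, 7: 17, 8: 26},
    "prop_hosp_events_mental": {2: 3, 3: 10, 4: 15, 5: 20, 6: 82, 7: 32, 8: 19},
    "prop_hospitalized_with_mental": {2: 0, 3: 3, 4: 15, 5: 19, 6: 71, 7: 36, 8: 12},
}

_COLUMNS = (
    "n",
    "death_rate",
    "hospitalization_rate",
    "mean_hosp",
    "sd_hosp",
    "mean_los",
    "sd_los",
    "prop_hosp_events_mental",
    "prop_hospitalized_with_mental",
)


def reference_cluster_summary() -> pd.DataFrame:
    """Published per-cluster outcome summary as a DataFrame.

    Columns match :func:`phenoprint.outcomes.summarize_outcomes`, so the
    table can be fed directly to :func:`compare_clusters`.
    """
    rows = [{"cluster": lab, **dict(zip(_COLUMNS, vals))} for lab, vals in _SUMMARY.items()]
    return pd.DataFrame(rows)


def published_asd() -> dict[str, dict[int, int]]:
    """Published integer ASD grid: outcome -> {cluster: percent}."""
    return {k: dict(v) for k, v in _PUBLISHED_ASD.items()}


def computed_asd(outcome: str, cluster: int) -> float:
    """ASD (percent, unrounded) recomputed from the published summaries.

    Applies the binary formula to rates/proportions and the continuous
    formula to means with SDs, comparing ``cluster`` against Cluster 1.
    """
    s = {lab: dict(zip(_COLUMNS, vals)) for lab, vals in _SUMMARY.items()}
    row, ref = s[cluster], s[REFERENCE_LABEL]
    if outcome == "death":
        return asd_binary(row["death_rate"], ref["death_rate"])
    if outcome == "hospitalization":
        return asd_binary(row["hospitalization_rate"], ref["hospitalization_rate"])
    if outcome == "n_hospitalizations":
        return asd_continuous(row["mean_hosp"], row["sd_hosp"], ref["mean_hosp"], ref["sd_hosp"])
    if outcome == "length_of_stay":
        return asd_continuous(row["mean_los"], row["sd_los"], ref["mean_los"], ref["sd_los"])
    if outcome in ("prop_hosp_events_mental", "prop_hospitalized_with_mental"):
        return asd_binary(row[outcome], ref[outcome])
    raise KeyError(f"unknown outcome {outcome!r}")
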
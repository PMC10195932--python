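"""One-year outcomes by cluster and standardized-difference comparison.

For each cluster the module summarizes mortality, any-hospitalization,
number of hospitalizations, total length of stay (LOS), psychosis, and
two mental-illness hospitalization proportions.  Clusters are compared
with chi-square tests (binary outcomes) or one-way ANOVA (continuous
outcomes) across all clusters, and with the absolute standardized
difference (ASD) of each cluster against a reference cluster.

ASD is the scale-free effect size conventionally used for cohort
balance checks; 10% or above flags a meaningful difference:

    binary      d = |p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2)
    continuous  d = |m1 - m2| / sqrt((s1^2 + s2^2) / 2)

reported as percent, rounded to the nearest integer (half away from
zero).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ASDResult",
    "ZeroDenominatorError",
    "asd_binary",
    "asd_continuous",
    "round_asd",
    "summarize_outcomes",
    "compare_clusters",
    "MEANINGFUL_ASD_PERCENT",
]

#: conventional threshold: an ASD of 10% or more flags a difference
MEANINGFUL_ASD_PERCENT = 10


class ZeroDenominatorError(ZeroDivisionError):
    """Both groups are degenerate; the standardized difference is undefined."""


def asd_binary(p1: float, p2: float) -> float:
    """Absolute standardized difference (percent) of two proportions."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
    denom = math.sqrt((p1 * (1.0 - p1) + p2 * (1.0 - p2)) / 2.0)
    if denom == 0.0:
        if p1 == p2:
            return 0.0
        raise ZeroDenominatorError(
            f"both proportions degenerate ({p1}, {p2}); ASD undefined"
        )
    return 100.0 * abs(p1 - p2) / denom


def asd_continuous(m1: float, s1: float, m2: float, s2: float) -> float:
    """Absolute standardized difference (percent) of two means."""
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    denom = math.sqrt((s1 * s1 + s2 * s2) / 2.0)
    if denom == 0.0:
        if m1 == m2:
            return 0.0
        raise ZeroDenominatorError("both SDs zero with unequal means; ASD undefined")
    return 100.0 * abs(m1 - m2) / denom


def round_asd(asd_percent: float) -> int:
    """Round an ASD percent to the nearest integer, half away from zero."""
    return int(math.floor(asd_percent + 0.5))


@dataclass(frozen=True)
class ASDResult:
    """One cluster-vs-reference standardized difference."""

    outcome_name: str
    cluster_label: int
    reference_label: int
    asd_percent: int

    @property
    def meaningful(self) -> bool:
        return self.asd_percent >= MEANINGFUL_ASD_PERCENT


# ---------------------------------------------------------------------------
# per-cluster summaries
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = (
    "patient_id",
    "died_within_1y",
    "hospitalizations_1y",
    "total_los_days_1y",
    "psychosis_1y",
    "mental_illness_hospitalizations_1y",
)


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"outcome records missing columns {missing}")
    if (records["mental_illness_hospitalizations_1y"] > records["hospitalizations_1y"]).any():
        raise ValueError("mental-illness hospitalizations exceed total hospitalizations")
    if (records["hospitalizations_1y"] < 0).any() or (records["total_los_days_1y"] < 0).any():
        raise ValueError("negative hospitalization count or LOS")
    return records


def summarize_outcomes(records: pd.DataFrame, assignments: dict) -> pd.DataFrame:
    """Per-cluster one-year outcome summary.

    ``records`` has one row per patient with columns
    ``patient_id, died_within_1y, hospitalizations_1y,
    total_los_days_1y, psychosis_1y,
    mental_illness_hospitalizations_1y``; ``assignments`` maps
    patient_id -> cluster label.  Returns one row per cluster with
    rates (proportions), means and sample SDs, and the two
    mental-illness proportions: the event-level share of
    hospitalizations due to mental illness, and among hospitalized
    patients the fraction with at least one mental-illness admission.
    """
    records = _validate_records(records)
    df = records.copy()
    try:
        df["cluster"] = df["patient_id"].map(lambda p: assignments[p])
    except KeyError as e:
        raise ValueError(f"patient {e.args[0]!r} has no cluster assignment") from None
    rows = []
    for lab, grp in df.groupby("cluster"):
        n = len(grp)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"cluster {lab} is empty")
            continue
        hosp = grp["hospitalizations_1y"].to_numpy(dtype=float)
        los = grp["total_los_days_1y"].to_numpy(dtype=float)
        total_hosp = hosp.sum()
        hospitalized = grp[grp["hospitalizations_1y"] >= 1]
        rows.append(
            {
                "cluster": int(lab),
                "n": n,
                "death_rate": float(grp["died_within_1y"].mean()),
                "hospitalization_rate": float((hosp >= 1).mean()),
                "mean_hosp": float(hosp.mean()),
                "sd_hosp": float(hosp.std(ddof=1)) if n > 1 else 0.0,
                "mean_los": float(los.mean()),
                "sd_los": float(los.std(ddof=1)) if n > 1 else 0.0,
                "psychosis_rate": float(grp["psychosis_1y"].mean()),
                "prop_hosp_events_mental": (
                    float(grp["mental_illness_hospitalizations_1y"].sum() / total_hosp)
                    if total_hosp > 0
                    else float("nan")
                ),
                "prop_hospitalized_with_mental": (
                    float((hospitalized["mental_illness_hospitalizations_1y"] >= 1).mean())
                    if len(hospitalized) > 0
                    else float("nan")
                ),
            }
        )
    out = pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# cross-cluster comparison
# ---------------------------------------------------------------------------

_BINARY_OUTCOMES = {
    "death": ("death_rate", "died_within_1y"),
    "hospitalization": ("hospitalization_rate", None),
    "psychosis": ("psychosis_rate", "psychosis_1y"),
}
_CONTINUOUS_OUTCOMES = {
    "n_hospitalizations": ("mean_hosp", "sd_hosp", "hospitalizations_1y"),
    "length_of_stay": ("mean_los", "sd_los", "total_los_days_1y"),
}
_PROPORTION_OUTCOMES = {
    "prop_hosp_events_mental": "prop_hosp_events_mental",
    "prop_hospitalized_with_mental": "prop_hospitalized_with_mental",
}


def compare_clusters(
    summaries: pd.DataFrame,
    records: pd.DataFrame | None = None,
    assignments: dict | None = None,
    reference_label: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ASDs vs the reference cluster plus significance tests.

    ``summaries`` is the output of :func:`summarize_outcomes` (or any
    table with the same columns, e.g. published group statistics).
    When patient-level ``records`` and ``assignments`` are supplied,
    chi-square tests (binary outcomes) and one-way ANOVA (continuous
    outcomes) across all clusters are computed as well; otherwise the
    test table is empty.

    ``reference_label`` defaults to the lowest cluster label, which
    under the package's labeling convention is the least-active
    ("least prodrome") cluster.

    Returns ``(asd_table, test_table)``.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 clusters to compare")
    summaries = summaries.set_index("cluster", drop=False)
    if reference_label is None:
        reference_label = int(summaries.index.min())
    if reference_label not in summaries.index:
        raise ValueError(f"reference cluster {reference_label} not present")
    ref = summaries.loc[reference_label]

    asd_rows = []
    for lab in summaries.index:
        if lab == reference_label:
            continue
        row = summaries.loc[lab]
        for name, (rate_col, _) in _BINARY_OUTCOMES.items():
            if rate_col in summaries.columns:
                _append_asd(asd_rows, name, lab, reference_label,
                            asd_binary(row[rate_col], ref[rate_col]))
        for name, (m_col, s_col, _) in _CONTINUOUS_OUTCOMES.items():
            if m_col in summaries.columns:
                _append_asd(asd_rows, name, lab, reference_label,
                            asd_continuous(row[m_col], row[s_col], ref[m_col], ref[s_col]))
        for name, col in _PROPORTION_OUTCOMES.items():
            if col in summaries.columns:
                p1, p2 = row[col], ref[col]
                if np.isnan(p1) or np.isnan(p2):
                    warnings.warn(f"{name}: undefined proportion in cluster {lab} "
                                  f"or reference; ASD skipped")
                    continue
                _append_asd(asd_rows, name, lab, reference_label, asd_binary(p1, p2))
    asd_table = pd.DataFrame(asd_rows)

    test_rows = []
    if records is not None and assignments is not None:
        records = _validate_records(records)
        df = records.copy()
        df["cluster"] = df["patient_id"].map(lambda p: assignments[p])
        df["any_hospitalization_1y"] = df["hospitalizations_1y"] >= 1
        binary_cols = {
            "death": "died_within_1y",
            "hospitalization": "any_hospitalization_1y",
            "psychosis": "psychosis_1y",
        }
        for name, col in binary_cols.items():
            table = pd.crosstab(df[col].astype(bool), df["cluster"])
            if table.shape[0] < 2 or (table.to_numpy().sum(axis=1) == 0).any():
                warnings.warn(f"{name}: degenerate contingency table; test skipped")
                continue
            # uncorrected Pearson statistic (no Yates continuity correction)
            chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
            test_rows.append({"outcome_name": name, "test": "chi-square",
                              "statistic": float(chi2), "p_value": float(p), "dof": int(dof)})
        for name, (_, _, col) in _CONTINUOUS_OUTCOMES.items():
            groups = [g.to_numpy(dtype=float) for _, g in df.groupby("cluster")[col]]
            if any(len(g) < 2 for g in groups):
                warnings.warn(f"{name}: a cluster has < 2 patients; ANOVA skipped")
                continue
            if all(np.ptp(g) == 0 for g in groups):
                warnings.warn(f"{name}: no within-group variance; ANOVA skipped")
                continue
            f, p = stats.f_oneway(*groups)
            test_rows.append({"outcome_name": name, "test": "anova",
                              "statistic": float(f), "p_value": float(p),
                              "dof": len(groups) - 1})
    test_table = pd.DataFrame(test_rows)
    return asd_table, test_table


def _append_asd(rows: list, name: str, lab, ref_lab, asd: float) -> None:
    pct = round_asd(asd)
    rows.append(
        {
            "outcome_name": name,
            "cluster": int(lab),
            "reference": int(ref_lab),
            "asd_percent": pct,
            "meaningful": pct >= MEANINGFUL_ASD_PERCENT,
        }
    )
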
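"""Outcome summaries, standardized differences and significance tests."""

import numpy as np
import pandas as pd
import pytest

import phenoprint as pp
from phenoprint.outcomes import (
    MEANINGFUL_ASD_PERCENT,
    ZeroDenominatorError,
    asd_binary,
    asd_continuous,
    compare_clusters,
    round_asd,
    summarize_outcomes,
)
from phenoprint.synthetic import expected_any_hospitalization_rate


class TestASDFormulas:
    @pytest.mark.parametrize(
        "p1, p2, expected_pct",
        [(0.046, 0.013, 20), (0.353, 0.730, 82), (0.3, 0.3, 0)],
    )
    def test_binary_examples(self, p1, p2, expected_pct):
        assert round_asd(asd_binary(p1, p2)) == expected_pct

    @pytest.mark.parametrize(
        "m1, s1, m2, s2, expected_pct",
        [(1.4, 2.2, 0.5, 1.1, 52), (4.0, 21.3, 11.1, 35.1, 24), (2.0, 3.0, 2.0, 9.0, 0)],
    )
    def test_continuous_examples(self, m1, s1, m2, s2, expected_pct):
        assert round_asd(asd_continuous(m1, s1, m2, s2)) == expected_pct

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(50):
            p1, p2 = rng.uniform(0.01, 0.99, 2)
            assert asd_binary(p1, p2) == pytest.approx(asd_binary(p2, p1))
            assert asd_binary(p1, p2) >= 0
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.1, 3, 2)
            assert asd_continuous(m1, s1, m2, s2) == pytest.approx(
                asd_continuous(m2, s2, m1, s1)
            )

    def test_continuous_affine_invariance(self, rng):
        m1, s1, m2, s2 = 3.0, 1.5, 5.0, 2.5
        a, b = 7.3, -2.1
        assert asd_continuous(a * m1 + b, a * s1, a * m2 + b, a * s2) == pytest.approx(
            asd_continuous(m1, s1, m2, s2)
        )

    def test_degenerate_inputs(self):
        with pytest.raises(ZeroDenominatorError):
            asd_binary(0.0, 1.0)
        assert asd_binary(0.0, 0.0) == 0.0
        with pytest.raises(ZeroDenominatorError):
            asd_continuous(1.0, 0.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            asd_binary(-0.1, 0.5)

    @pytest.mark.parametrize("x, expected", [(14.5, 15), (14.49, 14), (0.4, 0), (9.5, 10)])
    def test_rounding_half_away_from_zero(self, x, expected):
        assert round_asd(x) == expected


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "died_within_1y",
            "hospitalizations_1y",
            "total_los_days_1y",
            "psychosis_1y",
            "mental_illness_hospitalizations_1y",
        ],
    )


class TestSummaries:
    def test_small_cluster_rates(self):
        rec = _records(
            [
                ("a", True, 0, 0.0, False, 0),
                ("b", False, 2, 10.0, False, 1),
                ("c", False, 0, 0.0, True, 0),
                ("d", False, 0, 0.0, False, 0),
            ]
        )
        s = summarize_outcomes(rec, {p: 1 for p in "abcd"})
        row = s.iloc[0]
        assert row["death_rate"] == 0.25
        assert row["hospitalization_rate"] == 0.25
        assert row["mean_hosp"] == 0.5
        assert row["psychosis_rate"] == 0.25
        assert row["prop_hosp_events_mental"] == 0.5       # 1 of 2 admissions
        assert row["prop_hospitalized_with_mental"] == 1.0  # the only admitted patient

    def test_two_cluster_means(self):
        rec = _records(
            [("a", False, 0, 0.0, False, 0), ("b", False, 2, 8.0, False, 2)]
        )
        s = summarize_outcomes(rec, {"a": 1, "b": 1})
        assert s.iloc[0]["hospitalization_rate"] == 0.5
        assert s.iloc[0]["mean_hosp"] == 1.0

    def test_invariant_violation_rejected(self):
        rec = _records([("a", False, 1, 2.0, False, 3)])
        with pytest.raises(ValueError, match="mental-illness"):
            summarize_outcomes(rec, {"a": 1})

    def test_missing_assignment_rejected(self):
        rec = _records([("a", False, 0, 0.0, False, 0)])
        with pytest.raises(ValueError, match="no cluster assignment"):
            summarize_outcomes(rec, {})


class TestCompareClusters:
    def test_identical_clusters_have_zero_asd(self):
        rows = []
        for cl in (1, 2):
            for i in range(8):
                rows.append((f"p{cl}{i}", i == 0, i % 3, float(i), i == 1, min(i % 3, 1)))
        rec = _records(rows)
        assign = {f"p{cl}{i}": cl for cl in (1, 2) for i in range(8)}
        summaries = summarize_outcomes(rec, assign)
        asd, tests = compare_clusters(summaries, rec, assign)
        assert (asd["asd_percent"] == 0).all()
        assert not asd["meaningful"].any()
        assert (tests["p_value"] > 0.5).all()

    def test_chi_square_matches_closed_form_2x2(self):
        # 2 clusters, death outcome: a,b = deaths; table [[a, b], [c, d]]
        a, b, c, d = 6, 2, 14, 18
        rows, assign = [], {}
        pid = 0
        for cl, (dead, alive) in {1: (a, c), 2: (b, d)}.items():
            for died in [True] * dead + [False] * alive:
                rows.append((f"p{pid}", died, 0, 0.0, False, 0))
                assign[f"p{pid}"] = cl
                pid += 1
        rec = _records(rows)
        summaries = summarize_outcomes(rec, assign)
        _, tests = compare_clusters(summaries, rec, assign)
        n = a + b + c + d
        expected = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
        got = tests.set_index("outcome_name").loc["death", "statistic"]
        assert got == pytest.approx(expected)

    def test_reference_cluster_configurable(self):
        summaries = pd.DataFrame(
            {
                "cluster": [1, 2],
                "death_rate": [0.1, 0.3],
                "hospitalization_rate": [0.2, 0.2],
                "psychosis_rate": [0.0, 0.0],
            }
        )
        asd1, _ = compare_clusters(summaries.copy())
        asd2, _ = compare_clusters(summaries.copy(), reference_label=2)
        assert set(asd1["cluster"]) == {2} and set(asd2["cluster"]) == {1}
        d1 = asd1.set_index("outcome_name").loc["death", "asd_percent"]
        d2 = asd2.set_index("outcome_name").loc["death", "asd_percent"]
        assert d1 == d2 == round_asd(asd_binary(0.1, 0.3))

    def test_single_cluster_rejected(self):
        summaries = pd.DataFrame({"cluster": [1], "death_rate": [0.1]})
        with pytest.raises(ValueError):
            compare_clusters(summaries)


class TestPlantedEffectFlags:
    def test_flags_track_planted_effect_sizes(self, specs2000, cohort2000):
        """ASD >= 10% flags on a large synthetic cohort should agree with
        the effect sizes planted in the generator, away from the
        threshold boundary."""
        ref_label = "no_prodrome"
        out = cohort2000.outcomes
        assign = {p: lab for p, lab in cohort2000.true_labels.items()}
        # map archetype labels to integers for the comparison machinery
        names = sorted({s.label for s in specs2000})
        codes = {lab: i + 1 for i, lab in enumerate(names)}
        codes[ref_label], codes[names[0]] = 1, codes[ref_label]  # reference = 1
        int_assign = {p: codes[lab] for p, lab in assign.items()}
        summaries = summarize_outcomes(out, int_assign)
        asd, _ = compare_clusters(summaries, reference_label=1)
        ref_spec = next(s for s in specs2000 if s.label == ref_label)
        for spec in specs2000:
            if spec.label == ref_label:
                continue
            planted = asd_binary(spec.p_death, ref_spec.p_death)
            if abs(planted - MEANINGFUL_ASD_PERCENT) < 3:
                continue  # too close to the flag boundary to call
            got = asd[(asd["cluster"] == codes[spec.label]) & (asd["outcome_name"] == "death")]
            assert bool(got["meaningful"].iloc[0]) == (planted >= MEANINGFUL_ASD_PERCENT)
            planted_h = asd_binary(
                expected_any_hospitalization_rate(spec),
                expected_any_hospitalization_rate(ref_spec),
            )
            if abs(planted_h - MEANINGFUL_ASD_PERCENT) < 3:
                continue
            got_h = asd[(asd["cluster"] == codes[spec.label]) & (asd["outcome_name"] == "hospitalization")]
            assert bool(got_h["meaningful"].iloc[0]) == (planted_h >= MEANINGFUL_ASD_PERCENT)
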
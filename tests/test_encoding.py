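"""Temporal encoding: week bins, graded scores, symptom matching,
image construction and its invariants."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenoprint as pp
from phenoprint.encoding import (
    N_WEEKS,
    DegenerateDistributionError,
    VitalScorer,
    default_lexicon,
    read_images,
    week_offset,
    week_to_column,
    write_images,
)
from phenoprint.registry import UnknownCodeError


class TestWeekOffset:
    @pytest.mark.parametrize(
        "days_before, expected",
        [(0, 0), (3, 0), (6, 0), (7, -1), (350, -50), (364, -52)],
    )
    def test_backward_bins(self, days_before, expected):
        idx = date(2012, 6, 15)
        ev = date.fromordinal(idx.toordinal() - days_before)
        assert week_offset(ev, idx) == expected

    def test_far_past_event_is_out_of_window(self):
        idx = date(2012, 6, 15)
        ev = date.fromordinal(idx.toordinal() - 400)
        assert week_offset(ev, idx) < -52

    def test_post_index_same_week_included(self):
        idx = date(2012, 6, 15)
        assert week_offset(date(2012, 6, 18), idx) == 0


class TestLabStandardizer:
    def test_sample_moments(self):
        s = pp.fit_lab_standardizer([1.0, 2.0, 3.0])
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            pp.fit_lab_standardizer([5.0, 5.0, 5.0])

    def test_recovers_normal_parameters(self, rng):
        mu, sigma, n = 100.0, 25.0, 4000
        s = pp.fit_lab_standardizer(rng.normal(mu, sigma, n))
        assert abs(s.mean - mu) < 3 * sigma / np.sqrt(n)
        assert abs(s.sd - sigma) < 3 * sigma / np.sqrt(2 * n)

    @pytest.mark.parametrize(
        "z, expected", [(0.0, 0.0), (1.5, 0.5), (3.0, 1.0), (-3.0, 1.0), (7.0, 1.0)]
    )
    def test_score_linear_in_abs_z_with_cap(self, z, expected):
        s = pp.LabStandardizer(mean=10.0, sd=2.0, cap=3.0)
        assert pp.lab_score(10.0 + z * 2.0, s) == pytest.approx(expected)


class TestVitalScorer:
    scorer = VitalScorer(lo_normal=60, hi_normal=100, lo_extreme=30, hi_extreme=180)

    @pytest.mark.parametrize(
        "value, expected",
        [(80, 0.0), (60, 0.0), (100, 0.0), (180, 1.0), (250, 1.0), (30, 1.0),
         (140, 0.5), (45, 0.5)],
    )
    def test_piecewise_linear(self, value, expected):
        assert pp.vital_score(value, self.scorer) == pytest.approx(expected)

    def test_one_sided_scorer(self):
        pain = VitalScorer(0, 1, None, 10)
        assert pp.vital_score(0.5, pain) == 0.0
        assert pp.vital_score(10, pain) == 1.0
        assert pp.vital_score(5.5, pain) == pytest.approx(0.5)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            VitalScorer(60, 100, 70, 180)


class TestSymptomMatching:
    def test_empty_text(self, registry):
        assert pp.match_symptoms("", default_lexicon(registry)) == set()

    def test_single_and_multiple_groups(self, registry):
        lex = default_lexicon(registry)
        assert pp.match_symptoms("pt reports RACING THOUGHTS today", lex) == {"racing thoughts"}
        got = pp.match_symptoms("insomnia with suicidal ideation", lex)
        assert got == {"insomnia", "suicidal ideation"}

    def test_word_boundaries(self, registry):
        lex = default_lexicon(registry)
        # "panicking" must not trigger the "panic" keyword
        assert "anxiety" not in pp.match_symptoms("patient was panicking", lex)
        assert "anxiety" in pp.match_symptoms("panic attack last night", lex)

    def test_every_group_names_a_registry_row(self, registry):
        lex = default_lexicon(registry)
        for group in lex.groups:
            assert registry.by_name(group).group == "symptom"


class TestEncodePatient:
    def test_no_events_gives_zero_image(self, registry):
        img = pp.encode_patient([], registry, patient_id="p0")
        assert img.matrix.shape == (84, N_WEEKS)
        assert not img.matrix.any()

    def test_single_diagnosis_sets_one_pixel(self, registry):
        ev = [{"patient_id": "p1", "week_offset": -50, "code": "540"}]
        img = pp.encode_patient(ev, registry)
        assert img.pixel(30, -50) == 1.0
        assert img.matrix.sum() == 1.0

    def test_graded_same_week_takes_max(self, registry):
        s = pp.LabStandardizer(mean=100.0, sd=10.0, cap=3.0)
        ev = [
            {"patient_id": "p1", "week_offset": -4, "code": "glucose", "value": 106.0},
            {"patient_id": "p1", "week_offset": -4, "code": "glucose", "value": 121.0},
        ]
        img = pp.encode_patient(ev, registry, standardizers={"glucose": s})
        assert img.pixel(46, -4) == pytest.approx(0.7)

    def test_hospitalization_marks_spanned_weeks(self, registry):
        ev = [{"patient_id": "p1", "week_offset": -3, "code": "hospitalization", "end_week": -1}]
        img = pp.encode_patient(ev, registry)
        row = img.matrix[0]
        assert [pp.TemporalImage("p1", img.matrix).pixel(1, w) for w in (-4, -3, -2, -1, 0)] == [0, 1, 1, 1, 0]
        assert row.sum() == 3

    def test_out_of_window_events_dropped(self, registry):
        ev = [{"patient_id": "p1", "week_offset": -58, "code": "540"}]
        assert not pp.encode_patient(ev, registry).matrix.any()

    def test_note_text_sets_symptom_rows(self, registry):
        ev = [{"patient_id": "p1", "week_offset": -2, "note_text": "worsening insomnia"}]
        img = pp.encode_patient(ev, registry)
        assert img.pixel(registry.by_name("insomnia").row_index, -2) == 1.0

    def test_unknown_code_policy(self, registry):
        ev = [{"patient_id": "p1", "week_offset": -2, "code": "nonsense"}]
        with pytest.raises(UnknownCodeError):
            pp.encode_patient(ev, registry)
        assert not pp.encode_patient(ev, registry, unknown="drop").matrix.any()

    def test_two_patients_in_one_frame_rejected(self, registry):
        ev = [
            {"patient_id": "a", "week_offset": 0, "code": "540"},
            {"patient_id": "b", "week_offset": 0, "code": "540"},
        ]
        with pytest.raises(ValueError, match="more than one patient"):
            pp.encode_patient(ev, registry)

    def test_date_based_events(self, registry):
        ev = [{"patient_id": "p1", "date": "2012-01-02", "code": "540"}]
        img = pp.encode_patient(ev, registry, index_date=date(2012, 12, 17))
        assert img.pixel(30, -50) == 1.0


# --- property tests ---------------------------------------------------------

_event = st.fixed_dictionaries(
    {
        "patient_id": st.just("p"),
        "week_offset": st.integers(-60, 2),
        "code": st.sampled_from(["540", "296.4", "305", "hospitalization", "99213"]),
    }
)


class TestEncodingProperties:
    @given(events=st.lists(_event, max_size=25))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_range_and_order_invariance(self, events):
        reg = pp.default_registry()
        img = pp.encode_patient(events, reg, patient_id="p")
        assert img.matrix.min() >= 0 and img.matrix.max() <= 1
        assert set(np.unique(img.matrix)) <= {0.0, 1.0}  # only binary codes drawn
        rev = pp.encode_patient(list(reversed(events)), reg, patient_id="p")
        assert np.array_equal(img.matrix, rev.matrix)

    @given(events=st.lists(_event, max_size=15), extra=_event)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_adding_an_event_never_decreases_pixels(self, events, extra):
        reg = pp.default_registry()
        base = pp.encode_patient(events, reg, patient_id="p")
        more = pp.encode_patient(events + [extra], reg, patient_id="p")
        assert (more.matrix >= base.matrix - 1e-15).all()


class TestImagePersistence:
    def test_round_trip(self, stack100, tmp_path):
        sub = pp.ImageStack(stack100.patient_ids[:12], stack100.array[:12])
        p = tmp_path / "img.tsv"
        write_images(p, sub)
        back = read_images(p)
        assert back.patient_ids == sub.patient_ids
        np.testing.assert_array_equal(back.array, sub.array)

    def test_all_zero_patient_survives(self, tmp_path, registry):
        stack = pp.ImageStack(["z1"], np.zeros((1, registry.n_features, N_WEEKS)))
        p = tmp_path / "img.tsv"
        write_images(p, stack)
        back = read_images(p)
        assert back.patient_ids == ["z1"]
        assert not back.array.any()
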
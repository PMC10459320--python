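"""Tests for cut-off classification, alert zones and flip detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from htspot import (
    ClassificationPolicy,
    Direction,
    MarkerDefinition,
    ScreeningSample,
    alert_zone_bounds,
    classify_sample,
    flip_threshold_ht,
    load_panel,
    load_samples,
    screen_cohort,
)
from htspot.util import round_half_away
from paper_values import CUTOFF_BOUNDARIES


def make_sample(marker: str, c_exp: float, ht: float | None = 50.0) -> ScreeningSample:
    return ScreeningSample(sample_id="s1", ht=ht, concentrations={marker: c_exp})


class TestPanel:
    def test_builtin_panel_contents(self, panel):
        assert len(panel) == 33
        downs = [m for m in panel if m.direction is Direction.DOWN]
        assert [m.name for m in downs] == ["C0"]
        assert all(m.alert_fraction == 0.10 for m in panel)

    def test_published_boundary_column(self, marker_by_name):
        """All 33 boundary concentrations reproduce at 3 decimals."""
        for name, cutoff, direction, boundary in CUTOFF_BOUNDARIES:
            m = marker_by_name[name]
            assert m.cutoff == cutoff and m.direction.value == direction
            assert round_half_away(alert_zone_bounds(m)[0], 3) == boundary

    def test_invalid_marker_rejected(self):
        with pytest.raises(ValueError):
            MarkerDefinition("X", cutoff=-1.0)
        with pytest.raises(ValueError):
            MarkerDefinition("X", cutoff=1.0, alert_fraction=1.0)


class TestAlertZone:
    def test_up_marker_zone_below_cutoff(self, marker_by_name):
        boundary, cutoff = alert_zone_bounds(marker_by_name["Val"])
        assert (boundary, cutoff) == (pytest.approx(261.0), 290.0)

    def test_down_marker_zone_above_cutoff(self, marker_by_name):
        boundary, cutoff = alert_zone_bounds(marker_by_name["C0"])
        assert (boundary, cutoff) == (pytest.approx(6.875), 6.25)

    def test_zero_fraction_empties_the_zone(self, model):
        m = MarkerDefinition("Val", 290.0, Direction.UP, alert_fraction=0.0)
        out = classify_sample(make_sample("Val", 280.0, ht=30.0), m, 50.0, model)
        assert not out.in_alert_zone and out.raw_status == "negative"
        assert out.corrected_concentration == 280.0  # no correction applied


class TestClassifySample:
    def test_alert_zone_sample_at_calibration_ht_does_not_flip(self, marker_by_name, model):
        out = classify_sample(make_sample("Val", 261.0, ht=50.0), marker_by_name["Val"], 50.0, model)
        assert out.raw_status == "negative" and out.in_alert_zone
        assert out.corrected_concentration == pytest.approx(261.0)
        assert not out.flipped

    def test_low_ht_valine_flips_to_positive(self, marker_by_name, model):
        out = classify_sample(make_sample("Val", 261.0, ht=30.0), marker_by_name["Val"], 50.0, model)
        assert out.corrected_concentration == pytest.approx(261.0 * 1.11 / 0.97, abs=1e-6)
        assert out.corrected_status == "positive" and out.flipped

    def test_high_ht_carnitine_flips_to_positive(self, marker_by_name, model):
        out = classify_sample(make_sample("C0", 6.875, ht=65.0), marker_by_name["C0"], 50.0, model)
        assert out.corrected_concentration == pytest.approx(6.875 * 0.865 / 0.97, abs=1e-9)
        assert out.corrected_status == "positive" and out.flipped

    def test_value_at_cutoff_is_alert_zone_not_positive(self, marker_by_name, model):
        out = classify_sample(make_sample("Val", 290.0), marker_by_name["Val"], 50.0, model)
        assert out.raw_status == "negative" and out.in_alert_zone

    def test_inclusive_cutoff_policy_calls_equality_positive(self, marker_by_name, model):
        policy = ClassificationPolicy(cutoff_inclusive_positive=True)
        out = classify_sample(make_sample("Val", 290.0), marker_by_name["Val"], 50.0, model, policy)
        assert out.raw_status == "positive" and not out.in_alert_zone

    def test_correct_all_reevaluates_marginal_positive(self, marker_by_name, model):
        """A barely-positive valine at high Ht drops below the cut-off when
        every sample is corrected (positive-to-negative flip)."""
        policy = ClassificationPolicy(correct_all=True)
        out = classify_sample(make_sample("Val", 295.0, ht=65.0), marker_by_name["Val"], 50.0,
                              model, policy)
        assert out.raw_status == "positive" and out.corrected_status == "negative"
        assert out.flipped

    def test_missing_marker_concentration_raises(self, marker_by_name, model):
        with pytest.raises(KeyError, match="no concentration"):
            classify_sample(make_sample("Leu", 100.0), marker_by_name["Val"], 50.0, model)

    def test_missing_ht_raises_only_when_correction_needed(self, marker_by_name, model):
        plain = classify_sample(make_sample("Val", 100.0, ht=None), marker_by_name["Val"], 50.0, model)
        assert plain.raw_status == "negative" and not plain.in_alert_zone
        with pytest.raises(ValueError, match="hematocrit required"):
            classify_sample(make_sample("Val", 261.0, ht=None), marker_by_name["Val"], 50.0, model)


class TestFlipThreshold:
    def test_valine_threshold_below_35(self, marker_by_name, model):
        ht_star = flip_threshold_ht(marker_by_name["Val"], 261.0, 50.0, model)
        assert ht_star == pytest.approx((1.32 - 0.97 / 0.9) / 0.0070, abs=1e-9)
        assert round_half_away(ht_star, 2) == 34.60 < 35.0

    def test_carnitine_threshold_above_calibration(self, marker_by_name, model):
        ht_star = flip_threshold_ht(marker_by_name["C0"], 6.875, 50.0, model)
        assert round_half_away(ht_star, 2) == 62.60

    def test_at_cutoff_threshold_is_calibration_ht(self, marker_by_name, model):
        assert flip_threshold_ht(marker_by_name["Val"], 290.0, 50.0, model) == pytest.approx(50.0)

    def test_no_crossing_reported_as_none(self, marker_by_name, model):
        # a tiny valine value can never be corrected across the cut-off
        assert flip_threshold_ht(marker_by_name["Val"], 10.0, 50.0, model) is None

    def test_positive_side_input_rejected(self, marker_by_name, model):
        with pytest.raises(ValueError, match="already positive"):
            flip_threshold_ht(marker_by_name["Val"], 300.0, 50.0, model)

    @settings(derandomize=True, max_examples=200)
    @given(
        frac=st.floats(min_value=0.90, max_value=1.0),
        ht=st.floats(min_value=20.0, max_value=70.0),
        down=st.booleans(),
    )
    def test_classification_flips_exactly_on_flip_side(self, frac, ht, down):
        """classify_sample flips iff the sample Ht is on the flip side of the
        analytic threshold (up markers flip below it, down markers above)."""
        from htspot import DispersionModel

        model = DispersionModel()
        if down:
            marker = MarkerDefinition("C0", 6.25, Direction.DOWN)
            c_exp = marker.cutoff * (2.0 - frac)  # in (cutoff, 1.1*cutoff]
        else:
            marker = MarkerDefinition("Val", 290.0, Direction.UP)
            c_exp = marker.cutoff * frac
        ht_star = flip_threshold_ht(marker, c_exp, 50.0, model)
        out = classify_sample(make_sample(marker.name, c_exp, ht=ht), marker, 50.0, model)
        if ht_star is None:
            assert not out.flipped
        elif abs(ht - ht_star) > 1e-9:  # skip the knife edge
            expected = ht > ht_star if down else ht < ht_star
            assert out.flipped == expected


class TestScreenCohort:
    def test_empty_cohort_gives_zero_counts(self, panel, model):
        df = screen_cohort([], panel, 50.0, model)
        assert len(df) == 33
        assert (df[["n_definite_positive", "n_alert_zone", "n_flipped"]] == 0).all().all()

    def test_counts_are_conserved_and_missing_counted(self, marker_by_name, model):
        val = marker_by_name["Val"]
        samples = [
            make_sample("Val", 300.0),  # definite positive
            make_sample("Val", 275.0),  # alert zone
            make_sample("Val", 100.0),  # plain negative
            ScreeningSample("s4", 50.0, {"Leu": 10.0}),  # missing Val
        ]
        df = screen_cohort(samples, [val], 50.0, model)
        row = df.loc["Val"]
        assert (row.n_definite_positive, row.n_alert_zone, row.n_plain_negative,
                row.n_missing) == (1, 1, 1, 1)
        assert (row.n_definite_positive + row.n_alert_zone + row.n_plain_negative
                + row.n_missing) == len(samples)

    def test_flip_count_matches_per_sample_classification(self, marker_by_name, model):
        """Summary flips equal the brute-force count over classify_sample."""
        val = marker_by_name["Val"]
        rng = np.random.default_rng(4)
        samples = [
            make_sample("Val", float(c), ht=float(h))
            for c, h in zip(rng.uniform(261, 290, 50), rng.uniform(20, 70, 50))
        ]
        df = screen_cohort(samples, [val], 50.0, model)
        brute = sum(classify_sample(s, val, 50.0, model).flipped for s in samples)
        assert df.loc["Val", "n_flipped"] == brute
        assert brute > 0  # low-Ht alert samples do flip


class TestFileDialects:
    def test_panel_round_trip_comma_and_tab(self, tmp_path):
        for sep, name in ((",", "p.csv"), ("\t", "p.tsv")):
            path = tmp_path / name
            path.write_text(
                "marker{0}cutoff{0}direction{0}alert_fraction\n"
                "Val{0}290.0{0}up{0}0.10\nC0{0}6.25{0}down{0}0.10\n".format(sep)
            )
            panel = load_panel(path)
            assert [m.name for m in panel] == ["Val", "C0"]
            assert panel[1].direction is Direction.DOWN

    def test_unknown_direction_token_rejected(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("marker,cutoff,direction\nVal,290.0,sideways\n")
        with pytest.raises(ValueError, match="direction token"):
            load_panel(path)

    def test_samples_with_empty_cells(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text(
            "sample_id,ht,Val,Leu\nA,50,261.0,\nB,,100.0,200.0\n"
        )
        samples = load_samples(path)
        assert samples[0].concentrations == {"Val": 261.0}
        assert samples[1].ht is None and samples[1].concentrations["Leu"] == 200.0
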
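"""Standardization, aggregation, classification and rate arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpsir_eri import (
    IndicatorSeries,
    StandardizedSeries,
    WeightVector,
    annual_rate,
    classify,
    composite_eri,
    compute_trajectory,
    default_risk_table,
    indicator_score,
    load_hierarchy,
    rollup,
    standardize,
    subindex_composite,
)
from dpsir_eri.scoring import ScoringError

YEARS = [2006, 2007, 2008]


def series(values, polarity="positive", factor="C1", years=None):
    years = years if years is not None else list(range(2006, 2006 + len(values)))
    return IndicatorSeries(factor, years, values, polarity)


class TestStandardize:
    def test_positive_polarity_endpoints(self):
        z = standardize(series([1, 2, 3])).z_values
        np.testing.assert_allclose(z, [0, 0.5, 1])

    def test_negative_polarity_is_the_reflection(self):
        z = standardize(series([1, 2, 3], polarity="negative")).z_values
        np.testing.assert_allclose(z, [1, 0.5, 0])

    def test_constant_series_maps_to_neutral_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            z = standardize(series([2, 2, 2])).z_values
        np.testing.assert_allclose(z, 0.5)
        assert "constant series" in caplog.text

    def test_fixed_bounds_rescale_against_external_range(self):
        z = standardize(series([1, 2, 3]), bounds=(0, 4)).z_values
        np.testing.assert_allclose(z, [0.25, 0.5, 0.75])

    def test_values_outside_fixed_bounds_rejected(self):
        with pytest.raises(ScoringError, match="bounds"):
            standardize(series([1, 2, 5]), bounds=(0, 4))

    @settings(deadline=None)
    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=1, max_size=20),
           st.sampled_from(["positive", "negative"]))
    def test_boundedness(self, values, polarity):
        years = list(range(2000, 2000 + len(values)))
        z = standardize(series(values, polarity, years=years)).z_values
        assert np.all(z >= 0) and np.all(z <= 1)

    def test_years_must_increase(self):
        with pytest.raises(ScoringError, match="increasing"):
            IndicatorSeries("C1", [2006, 2006], [1, 2], "positive")


class TestIndicatorScore:
    def test_weighted_sum_hand_oracle(self):
        w = WeightVector(np.array([0.5, 0.3, 0.2]))
        assert indicator_score([0.2, 0.4, 0.6], w) == pytest.approx(0.34)

    def test_convexity_on_equal_values(self):
        w = WeightVector(np.array([0.1, 0.6, 0.3]))
        assert indicator_score([0.7, 0.7, 0.7], w) == pytest.approx(0.7)
        assert indicator_score([1, 1, 1], w) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ScoringError):
            indicator_score([0.2], WeightVector(np.array([0.5, 0.5])))


TINY_DOC = {
    "name": "tiny",
    "nodes": [
        {"id": "A1", "label": "Driving forces"},
        {"id": "B1", "parent": "A1"},
        {"id": "C1", "parent": "B1", "polarity": "positive"},
        {"id": "C2", "parent": "B1", "polarity": "positive"},
        {"id": "B2", "parent": "A1", "polarity": "positive"},
        {"id": "A2", "label": "Response"},
        {"id": "B3", "parent": "A2", "polarity": "negative"},
    ],
}


def std(factor, z, years=YEARS):
    return StandardizedSeries(factor, years, z)


class TestRollup:
    def test_single_leaf_chain_passes_through(self):
        doc = {"nodes": [{"id": "A1"}, {"id": "B1", "parent": "A1"},
                         {"id": "C1", "parent": "B1", "polarity": "positive"}]}
        h = load_hierarchy(doc)
        out = rollup(h, {"C1": std("C1", [0.2, 0.7, 0.9])})
        np.testing.assert_allclose(out["A1"], [0.2, 0.7, 0.9])

    def test_symmetric_two_children(self):
        doc = {"nodes": [{"id": "A1"},
                         {"id": "B1", "parent": "A1", "polarity": "positive"},
                         {"id": "B2", "parent": "A1", "polarity": "positive"}]}
        h = load_hierarchy(doc)
        weights = {"A1": WeightVector(np.array([0.5, 0.5]), ("B1", "B2"))}
        out = rollup(h, {"B1": std("B1", [0.2] * 3), "B2": std("B2", [0.8] * 3)}, weights)
        np.testing.assert_allclose(out["A1"], 0.5)

    def test_published_driving_force_weights_as_basis_vector(self, h):
        """Leaf score 1 on the first indicator, 0 elsewhere, picks its weight."""
        from dpsir_eri import ScoreVector, ahp_weights

        w, _ = ahp_weights(ScoreVector(("B1", "B2", "B3"), [6.5, 5.0, 3.5]))
        doc = {"nodes": [{"id": "A1"},
                         {"id": "B1", "parent": "A1", "polarity": "positive"},
                         {"id": "B2", "parent": "A1", "polarity": "positive"},
                         {"id": "B3", "parent": "A1", "polarity": "positive"}]}
        tiny = load_hierarchy(doc)
        out = rollup(
            tiny,
            {"B1": std("B1", [1.0] * 3), "B2": std("B2", [0.0] * 3),
             "B3": std("B3", [0.0] * 3)},
            {"A1": w},
        )
        np.testing.assert_allclose(np.round(out["A1"], 4), 0.4333)

    def test_depth_one_tree_reduces_to_indicator_score(self):
        h = load_hierarchy(TINY_DOC)
        z = {"C1": 0.3, "C2": 0.9, "B2": 0.5, "B3": 0.1}
        standardized = {k: std(k, [v] * 3) for k, v in z.items()}
        w_b1 = WeightVector(np.array([0.7, 0.3]), ("C1", "C2"))
        w_a1 = WeightVector(np.array([0.6, 0.4]), ("B1", "B2"))
        out = rollup(h, standardized, {"B1": w_b1, "A1": w_a1})
        b1 = indicator_score([0.3, 0.9], w_b1)
        expected = indicator_score([b1, 0.5], w_a1)
        np.testing.assert_allclose(out["A1"], expected)

    def test_internal_series_short_circuits_its_subtree(self):
        h = load_hierarchy(TINY_DOC)
        standardized = {"B1": std("B1", [0.4] * 3), "B2": std("B2", [0.8] * 3),
                        "B3": std("B3", [0.1] * 3)}
        out = rollup(h, standardized)  # equal sibling weights
        np.testing.assert_allclose(out["A1"], 0.6)

    def test_missing_leaf_named(self):
        h = load_hierarchy(TINY_DOC)
        with pytest.raises(ScoringError, match="C2"):
            rollup(h, {"C1": std("C1", [0.5] * 3), "B2": std("B2", [0.5] * 3),
                       "B3": std("B3", [0.5] * 3)})

    def test_mismatched_weights_rejected(self):
        h = load_hierarchy(TINY_DOC)
        standardized = {"B1": std("B1", [0.4] * 3), "B2": std("B2", [0.8] * 3),
                        "B3": std("B3", [0.1] * 3)}
        bad = {"A1": WeightVector(np.array([1.0]), ("B9",))}
        with pytest.raises(ScoringError, match="A1"):
            rollup(h, standardized, bad)


class TestComposite:
    def test_convexity(self):
        w = WeightVector(np.full(5, 0.2))
        assert composite_eri([0.5] * 5, w) == pytest.approx(0.5)

    def test_basis_vector_picks_the_weight(self):
        w = WeightVector(np.array([0.2, 0.3, 0.1, 0.25, 0.15]))
        assert composite_eri([1, 0, 0, 0, 0], w) == pytest.approx(0.2)

    def test_uniform_hand_mean(self):
        w = WeightVector(np.full(5, 0.2))
        assert composite_eri([0.3, 0.6, 0.5, 0.4, 0.2], w) == pytest.approx(0.4)

    def test_dimension_mismatch(self):
        with pytest.raises(ScoringError):
            composite_eri([0.5, 0.5], WeightVector(np.full(5, 0.2)))

    def test_subset_composite_renormalizes(self):
        assert subindex_composite([0.22], [0.4]) == pytest.approx(0.22)
        assert subindex_composite([0.22] * 4, [0.1, 0.2, 0.3, 0.4]) == pytest.approx(0.22)
        assert subindex_composite([0.2, 0.3, 0.4, 0.5],
                                  [0.25] * 4) == pytest.approx(0.35)

    def test_empty_subset_rejected(self):
        with pytest.raises(ScoringError):
            subindex_composite([], [])

    @settings(deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=5, max_size=5))
    def test_eri_bounded_for_convex_weights(self, scores):
        w = WeightVector(np.array([0.1, 0.3, 0.25, 0.15, 0.2]))
        assert 0.0 <= composite_eri(scores, w) <= 1.0


class TestMonotonicity:
    """Raising a positive leaf (fixed bounds) never lowers the composite."""

    def test_positive_leaf_monotone_up_negative_leaf_monotone_down(self):
        h = load_hierarchy(TINY_DOC)
        a_w = WeightVector(np.array([0.6, 0.4]), ("A1", "A2"))

        def eri_with(c1, b3):
            raw = {
                "C1": series(c1, factor="C1"),
                "C2": series([0.5, 0.6, 0.7], factor="C2"),
                "B2": series([0.2, 0.3, 0.4], factor="B2"),
                "B3": series(b3, polarity="negative", factor="B3"),
            }
            standardized = {k: standardize(s, bounds=(0.0, 2.0)) for k, s in raw.items()}
            out = rollup(h, standardized)
            traj = compute_trajectory(out, a_w)
            return traj.eri

        # raise one positive-polarity value, all else fixed
        base = eri_with([0.5, 0.6, 0.7], [1.0, 1.0, 1.0])
        up = eri_with([0.9, 0.6, 0.7], [1.0, 1.0, 1.0])
        assert up[0] >= base[0] and np.allclose(up[1:], base[1:])
        # raise one negative-polarity value: composite must not increase
        neg_up = eri_with([0.5, 0.6, 0.7], [1.5, 1.0, 1.0])
        assert neg_up[0] <= base[0]


class TestClassify:
    def test_published_classifications(self):
        assert classify(0.48) == "III"
        assert classify(0.3489) == "II"
        assert classify(0.85) == "V"

    def test_five_contiguous_bands_with_critical_point(self):
        table = default_risk_table()
        assert len(table.bands) == 5
        assert [b.label for b in table.bands] == ["I", "II", "III", "IV", "V"]
        assert table.bands[-1].lower == 0.8
        assert table.bands[0].lower == 0.0 and table.bands[-1].upper == 1.0

    def test_half_open_edges_and_totality(self):
        assert classify(0.2) == "II"
        assert classify(0.4) == "III"
        assert classify(0.8) == "V"
        assert classify(1.0) == "V"
        assert classify(0.0) == "I"
        for v in np.linspace(0, 1, 101):
            assert classify(float(v)) in "I II III IV V".split()

    def test_below_published_floor_folds_into_band_one(self):
        assert classify(0.05) == "I"

    def test_out_of_range_rejected(self):
        for v in (-0.1, 1.1, float("nan")):
            with pytest.raises(ScoringError):
                classify(v)


class TestAnnualRate:
    def test_published_level_change_rate(self):
        assert round(annual_rate(0.3489, 0.4351, 5), 4) == 0.0172

    def test_constant_and_direct_arithmetic(self):
        assert annual_rate(0.4, 0.4, 7) == 0.0
        assert annual_rate(0.2, 0.3, 10) == pytest.approx(0.01)

    def test_zero_years_rejected(self):
        with pytest.raises(ScoringError):
            annual_rate(0.2, 0.3, 0)


class TestTrajectory:
    def test_levels_consistent_with_classifier(self):
        scores = pd.DataFrame(
            {"A1": [0.1, 0.5], "A2": [0.2, 0.6], "A3": [0.3, 0.7],
             "A4": [0.1, 0.5], "A5": [0.3, 0.7]},
            index=pd.Index([2006, 2007], name="year"),
        )
        traj = compute_trajectory(scores, WeightVector(np.full(5, 0.2),
                                                       tuple(scores.columns)))
        for value, level in zip(traj.eri, traj.levels):
            assert classify(float(value)) == level
        frame = traj.to_frame()
        assert list(frame.columns) == ["S_A1", "S_A2", "S_A3", "S_A4", "S_A5",
                                       "ERI", "level"]
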
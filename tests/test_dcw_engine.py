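"""Correlation-weight table, DCW, regression, and the Monte-Carlo optimiser."""

import numpy as np
import pytest

from dcwqsar.corpus import Compound, CompoundSet
from dcwqsar.dcw_engine import (
    CorrelationWeightTable,
    DcwRegressor,
    apply_threshold,
    attribute_frequencies,
    compound_profile,
    compute_dcw,
    fit_regression,
    monte_carlo_optimize,
    predict,
    target_function,
)


def toy_sets():
    sub = CompoundSet(
        [
            Compound("s1", "CCO", 1.0),
            Compound("s2", "CCCO", 2.0),
            Compound("s3", "CCCCO", 3.0),
            Compound("s4", "CO", 0.5),
            Compound("s5", "CCCCCO", 4.0),
        ]
    )
    inv = CompoundSet(
        [
            Compound("i1", "CCCO", 2.1),
            Compound("i2", "CO", 0.4),
            Compound("i3", "CCCCO", 3.2),
            Compound("i4", "CCO", 1.1),
        ]
    )
    return sub, inv


class TestFrequenciesAndThreshold:
    def test_compound_counts_not_instances(self):
        freqs = attribute_frequencies(["CC", "CCC"], mode="smiles", smiles_scheme=("S1",))
        assert freqs == {"S1:C": 2}  # two compounds, not five tokens

    def test_empty(self):
        assert attribute_frequencies([], mode="smiles") == {}

    def test_fixture_counts_bounded(self, split1):
        freqs = attribute_frequencies(split1["subtraining"], mode="smiles")
        assert freqs and max(freqs.values()) <= 131

    def test_threshold_zero_blocks_nothing(self):
        assert apply_threshold({"A": 1, "B": 5}, 0) == frozenset()

    def test_threshold_strict(self):
        assert apply_threshold({"A": 1, "B": 5}, 2) == {"A"}
        assert apply_threshold({"A": 1, "B": 5}, 99) == {"A", "B"}

    def test_threshold_monotone(self, split1):
        """blocked(T1) ⊆ blocked(T2) whenever T1 < T2."""
        freqs = attribute_frequencies(split1["subtraining"], mode="hybrid")
        previous = frozenset()
        for t in (0, 1, 2, 5, 10, 50):
            blocked = apply_threshold(freqs, t)
            assert previous <= blocked
            previous = blocked


class TestDcw:
    def test_planted_table(self):
        cw = CorrelationWeightTable({"S1:C": 0.5, "S2:C|C": 2.0})
        profile = compound_profile("CC", mode="smiles")
        assert compute_dcw(profile, cw) == pytest.approx(0.5 * 2 + 2.0 * 1)

    def test_all_zero_weights(self):
        cw = CorrelationWeightTable({})
        assert compute_dcw(compound_profile("CCO", mode="hybrid"), cw) == 0.0

    def test_blocked_contribute_zero(self):
        cw = CorrelationWeightTable({"S1:C": 1.0}, blocked=frozenset({"S1:C"}))
        assert compute_dcw(compound_profile("CC", mode="smiles"), cw) == 0.0

    def test_linearity_over_partition(self):
        """DCW of a profile equals the sum of DCWs of any partition of it."""
        cw = CorrelationWeightTable({"S1:C": 0.3, "S1:O": -1.2, "S2:C|C": 0.7})
        profile = compound_profile("CCOCC", mode="smiles")
        items = list(profile.items())
        part1 = dict(items[::2])
        part2 = dict(items[1::2])
        assert compute_dcw(profile, cw) == pytest.approx(
            compute_dcw(part1, cw) + compute_dcw(part2, cw)
        )


class TestRegressionAndObjective:
    def test_exact_line(self):
        c0, c1, r = fit_regression([0, 1, 2, 3], [2, 5, 8, 11])
        assert (c0, c1, r) == pytest.approx((2.0, 3.0, 1.0))

    def test_anticorrelated(self):
        c0, c1, r = fit_regression([0.0, 1.0, 2.0], [1.0, 0.0, -1.0])
        assert (c1, r) == pytest.approx((-1.0, -1.0))

    def test_against_normal_equations(self):
        """Matches the closed-form normal-equation solution to 1e-10."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        c0, c1, _ = fit_regression(x, y)
        assert c0 == pytest.approx(intercept, abs=1e-10)
        assert c1 == pytest.approx(slope, abs=1e-10)

    def test_degenerate_descriptor(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize(
        "r_sub, r_inv, expected",
        [(1.0, 1.0, 2.0), (0.8, 0.8, 1.6), (0.9, 0.7, 1.598)],
    )
    def test_target_function(self, r_sub, r_inv, expected):
        assert target_function(r_sub, r_inv, 0.01) == pytest.approx(expected)


class TestMonteCarlo:
    def test_zero_epochs_is_baseline(self):
        sub, inv = toy_sets()
        est = monte_carlo_optimize(sub, inv, mode="smiles", n_epochs=0, random_state=0)
        assert est.tf_trajectory_ == [est.tf_trajectory_[0]]
        assert np.isfinite(est.predict(sub)).all()

    def test_negative_epochs_rejected(self):
        sub, inv = toy_sets()
        with pytest.raises(ValueError):
            monte_carlo_optimize(sub, inv, mode="smiles", n_epochs=-1)

    def test_tf_trajectory_monotone(self, split1):
        est = DcwRegressor(mode="hybrid", n_epochs=8, random_state=3)
        est.fit(split1["subtraining"], X_invisible=split1["invtraining"])
        tf = est.tf_trajectory_
        assert len(tf) == 9
        assert all(b >= a for a, b in zip(tf, tf[1:]))

    def test_seed_determinism(self):
        sub, inv = toy_sets()
        a = monte_carlo_optimize(sub, inv, mode="smiles", n_epochs=10, random_state=42)
        b = monte_carlo_optimize(sub, inv, mode="smiles", n_epochs=10, random_state=42)
        assert a.weights_ == b.weights_  # bit-identical
        assert (a.intercept_, a.slope_) == (b.intercept_, b.slope_)

    def test_toy_signal_recovered(self):
        """Endpoints proportional to chain length are fit almost exactly."""
        sub, inv = toy_sets()
        est = monte_carlo_optimize(sub, inv, mode="smiles", n_epochs=40, random_state=0)
        assert est.r_sub_**2 > 0.95

    def test_predict_empty_profile_gives_intercept(self, quick_model):
        pred, unknown = predict(quick_model, Compound("x", "[Xe]", 0.0))
        assert pred == pytest.approx(quick_model.intercept_)
        assert unknown >= 1

    def test_predictions_finite_on_dataset(self, quick_model, fixture_set):
        assert np.isfinite(quick_model.predict(fixture_set)).all()

    def test_unknown_attribute_count(self, quick_model):
        _, unknown = quick_model.predict_with_unknown(["[Po][Po]"])
        assert unknown[0] >= 2

    def test_calibration_monitoring_reports_best_epoch(self, split1):
        est = DcwRegressor(mode="smiles", n_epochs=4, random_state=0)
        est.fit(
            split1["subtraining"],
            X_invisible=split1["invtraining"],
            X_calibration=split1["calibration"],
        )
        assert len(est.calibration_r2_per_epoch_) == 4
        assert 1 <= est.best_epoch_ <= 4
        # reported, never applied: the fitted weights are the epoch-4 weights
        assert est.n_epochs == 4

    def test_empty_attribute_space_rejected(self):
        est = DcwRegressor(mode="smiles", smiles_scheme=("S2",))
        with pytest.raises(ValueError, match="empty attribute space"):
            est.fit(["C", "C", "C"], [1.0, 2.0, 3.0])

    def test_sklearn_params_round_trip(self):
        est = DcwRegressor(threshold=2, n_epochs=5)
        clone_params = est.get_params()
        est2 = DcwRegressor(**clone_params)
        assert est2.get_params() == clone_params
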
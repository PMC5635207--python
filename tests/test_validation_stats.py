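"""Quality statistics: r², LOO q², RMSE, Fisher F, and the four-set report."""

import io

import numpy as np
import pytest

from dcwqsar.corpus import read_compound_table
from dcwqsar.validation_stats import (
    f_critical,
    fisher_f,
    four_set_report,
    q2_loo,
    r_squared,
    rmse,
)


class TestRSquared:
    def test_exact_line(self):
        assert r_squared([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_anticorrelated_squares_to_one(self):
        assert r_squared([1, 2, 3], [3, 2, 1]) == pytest.approx(1.0)

    def test_against_direct_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=4), rng.normal(size=4)
        num = np.sum((x - x.mean()) * (y - y.mean())) ** 2
        den = np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        assert r_squared(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            r_squared([1, 1, 1], [1, 2, 3])


def explicit_loo_q2(x, y):
    """Oracle: leave-one-out by literally refitting n one-variable OLS models."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    press = 0.0
    for i in range(x.size):
        mask = np.arange(x.size) != i
        xi, yi = x[mask], y[mask]
        slope = np.sum((xi - xi.mean()) * (yi - yi.mean())) / np.sum((xi - xi.mean()) ** 2)
        intercept = yi.mean() - slope * xi.mean()
        press += (y[i] - (intercept + slope * x[i])) ** 2
    return 1.0 - press / np.sum((y - y.mean()) ** 2)


class TestQ2:
    def test_exact_line_is_one(self):
        x = np.arange(8.0)
        assert q2_loo(x, 2 * x + 1) == pytest.approx(1.0)

    def test_shortcut_equals_explicit_refits(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5)
        y = 0.7 * x + rng.normal(scale=0.3, size=5)
        assert q2_loo(x, y) == pytest.approx(explicit_loo_q2(x, y), abs=1e-10)

    def test_shortcut_equals_explicit_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert q2_loo(x, y) == pytest.approx(explicit_loo_q2(x, y), abs=1e-9)

    def test_q2_below_r2_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            pred = np.polyval(np.polyfit(x, y, 1), x)
            assert q2_loo(x, y) <= r_squared(pred, y) + 1e-12


class TestRmse:
    def test_zero_on_equal(self):
        assert rmse([1, 2], [1, 2]) == 0.0

    def test_constant_residual(self):
        assert rmse([1.5, 2.5, 3.5], [1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_hand_case(self):
        assert rmse([1, 2, 3], [2, 2, 5]) == pytest.approx(np.sqrt((1 + 0 + 4) / 3))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1])


class TestFisher:
    @pytest.mark.parametrize(
        "r2, n, expected",
        [
            # published quality-table rows whose integer F follows exactly
            # from the printed 4-decimal r²
            (0.8291, 60, 281),
            (0.8183, 60, 261),
            (0.6290, 60, 98),
            (0.8888, 60, 464),
            (0.8204, 60, 265),
            (0.7593, 60, 183),
            (0.5008, 60, 58),
            (0.4645, 60, 50),
            (0.7021, 60, 137),
            (0.5712, 60, 77),
        ],
    )
    def test_reproduces_printed_integer_f(self, r2, n, expected):
        assert round(fisher_f(r2, n)) == expected

    def test_rounded_r2_rows_within_one_unit(self):
        """Rows where the source computed F from unrounded r²: the printed
        4-decimal r² lands within one integer unit of the printed F."""
        for r2, n, printed in [(0.8029, 131, 526), (0.7940, 60, 223),
                               (0.6839, 60, 126), (0.8085, 131, 545)]:
            assert abs(fisher_f(r2, n) - printed) <= 1.0

    def test_zero_r2(self):
        assert fisher_f(0.0, 100) == 0.0

    def test_r2_one_rejected(self):
        with pytest.raises(ValueError):
            fisher_f(1.0, 10)

    def test_critical_values(self):
        assert f_critical(60) == pytest.approx(4.007, abs=1e-3)
        assert f_critical(131) == pytest.approx(3.915, abs=1e-3)

    def test_critical_large_n_limit(self):
        assert f_critical(10**6) == pytest.approx(3.8415, abs=1e-3)


class TestFourSetReport:
    def test_report_columns(self, quick_model, fixture_set):
        report = four_set_report(quick_model, None, fixture_set)
        assert set(report.rows) == {
            "subtraining", "invtraining", "calibration", "validation",
        }
        for label, row in report.rows.items():
            assert 0 <= row.r2 <= 1
            assert row.s >= 0
            assert row.f >= 0
            assert (row.q2 is None) == (label == "validation")
            if row.q2 is not None:
                assert row.q2 <= row.r2 + 1e-12

    def test_report_ns(self, quick_model, fixture_set):
        report = four_set_report(quick_model, None, fixture_set)
        assert [report[l].n for l in ("subtraining", "invtraining", "calibration", "validation")] == [131, 131, 60, 60]

    def test_null_model_near_zero_r2(self):
        """Zero-epoch models on pure-noise endpoints show no spurious skill."""
        from dcwqsar.corpus import Compound, CompoundSet, random_split
        from dcwqsar.dcw_engine import DcwRegressor
        from dcwqsar.synthetic_data import default_planted_model, generate_compounds

        rng = np.random.default_rng(0)
        r2s = []
        for seed in range(20):
            pm = default_planted_model(seed=seed)
            cs = generate_compounds(pm, n=60, length_range=(4, 12))
            noise = CompoundSet(
                [Compound(c.id, c.smiles, float(v), c.set_label)
                 for c, v in zip(cs, rng.normal(5, 1, len(cs)))]
            )
            split = random_split(noise, (20, 20, 10, 10), seed=seed)
            labeled = noise.with_split(split)
            est = DcwRegressor(mode="smiles", n_epochs=0, random_state=seed)
            est.fit(labeled.subset("subtraining"), X_invisible=labeled.subset("invtraining"))
            report = four_set_report(est, None, labeled)
            r2s.append(report["validation"].r2)
        assert np.mean(r2s) < 0.1

    def test_text_and_csv_render(self, quick_model, fixture_set):
        report = four_set_report(quick_model, None, fixture_set)
        text = report.to_text()
        assert "Sub-training" in text and "Validation" in text
        csv = report.to_csv()
        assert csv.count("\n") == 5

    def test_csv_round_trip_lossless(self, quick_model, fixture_set):
        report = four_set_report(quick_model, None, fixture_set)
        lines = report.to_csv().strip().splitlines()
        header = lines[0].split(",")
        parsed = [dict(zip(header, ln.split(","))) for ln in lines[1:]]
        for row_label, row in zip(parsed, report.rows.values()):
            assert float(row_label["r2"]) == row.r2
            assert float(row_label["F"]) == row.f
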
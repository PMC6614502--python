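import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVR

from blankqc.simulate import SimulationConfig, generate_batch
from blankqc.svrc import (
    EPSILON_RANGE,
    GAMMA_RANGE,
    correct_table,
    epsilon_grid,
    fit_trend,
    gamma_grid,
    reference_orders,
    rsd,
    select_hyperparameters,
)

from conftest import make_table


class TestRsd:
    def test_examples(self):
        assert rsd([90, 100, 110]) == pytest.approx(10.0)
        assert rsd([5, 5, 5, 5]) == 0.0

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = rng.uniform(1, 100, size=rng.integers(2, 40))
            mean = sum(v) / len(v)
            sd = (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5
            assert rsd(v) == pytest.approx(100 * sd / mean, rel=1e-12)

    def test_undefined_cases(self):
        assert np.isnan(rsd([5.0]))
        assert np.isnan(rsd([-1.0, 1.0]))


class TestSelectHyperparameters:
    def test_c_is_reference_median(self):
        C, eps, gamma, r = select_hyperparameters(
            [1, 5, 9, 13, 17], [90, 100, 110, 120, 130], n_eps=3, n_gamma=3)
        assert C == 110.0

    def test_constant_references_trivial_fit(self):
        C, eps, gamma, r = select_hyperparameters([1, 2, 3, 4], [100] * 4)
        assert (C, eps, r) == (100.0, 0.0, 0.0)
        trend = fit_trend([1, 2, 3, 4], [100] * 4, C, eps, gamma, np.arange(1, 10))
        np.testing.assert_allclose(trend, 100.0)

    def test_too_few_references_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            select_hyperparameters([1, 2, 3], [1.0, 2.0, 3.0])

    def test_search_ranges_respected(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            orders = np.sort(rng.uniform(1, 170, 8))
            areas = 1e4 * (1 + 0.3 * np.sin(orders / 40)) * rng.uniform(0.9, 1.1, 8)
            C, eps, gamma, r = select_hyperparameters(orders, areas, n_eps=4, n_gamma=7)
            assert EPSILON_RANGE[0] * C <= eps <= EPSILON_RANGE[1] * C * (1 + 1e-12)
            assert GAMMA_RANGE[0] <= gamma <= GAMMA_RANGE[1]
            assert r >= 0

    def test_matches_exhaustive_refit_oracle(self):
        """LOOCV grid selection equals a brute-force loop over every node
        that refits public sklearn SVR models leave-one-out."""
        rng = np.random.default_rng(11)
        orders = np.arange(1.0, 8.0)  # 7 reference injections
        areas = 1e3 * (1 + 0.08 * orders) * (1 + 0.04 * rng.standard_normal(7))
        n_eps, n_gamma = 4, 7
        C, eps, gamma, r = select_hyperparameters(orders, areas,
                                                  n_eps=n_eps, n_gamma=n_gamma)
        t = (orders - orders.min()) / (orders.max() - orders.min())
        best = None
        for g in gamma_grid(n_gamma):
            for e in epsilon_grid(np.median(areas), n_eps):
                errs = []
                for i in range(len(orders)):
                    keep = np.arange(len(orders)) != i
                    m = SVR(C=np.median(areas), epsilon=e, gamma=g)
                    m.fit(t[keep, None], areas[keep])
                    errs.append(m.predict(t[i:i + 1, None])[0] - areas[i])
                rm = float(np.sqrt(np.mean(np.square(errs))))
                key = (rm, g, -e)
                if best is None or key < best[0]:
                    best = (key, e, g, rm)
        assert (eps, gamma) == (best[1], best[2])
        assert r == pytest.approx(best[3], rel=1e-9)


class TestFitTrend:
    def test_epsilon_insensitive_at_references(self):
        # smooth drift well within reach of the RBF family: residuals at the
        # training points stay within the epsilon tube
        orders = np.linspace(1, 60, 12)
        areas = 1e4 * (1 + 0.2 * np.sin(orders / 25))
        C = float(np.median(areas))
        eps = 0.05 * C
        trend = fit_trend(orders, areas, C, eps, 1.0, orders)
        assert np.all(np.abs(trend - areas) <= eps * (1 + 1e-6))

    def test_linear_drift_midpoints_within_rmsecv(self):
        orders = np.arange(1.0, 30.0, 2.0)
        line = 5e3 * (1 + 0.01 * orders)
        C, eps, gamma, r = select_hyperparameters(orders, line, n_eps=4, n_gamma=9)
        mid = orders[:-1] + 1.0
        trend = fit_trend(orders, line, C, eps, gamma, mid)
        truth = 5e3 * (1 + 0.01 * mid)
        assert np.all(np.abs(trend - truth) <= 2 * max(r, eps))


def _drifting_table(n_feat=8, noise=0.0, seed=0):
    cfg = SimulationConfig(
        n_features_by_class={"informative_stable": n_feat},
        n_cycles_intense=3, n_cycles_mild=3, drift_amplitude=0.2,
        noise_rsd=noise, seed=seed,
    )
    return generate_batch(cfg)


class TestCorrectTable:
    def test_reference_set_is_leading_qcs_plus_preblank_samples(self, small_batch):
        table, _, _ = small_batch
        refs = reference_orders(table, j=1)
        seq = table.sequence
        assert set(seq.loc[refs, "sample_class"]) == {"QC", "sample"}
        sample_refs = [r for r in refs if seq.loc[r, "sample_class"] == "sample"]
        assert all(seq.loc[r, "position_after_blank"] == 8 for r in sample_refs)
        n_cycles = seq.loc[seq["cycle_id"] > 0, "cycle_id"].nunique()
        assert len(sample_refs) == n_cycles

    def test_identity_when_trend_equals_median(self):
        table, _ = _drifting_table(n_feat=4)
        med = table.area[reference_orders(table)].median(axis=1)
        trends = pd.DataFrame(
            np.tile(med.to_numpy()[:, None], table.n_injections),
            index=table.feature_ids, columns=table.run_orders)
        corrected, fits = correct_table(table, trends=trends)
        np.testing.assert_allclose(
            corrected.area.to_numpy(), table.area.to_numpy(), rtol=1e-12)

    def test_true_trend_recovers_constant_areas(self):
        table, truth = _drifting_table(n_feat=5, noise=0.0)
        corrected, _ = correct_table(table, trends=truth.drift_curve)
        samples = table.injections_where(sample_class="sample")
        a = corrected.area[samples].to_numpy()
        dev = np.abs(a / a[:, :1] - 1)
        assert dev.max() < 1e-6

    def test_svr_correction_reduces_reference_rsd(self):
        table, _ = _drifting_table(n_feat=10, noise=0.05, seed=2)
        corrected, fits = correct_table(table, n_eps=4, n_gamma=9)
        refs = reference_orders(table)
        raw = table.area[refs].apply(rsd, axis=1)
        cor = corrected.area[refs].apply(rsd, axis=1)
        assert (cor < raw).mean() >= 0.9
        assert all(f.corrected for f in fits)

    def test_rescaling_equivariance(self):
        table, _ = _drifting_table(n_feat=3, noise=0.03, seed=5)
        scaled = table.copy()
        c = 7.5
        scaled.area *= c
        a, _ = correct_table(table, n_eps=3, n_gamma=5)
        b, _ = correct_table(scaled, n_eps=3, n_gamma=5)
        np.testing.assert_allclose(
            b.area.to_numpy(), c * a.area.to_numpy(), rtol=1e-8)

    def test_reference_median_approximately_preserved(self):
        table, _ = _drifting_table(n_feat=5, noise=0.05, seed=3)
        corrected, _ = correct_table(table, n_eps=3, n_gamma=5)
        refs = reference_orders(table)
        raw_med = table.area[refs].median(axis=1).to_numpy()
        cor_med = corrected.area[refs].median(axis=1).to_numpy()
        assert np.all(np.abs(cor_med / raw_med - 1) < 0.12)

    def test_uncorrectable_feature_passed_through(self):
        area = np.ones((2, 14))
        area[1] = 0.0  # no positive references
        classes = (["QC"] * 2 + ["blank"] + ["sample"] * 8 + ["blank"]
                   + ["sample"] * 2)
        table = make_table(classes, area)
        with pytest.warns(UserWarning, match="uncorrected"):
            corrected, fits = correct_table(table)
        assert not fits[1].corrected
        np.testing.assert_array_equal(
            corrected.area.to_numpy()[1], table.area.to_numpy()[1])
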
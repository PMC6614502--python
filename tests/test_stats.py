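import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats as sps
from sklearn.metrics import silhouette_score

from blankqc import BatchConditioning
from blankqc.stats import (
    bh_fdr,
    blank_pca,
    conditioning_curve,
    gpca_delta,
    pca_overview,
    permutation_p,
    welch_ttest,
)


def delta_eigh_oracle(X, groups):
    """Independent route: eigendecomposition of the cross-product matrices."""
    X = np.asarray(X, float)
    Xc = X - X.mean(0)
    g = np.asarray(groups)
    Y = np.column_stack([
        (g == lv) / np.sqrt((g == lv).sum()) for lv in np.unique(g)])
    M = Y.T @ Xc
    w, V = np.linalg.eigh(M.T @ M)
    vg = V[:, np.argmax(w)]
    w1, V1 = np.linalg.eigh(Xc.T @ Xc)
    v1 = V1[:, np.argmax(w1)]
    return np.var(Xc @ vg, ddof=1) / np.var(Xc @ v1, ddof=1)


class TestGpcaDelta:
    def test_perfectly_separated_duplicate_rows(self):
        a, b = np.zeros(5), np.ones(5)
        X = np.vstack([a, a, b, b])
        assert gpca_delta(X, [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_matches_oracle_on_fixed_instance(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((8, 20))
        g = [0] * 4 + [1] * 4
        assert gpca_delta(X, g) == pytest.approx(delta_eigh_oracle(X, g), abs=1e-10)

    def test_pc1_orthogonal_to_group_difference(self):
        # variance dominated by a direction orthogonal to the group shift
        rng = np.random.default_rng(3)
        n = 12
        X = np.zeros((n, 6))
        X[:, 0] = 10 * rng.standard_normal(n)     # dominant, group-free
        g = np.array([0] * 6 + [1] * 6)
        X[g == 1, 1] += 1.0                        # small group shift
        d = gpca_delta(X, g)
        assert d == pytest.approx(delta_eigh_oracle(X, g), abs=1e-10)
        assert d < 1.0

    @given(hnp.arrays(np.float64, (10, 7),
                      elements=st.floats(-50, 50, allow_nan=False)),
           st.lists(st.sampled_from([0, 1]), min_size=10, max_size=10))
    @settings(deadline=None, max_examples=60)
    def test_delta_bounded_by_one(self, X, groups):
        groups = np.asarray(groups)
        Xc = X - X.mean(0)
        if len(np.unique(groups)) < 2 or np.linalg.norm(Xc) < 1e-6:
            return
        d = gpca_delta(X, groups)
        assert 0 <= d <= 1 + 1e-10

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gpca_delta(np.eye(4), [0, 0, 0, 0])


class TestPermutationP:
    def test_strong_separation_gives_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 20)) * 0.01
        X[6:] += 5
        p, d, perm = permutation_p(X, [0] * 6 + [1] * 6, m=100, seed=1)
        assert p == 0.0 and d > 0.99

    def test_formula_and_resolution(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 15))
        g = [0] * 5 + [1] * 5
        m = 40
        p, d, perm = permutation_p(X, g, m=m, seed=2)
        assert p == np.sum(d < perm) / m      # printed formula, strict <
        assert p in {i / m for i in range(m + 1)}

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10, 15))
        g = [0] * 5 + [1] * 5
        r1 = permutation_p(X, g, m=50, seed=9)
        r2 = permutation_p(X, g, m=50, seed=9)
        assert r1[0] == r2[0]
        np.testing.assert_array_equal(r1[2], r2[2])


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_ttest([1, 2, 3], [1, 2, 3])
        assert (t, p) == (0.0, 1.0)

    def test_separated_groups(self):
        t, df, p = welch_ttest([1, 2, 3, 4], [11, 12, 13, 14])
        assert p < 1e-3

    def test_degenerate_zero_variance(self):
        assert welch_ttest([2, 2, 2], [2, 2])[2] == 1.0
        assert welch_ttest([2, 2, 2], [3, 3])[2] == 0.0

    def test_matches_closed_form(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.normal(0, 1, rng.integers(3, 12))
            y = rng.normal(0.5, 2, rng.integers(3, 12))
            t, df, p = welch_ttest(x, y)
            vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
            t0 = (x.mean() - y.mean()) / np.sqrt(vx + vy)
            df0 = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
            p0 = 2 * sps.t.sf(abs(t0), df0)
            assert t == pytest.approx(t0, abs=1e-10)
            assert df == pytest.approx(df0, rel=1e-10)
            assert p == pytest.approx(p0, abs=1e-12)


def bh_oracle(p):
    """min over the tail of (n/k) p_(k), capped at 1."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(n)
    for rank_pos, idx in enumerate(order, start=1):
        tail = [n / k * p[order[k - 1]] for k in range(rank_pos, n + 1)]
        out[idx] = min(1.0, min(tail))
    return out


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05]), [0.05] * 5)

    def test_single_and_all_ones(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_min_over_tail_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    @given(hnp.arrays(np.float64, st.integers(1, 30),
                      elements=st.floats(0, 1, allow_nan=False)))
    @settings(deadline=None, max_examples=50)
    def test_adjusted_never_below_raw(self, p):
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        assert (adj < 0.05).sum() <= (p < 0.05).sum() + 0  # no new discoveries

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestPcaOverview:
    def test_rank_one_matrix(self):
        X = np.outer([1, 2, 3, 4.0], [1, 0, 2.0])
        scores, loadings, frac = pca_overview(X, n_components=2)
        assert frac[0] == pytest.approx(1.0)

    def test_reconstruction_error_is_discarded_energy(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 6))
        Xc = X - X.mean(0)
        k = 2
        scores, loadings, frac = pca_overview(X, n_components=k)
        err = np.linalg.norm(Xc - scores @ loadings.T) ** 2
        s = np.linalg.svd(Xc, compute_uv=False)
        assert err == pytest.approx(np.sum(s[k:] ** 2), rel=1e-8)

    def test_matches_dense_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 50))
        scores, loadings, frac = pca_overview(X, n_components=3)
        Xc = X - X.mean(0)
        U, s, Vt = np.linalg.svd(Xc)
        for c in range(3):
            ref = U[:, c] * s[c]
            agree = min(np.abs(scores[:, c] - ref).max(),
                        np.abs(scores[:, c] + ref).max())
            assert agree < 1e-10
        assert np.allclose(frac, s[:3] ** 2 / np.sum(s**2))

    def test_sign_convention(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((8, 5))
        _, loadings, _ = pca_overview(X, n_components=2)
        for c in range(2):
            assert loadings[np.argmax(np.abs(loadings[:, c])), c] > 0

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pca_overview(np.ones((5, 3)))


class TestConditioningCurve:
    def test_reproducible_and_ordered(self, small_results):
        curve = small_results.curves["intense"]
        assert list(curve["position_n"]) == list(range(1, 8))
        assert set(curve.columns) >= {"delta", "p_value", "n_sig_area",
                                      "n_sig_rt", "n_sig_width"}
        assert ((curve["delta"] > 0) & (curve["delta"] <= 1)).all()

    def test_bitwise_reproducible(self, small_batch):
        table, truth, sim = small_batch
        inf = truth.class_by_feature.index[
            truth.class_by_feature.str.startswith("informative")]
        sub = table.subset_features(inf)
        c1, _ = conditioning_curve(sub, "intense", m=30, seed=4)
        c2, _ = conditioning_curve(sub, "intense", m=30, seed=4)
        pd.testing.assert_frame_equal(c1, c2)

    def test_pooling_invariant_to_cycle_order(self, small_batch):
        # relabelling the run orders cycle-wise must not change the pooled
        # per-position sets, hence not the counts
        table, truth, sim = small_batch
        inf = truth.class_by_feature.index[
            truth.class_by_feature.str.startswith("informative")]
        sub = table.subset_features(inf)
        curve, _ = conditioning_curve(sub, "intense", m=10, seed=0)
        seq = sub.sequence
        intense = seq[(seq["cycle_type"] == "intense")]
        cids = sorted(intense["cycle_id"].unique())
        # swap the data of the first and last intense cycle
        a = intense.index[intense["cycle_id"] == cids[0]]
        b = intense.index[intense["cycle_id"] == cids[-1]]
        swapped = sub.copy()
        for m_ in ("area", "rt", "width"):
            mat = getattr(swapped, m_)
            mat[list(a) + list(b)] = mat[list(b) + list(a)].to_numpy()
        curve2, _ = conditioning_curve(swapped, "intense", m=10, seed=0)
        pd.testing.assert_frame_equal(
            curve[["n_sig_area", "n_sig_rt", "n_sig_width"]],
            curve2[["n_sig_area", "n_sig_rt", "n_sig_width"]])

    def test_null_batch_counts_at_false_positive_level(self):
        from blankqc.simulate import urine_like, generate_batch

        sim = urine_like(seed=7)
        sim.n_features_by_class = {"informative_stable": 60, "contaminant": 10}
        sim.n_cycles_intense = sim.n_cycles_mild = 4
        sim.drift_amplitude = 0.0
        table, truth = generate_batch(sim)
        inf = truth.class_by_feature.index[
            truth.class_by_feature == "informative_stable"]
        curve, _ = conditioning_curve(table.subset_features(inf), "intense",
                                      m=50, seed=3)
        assert (curve["n_sig_area"] <= 0.05 * len(inf)).all()


class TestBlankPca:
    def test_first_blanks_separate(self, small_results):
        sc = small_results.blank_scores
        intense = sc[sc["cycle_type"] == "intense"]
        labels = (intense["blank_position"] == 1).to_numpy()
        sil = silhouette_score(intense[["PC1"]].to_numpy(), labels)
        assert sil > 0

    def test_carryover_loads_stronger_than_contaminants(self, small_results, small_batch):
        _, truth, _ = small_batch
        ld = small_results.blank_loadings
        co1 = truth.class_by_feature.index[truth.class_by_feature == "carryover_1"]
        cont = truth.class_by_feature.index[truth.class_by_feature == "contaminant"]
        co_mag = ld.loc[ld.index.intersection(co1), "PC1"].abs().median()
        cont_mag = ld.loc[ld.index.intersection(cont), "PC1"].abs().median()
        assert co_mag > cont_mag

    def test_identical_blanks_rejected(self, small_batch):
        table, truth, _ = small_batch
        flat = table.copy()
        blanks = flat.injections_where(sample_class="blank")
        flat.area[blanks] = 1.0
        cont = truth.class_by_feature.index[truth.class_by_feature == "contaminant"]
        with pytest.raises(ValueError):
            blank_pca(flat, cont)
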
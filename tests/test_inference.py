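import numpy as np
import pytest
from scipy import stats as sps
from scipy.stats import rankdata

from decflow.dynec import WindowSpec
from decflow.errors import DataError, ParameterError
from decflow.inference import (
    edgewise_ttest,
    fdr_bh,
    icc_2_1,
    nbs_component_test,
    reliability_across_windows,
    spearman_assoc,
)
from decflow.synthdata import SimConfig, simulate_cohort

import pandas as pd


def brute_bh(p, q):
    """Step-up enumeration oracle: largest i with p_(i) <= q i/m."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    k_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= q * i / m:
            k_star = i
    reject[order[:k_star]] = True
    adj = np.empty(m)
    prev = 1.0
    for i in range(m, 0, -1):
        prev = min(prev, p[order[i - 1]] * m / i)
        adj[order[i - 1]] = prev
    return adj, reject


class TestEdgewise:
    def _groups(self, seed=0, shift=None, n=20, d=5):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, d, d))
        b = rng.normal(size=(n, d, d))
        if shift is not None:
            i, j, delta = shift
            a[:, i, j] += delta
        return a, b

    def test_identical_groups(self):
        a, _ = self._groups()
        res = edgewise_ttest(a, a.copy())
        off = ~np.eye(a.shape[1], dtype=bool)
        np.testing.assert_allclose(res.t[off], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.p[off], 1.0, atol=1e-12)

    def test_planted_shift_attains_min_p(self):
        a, b = self._groups(seed=1, shift=(1, 3, 5.0))
        res = edgewise_ttest(a, b)
        assert np.unravel_index(np.nanargmin(res.p), res.p.shape) == (1, 3)

    def test_label_swap_negates_t(self):
        a, b = self._groups(seed=2)
        r1 = edgewise_ttest(a, b)
        r2 = edgewise_ttest(b, a)
        off = ~np.eye(a.shape[1], dtype=bool)
        np.testing.assert_allclose(r1.t[off], -r2.t[off], atol=1e-12)

    def test_matches_scipy_welch(self):
        a, b = self._groups(seed=3, n=12)
        res = edgewise_ttest(a, b)
        t_ref, p_ref = sps.ttest_ind(a, b, axis=0, equal_var=False)
        off = ~np.eye(a.shape[1], dtype=bool)
        np.testing.assert_allclose(res.t[off], t_ref[off], atol=1e-10)
        np.testing.assert_allclose(res.p[off], p_ref[off], atol=1e-10)

    def test_nan_subjects_excluded_per_edge(self):
        a, b = self._groups(seed=4, n=10)
        a[0] = np.nan
        res = edgewise_ttest(a, b)
        assert res.n_a.max() == 9
        assert np.isfinite(res.t[0, 1])

    def test_empty_state_group_rejected(self):
        a, b = self._groups(n=3)
        with pytest.raises(DataError):
            edgewise_ttest(np.full_like(a, np.nan), b)


class TestNBS:
    def test_no_suprathreshold_edges(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 4, 4))
        res = nbs_component_test(a, a + 0.0, primary_t_threshold=50.0, n_perm=100, seed=0)
        assert res.components == []

    def test_planted_cluster_detected(self):
        rng = np.random.default_rng(5)
        d, n = 8, 20
        a = rng.normal(size=(n, d, d))
        b = rng.normal(size=(n, d, d))
        cluster_nodes = [0, 1, 2, 3]
        for i in cluster_nodes:
            for j in cluster_nodes:
                if i != j:
                    a[:, i, j] += 3.0
        res = nbs_component_test(a, b, primary_t_threshold=3.0, n_perm=1000, seed=0)
        assert len(res.components) >= 1
        top = res.components[0]
        assert set(top.nodes) == set(cluster_nodes)
        assert top.p_value < 0.05
        assert res.surviving.sum() == top.size

    def test_node_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        d, n = 6, 15
        a = rng.normal(size=(n, d, d))
        b = rng.normal(size=(n, d, d))
        a[:, 0, 1] += 4.0
        a[:, 1, 2] += 4.0
        perm = np.array([3, 5, 0, 1, 2, 4])
        a_p = a[:, perm][:, :, perm]
        b_p = b[:, perm][:, :, perm]
        r1 = nbs_component_test(a, b, primary_t_threshold=3.0, n_perm=200, seed=3)
        r2 = nbs_component_test(a_p, b_p, primary_t_threshold=3.0, n_perm=200, seed=3)
        assert [c.size for c in r1.components] == [c.size for c in r2.components]
        assert [c.p_value for c in r1.components] == [c.p_value for c in r2.components]

    def test_n_perm_floor(self):
        a = np.zeros((5, 3, 3))
        with pytest.raises(ParameterError):
            nbs_component_test(a, a, n_perm=50)


class TestFdrBH:
    def test_hand_example(self):
        adj, rej = fdr_bh([0.002, 0.01, 0.03, 0.04], q=0.05)
        np.testing.assert_allclose(adj, [0.008, 0.02, 0.04, 0.04])
        assert rej.all()

    def test_all_ones(self):
        adj, rej = fdr_bh([1.0, 1.0, 1.0], q=0.05)
        assert not rej.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_single_p(self):
        adj, rej = fdr_bh([0.03], q=0.05)
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_brute_force_1000_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            q = float(rng.uniform(0.01, 0.2))
            adj, rej = fdr_bh(p, q=q)
            adj_o, rej_o = brute_bh(p, q)
            np.testing.assert_allclose(adj, adj_o, atol=1e-12)
            assert np.array_equal(rej, rej_o)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.random(50)
        adj, rej = fdr_bh(p, q=0.05)
        rej_ref, adj_ref, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, adj_ref, atol=1e-12)
        assert np.array_equal(rej, rej_ref)

    def test_nan_propagates(self):
        adj, rej = fdr_bh([0.01, np.nan, 0.5], q=0.05)
        assert np.isnan(adj[1]) and not rej[1]
        assert np.isfinite(adj[0])

    def test_out_of_range(self):
        with pytest.raises(DataError):
            fdr_bh([0.5, 1.5])
        with pytest.raises(ParameterError):
            fdr_bh([0.5], q=0.0)


class TestSpearman:
    def _tables(self, x, y):
        metrics = pd.DataFrame({"subject_id": range(len(x)), "F": x})
        clinical = pd.DataFrame({"subject_id": range(len(y)), "MoCA": y})
        return metrics, clinical

    def test_monotone(self):
        m, c = self._tables([1, 2, 3, 4], [10, 20, 30, 40])
        out = spearman_assoc(m, c, clinical_cols=("MoCA",))
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_reversed(self):
        m, c = self._tables([1, 2, 3, 4], [40, 30, 20, 10])
        out = spearman_assoc(m, c, clinical_cols=("MoCA",))
        assert out["rho"].iloc[0] == pytest.approx(-1.0)

    def test_ties_match_rank_formula(self):
        rng = np.random.default_rng(10)
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 5, size=30).astype(float)
        m, c = self._tables(x, y)
        out = spearman_assoc(m, c, clinical_cols=("MoCA",))
        # oracle: Pearson correlation of average ranks
        rho_oracle = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
        assert out["rho"].iloc[0] == pytest.approx(rho_oracle, abs=1e-12)

    def test_constant_flagged(self):
        m, c = self._tables([1.0, 1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4, 5])
        out = spearman_assoc(m, c, clinical_cols=("MoCA",))
        assert out["flag"].iloc[0] == "constant"
        assert np.isnan(out["rho"].iloc[0])

    def test_insufficient_n_flagged(self):
        m, c = self._tables([1, 2, 3], [3, 2, 1])
        out = spearman_assoc(m, c, clinical_cols=("MoCA",))
        assert out["flag"].iloc[0] == "insufficient-n"


def icc_oracle(x):
    """Independent ANOVA mean-squares computation (textbook formulas)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    gm = x.mean()
    msr = k * sum((x[i].mean() - gm) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - gm) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + gm) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_columns(self):
        x = np.column_stack([[1.0, 2.0, 3.0, 4.0]] * 2)
        res = icc_2_1(x)
        assert res.icc == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_reversed_columns_negative(self):
        x = np.column_stack([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        res = icc_2_1(x)
        assert res.icc == pytest.approx(icc_oracle(x), abs=1e-12)
        assert res.icc < 0

    def test_oracle_random(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=(rng.integers(3, 12), rng.integers(2, 5)))
            assert icc_2_1(x).icc == pytest.approx(icc_oracle(x), abs=1e-10)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(12)
        x = rng.normal(size=(10, 3)) + np.arange(10)[:, None]
        res = icc_2_1(x)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 3),
            "rater": np.tile(np.arange(3), 10),
            "score": x.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]  # two-way random, single
        assert res.icc == pytest.approx(icc2, abs=1e-6)

    def test_offset_lowers_absolute_agreement(self):
        rng = np.random.default_rng(13)
        base = rng.normal(size=10)
        x0 = np.column_stack([base, base + rng.normal(0, 0.1, 10)])
        x1 = x0.copy()
        x1[:, 1] += 2.0
        assert icc_2_1(x1).icc < icc_2_1(x0).icc

    def test_missing_cells_rejected(self):
        x = np.ones((4, 2))
        x[0, 0] = np.nan
        with pytest.raises(DataError):
            icc_2_1(x)
        with pytest.raises(ParameterError):
            icc_2_1(np.ones((2, 2)))


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(SimConfig(n_subjects=(5, 5), n_timepoints=170), seed=21)


class TestReliability:
    def test_same_setting_twice_gives_unity(self, cohort):
        spec = WindowSpec(18, 2)
        out = reliability_across_windows(cohort.subjects, [spec, spec], seed=0)
        np.testing.assert_allclose(out["icc"].to_numpy(), 1.0, atol=1e-9)

    def test_shuffled_columns_near_zero(self):
        rng = np.random.default_rng(14)
        a = rng.uniform(size=200)
        b = rng.permutation(a)
        res = icc_2_1(np.column_stack([a, b]))
        assert abs(res.icc) < 0.2

    def test_requires_two_settings(self, cohort):
        with pytest.raises(ParameterError):
            reliability_across_windows(cohort.subjects, [WindowSpec(18, 2)])
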
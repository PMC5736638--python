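"""Restricted PCA, the L1 / L1-L2 statistics, empirical nulls and BH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import infosig as isg
from infosig.activity import derive_seed


def brute_force_pca(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Independent oracle: dense eigendecomposition of the gene-gene sample
    covariance (samples as observations, denominator n-1)."""
    centered = values - values.mean(axis=1, keepdims=True)
    n = values.shape[1]
    cov = centered @ centered.T / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


class TestCenterGenes:
    def test_mean_subtraction(self):
        ds = isg.ExpressionDataset(
            "D", ["a", "b"], ["s1", "s2", "s3"],
            np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]),
        )
        out = isg.center_genes(ds)
        assert np.allclose(out.values[0], [-1, 0, 1])
        assert np.allclose(out.values[1], [0, 0, 0])

    def test_idempotent(self, tiny_ds):
        once = isg.center_genes(tiny_ds)
        twice = isg.center_genes(once)
        assert np.allclose(once.values, twice.values)


class TestRestrictedPca:
    def test_matches_dense_eigendecomposition_oracle(self, tiny_ds):
        matched = tiny_ds.gene_ids
        evals, eigengene, metasample = isg.restricted_pca(tiny_ds, matched)
        ref_evals, ref_evecs = brute_force_pca(tiny_ds.values)
        k = len(evals)
        assert np.allclose(evals, ref_evals[:k], atol=1e-9)
        # eigenvector agreement up to sign
        dot = abs(float(eigengene @ ref_evecs[:, 0]))
        assert dot == pytest.approx(1.0, abs=1e-9)

    def test_trace_identity(self, tiny_ds):
        evals, _, _ = isg.restricted_pca(tiny_ds, tiny_ds.gene_ids)
        centered = tiny_ds.values - tiny_ds.values.mean(axis=1, keepdims=True)
        total_var = np.sum(centered**2) / (centered.shape[1] - 1)
        assert evals.sum() == pytest.approx(total_var, abs=1e-8)

    def test_rank_one_pair(self):
        rng = np.random.default_rng(3)
        g1 = rng.normal(size=8)
        values = np.vstack([g1, 2 * g1])
        ds = isg.ExpressionDataset("D", ["a", "b"], [f"s{i}" for i in range(8)], values)
        evals, eigengene, _ = isg.restricted_pca(ds, ["a", "b"])
        assert evals[1] == pytest.approx(0.0, abs=1e-12)
        expected = np.array([1.0, 2.0]) / np.sqrt(5.0)
        assert np.allclose(np.abs(eigengene), expected, atol=1e-9)

    def test_metasample_variance_equals_first_eigenvalue(self, tiny_ds):
        evals, _, metasample = isg.restricted_pca(tiny_ds, tiny_ds.gene_ids)
        assert np.var(metasample, ddof=1) == pytest.approx(evals[0], rel=1e-9)

    def test_unit_norm_eigengene_and_deterministic_sign(self, tiny_ds):
        _, eigengene, metasample = isg.restricted_pca(tiny_ds, tiny_ds.gene_ids)
        assert np.linalg.norm(eigengene) == pytest.approx(1.0, abs=1e-9)
        centered = tiny_ds.values - tiny_ds.values.mean(axis=1, keepdims=True)
        mean_profile = centered.mean(axis=0)
        assert float(metasample @ mean_profile) >= 0

    def test_all_zero_submatrix_rejected(self):
        ds = isg.ExpressionDataset(
            "D", ["a", "b"], ["s1", "s2", "s3"], np.ones((2, 3)) * 7
        )
        with pytest.raises(ValueError, match="constant"):
            isg.restricted_pca(ds, ["a", "b"])


class TestStatistics:
    @pytest.mark.parametrize(
        "evals,expected", [((4, 0, 0), 1.0), ((2, 1, 1), 0.5)]
    )
    def test_l1_examples(self, evals, expected):
        assert isg.l1_statistic(np.array(evals, dtype=float)) == expected

    def test_l1_all_zero_rejected(self):
        with pytest.raises(ValueError):
            isg.l1_statistic(np.zeros(3))

    @pytest.mark.parametrize(
        "evals,expected", [((2, 1), 2.0), ((3, 3), 1.0)]
    )
    def test_l1l2_examples(self, evals, expected):
        assert isg.l1l2_statistic(np.array(evals, dtype=float)) == expected

    def test_l1l2_rank_one_is_infinite(self):
        assert isg.l1l2_statistic(np.array([2.0, 0.0])) == np.inf

    def test_l1_invariant_under_sample_and_gene_permutation(self, tiny_ds):
        evals, _, _ = isg.restricted_pca(tiny_ds, tiny_ds.gene_ids)
        l1 = isg.l1_statistic(evals)
        rng = np.random.default_rng(5)
        gp, sp = rng.permutation(6), rng.permutation(10)
        permuted = isg.ExpressionDataset(
            "P",
            [tiny_ds.gene_ids[i] for i in gp],
            [tiny_ds.sample_ids[j] for j in sp],
            tiny_ds.values[np.ix_(gp, sp)],
        )
        evals_p, _, _ = isg.restricted_pca(permuted, permuted.gene_ids)
        assert isg.l1_statistic(evals_p) == pytest.approx(l1, rel=1e-12)


class TestBuildNull:
    def test_deterministic_given_seed(self, tiny_ds):
        a = isg.build_null(tiny_ds, 3, 20, seed=11)
        b = isg.build_null(tiny_ds, 3, 20, seed=11)
        assert np.array_equal(a.l1_samples, b.l1_samples)
        assert np.array_equal(a.l1l2_samples, b.l1l2_samples)

    def test_ranges(self, tiny_ds):
        null = isg.build_null(tiny_ds, 4, 30, seed=1)
        assert np.all((null.l1_samples > 0) & (null.l1_samples <= 1))
        assert np.all(null.l1l2_samples >= 1)

    def test_full_gene_set_draws_identical(self, tiny_ds):
        null = isg.build_null(tiny_ds, 6, 10, seed=2)
        assert np.allclose(null.l1_samples, null.l1_samples[0])

    def test_set_size_exceeding_gene_count_rejected(self, tiny_ds):
        with pytest.raises(ValueError):
            isg.build_null(tiny_ds, 7, 10, seed=0)

    def test_monte_carlo_self_consistency_on_noise(self):
        """Mean null L1 agrees between two independent seeds within 3 SEM."""
        rng = np.random.default_rng(10)
        ds = isg.ExpressionDataset(
            "N", [f"g{i}" for i in range(500)], [f"s{j}" for j in range(60)],
            rng.standard_normal((500, 60)),
        )
        a = isg.build_null(ds, 30, 150, seed=1)
        b = isg.build_null(ds, 30, 150, seed=2)
        sem = np.sqrt(a.l1_samples.var() / 150 + b.l1_samples.var() / 150)
        assert abs(a.l1_samples.mean() - b.l1_samples.mean()) < 3 * sem


class TestEmpiricalPvalue:
    def test_above_all_nulls(self):
        assert isg.empirical_pvalue(10.0, np.arange(99) / 100) == pytest.approx(1 / 100)

    def test_below_all_nulls(self):
        assert isg.empirical_pvalue(-1.0, np.arange(99)) == 1.0

    def test_median_of_101_distinct(self):
        null = np.arange(101, dtype=float)
        assert isg.empirical_pvalue(50.0, null) == pytest.approx((1 + 51) / 102)

    def test_infinite_observed(self):
        assert isg.empirical_pvalue(np.inf, np.arange(50)) == pytest.approx(1 / 51)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=40),
        st.floats(-100, 100),
        st.floats(0, 10),
    )
    def test_monotone_non_increasing_in_observed(self, null, obs, delta):
        null = np.array(null)
        assert isg.empirical_pvalue(obs + delta, null) <= isg.empirical_pvalue(obs, null)


def step_up_oracle(p):
    """Hand-rolled BH step-up, independent of the implementation path."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.005, 0.5), (0.01, 0.5)),
            ((0.3,), (0.3,)),
        ],
    )
    def test_worked_examples(self, p, expected):
        assert np.allclose(isg.bh_adjust(p), expected)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5, np.nan])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            isg.bh_adjust([0.5, bad])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=30))
    def test_matches_step_up_oracle_and_dominates_input(self, p):
        adj = isg.bh_adjust(p)
        assert np.allclose(adj, step_up_oracle(p), atol=1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        # adjusted order respects raw order
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestScoreCollection:
    def test_single_fully_matched_signature(self, tiny_ds):
        coll = isg.SignatureCollection(
            [isg.GeneSignature("S", "c", tuple(tiny_ds.gene_ids[:4]))]
        )
        res = isg.score_collection(
            coll, tiny_ds, isg.ActivityConfig(min_genes=2, n_draws=30, seed=0)
        )
        assert len(res) == 1
        r = res[0]
        assert r.n_matched == 4
        assert 0 < r.l1 <= 1 and r.l1l2 >= 1
        assert 0 < r.p_l1 <= 1 and 0 < r.padj_l1 <= 1
        assert len(r.metasample) == 10
        assert np.linalg.norm(r.eigengene) == pytest.approx(1.0, abs=1e-9)

    def test_below_min_genes_skipped(self, tiny_ds):
        coll = isg.SignatureCollection(
            [isg.GeneSignature("S", "c", ("g0", "g1", "nope"))]
        )
        res = isg.score_collection(
            coll, tiny_ds, isg.ActivityConfig(min_genes=10, n_draws=10, seed=0)
        )
        assert res == []

    def test_null_sharing_and_determinism(self, tiny_ds):
        coll = isg.SignatureCollection(
            [
                isg.GeneSignature("A", "c", ("g0", "g1", "g2")),
                isg.GeneSignature("B", "c", ("g3", "g4", "g5")),
            ]
        )
        cfg = isg.ActivityConfig(min_genes=2, n_draws=50, seed=9)
        r1 = isg.score_collection(coll, tiny_ds, cfg)
        r2 = isg.score_collection(coll, tiny_ds, cfg)
        assert [(r.p_l1, r.p_l1l2) for r in r1] == [(r.p_l1, r.p_l1l2) for r in r2]

    def test_pvalue_calibration_on_pure_noise(self):
        """Null-data p-values are stochastically >= uniform on a grid."""
        rng = np.random.default_rng(21)
        ds = isg.ExpressionDataset(
            "N", [f"g{i}" for i in range(400)], [f"s{j}" for j in range(50)],
            rng.standard_normal((400, 50)),
        )
        # distinct sizes so each signature gets an independent null
        sigs = []
        genes = np.array(ds.gene_ids, dtype=object)
        for i, size in enumerate(range(15, 55)):
            chosen = rng.choice(genes, size=size, replace=False)
            sigs.append(isg.GeneSignature(f"R{i}", "c", tuple(chosen.tolist())))
        res = isg.score_collection(
            isg.SignatureCollection(sigs), ds,
            isg.ActivityConfig(min_genes=10, n_draws=199, seed=3),
        )
        p = np.array([r.p_l1 for r in res])
        n = p.size
        for t in (0.1, 0.25, 0.5):
            frac = float(np.mean(p <= t))
            assert frac <= t + 3 * np.sqrt(t * (1 - t) / n)


def test_derive_seed_stable_and_bounded():
    s = derive_seed(123, "null", "D1", 50)
    assert s == derive_seed(123, "null", "D1", 50)
    assert 0 <= s < 2**31
    assert s != derive_seed(123, "null", "D1", 51)
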
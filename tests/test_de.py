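import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, rankdata

from georif.de import (
    DispersionEstimate,
    _exact_p,
    bh_adjust,
    equalized_counts,
    estimate_common_dispersion,
    log_cpm,
    nb_exact_test,
    select_de,
    tmm_factors,
)
from georif.exceptions import DesignError
from georif.io import CountMatrix
from georif.synth import SynthParams, generate_null


def _matrix(counts, n1, n2):
    counts = np.asarray(counts)
    samples = [f"s{i}" for i in range(counts.shape[1])]
    cmap = {s: ("A" if i < n1 else "B") for i, s in enumerate(samples)}
    return CountMatrix(
        pd.DataFrame(counts, index=[f"g{i}" for i in range(counts.shape[0])], columns=samples),
        cmap,
        ("A", "B"),
    )


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _tmm_oracle(obs, ref, lib_obs, lib_ref, trim_m=0.3, trim_a=0.05):
    """Direct, loop-based application of the trim/weight definition."""
    ms, as_, ws = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            po, pr = o / lib_obs, r / lib_ref
            ms.append(np.log2(po / pr))
            as_.append(0.5 * np.log2(po * pr))
            ws.append((lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r))
    ms, as_, ws = map(np.array, (ms, as_, ws))
    n = len(ms)
    rm, ra = rankdata(ms), rankdata(as_)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2.0 ** (np.sum(ms[keep] / ws[keep]) / np.sum(1.0 / ws[keep]))


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        col = np.random.default_rng(0).poisson(100, 50)
        m = _matrix(np.tile(col[:, None], (1, 6)), 3, 3)
        np.testing.assert_allclose(tmm_factors(m).to_numpy(), 1.0, atol=1e-12)

    def test_depth_difference_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(100, 60)
        counts = np.column_stack([a, 2 * a, a, 2 * a])
        m = _matrix(counts, 2, 2)
        f = tmm_factors(m).to_numpy()
        np.testing.assert_allclose(f, f[0], atol=1e-12)

    def test_matches_direct_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            counts = rng.negative_binomial(5, 0.05, size=(300, 4)) + 1
            m = _matrix(counts, 2, 2)
            f = tmm_factors(m, ref_sample="s0")
            libs = counts.sum(axis=0)
            expected = np.array(
                [1.0]
                + [
                    _tmm_oracle(counts[:, j], counts[:, 0], libs[j], libs[0])
                    for j in range(1, 4)
                ]
            )
            expected /= np.exp(np.mean(np.log(expected)))
            np.testing.assert_allclose(f.to_numpy(), expected, rtol=0, atol=1e-9)

    def test_all_zero_sample_rejected(self):
        counts = np.ones((5, 4), dtype=int)
        counts[:, 2] = 0
        with pytest.raises(DesignError, match="all-zero"):
            tmm_factors(_matrix(counts, 2, 2))


class TestLogCPM:
    def test_direct_formula(self):
        counts = np.zeros((2, 4), dtype=int)
        counts[1] = [999_998, 999_998, 999_998, 999_998]  # fills library to ~1e6
        counts[0, 0] = 0
        counts[1, 0] = 1_000_000
        m = _matrix(counts, 2, 2)
        f = pd.Series(1.0, index=m.sample_ids)
        nm = log_cpm(m, f, pseudocount=0.5)
        assert nm.log_expr.iloc[0, 0] == pytest.approx(np.log2(0.5), abs=1e-9)

    def test_scaling_invariance_with_scaled_pseudocount(self, small_counts):
        f = pd.Series(1.0, index=small_counts.sample_ids)
        a = log_cpm(small_counts, f, pseudocount=0.5).log_expr
        doubled = CountMatrix(
            small_counts.counts * 2, small_counts.condition_of, small_counts.conditions
        )
        b = log_cpm(doubled, f, pseudocount=1.0).log_expr
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_monotone_in_count(self, small_counts):
        f = pd.Series(1.0, index=small_counts.sample_ids)
        nm = log_cpm(small_counts, f)
        col = small_counts.counts.iloc[:, 0].to_numpy()
        expr = nm.log_expr.iloc[:, 0].to_numpy()
        order = np.argsort(col)
        assert (np.diff(expr[order]) >= 0).all()

    def test_norm_factor_geometric_mean_enforced(self, small_counts):
        f = pd.Series(1.0, index=small_counts.sample_ids)
        nm = log_cpm(small_counts, f)
        assert abs(np.log(nm.norm_factors).mean()) < 1e-9


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------


class TestDispersion:
    def test_poisson_data_gives_near_zero_alpha(self):
        params = SynthParams(n_genes=2000, n_samples_per_condition=5, alpha=0.0,
                             mean_range=(1, 1000))
        cm = generate_null(params, 11).drop_unexpressed()
        f = tmm_factors(cm)
        d = estimate_common_dispersion(cm, f, tagwise=False)
        assert d.alpha_common < 0.05

    def test_shrinkage_limit_to_common(self):
        params = SynthParams(n_genes=200, n_samples_per_condition=5, alpha=0.3,
                             mean_range=(10, 500))
        cm = generate_null(params, 2).drop_unexpressed()
        f = tmm_factors(cm)
        d = estimate_common_dispersion(cm, f, tagwise=True, prior_weight=1e12)
        np.testing.assert_allclose(
            d.alpha_tagwise.to_numpy(), d.alpha_common, rtol=1e-6
        )

    def test_single_sample_condition_rejected_at_container(self):
        counts = np.random.default_rng(0).poisson(50, size=(10, 3))
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(10)],
                          columns=["s0", "s1", "s2"])
        with pytest.raises(DesignError, match="need >= 2"):
            CountMatrix(df, {"s0": "A", "s1": "A", "s2": "B"}, ("A", "B"))


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------


class TestExactTest:
    def test_balanced_equal_split_is_one(self):
        assert _exact_p(10, 10, 4, 4, 0.2) == 1.0

    def test_zero_total_is_one(self):
        assert _exact_p(0, 0, 4, 4, 0.2) == 1.0

    def test_poisson_limit_matches_binomial_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            total = int(rng.integers(1, 31))
            s1 = int(rng.integers(0, total + 1))
            pr = binom.pmf(np.arange(total + 1), total, n1 / (n1 + n2))
            oracle = min(1.0, pr[pr <= pr[s1] * (1 + 1e-12)].sum())
            assert _exact_p(s1, total - s1, n1, n2, 0.0) == pytest.approx(oracle, abs=1e-10)

    def test_condition_swap_leaves_pvalues_and_negates_logfc(self):
        params = SynthParams(n_genes=300, n_samples_per_condition=5, alpha=0.2,
                             mean_range=(5, 500))
        cm = generate_null(params, 3).drop_unexpressed()
        f = tmm_factors(cm)
        disp = estimate_common_dispersion(cm, f, tagwise=False)
        swapped = cm.with_conditions(cm.conditions[1], cm.conditions[0])
        p1 = nb_exact_test(cm, f, disp)
        p2 = nb_exact_test(swapped, f, disp)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-12)
        d1 = select_de(cm, f, p1)
        d2 = select_de(swapped, f, p2)
        np.testing.assert_allclose(
            d1.table["logFC"].to_numpy(), -d2.table["logFC"].to_numpy(), atol=1e-12
        )

    def test_power_on_planted_eightfold_changes(self):
        rng = np.random.default_rng(9)
        n_genes, n_de = 300, 40
        mu = np.exp(rng.uniform(np.log(20), np.log(500), n_genes))
        lam1 = np.tile(mu[:, None], (1, 10))
        lam1[:n_de] *= 8.0
        lam2 = np.tile(mu[:, None], (1, 10))
        draw = lambda lam: rng.poisson(rng.gamma(1 / 0.1, lam * 0.1))
        counts = np.hstack([draw(lam1), draw(lam2)])
        m = _matrix(counts, 10, 10)
        f = tmm_factors(m)
        disp = estimate_common_dispersion(m, f)
        res = select_de(m, f, nb_exact_test(m, f, disp), fdr_cutoff=0.05)
        flagged = res.table["is_de"].to_numpy()[:n_de]
        assert flagged.mean() >= 0.90


# ---------------------------------------------------------------------------
# BH and DE selection
# ---------------------------------------------------------------------------


def _bh_oracle(p):
    """Literal step-up definition."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_hand_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_single_and_degenerate(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_fdr_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(4)
        p = rng.random(200)
        fdr = bh_adjust(p)
        assert (fdr >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-15).all()


class TestSelectDE:
    def test_boundary_fdr_not_de(self, small_counts):
        f = pd.Series(1.0, index=small_counts.sample_ids)
        pvals = pd.Series(1.0, index=small_counts.gene_ids)
        res = select_de(small_counts, f, pvals, fdr_cutoff=0.05)
        # fdr == 1 everywhere; also check the strict-< convention directly
        assert not res.table["is_de"].any()
        assert (pd.Series([0.05]) < 0.05).iloc[0] == False  # noqa: E712

    def test_equalized_counts_rounding_half_to_even(self, small_counts):
        f = pd.Series(1.0, index=small_counts.sample_ids)
        eq = equalized_counts(small_counts, f)
        assert (eq.to_numpy() == np.round(eq.to_numpy())).all()

    def test_per_gene_dispersion_fallback(self):
        d = DispersionEstimate(0.3, None)
        np.testing.assert_allclose(d.per_gene(["a", "b"]), 0.3)
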
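import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

from georif.de import NormalizedMatrix, DEResult
from georif.io import RegulatorCatalog
from georif.metrics import (
    FISHER_DMAX,
    association_matrices,
    distance_to_association,
    fisher_distance,
    pairwise_association,
    sobolev_distance,
    statistical_correlation,
    to_simplex,
)
from tests.conftest import random_simplex


class TestSimplexEmbedding:
    def test_constant_profile_maps_to_uniform(self):
        np.testing.assert_allclose(to_simplex([1.0, 1.0, 1.0]), 1 / 3, atol=1e-12)

    def test_two_point_profile(self):
        p = to_simplex([0.0, 1.0])
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert p[1] > 0.99 and p[0] > 0

    def test_normalization_on_random_profiles(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            x = rng.standard_normal(int(rng.integers(3, 30))) * rng.uniform(0.1, 50)
            p = to_simplex(x)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert (p >= 0).all()

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10)
        np.testing.assert_allclose(to_simplex(x), to_simplex(3.0 * x - 7.0), atol=1e-12)


class TestFisherDistance:
    def test_identity(self):
        assert fisher_distance([0.5, 0.5], [0.5, 0.5]) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_maximal(self):
        assert fisher_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.pi / 2, abs=1e-12)

    def test_closed_form_spot_value(self):
        d = fisher_distance([0.5, 0.5], [0.9, 0.1])
        assert d == pytest.approx(np.arccos(np.sqrt(0.45) + np.sqrt(0.05)), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fisher_distance([1.0], [0.5, 0.5])

    def test_bounded_by_half_pi(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            n = int(rng.integers(2, 20))
            assert fisher_distance(random_simplex(rng, n), random_simplex(rng, n)) <= np.pi / 2 + 1e-12


class TestSobolevDistance:
    def test_identity(self):
        p = [0.2, 0.3, 0.5]
        assert sobolev_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_hand_spot_value_order_one(self):
        d = sobolev_distance([0.5, 0.5], [0.9, 0.1], order_k=1)
        assert d == pytest.approx(np.sqrt(1.6), abs=1e-9)

    def test_order_zero_is_euclidean(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(2, 20))
            p, q = random_simplex(rng, n), random_simplex(rng, n)
            assert sobolev_distance(p, q, 0) == pytest.approx(
                np.linalg.norm(p - q), abs=1e-12
            )

    @pytest.mark.parametrize("n", [4, 8, 16, 64])
    def test_spectral_parseval_equivalence(self, n):
        rng = np.random.default_rng(n)
        for _ in range(50):
            p, q = random_simplex(rng, n), random_simplex(rng, n)
            w_hat = np.fft.fft(p - q, norm="ortho")
            eig = np.abs(1.0 - np.exp(2j * np.pi * np.arange(n) / n)) ** 2
            spectral = np.sqrt(np.sum((1.0 + eig) * np.abs(w_hat) ** 2))
            assert sobolev_distance(p, q, 1) == pytest.approx(spectral, abs=1e-10)


class TestMetricAxioms:
    @pytest.mark.parametrize("dist", [fisher_distance, sobolev_distance])
    def test_axioms_on_random_pairs(self, dist):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(2, 15))
            p, q, r = (random_simplex(rng, n) for _ in range(3))
            dpq, dqp = dist(p, q), dist(q, p)
            assert dpq >= 0
            assert dist(p, p) == pytest.approx(0.0, abs=1e-9)
            assert dpq == pytest.approx(dqp, abs=1e-12)
            assert dpq <= dist(p, r) + dist(r, q) + 1e-9


class TestStatisticalCorrelation:
    def test_perfect_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert statistical_correlation(x, x) == pytest.approx(1.0)
        assert statistical_correlation(x, -x) == pytest.approx(-1.0)

    def test_spearman_monotone_is_one(self):
        assert statistical_correlation([1, 2, 3], [2, 4, 7], "spearman") == pytest.approx(1.0)

    def test_zero_variance_defined_as_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert statistical_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == 0.0

    @pytest.mark.parametrize("which,oracle", [("pearson", pearsonr), ("spearman", spearmanr)])
    def test_matches_scipy_oracle(self, which, oracle):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            x, y = rng.standard_normal(n), rng.standard_normal(n)
            assert statistical_correlation(x, y, which) == pytest.approx(
                oracle(x, y)[0], abs=1e-12
            )


class TestDistanceToAssociation:
    def test_endpoints(self):
        assert distance_to_association(0.0, "fisher", FISHER_DMAX) == 1.0
        assert distance_to_association(FISHER_DMAX, "fisher", FISHER_DMAX) == pytest.approx(0.0)

    def test_spot_value(self):
        d = np.arccos(np.sqrt(0.45) + np.sqrt(0.05))
        a = distance_to_association(d, "fisher", FISHER_DMAX)
        assert a == pytest.approx(1 - d / (np.pi / 2), abs=1e-9)
        assert a == pytest.approx(0.7048, abs=5e-4)

    def test_strictly_decreasing(self):
        ds = np.linspace(0, 1, 50)
        vals = [distance_to_association(d, "sobolev", 1.0) for d in ds]
        assert (np.diff(vals) < 0).all()

    def test_exceeding_dmax_rejected(self):
        with pytest.raises(ValueError):
            distance_to_association(1.1, "sobolev", 1.0)


def _make_nm_de(rng, n_reg=2, n_de=3, n_other=2, n_per=5):
    genes = (
        [f"r{i}" for i in range(n_reg)]
        + [f"d{i}" for i in range(n_de)]
        + [f"o{i}" for i in range(n_other)]
    )
    samples = [f"s{i}" for i in range(2 * n_per)]
    expr = rng.standard_normal((len(genes), len(samples))) + 8.0
    nm = NormalizedMatrix(
        pd.DataFrame(expr, index=genes, columns=samples),
        pd.Series(1.0, index=samples),
        pd.Series(10_000, index=samples),
    )
    table = pd.DataFrame(
        {
            "gene": genes,
            "e1": 8.0,
            "e2": 7.0,
            "logFC": 1.0,
            "pvalue": 0.5,
            "fdr": 0.5,
            "is_de": [g.startswith("d") for g in genes],
        }
    )
    de = DEResult(table, 0.05)
    cat = RegulatorCatalog({f"r{i}": frozenset({"TF"}) for i in range(n_reg)})
    cond = (samples[:n_per], samples[n_per:])
    return nm, de, cat, cond


class TestAssociationMatrices:
    @pytest.mark.parametrize("metric", ["pearson", "spearman", "fisher", "sobolev"])
    def test_shape_contract_and_range(self, metric):
        rng = np.random.default_rng(31)
        nm, de, cat, cond = _make_nm_de(rng)
        a = association_matrices(nm, de, cat, metric, conditions_samples=cond)
        assert a.r1.shape == (2, 3) and a.r2.shape == (2, 3)
        lo = -1.0 if metric in ("pearson", "spearman") else 0.0
        for r in (a.r1, a.r2):
            assert (r.to_numpy() >= lo - 1e-9).all() and (r.to_numpy() <= 1.0 + 1e-9).all()

    def test_identical_condition_profiles_give_equal_entries(self):
        rng = np.random.default_rng(37)
        nm, de, cat, cond = _make_nm_de(rng)
        expr = nm.log_expr.copy()
        expr[cond[1]] = expr[cond[0]].to_numpy()
        nm2 = NormalizedMatrix(expr, nm.norm_factors, nm.lib_sizes)
        for metric in ("pearson", "fisher", "sobolev"):
            a = association_matrices(nm2, de, cat, metric, conditions_samples=cond)
            np.testing.assert_allclose(a.r1.to_numpy(), a.r2.to_numpy(), atol=1e-12)

    def test_pearson_entries_match_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            nm, de, cat, cond = _make_nm_de(rng, n_per=int(rng.integers(4, 9)))
            a = association_matrices(nm, de, cat, "pearson", conditions_samples=cond)
            for reg in a.r1.index:
                for gene in a.r1.columns:
                    x = nm.log_expr.loc[reg, cond[0]].to_numpy()
                    y = nm.log_expr.loc[gene, cond[0]].to_numpy()
                    assert a.r1.loc[reg, gene] == pytest.approx(pearsonr(x, y)[0], abs=1e-12)

    def test_sobolev_dmax_shared_and_recorded(self):
        rng = np.random.default_rng(43)
        nm, de, cat, cond = _make_nm_de(rng)
        a = association_matrices(nm, de, cat, "sobolev", conditions_samples=cond)
        assert np.isfinite(a.d_max) and a.d_max > 0
        assert min(a.r1.to_numpy().min(), a.r2.to_numpy().min()) == pytest.approx(0.0, abs=1e-12)

    def test_empty_de_set_rejected(self):
        rng = np.random.default_rng(47)
        nm, de, cat, cond = _make_nm_de(rng)
        table = de.table.copy()
        table["is_de"] = False
        with pytest.raises(ValueError, match="empty DE set"):
            association_matrices(nm, DEResult(table, 0.05), cat, "pearson",
                                 conditions_samples=cond)

    def test_absent_regulator_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(53)
        nm, de, cat, cond = _make_nm_de(rng)
        cat2 = RegulatorCatalog({**cat.classes_of, "ghost": frozenset({"TF"})})
        with caplog.at_level("WARNING"):
            a = association_matrices(nm, de, cat2, "pearson", conditions_samples=cond)
        assert "ghost" not in a.r1.index
        assert "dropped" in caplog.text

    def test_pairwise_association_unit_diagonal(self):
        rng = np.random.default_rng(59)
        profiles = pd.DataFrame(rng.standard_normal((4, 12)), index=list("abcd"))
        for metric in ("pearson", "spearman", "fisher", "sobolev"):
            m = pairwise_association(profiles, metric)
            np.testing.assert_allclose(np.diag(m.to_numpy()), 1.0, atol=1e-12)
            np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T, atol=1e-12)
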
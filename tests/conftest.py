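import numpy as np
import pandas as pd
import pytest

from georif.io import CountMatrix, RegulatorCatalog
from georif.synth import SynthParams, generate_wired, make_default_truth


@pytest.fixture
def small_counts() -> CountMatrix:
    """6 genes x 6 samples, two conditions of 3, deterministic."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(200, size=(6, 6))
    df = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(6)],
    )
    condition_of = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
    return CountMatrix(df, condition_of, ("A", "B"))


@pytest.fixture
def small_catalog() -> RegulatorCatalog:
    return RegulatorCatalog(
        {"g0": frozenset({"TF"}), "g1": frozenset({"TF", "EF"}), "g2": frozenset({"lncRNA"})}
    )


@pytest.fixture
def wired_fixture():
    """Factory for small wired fixtures: (counts, catalog, truth) given a seed."""

    def make(seed: int = 0, n_genes: int = 200, n_regulators: int = 20, n_targets: int = 10):
        params = SynthParams(
            n_genes=n_genes,
            n_samples_per_condition=10,
            alpha=0.02,
            mean_range=(50.0, 1000.0),
            tau=1.0,
        )
        truth, catalog = make_default_truth(
            params,
            seed=seed,
            n_de=n_targets,
            n_targets=n_targets,
            n_wired=1,
            rho=0.9,
            n_regulators=n_regulators,
        )
        cm, truth = generate_wired(params, truth)
        return cm, catalog, truth

    return make


def random_simplex(rng: np.random.Generator, n: int) -> np.ndarray:
    p = rng.dirichlet(np.ones(n))
    return p


def random_correlation(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random PSD correlation matrix (Gram matrix of random vectors)."""
    a = rng.standard_normal((n, n + 3))
    cov = a @ a.T
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr
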
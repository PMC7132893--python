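"""Simulation-based evaluation of the pipeline on its own synthetic fixtures.

These routines quantify the statistical behaviour the package is designed
around: type-I-error calibration of the exact test on null data, recovery of
the NB dispersion, recovery of a planted differentially wired regulator by
each association measure, and elimination of mediated edges by PCIT.  They
are used by the test suite and by ``scripts/acceptance.py``; run sizes are
arguments so callers can trade precision for time.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import de as de_mod
from .pcit import pcit_filter
from .pipeline import RIFAnalysis
from .synth import SynthParams, WIRED_PARAMS, generate_null, generate_wired, make_default_truth

NULL_PARAMS = SynthParams(
    n_genes=2000, n_samples_per_condition=10, alpha=0.4, mean_range=(1.0, 1000.0)
)


def null_calibration(
    n_seeds: int = 20,
    params: SynthParams = NULL_PARAMS,
    fdr_cutoff: float = 0.05,
    base_seed: int = 0,
) -> dict[str, float]:
    """Exact-test calibration on null NB data.

    Returns the mean fraction of genes flagged at BH-FDR < ``fdr_cutoff``
    (should not exceed the nominal level) and the mean empirical CDF of the
    p-values at 0.05 (super-uniformity check).
    """
    fracs, ecdfs = [], []
    for i in range(n_seeds):
        cm = generate_null(params, base_seed + i).drop_unexpressed()
        factors = de_mod.tmm_factors(cm)
        disp = de_mod.estimate_common_dispersion(cm, factors, tagwise=True)
        p = de_mod.nb_exact_test(cm, factors, disp).to_numpy()
        fdr = de_mod.bh_adjust(p)
        fracs.append(float((fdr < fdr_cutoff).mean()))
        ecdfs.append(float((p <= 0.05).mean()))
    return {
        "mean_de_fraction": float(np.mean(fracs)),
        "mean_ecdf_at_005": float(np.mean(ecdfs)),
        "n_genes": params.n_genes,
        "n_seeds": n_seeds,
    }


def dispersion_recovery(
    n_runs: int = 50,
    params: SynthParams = NULL_PARAMS,
    band: tuple[float, float] = (0.3, 0.5),
    base_seed: int = 0,
) -> dict[str, float]:
    """Fraction of runs whose common-dispersion estimate falls in ``band``."""
    alphas = []
    for i in range(n_runs):
        cm = generate_null(params, base_seed + i).drop_unexpressed()
        factors = de_mod.tmm_factors(cm)
        est = de_mod.estimate_common_dispersion(cm, factors, tagwise=False)
        alphas.append(est.alpha_common)
    alphas = np.asarray(alphas)
    return {
        "fraction_in_band": float(((alphas >= band[0]) & (alphas <= band[1])).mean()),
        "mean_alpha": float(alphas.mean()),
        "n_runs": n_runs,
    }


def planted_recovery(
    n_seeds: int = 100,
    *,
    n_genes: int = 400,
    n_targets: int = 20,
    rho: float = 0.9,
    n_regulators: int = 51,
    rank_cutoff: int = 3,
    base_seed: int = 0,
    metrics: tuple[str, ...] = ("pearson", "spearman", "fisher", "sobolev"),
) -> dict[str, dict[str, float]]:
    """Recovery of one planted wired regulator among decoys, per measure.

    Each seed builds a wired fixture (1 wired regulator with ``n_targets``
    planted DE targets, ``n_regulators - 1`` decoys), runs the full pipeline
    and records whether the planted regulator reaches RIF rank <=
    ``rank_cutoff`` (best of the RIF1/RIF2 rankings, matching the method's
    top-by-either-score selection) and whether it enters the final network
    node set.
    """
    params = replace(WIRED_PARAMS, n_genes=n_genes)
    hits = {m: [] for m in metrics}
    in_net = {m: [] for m in metrics}
    for i in range(n_seeds):
        truth, catalog = make_default_truth(
            params,
            seed=base_seed + i,
            n_de=n_targets,
            n_targets=n_targets,
            n_wired=1,
            rho=rho,
            n_regulators=n_regulators,
        )
        cm, truth = generate_wired(params, truth)
        res = RIFAnalysis(cm, catalog, metrics=metrics, dispersion="common").fit()
        wired_reg = next(iter(truth.wired))
        for m in metrics:
            row = res.rif_tables[m].frame.set_index("regulator").loc[wired_reg]
            hits[m].append(min(int(row["rank1"]), int(row["rank2"])) <= rank_cutoff)
            in_net[m].append(wired_reg in res.networks[m].node_set)
    return {
        m: {
            "rank_recovery_rate": float(np.mean(hits[m])),
            "network_recovery_rate": float(np.mean(in_net[m])),
            "n_seeds": n_seeds,
        }
        for m in metrics
    }


def chain_elimination() -> dict[str, bool]:
    """The exact 3-node chain fixture: indirect edge out, direct edges kept."""
    corr = np.array([[1.0, 0.81, 0.9], [0.81, 1.0, 0.9], [0.9, 0.9, 1.0]])
    survived = pcit_filter(corr)
    return {
        "indirect_edge_eliminated": bool(~survived[0, 1]),
        "direct_edges_survive": bool(survived[0, 2] and survived[1, 2]),
    }


def mediation_elimination(
    n_seeds: int = 100,
    n_samples: int = 40,
    strength: float = 0.9,
    base_seed: int = 0,
) -> dict[str, float]:
    """Fraction of runs in which PCIT eliminates a purely mediated edge.

    x and y each load on a shared mediator z with the given strength and
    are conditionally independent given z.
    """
    eliminated = 0
    noise = np.sqrt(1.0 - strength**2)
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        z = rng.standard_normal(n_samples)
        x = strength * z + noise * rng.standard_normal(n_samples)
        y = strength * z + noise * rng.standard_normal(n_samples)
        survived = pcit_filter(np.corrcoef(np.vstack([x, y, z])))
        eliminated += int(not survived[0, 1])
    return {"elimination_rate": eliminated / n_seeds, "n_seeds": n_seeds}
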
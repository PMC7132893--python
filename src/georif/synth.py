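"""Synthetic paired two-condition count fixtures with known ground truth.

Counts are gamma-Poisson (negative binomial): a gene with latent mean ``mu``
and dispersion ``alpha`` is drawn as ``Poisson(Gamma(1/alpha, mu*alpha))``
so its marginal variance follows ``v = mu + alpha*mu^2``.  The *wired*
preset plants two kinds of signal:

* differential expression — selected genes have their condition-1 mean
  multiplied by a fold change;
* differential wiring — each wired regulator shares a per-sample latent
  Gaussian factor with its target genes in condition 1 only, with weight
  ``rho``, so the regulator-target co-expression is ~rho in condition 1 and
  ~0 in condition 2.  Wiring lives on the latent log-mean, which makes the
  induced correlation controllable and visible to any association measure.

Biological sample-to-sample variability is carried by a log-normal latent
layer of standard deviation ``tau`` (natural-log scale); the NB ``alpha`` of
the wired preset is therefore a small residual (technical) dispersion.
All draws are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, RegulatorCatalog

CONDITION_1 = "tumor"
CONDITION_2 = "normal"


@dataclass(frozen=True)
class SynthParams:
    """Size and noise parameters of a synthetic fixture."""

    n_genes: int = 2000
    n_samples_per_condition: int = 20
    alpha: float = 0.1  # NB dispersion
    mean_range: tuple[float, float] = (1.0, 1000.0)  # log-uniform baseline means
    tau: float = 0.0  # latent log-normal sd (natural log); 0 = pure NB

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_condition < 2:
            raise ValueError("need >= 1 gene and >= 2 samples per condition")
        if self.alpha < 0 or self.tau < 0:
            raise ValueError("alpha and tau must be >= 0")
        lo, hi = self.mean_range
        if not 0 < lo <= hi:
            raise ValueError("mean_range must be positive and ordered")


#: Conditions of the wired preset: expressed-gene fixture (baseline means in
#: the well-measured range) whose biological variability lives on the latent
#: log-normal layer, with a small residual NB dispersion.  At these noise
#: levels the planted latent wiring of strength rho is realized as a
#: regulator-target count correlation close to rho, as the construction
#: intends (count-noise attenuation stays small).
WIRED_PARAMS = SynthParams(
    n_genes=2000,
    n_samples_per_condition=20,
    alpha=0.02,
    mean_range=(50.0, 1000.0),
    tau=1.0,
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted signal of a wired fixture.

    ``de_genes`` maps gene id -> condition-1 fold change; ``wired`` maps
    regulator id -> (targets, rho).  Targets must be planted DE genes.
    """

    de_genes: dict[str, float] = field(default_factory=dict)
    wired: dict[str, tuple[tuple[str, ...], float]] = field(default_factory=dict)
    seed: int = 0
    params: SynthParams = field(default_factory=SynthParams)

    def __post_init__(self) -> None:
        for reg, (targets, rho) in self.wired.items():
            if not 0 <= rho <= 1:
                raise ValueError(f"wiring strength rho={rho} outside [0, 1]")
            missing = [t for t in targets if t not in self.de_genes]
            if missing:
                raise ValueError(f"targets of {reg} not in de_genes: {missing}")


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _sample_frame(n_per: int) -> tuple[list[str], dict[str, str], dict[str, str]]:
    t = [f"T{i:03d}" for i in range(n_per)]
    c = [f"N{i:03d}" for i in range(n_per)]
    condition_of = {**{s: CONDITION_1 for s in t}, **{s: CONDITION_2 for s in c}}
    pair_of = {**{s: f"D{i:03d}" for i, s in enumerate(t)},
               **{s: f"D{i:03d}" for i, s in enumerate(c)}}
    return t + c, condition_of, pair_of


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def generate_null(params: SynthParams, seed: int) -> CountMatrix:
    """Two-condition NB counts with the same law in both conditions.

    Baseline means are log-uniform over ``params.mean_range``; no DE and no
    wiring is planted.  With ``tau > 0`` a per-gene-per-sample log-normal
    latent layer is added (extra overdispersion beyond ``alpha``).
    """
    rng = np.random.default_rng(seed)
    n = params.n_genes
    samples, condition_of, pair_of = _sample_frame(params.n_samples_per_condition)
    lo, hi = params.mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    mean = np.broadcast_to(mu[:, None], (n, len(samples))).copy()
    if params.tau > 0:
        eps = rng.standard_normal((n, len(samples)))
        mean = mean * np.exp(params.tau * eps - params.tau**2 / 2.0)
    counts = _nb_draw(rng, mean, params.alpha)
    return CountMatrix(
        pd.DataFrame(counts, index=_ids("g", n), columns=samples),
        condition_of,
        (CONDITION_1, CONDITION_2),
        pair_of,
    )


def catalog_plan(n_regulators: int) -> dict[str, int]:
    """Regulator class sizes that tile ``n_regulators`` exactly.

    Proportions follow the default fixture: ~30% EF, ~10% lncRNA, with ~10%
    of the catalog carrying both TF and EF labels; TFs fill the remainder
    (70 TF / 30 EF / 10 dual / 10 lncRNA at the default 100 regulators).
    """
    n_ef = max(1, round(0.3 * n_regulators))
    n_overlap = min(n_ef, max(1, round(0.1 * n_regulators)))
    n_lnc = max(1, round(0.1 * n_regulators))
    n_tf = n_regulators - n_lnc - (n_ef - n_overlap)
    if n_tf < n_overlap:
        raise ValueError(f"too few regulators ({n_regulators}) for the class plan")
    return {"TF": n_tf, "EF": n_ef, "TF_EF_overlap": n_overlap, "lncRNA": n_lnc}


def make_default_truth(
    params: SynthParams = WIRED_PARAMS,
    seed: int = 0,
    *,
    n_de: int = 100,
    fold_change: float = 4.0,
    n_wired: int = 1,
    n_targets: int = 20,
    rho: float = 0.9,
    n_regulators: int = 100,
) -> tuple[SyntheticTruth, RegulatorCatalog]:
    """Draw a planted-truth plan and a matching regulator catalog.

    Regulators (wired + decoys) are drawn disjoint from the DE genes so the
    wiring targets are well defined; the catalog classes follow
    :func:`default_catalog_plan` proportions (overlapping TF/EF sets).
    """
    rng = np.random.default_rng(seed)
    genes = _ids("g", params.n_genes)
    if n_de + n_regulators > params.n_genes:
        raise ValueError("fixture too small for the requested DE genes and regulators")
    chosen = rng.choice(params.n_genes, size=n_de + n_regulators, replace=False)
    de_ids = [genes[i] for i in chosen[:n_de]]
    reg_ids = sorted(genes[i] for i in chosen[n_de:])
    de_genes = {g: fold_change for g in de_ids}
    wired: dict[str, tuple[tuple[str, ...], float]] = {}
    for w in range(n_wired):
        targets = tuple(
            de_ids[i]
            for i in rng.choice(n_de, size=min(n_targets, n_de), replace=False)
        )
        wired[reg_ids[w]] = (targets, rho)
    plan = catalog_plan(len(reg_ids))
    classes: dict[str, set[str]] = {g: set() for g in reg_ids}
    n_tf, n_ef, n_overlap = plan["TF"], plan["EF"], plan["TF_EF_overlap"]
    for g in reg_ids[:n_tf]:
        classes[g].add("TF")
    for g in reg_ids[n_tf - n_overlap : n_tf - n_overlap + n_ef]:
        classes[g].add("EF")
    for g in reg_ids[n_tf - n_overlap + n_ef :]:
        classes[g].add("lncRNA")
    catalog = RegulatorCatalog({g: frozenset(c) for g, c in classes.items()})
    truth = SyntheticTruth(de_genes, wired, seed, params)
    return truth, catalog


def generate_wired(
    params: SynthParams, truth: SyntheticTruth
) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate counts with the planted DE and wiring of ``truth``.

    Condition-1 means of planted DE genes are multiplied by their fold
    change.  Each wired regulator follows a per-sample latent factor in all
    samples; its targets mix that factor with weight ``rho`` in condition 1
    only.  With ``rho = 0`` this reduces to :func:`generate_null` plus the
    fold changes.
    """
    params = replace(params, tau=params.tau if params.tau > 0 else WIRED_PARAMS.tau)
    rng = np.random.default_rng(truth.seed)
    n = params.n_genes
    genes = _ids("g", n)
    gene_idx = {g: i for i, g in enumerate(genes)}
    samples, condition_of, pair_of = _sample_frame(params.n_samples_per_condition)
    n_s = len(samples)
    n1 = params.n_samples_per_condition
    lo, hi = params.mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    base = np.broadcast_to(mu[:, None], (n, n_s)).copy()
    for g, fc in truth.de_genes.items():
        base[gene_idx[g], :n1] *= fc
    # latent Gaussian layer: factors drive wired regulators and their targets
    eps = rng.standard_normal((n, n_s))
    for reg, (targets, rho) in truth.wired.items():
        f = rng.standard_normal(n_s)
        eps[gene_idx[reg]] = f
        for t in targets:
            i = gene_idx[t]
            eps[i, :n1] = rho * f[:n1] + np.sqrt(1.0 - rho**2) * eps[i, :n1]
    mean = base * np.exp(params.tau * eps - params.tau**2 / 2.0)
    counts = _nb_draw(rng, mean, params.alpha)
    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        condition_of,
        (CONDITION_1, CONDITION_2),
        pair_of,
    )
    return cm, replace(truth, params=params)


# ---------------------------------------------------------------------------
# Truth sidecar serialization
# ---------------------------------------------------------------------------


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write the planted truth as a sidecar TSV (round-trips via read_truth)."""
    rows: list[tuple[str, str, str, str]] = []
    p = truth.params
    rows.append(("param", "seed", repr(truth.seed), ""))
    rows.append(("param", "n_genes", repr(p.n_genes), ""))
    rows.append(("param", "n_samples_per_condition", repr(p.n_samples_per_condition), ""))
    rows.append(("param", "alpha", repr(p.alpha), ""))
    rows.append(("param", "mean_lo", repr(p.mean_range[0]), ""))
    rows.append(("param", "mean_hi", repr(p.mean_range[1]), ""))
    rows.append(("param", "tau", repr(p.tau), ""))
    for g, fc in truth.de_genes.items():
        rows.append(("de", g, repr(fc), ""))
    for reg, (targets, rho) in truth.wired.items():
        for t in targets:
            rows.append(("wired", reg, t, repr(rho)))
    pd.DataFrame(rows, columns=["record", "key", "value", "extra"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path: str | Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    params_raw = {r["key"]: r["value"] for _, r in df[df["record"] == "param"].iterrows()}
    params = SynthParams(
        n_genes=int(params_raw["n_genes"]),
        n_samples_per_condition=int(params_raw["n_samples_per_condition"]),
        alpha=float(params_raw["alpha"]),
        mean_range=(float(params_raw["mean_lo"]), float(params_raw["mean_hi"])),
        tau=float(params_raw["tau"]),
    )
    de_genes = {
        r["key"]: float(r["value"]) for _, r in df[df["record"] == "de"].iterrows()
    }
    wired: dict[str, tuple[tuple[str, ...], float]] = {}
    grouped: dict[str, tuple[list[str], float]] = {}
    for _, r in df[df["record"] == "wired"].iterrows():
        grouped.setdefault(r["key"], ([], float(r["extra"])))[0].append(r["value"])
    for reg, (targets, rho) in grouped.items():
        wired[reg] = (tuple(targets), rho)
    return SyntheticTruth(de_genes, wired, int(params_raw["seed"]), params)
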
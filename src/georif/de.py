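"""Normalization and differential expression for two-condition count data.

The model is the standard negative-binomial one for RNA-seq counts: the
variance of a gene with mean ``mu`` is ``v = mu + alpha * mu**2`` with
overdispersion ``alpha >= 0`` (``alpha == 0`` is Poisson).  Sequencing-depth
differences are removed with trimmed-mean-of-M-values (TMM) factors, the
dispersion is estimated by maximizing the conditional negative-binomial
log-likelihood on counts equalized to a common effective library size, and
differential expression is assessed with an exact conditional test on the
per-condition totals, followed by Benjamini-Hochberg FDR control.

The test is unpaired; donor/pair labels on the samples are carried through
but not exploited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .exceptions import DesignError
from .io import CountMatrix

logger = logging.getLogger(__name__)

ALPHA_MIN = 1e-6
ALPHA_MAX = 10.0


@dataclass(frozen=True)
class NormalizedMatrix:
    """log2 counts-per-million with the factors that produced them."""

    log_expr: pd.DataFrame  # genes x samples, log2 CPM
    norm_factors: pd.Series  # per sample, geometric mean 1
    lib_sizes: pd.Series  # per sample raw totals

    def __post_init__(self) -> None:
        lf = np.log(self.norm_factors.to_numpy(dtype=float))
        if abs(lf.mean()) > 1e-9:
            raise ValueError("norm_factors must have geometric mean 1")
        if not np.isfinite(self.log_expr.to_numpy()).all():
            raise ValueError("log expression must be finite")

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.norm_factors


@dataclass(frozen=True)
class DispersionEstimate:
    """Common and (optionally shrunken) per-gene NB dispersions."""

    alpha_common: float
    alpha_tagwise: pd.Series | None = None

    def per_gene(self, gene_ids: list[str]) -> np.ndarray:
        if self.alpha_tagwise is None:
            return np.full(len(gene_ids), self.alpha_common)
        return self.alpha_tagwise.reindex(gene_ids).fillna(self.alpha_common).to_numpy()


@dataclass(frozen=True)
class DEResult:
    """Per-gene DE summary on the log2-CPM scale.

    ``e1``/``e2`` are the mean log2 CPM in conditions 1 and 2 and feed the
    PIF and RIF2 scores downstream; ``is_de`` is ``fdr < fdr_cutoff``
    (strict).
    """

    table: pd.DataFrame  # gene, e1, e2, logFC, pvalue, fdr, is_de
    fdr_cutoff: float

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene"])

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.loc[self.table["is_de"], "gene"])

    @property
    def n_de(self) -> int:
        return int(self.table["is_de"].sum())


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference sample."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        logger.warning("no genes shared with the reference sample; factor set to 1")
        return 1.0
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # inverse asymptotic variance of M (delta method for binomial counts)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    inv_w = 1.0 / w[keep2]
    return float(2.0 ** (np.sum(inv_w * m[keep2]) / np.sum(inv_w)))


def tmm_factors(
    m: CountMatrix,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    Per sample, the factor is the weighted mean of log2 expression ratios
    against a reference sample, after trimming ``trim_m`` of the M-values
    and ``trim_a`` of the A-values from each tail; weights are the inverse
    asymptotic variances of M.  Factors are rescaled to geometric mean 1.
    """
    counts = m.counts.to_numpy(dtype=float)
    libs = counts.sum(axis=0)
    if (libs == 0).any():
        bad = [s for s, l in zip(m.sample_ids, libs) if l == 0]
        raise DesignError(f"all-zero sample(s): {bad}")
    if ref_sample is None:
        # sample whose upper-quartile expression fraction is closest to the mean
        q75 = np.quantile(counts / libs, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        if ref_sample not in m.sample_ids:
            raise DesignError(f"reference sample {ref_sample!r} not in matrix")
        ref_idx = m.sample_ids.index(ref_sample)
    ref = counts[:, ref_idx]
    factors = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_pair(counts[:, j], ref, libs[j], libs[ref_idx], trim_m, trim_a)
            for j in range(counts.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.sample_ids, name="tmm_factor")


def log_cpm(m: CountMatrix, factors: pd.Series, pseudocount: float = 0.5) -> NormalizedMatrix:
    """log2 counts-per-million on effective (TMM-scaled) library sizes."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    f = factors.reindex(m.sample_ids).to_numpy(dtype=float)
    if (f <= 0).any():
        raise ValueError("normalization factors must be positive")
    libs = m.lib_sizes.to_numpy(dtype=float)
    counts = m.counts.to_numpy(dtype=float)
    expr = np.log2((counts + pseudocount) / (libs * f) * 1e6)
    return NormalizedMatrix(
        pd.DataFrame(expr, index=m.gene_ids, columns=m.sample_ids),
        pd.Series(f / np.exp(np.mean(np.log(f))), index=m.sample_ids),
        m.lib_sizes,
    )


# ---------------------------------------------------------------------------
# Dispersion estimation (conditional likelihood on equalized counts)
# ---------------------------------------------------------------------------


def equalized_counts(m: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Counts rescaled to a common effective library size, rounded half-to-even."""
    eff = (m.lib_sizes * factors.reindex(m.sample_ids)).to_numpy(dtype=float)
    common = np.exp(np.mean(np.log(eff)))
    scaled = m.counts.to_numpy(dtype=float) * (common / eff)
    return pd.DataFrame(np.round(scaled), index=m.gene_ids, columns=m.sample_ids)


def _cond_loglik(y: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB conditional log-likelihood of one group given its total.

    ``y`` is genes x samples (equal effective library sizes assumed),
    ``alpha`` a per-gene dispersion vector; terms not involving alpha are
    dropped.
    """
    n = y.shape[1]
    r = 1.0 / alpha
    z = y.sum(axis=1)
    return (
        gammaln(y + r[:, None]).sum(axis=1)
        + gammaln(n * r)
        - gammaln(z + n * r)
        - n * gammaln(r)
    )


def _group_arrays(pseudo: pd.DataFrame, m: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    s1 = m.samples_of(m.conditions[0])
    s2 = m.samples_of(m.conditions[1])
    return pseudo[s1].to_numpy(dtype=float), pseudo[s2].to_numpy(dtype=float)


def _per_gene_mle(y1: np.ndarray, y2: np.ndarray, iters: int = 80) -> np.ndarray:
    """Vectorized golden-section maximization of the per-gene conditional
    log-likelihood over alpha in [ALPHA_MIN, ALPHA_MAX] (log scale)."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    n_genes = y1.shape[0]
    lo = np.full(n_genes, np.log(ALPHA_MIN))
    hi = np.full(n_genes, np.log(ALPHA_MAX))

    def f(log_alpha: np.ndarray) -> np.ndarray:
        a = np.exp(log_alpha)
        return _cond_loglik(y1, a) + _cond_loglik(y2, a)

    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        left = fc >= fd  # maximize
        hi = np.where(left, d, hi)
        lo = np.where(left, lo, c)
        c = hi - invphi * (hi - lo)
        d = lo + invphi * (hi - lo)
        fc, fd = f(c), f(d)
    return np.exp((lo + hi) / 2.0)


def estimate_common_dispersion(
    m: CountMatrix,
    factors: pd.Series,
    tagwise: bool = True,
    prior_weight: float = 10.0,
) -> DispersionEstimate:
    """Estimate the NB dispersion by conditional maximum likelihood.

    The common dispersion maximizes the conditional log-likelihood summed
    over all genes, on counts rescaled to a common effective library size.
    Per-gene estimates, if requested, are shrunk toward the common value
    with a fixed prior weight of ``prior_weight`` pseudo-genes:
    ``alpha_g = (w*alpha_common + n_g*alpha_hat_g) / (w + n_g)`` with
    ``n_g`` the number of samples.
    """
    for cond in m.conditions:
        if len(m.samples_of(cond)) < 2:
            raise DesignError(f"condition {cond!r} needs >= 2 samples")
    pseudo = equalized_counts(m, factors)
    y1, y2 = _group_arrays(pseudo, m)

    def neg_ll(alpha: float) -> float:
        a = np.full(y1.shape[0], alpha)
        return -float(np.sum(_cond_loglik(y1, a) + _cond_loglik(y2, a)))

    res = minimize_scalar(
        neg_ll, bounds=(ALPHA_MIN, ALPHA_MAX), method="bounded",
        options={"xatol": 1e-6},
    )
    alpha_common = float(res.x)
    if not tagwise:
        return DispersionEstimate(alpha_common)
    alpha_hat = _per_gene_mle(y1, y2)
    totals = y1.sum(axis=1) + y2.sum(axis=1)
    alpha_hat = np.where(totals > 0, alpha_hat, alpha_common)
    n_g = m.n_samples
    alpha_tag = (prior_weight * alpha_common + n_g * alpha_hat) / (prior_weight + n_g)
    return DispersionEstimate(alpha_common, pd.Series(alpha_tag, index=m.gene_ids))


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------


def _exact_p(s1: int, s2: int, n1: int, n2: int, alpha: float) -> float:
    """Two-sided conditional exact p-value for a split (s1, s2) of a total.

    The group total of ``n_k`` samples is modelled NB with mean ``n_k*mu``
    and dispersion ``alpha/n_k`` under equal means; the p-value sums the
    conditional probabilities of all splits no more probable than the
    observed one (exact ties included), capped at 1.
    """
    total = s1 + s2
    if total == 0:
        return 1.0
    mu = total / (n1 + n2)
    x = np.arange(total + 1, dtype=float)
    if alpha < 1e-10:
        # Poisson limit: conditional law is Binomial(total, n1/(n1+n2))
        m1, m2 = n1 * mu, n2 * mu
        lp = x * np.log(m1) - gammaln(x + 1) + (total - x) * np.log(m2) - gammaln(total - x + 1)
    else:
        r1, r2 = n1 / alpha, n2 / alpha
        m1, m2 = n1 * mu, n2 * mu
        lp1 = gammaln(x + r1) - gammaln(x + 1) + x * np.log(m1 / (r1 + m1))
        lp2 = (
            gammaln(total - x + r2)
            - gammaln(total - x + 1)
            + (total - x) * np.log(m2 / (r2 + m2))
        )
        lp = lp1 + lp2
    lp -= logsumexp(lp)
    p = np.exp(lp)
    include = p <= p[s1] * (1.0 + 1e-12)
    if include.all():
        return 1.0  # observed split is modal: every outcome counts
    return float(min(1.0, p[include].sum()))


def nb_exact_test(
    m: CountMatrix, factors: pd.Series, disp: DispersionEstimate
) -> pd.Series:
    """Per-gene two-sided exact-test p-values for a difference between conditions."""
    pseudo = equalized_counts(m, factors)
    y1, y2 = _group_arrays(pseudo, m)
    n1, n2 = y1.shape[1], y2.shape[1]
    s1 = np.round(y1.sum(axis=1)).astype(np.int64)
    s2 = np.round(y2.sum(axis=1)).astype(np.int64)
    alphas = disp.per_gene(m.gene_ids)
    pvals = np.array(
        [_exact_p(int(a), int(b), n1, n2, float(al)) for a, b, al in zip(s1, s2, alphas)]
    )
    return pd.Series(pvals, index=m.gene_ids, name="pvalue")


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de(
    m: CountMatrix,
    factors: pd.Series,
    pvals: pd.Series,
    fdr_cutoff: float = 0.05,
    pseudocount: float = 0.5,
    nm: NormalizedMatrix | None = None,
) -> DEResult:
    """Assemble the DE table: per-condition mean log2 CPM, logFC, p, FDR, flag."""
    if not 0 < fdr_cutoff < 1:
        raise ValueError("fdr_cutoff must be in (0, 1)")
    if nm is None:
        nm = log_cpm(m, factors, pseudocount)
    s1 = m.samples_of(m.conditions[0])
    s2 = m.samples_of(m.conditions[1])
    e1 = nm.log_expr[s1].mean(axis=1)
    e2 = nm.log_expr[s2].mean(axis=1)
    p = pvals.reindex(m.gene_ids).to_numpy(dtype=float)
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {
            "gene": m.gene_ids,
            "e1": e1.to_numpy(),
            "e2": e2.to_numpy(),
            "logFC": (e1 - e2).to_numpy(),
            "pvalue": p,
            "fdr": fdr,
            "is_de": fdr < fdr_cutoff,
        }
    )
    return DEResult(table, fdr_cutoff)


def de_result_from_list(
    m: CountMatrix,
    factors: pd.Series,
    de_genes: list[str],
    fdr_cutoff: float = 0.05,
    pseudocount: float = 0.5,
    nm: NormalizedMatrix | None = None,
) -> DEResult:
    """Build a DEResult from a precomputed DE gene list (bypasses the test).

    Expression means are still computed (PIF and RIF2 need them); p-values
    and FDR are set to NaN.
    """
    if nm is None:
        nm = log_cpm(m, factors, pseudocount)
    s1 = m.samples_of(m.conditions[0])
    s2 = m.samples_of(m.conditions[1])
    e1 = nm.log_expr[s1].mean(axis=1)
    e2 = nm.log_expr[s2].mean(axis=1)
    de_set = set(de_genes)
    unknown = de_set - set(m.gene_ids)
    if unknown:
        logger.warning("%d DE genes not in the count matrix are ignored", len(unknown))
    table = pd.DataFrame(
        {
            "gene": m.gene_ids,
            "e1": e1.to_numpy(),
            "e2": e2.to_numpy(),
            "logFC": (e1 - e2).to_numpy(),
            "pvalue": np.nan,
            "fdr": np.nan,
            "is_de": [g in de_set for g in m.gene_ids],
        }
    )
    return DEResult(table, fdr_cutoff)
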
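"""Co-expression association measures: Pearson, Spearman, Fisher, Sobolev.

The two statistical measures are ordinary sample correlations on log2-CPM
profiles.  The two geometric measures treat each profile as a point on the
probability simplex (after a shift-and-normalize embedding) and measure a
distance there:

* the Fisher information metric is the geodesic distance on the simplex,
  ``d = arccos(sum_i sqrt(p_i q_i))`` (range ``[0, pi/2]``; the factor-2
  convention would only rescale d and cancels in the association mapping);
* the Sobolev metric of order k combines the difference of the two points
  with its circular finite differences,
  ``d^2 = sum_{m=0..k} ||Delta^m (p - q)||^2``, where ``Delta`` is the
  circular first difference.  With the circular boundary the finite-
  difference form is exactly Parseval-equivalent to its spectral form.

Distances are mapped to associations in [0, 1] by ``a = 1 - d/d_max``
(``d_max = pi/2`` for Fisher; for Sobolev the maximum distance observed over
all regulator-gene pairs in both conditions, recorded for reproducibility).

The Sobolev metric depends on sample order (the "derivative" runs along the
sample axis).  The input sample order of the count matrix is used,
identically in both conditions; reordering samples changes Sobolev
distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .de import DEResult, NormalizedMatrix
from .io import RegulatorCatalog

logger = logging.getLogger(__name__)

METRICS = ("pearson", "spearman", "fisher", "sobolev")
STATISTICAL_METRICS = ("pearson", "spearman")
GEOMETRIC_METRICS = ("fisher", "sobolev")

FISHER_DMAX = np.pi / 2.0


@dataclass(frozen=True)
class AssociationSet:
    """Per-condition regulator x DE-gene association matrices for one measure.

    ``r1``/``r2`` hold the associations in conditions 1 and 2 (same shape,
    regulators as rows).  Statistical measures give values in [-1, 1];
    geometric measures give values in [0, 1] unless signed.  ``d_max`` is
    the distance normalizer actually used (NaN for statistical measures).
    """

    metric: str
    r1: pd.DataFrame
    r2: pd.DataFrame
    d_max: float = float("nan")

    def __post_init__(self) -> None:
        if self.r1.shape != self.r2.shape:
            raise ValueError("r1 and r2 must have the same shape")

    @property
    def regulators(self) -> list[str]:
        return list(self.r1.index)

    @property
    def de_genes(self) -> list[str]:
        return list(self.r1.columns)


# ---------------------------------------------------------------------------
# Simplex embedding and geometric distances
# ---------------------------------------------------------------------------


def to_simplex(x: np.ndarray) -> np.ndarray:
    """Embed a real profile on the probability simplex.

    Shift by ``-min(x) + delta`` with ``delta = 1e-8 * range`` (or 1e-8 for a
    constant profile, which maps to the uniform point), then normalize to
    unit sum.
    """
    x = np.asarray(x, dtype=float)
    rng = float(x.max() - x.min())
    delta = 1e-8 * rng if rng > 0 else 1e-8
    y = x - x.min() + delta
    return y / y.sum()


def _simplex_rows(profiles: np.ndarray) -> np.ndarray:
    rng = profiles.max(axis=1) - profiles.min(axis=1)
    delta = np.where(rng > 0, 1e-8 * rng, 1e-8)
    y = profiles - profiles.min(axis=1, keepdims=True) + delta[:, None]
    return y / y.sum(axis=1, keepdims=True)


def fisher_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Fisher information (geodesic) distance on the simplex, in [0, pi/2].

    ``arccos`` of the Bhattacharyya coefficient, evaluated in the equivalent
    half-angle form ``2*arcsin(||sqrt(p) - sqrt(q)|| / 2)`` (the argument is
    clipped to [0, 1]), which is exact at coinciding points where the arccos
    form loses half the floating-point digits.
    """
    p, q = np.asarray(p, dtype=float), np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("simplex points must have the same length")
    h = float(np.linalg.norm(np.sqrt(p) - np.sqrt(q)))
    return float(2.0 * np.arcsin(np.clip(h / 2.0, 0.0, 1.0)))


def _sobolev_features(rows: np.ndarray, order_k: int) -> np.ndarray:
    """Stack [x, Delta x, ..., Delta^k x] so that pairwise Euclidean distance
    of features equals the order-k Sobolev distance of the rows."""
    feats = [rows]
    cur = rows
    for _ in range(order_k):
        cur = np.roll(cur, -1, axis=1) - cur
        feats.append(cur)
    return np.concatenate(feats, axis=1)


def sobolev_distance(p: np.ndarray, q: np.ndarray, order_k: int = 1) -> float:
    """Sobolev distance of order ``order_k`` with circular finite differences.

    ``order_k = 0`` is the Euclidean norm of ``p - q``; each further order
    adds the squared norm of the next circular difference of ``p - q``.
    """
    if order_k < 0:
        raise ValueError("order_k must be >= 0")
    p, q = np.asarray(p, dtype=float), np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("simplex points must have the same length")
    w = p - q
    total = float(np.sum(w * w))
    cur = w
    for _ in range(order_k):
        cur = np.roll(cur, -1) - cur
        total += float(np.sum(cur * cur))
    return float(np.sqrt(total))


def distance_to_association(d: float, metric: str, d_max: float) -> float:
    """Map a distance to an association ``a = 1 - d/d_max`` in [0, 1]."""
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if d > d_max + 1e-9:
        raise ValueError(f"distance {d} exceeds d_max {d_max} for metric {metric}")
    return 1.0 - d / d_max


# ---------------------------------------------------------------------------
# Statistical correlations
# ---------------------------------------------------------------------------


def statistical_correlation(x: np.ndarray, y: np.ndarray, which: str = "pearson") -> float:
    """Sample Pearson correlation, or Spearman (Pearson on mid-ranks).

    A zero-variance profile has no defined correlation; it is reported as 0
    with a logged warning rather than NaN.
    """
    if which not in STATISTICAL_METRICS:
        raise ValueError(f"unknown statistical metric {which!r}")
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have the same length")
    if which == "spearman":
        x, y = rankdata(x), rankdata(y)
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt(np.sum(xc * xc)), np.sqrt(np.sum(yc * yc))
    if sx == 0 or sy == 0:
        logger.warning("zero-variance profile; correlation defined as 0")
        return 0.0
    return float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))


def _corr_matrix(x: np.ndarray, y: np.ndarray, which: str) -> np.ndarray:
    """Row-wise correlation matrix between the rows of x and the rows of y."""
    if which == "spearman":
        x = np.apply_along_axis(rankdata, 1, x)
        y = np.apply_along_axis(rankdata, 1, y)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt(np.sum(xc * xc, axis=1))
    sy = np.sqrt(np.sum(yc * yc, axis=1))
    zx, zy = sx == 0, sy == 0
    if zx.any() or zy.any():
        logger.warning(
            "%d zero-variance profiles; their correlations defined as 0",
            int(zx.sum() + zy.sum()),
        )
    sx = np.where(zx, 1.0, sx)
    sy = np.where(zy, 1.0, sy)
    r = (xc / sx[:, None]) @ (yc / sy[:, None]).T
    r[zx, :] = 0.0
    r[:, zy] = 0.0
    return np.clip(r, -1.0, 1.0)


def _geometric_distance_matrix(
    x: np.ndarray, y: np.ndarray, metric: str, order_k: int
) -> np.ndarray:
    """Pairwise Fisher or Sobolev distances between profile rows."""
    px, py = _simplex_rows(x), _simplex_rows(y)
    if metric == "fisher":
        sx, sy = np.sqrt(px), np.sqrt(py)
        sq = (
            np.sum(sx * sx, axis=1)[:, None]
            + np.sum(sy * sy, axis=1)[None, :]
            - 2.0 * sx @ sy.T
        )
        h = np.sqrt(np.maximum(sq, 0.0))
        return 2.0 * np.arcsin(np.clip(h / 2.0, 0.0, 1.0))
    fx = _sobolev_features(px, order_k)
    fy = _sobolev_features(py, order_k)
    sq = (
        np.sum(fx * fx, axis=1)[:, None]
        + np.sum(fy * fy, axis=1)[None, :]
        - 2.0 * fx @ fy.T
    )
    return np.sqrt(np.maximum(sq, 0.0))


# ---------------------------------------------------------------------------
# Association matrices
# ---------------------------------------------------------------------------


def pairwise_association(
    profiles: pd.DataFrame,
    metric: str,
    sobolev_order: int = 1,
    d_max: float | None = None,
) -> pd.DataFrame:
    """Square association matrix among the rows of ``profiles`` (one measure).

    Used for regulator-regulator correlations when PCIT is run on the same
    measure as the RIF stage.  For Sobolev, ``d_max`` defaults to the
    maximum observed distance.
    """
    x = profiles.to_numpy(dtype=float)
    if metric in STATISTICAL_METRICS:
        r = _corr_matrix(x, x, metric)
        np.fill_diagonal(r, 1.0)
    else:
        d = _geometric_distance_matrix(x, x, metric, sobolev_order)
        if metric == "fisher":
            dmax = FISHER_DMAX
        else:
            dmax = d_max if d_max is not None else float(d.max())
            if dmax <= 0:
                dmax = 1.0
        r = 1.0 - d / dmax
        np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=profiles.index, columns=profiles.index)


def association_matrices(
    nm: NormalizedMatrix,
    de: DEResult,
    cat: RegulatorCatalog,
    metric: str,
    *,
    conditions_samples: tuple[list[str], list[str]],
    sobolev_order: int = 1,
    signed_geometric: bool = False,
) -> AssociationSet:
    """Per-condition regulator x DE-gene association matrices.

    Profiles are log2-CPM rows of ``nm`` restricted to each condition's
    samples (count-matrix order).  Geometric measures route through the
    simplex embedding and distance, sharing a single ``d_max`` across both
    conditions.  Regulators absent from the matrix are dropped with a
    warning; regulators that are themselves DE stay on the regulator axis.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    de_genes = de.de_genes
    if not de_genes:
        raise ValueError("empty DE set")
    present = set(nm.log_expr.index)
    regulators = [g for g in nm.log_expr.index if g in cat]
    dropped = [g for g in cat.genes if g not in present]
    if dropped:
        logger.warning("%d regulators absent from the matrix were dropped", len(dropped))
    if not regulators:
        raise ValueError("no regulators present in the expression matrix")
    s1, s2 = conditions_samples
    if len(s1) < 3 or len(s2) < 3:
        raise ValueError("each condition needs >= 3 samples for association profiles")

    def block(samples: list[str], rows: list[str]) -> np.ndarray:
        return nm.log_expr.loc[rows, samples].to_numpy(dtype=float)

    x1, y1 = block(s1, regulators), block(s1, de_genes)
    x2, y2 = block(s2, regulators), block(s2, de_genes)

    if metric in STATISTICAL_METRICS:
        r1 = _corr_matrix(x1, y1, metric)
        r2 = _corr_matrix(x2, y2, metric)
        d_max = float("nan")
    else:
        d1 = _geometric_distance_matrix(x1, y1, metric, sobolev_order)
        d2 = _geometric_distance_matrix(x2, y2, metric, sobolev_order)
        if metric == "fisher":
            d_max = FISHER_DMAX
        else:
            d_max = float(max(d1.max(), d2.max()))
            if d_max <= 0:
                logger.warning("all Sobolev distances are zero; d_max set to 1")
                d_max = 1.0
        r1 = 1.0 - d1 / d_max
        r2 = 1.0 - d2 / d_max
        if signed_geometric:
            r1 = r1 * np.sign(_corr_matrix(x1, y1, "pearson"))
            r2 = r2 * np.sign(_corr_matrix(x2, y2, "pearson"))
    return AssociationSet(
        metric,
        pd.DataFrame(r1, index=regulators, columns=de_genes),
        pd.DataFrame(r2, index=regulators, columns=de_genes),
        d_max,
    )
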
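"""Partial-correlation-and-information-theory (PCIT) network filtering.

PCIT decides, for every pair of regulators, whether their direct correlation
can be explained away by some third regulator.  For each trio (x, y, z) the
three first-order partial correlations are computed and a trio tolerance is
set to the mean absolute ratio of partial to direct correlation (ratios with
a near-zero direct correlation are skipped):

    eps_z = mean(|r_xy.z / r_xy|, |r_xz.y / r_xz|, |r_yz.x / r_yz|)

The edge (x, y) is eliminated when some third node z reduces it to
insignificance relative to the flanking edges:

    |r_xy.z| < eps_z * |r_xz|   and   |r_xy.z| < eps_z * |r_yz|

so a pure chain x-z-y (where r_xy.z = 0) always loses its indirect x-y edge
while the two direct edges survive.  The comparison is strict: in an exactly
balanced trio (three equal correlations) the partials tie with the tolerance
bound and all three edges are kept.  The surviving edges are then thresholded
on the absolute direct correlation (default 0.90) to form the significant-
regulator network.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .de import NormalizedMatrix
from .io import RegulatorCatalog, RegulatorNetwork
from .metrics import pairwise_association
from .rif import RIFTable

logger = logging.getLogger(__name__)

_ZERO = 1e-12


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y given z.

    ``r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``.
    """
    denom_sq = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom_sq < _ZERO:
        raise ValueError("degenerate conditioning: a flanking correlation is +-1")
    return (r_xy - r_xz * r_yz) / np.sqrt(denom_sq)


def _validate_corr(corr: np.ndarray) -> None:
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if corr.shape[0] < 3:
        raise ValueError("PCIT needs >= 3 regulators")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")


def pcit_filter(corr: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Boolean matrix of edges surviving the PCIT elimination rule.

    The returned matrix is symmetric with a False diagonal.  An edge is
    eliminated as soon as one third node satisfies the tolerance condition;
    trios with a degenerate flank (|r| = 1) are skipped for that edge.
    """
    r = np.asarray(corr, dtype=float)
    _validate_corr(r)
    n = r.shape[0]
    survived = np.ones((n, n), dtype=bool)
    np.fill_diagonal(survived, False)
    with np.errstate(divide="ignore", invalid="ignore"):
        for x in range(n - 1):
            for y in range(x + 1, n):
                r_xy = r[x, y]
                z = np.setdiff1d(np.arange(n), [x, y])
                r_xz, r_yz = r[x, z], r[y, z]
                den_xy = (1.0 - r_xz**2) * (1.0 - r_yz**2)
                den_xz = (1.0 - r_xy**2) * (1.0 - r_yz**2)
                den_yz = (1.0 - r_xy**2) * (1.0 - r_xz**2)
                valid = (den_xy > _ZERO) & (den_xz > _ZERO) & (den_yz > _ZERO)
                p_xy = (r_xy - r_xz * r_yz) / np.sqrt(den_xy)
                p_xz = (r_xz - r_xy * r_yz) / np.sqrt(den_xz)
                p_yz = (r_yz - r_xy * r_xz) / np.sqrt(den_yz)
                # trio tolerance: mean |partial/direct| over non-degenerate pairs
                ratios = np.full((3, z.size), np.nan)
                if abs(r_xy) >= _ZERO:
                    ratios[0] = np.abs(p_xy / r_xy)
                ratios[1] = np.where(np.abs(r_xz) >= _ZERO, np.abs(p_xz / r_xz), np.nan)
                ratios[2] = np.where(np.abs(r_yz) >= _ZERO, np.abs(p_yz / r_yz), np.nan)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    eps = np.nanmean(ratios, axis=0)
                has_eps = ~np.isnan(eps)
                # strict comparison (with a hair of slack) so that exactly
                # balanced trios -- e.g. three equal correlations -- keep
                # their edges instead of dissolving entirely
                kill = (
                    valid
                    & has_eps
                    & (np.abs(p_xy) < eps * np.abs(r_xz) * (1.0 - 1e-9))
                    & (np.abs(p_xy) < eps * np.abs(r_yz) * (1.0 - 1e-9))
                )
                if kill.any():
                    survived[x, y] = survived[y, x] = False
    return survived


def min_abs_partial(corr: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Minimum |first-order partial correlation| over all conditioners, per pair."""
    r = np.asarray(corr, dtype=float)
    _validate_corr(r)
    n = r.shape[0]
    out = np.full((n, n), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        for x in range(n - 1):
            for y in range(x + 1, n):
                z = np.setdiff1d(np.arange(n), [x, y])
                den = (1.0 - r[x, z] ** 2) * (1.0 - r[y, z] ** 2)
                p = np.abs(r[x, y] - r[x, z] * r[y, z]) / np.sqrt(den)
                p = p[den > _ZERO]
                if p.size:
                    out[x, y] = out[y, x] = float(p.min())
    return out


def build_network(
    table: RIFTable,
    nm: NormalizedMatrix,
    edge_threshold: float = 0.90,
    *,
    catalog: RegulatorCatalog | None = None,
    corr_metric: str = "pearson",
    sobolev_order: int = 1,
    min_partial: float | None = None,
) -> RegulatorNetwork:
    """Network of selected regulators with PCIT-surviving strong edges.

    Direct associations are computed between the selected regulators over
    ALL samples pooled (both conditions), by default with Pearson
    correlation regardless of the RIF measure (PCIT is defined on
    correlations); ``corr_metric`` can switch to the run's own measure.
    Retained edges survive PCIT and have ``|r| >= edge_threshold``.
    Isolated nodes stay in the network.  With fewer than 3 selected
    regulators the PCIT stage is skipped with a warning.
    """
    selected = [g for g in table.frame.loc[table.frame["selected"], "regulator"]]
    present = [g for g in selected if g in nm.log_expr.index]
    if len(present) < len(selected):
        logger.warning(
            "%d selected regulators missing from the expression matrix",
            len(selected) - len(present),
        )
    g = nx.Graph()
    for node in present:
        g.add_node(
            node,
            classes=catalog.classes_string(node) if catalog is not None else "",
            metrics_found_by=table.metric,
        )
    if len(present) < 3:
        logger.warning(
            "only %d selected regulators; PCIT stage skipped", len(present)
        )
        if len(present) == 2:
            profiles = nm.log_expr.loc[present]
            corr = pairwise_association(profiles, corr_metric, sobolev_order)
            r = float(corr.iloc[0, 1])
            if abs(r) >= edge_threshold:
                g.add_edge(present[0], present[1], direct_correlation=r)
        return RegulatorNetwork(g, table.metric)
    profiles = nm.log_expr.loc[present]
    corr = pairwise_association(profiles, corr_metric, sobolev_order)
    r = corr.to_numpy()
    survived = pcit_filter(r)
    keep = survived & (np.abs(r) >= edge_threshold)
    if min_partial is not None:
        keep &= min_abs_partial(r) >= min_partial
    for i in range(len(present) - 1):
        for j in range(i + 1, len(present)):
            if keep[i, j]:
                g.add_edge(present[i], present[j], direct_correlation=float(r[i, j]))
    return RegulatorNetwork(g, table.metric)
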
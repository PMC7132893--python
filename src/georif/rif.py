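"""Regulatory impact factor scores: PIF, differential wiring, RIF1, RIF2.

For a two-condition experiment with per-gene mean log2-CPM expression ``e1``
and ``e2`` and regulator-gene associations ``r1`` and ``r2``:

* ``PIF_i = (e1_i^2 - e2_i^2) / 2`` — the phenotype impact factor of DE
  gene i (half the difference of squared expression);
* ``DW_ji = r1_ji - r2_ji`` — the differential wiring between regulator j
  and DE gene i;
* ``RIF1_j = mean_i PIF_i * DW_ji^2`` — regulators with large differential
  wiring to abundant, strongly DE genes (squared DW, following the original
  RIF definition; an unsquared variant is available);
* ``RIF2_j = mean_i [(e1_i r1_ji)^2 - (e2_i r2_ji)^2]`` — regulators whose
  expression predicts the abundance of DE genes.

Raw scores are z-standardized across regulators within each measure, ranked
by descending |z|, and the union of the top-k by either score is marked as
selected.  Relabelling the two conditions negates PIF, DW, RIF1 and RIF2
exactly, so |z| ranks and selection do not depend on the orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DEResult
from .io import RIF_TABLE_COLUMNS, RegulatorCatalog
from .metrics import AssociationSet

logger = logging.getLogger(__name__)

SELECT_MODES = ("abs", "positive", "negative")


@dataclass(frozen=True)
class RIFTable:
    """Per-regulator RIF scores, z-scores, ranks and selection flags."""

    frame: pd.DataFrame  # columns = io.RIF_TABLE_COLUMNS
    metric: str
    top_k: int

    @property
    def regulators(self) -> list[str]:
        return list(self.frame["regulator"])

    @property
    def selected(self) -> list[str]:
        return sorted(self.frame.loc[self.frame["selected"], "regulator"])


def pif_scores(de: DEResult) -> pd.Series:
    """Phenotype impact factor per DE gene: ``(e1^2 - e2^2) / 2``."""
    sub = de.table[de.table["is_de"]]
    if sub.empty:
        raise ValueError("empty DE set")
    e1 = sub["e1"].to_numpy(dtype=float)
    e2 = sub["e2"].to_numpy(dtype=float)
    return pd.Series(0.5 * (e1**2 - e2**2), index=list(sub["gene"]), name="pif")


def dw_matrix(a: AssociationSet) -> pd.DataFrame:
    """Differential wiring ``DW = r1 - r2`` (regulators x DE genes)."""
    return a.r1 - a.r2


def rif1(pif: pd.Series, dw: pd.DataFrame, squared_dw: bool = True) -> pd.Series:
    """``RIF1_j = mean_i PIF_i * DW_ji^2`` (or ``* DW_ji`` if unsquared)."""
    if dw.shape[1] == 0:
        raise ValueError("empty DE set")
    p = pif.reindex(dw.columns).to_numpy(dtype=float)
    if np.isnan(p).any():
        raise ValueError("PIF is missing for some DE genes in the DW matrix")
    w = dw.to_numpy(dtype=float)
    contrib = (w**2 if squared_dw else w) * p[None, :]
    return pd.Series(contrib.mean(axis=1), index=dw.index, name="rif1")


def rif2(de: DEResult, a: AssociationSet) -> pd.Series:
    """``RIF2_j = mean_i [(e1_i r1_ji)^2 - (e2_i r2_ji)^2]``."""
    if a.r1.shape[1] == 0:
        raise ValueError("empty DE set")
    sub = de.table.set_index("gene").loc[list(a.r1.columns)]
    e1 = sub["e1"].to_numpy(dtype=float)
    e2 = sub["e2"].to_numpy(dtype=float)
    r1 = a.r1.to_numpy(dtype=float)
    r2 = a.r2.to_numpy(dtype=float)
    vals = ((e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2).mean(axis=1)
    return pd.Series(vals, index=a.r1.index, name="rif2")


def _zscore(x: np.ndarray) -> np.ndarray:
    if x.size < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd < 1e-300:
        logger.warning("zero spread in raw RIF scores; z-scores defined as 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _top_k(z: pd.Series, top_k: int, mode: str) -> set[str]:
    # ties on the primary key fall back to the signed score, then gene id
    if mode == "abs":
        key = lambda g: (-abs(z[g]), -z[g], g)  # noqa: E731
    elif mode == "positive":
        key = lambda g: (-z[g], g)  # noqa: E731
    else:
        key = lambda g: (z[g], g)  # noqa: E731
    return set(sorted(z.index, key=key)[:top_k])


def standardize_and_select(
    rif1_raw: pd.Series,
    rif2_raw: pd.Series,
    top_k: int = 10,
    *,
    metric: str = "",
    catalog: RegulatorCatalog | None = None,
    select: str = "abs",
) -> RIFTable:
    """Z-standardize raw scores, rank by descending |z|, flag the top-k union.

    ``selected`` is the union of the top-k regulators by |rif1_z| and by
    |rif2_z| (ties broken by ascending gene id), so at most ``2*top_k``
    regulators are flagged per measure.  ``select`` switches the extremity
    criterion to signed z if wanted.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if select not in SELECT_MODES:
        raise ValueError(f"select must be one of {SELECT_MODES}")
    if not rif1_raw.index.equals(rif2_raw.index):
        rif2_raw = rif2_raw.reindex(rif1_raw.index)
    if len(rif1_raw) == 0:
        raise ValueError("no regulators to rank")
    z1 = pd.Series(_zscore(rif1_raw.to_numpy(dtype=float)), index=rif1_raw.index)
    z2 = pd.Series(_zscore(rif2_raw.to_numpy(dtype=float)), index=rif1_raw.index)
    rank1 = z1.abs().rank(method="dense", ascending=False).astype(int)
    rank2 = z2.abs().rank(method="dense", ascending=False).astype(int)
    chosen = _top_k(z1, top_k, select) | _top_k(z2, top_k, select)
    frame = pd.DataFrame(
        {
            "regulator": list(rif1_raw.index),
            "classes": [
                catalog.classes_string(g) if catalog is not None else ""
                for g in rif1_raw.index
            ],
            "metric": metric,
            "rif1_raw": rif1_raw.to_numpy(dtype=float),
            "rif2_raw": rif2_raw.to_numpy(dtype=float),
            "rif1_z": z1.to_numpy(),
            "rif2_z": z2.to_numpy(),
            "rank1": rank1.to_numpy(),
            "rank2": rank2.to_numpy(),
            "selected": [g in chosen for g in rif1_raw.index],
        }
    )[RIF_TABLE_COLUMNS]
    return RIFTable(frame, metric, top_k)


def score_regulators(
    de: DEResult,
    a: AssociationSet,
    top_k: int = 10,
    *,
    catalog: RegulatorCatalog | None = None,
    squared_dw: bool = True,
    select: str = "abs",
) -> RIFTable:
    """Convenience wrapper: PIF + DW -> RIF1, RIF2 -> standardized table."""
    pif = pif_scores(de)
    r1 = rif1(pif, dw_matrix(a), squared_dw=squared_dw)
    r2 = rif2(de, a)
    return standardize_and_select(
        r1, r2, top_k, metric=a.metric, catalog=catalog, select=select
    )
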
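"""Reading and writing of count matrices, regulator lists, score tables and networks.

All on-disk formats are plain tab-delimited UTF-8 text.  Gene identifiers are
opaque, case-sensitive strings; no symbol/accession conversion is attempted.
Floats are written with full ``repr`` precision so that outputs are
byte-stable and round-trip losslessly (to well below 1e-9).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import DesignError, FormatError

logger = logging.getLogger(__name__)

#: Recognized regulator classes, in canonical display order.
REGULATOR_CLASSES = ("TF", "EF", "lncRNA")

RIF_TABLE_COLUMNS = [
    "regulator",
    "classes",
    "metric",
    "rif1_raw",
    "rif2_raw",
    "rif1_z",
    "rif2_z",
    "rank1",
    "rank2",
    "selected",
]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene x sample count matrix with a two-condition design.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes as rows, samples as columns.
    condition_of
        Mapping from sample id to condition label; exactly two distinct
        labels must occur among the samples.
    conditions
        Orientation of the contrast: ``conditions[0]`` is "condition 1" in
        all downstream scores (PIF, DW, RIF signs depend on it).  Defaults to
        order of first appearance in the sample axis.
    pair_of
        Optional mapping from sample id to a donor/pair label.  Pair labels
        are carried through but not used by the (unpaired) exact test.
    """

    counts: pd.DataFrame
    condition_of: Mapping[str, str]
    conditions: tuple[str, str] = ()
    pair_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("counts must be numeric integers")
        if np.isnan(arr.astype(float)).any():
            raise FormatError("missing values are not allowed in the count matrix")
        if (arr < 0).any():
            raise FormatError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr), rtol=0, atol=0):
            raise FormatError("counts must be integers (found fractional values)")
        missing = [s for s in counts.columns if s not in self.condition_of]
        if missing:
            raise DesignError(f"samples without a condition label: {missing}")
        labels = [self.condition_of[s] for s in counts.columns]
        distinct = list(dict.fromkeys(labels))
        if len(distinct) != 2:
            raise DesignError(
                f"exactly two condition labels required, found {len(distinct)}: {distinct}"
            )
        if not self.conditions:
            object.__setattr__(self, "conditions", (distinct[0], distinct[1]))
        if sorted(self.conditions) != sorted(distinct):
            raise DesignError(
                f"conditions {self.conditions} do not match labels {distinct}"
            )
        for cond in self.conditions:
            n = labels.count(cond)
            if n < 2:
                raise DesignError(f"condition {cond!r} has {n} sample(s); need >= 2")
            if n < 3:
                logger.warning(
                    "condition %r has only %d samples; correlations need >= 3", cond, n
                )
        if not np.issubdtype(arr.dtype, np.integer):
            object.__setattr__(self, "counts", counts.astype(np.int64))

    # -- convenience accessors ---------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids of one condition, in count-matrix column order."""
        return [s for s in self.counts.columns if self.condition_of[s] == condition]

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def drop_unexpressed(self) -> "CountMatrix":
        """Drop genes with zero counts in every sample (logged)."""
        keep = self.counts.sum(axis=1) > 0
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d genes with zero counts in all samples", n_drop)
            return CountMatrix(
                self.counts.loc[keep], self.condition_of, self.conditions, self.pair_of
            )
        return self

    def with_conditions(self, cond1: str, cond2: str) -> "CountMatrix":
        """Return a copy with an explicit condition orientation."""
        return CountMatrix(self.counts, self.condition_of, (cond1, cond2), self.pair_of)


@dataclass(frozen=True)
class RegulatorCatalog:
    """Candidate regulators with (possibly overlapping) class labels.

    A gene may be e.g. both a transcription factor and an epigenetic factor;
    class sets are therefore not disjoint and merging catalogs unions them.
    """

    classes_of: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, classes in self.classes_of.items():
            bad = set(classes) - set(REGULATOR_CLASSES)
            if bad:
                raise FormatError(f"unknown regulator class {bad} for gene {gene!r}")
            if not classes:
                raise FormatError(f"gene {gene!r} has an empty class set")

    @property
    def genes(self) -> list[str]:
        return list(self.classes_of)

    def __len__(self) -> int:
        return len(self.classes_of)

    def __contains__(self, gene: str) -> bool:
        return gene in self.classes_of

    def classes_string(self, gene: str) -> str:
        """Classes of one gene joined in canonical order, e.g. ``"TF,EF"``."""
        classes = self.classes_of.get(gene, frozenset())
        return ",".join(c for c in REGULATOR_CLASSES if c in classes)

    def merge(self, other: "RegulatorCatalog") -> "RegulatorCatalog":
        merged = {g: set(c) for g, c in self.classes_of.items()}
        for gene, classes in other.classes_of.items():
            merged.setdefault(gene, set()).update(classes)
        return RegulatorCatalog({g: frozenset(c) for g, c in merged.items()})


def merge_catalogs(*catalogs: RegulatorCatalog) -> RegulatorCatalog:
    """Union class sets per gene across any number of catalogs."""
    out = RegulatorCatalog({})
    for cat in catalogs:
        out = out.merge(cat)
    return out


@dataclass(frozen=True)
class RegulatorNetwork:
    """Selected regulators and their PCIT-surviving interactions.

    ``graph`` is an undirected :class:`networkx.Graph`; every node carries
    ``classes`` (comma-joined string) and edges carry ``direct_correlation``.
    Isolated nodes are retained: the node set is the set of significant
    regulators, whether or not they interact.
    """

    graph: nx.Graph
    metric: str

    @property
    def node_set(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _check_header_duplicates(path: Path) -> None:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise FormatError(f"duplicate sample id in header of {path}: {s!r}")
        seen.add(s)


def read_counts(
    path: str | Path,
    condition_map_path: str | Path,
    conditions: tuple[str, str] | None = None,
) -> CountMatrix:
    """Read a gene x sample count TSV plus a sample->condition map.

    The count file has a header row of sample ids and gene ids in the first
    column.  The condition map is a two-column TSV (sample_id, condition)
    with an optional third column of donor/pair labels.
    """
    path, condition_map_path = Path(path), Path(condition_map_path)
    _check_header_duplicates(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"non-numeric counts in column {col!r} of {path}")
    cmap = pd.read_csv(condition_map_path, sep="\t", header=None, dtype=str, comment="#")
    if cmap.shape[1] < 2:
        raise FormatError(f"condition map {condition_map_path} needs >= 2 columns")
    condition_of = dict(zip(cmap[0], cmap[1]))
    pair_of = dict(zip(cmap[0], cmap[2])) if cmap.shape[1] >= 3 else None
    return CountMatrix(df, condition_of, conditions or (), pair_of)


def write_counts(m: CountMatrix, path: str | Path, condition_map_path: str | Path) -> None:
    """Write a CountMatrix and its condition map (inverse of :func:`read_counts`)."""
    m.counts.to_csv(path, sep="\t", index_label="gene")
    rows = []
    for s in m.sample_ids:
        row = [s, m.condition_of[s]]
        if m.pair_of is not None:
            row.append(m.pair_of.get(s, ""))
        rows.append(row)
    pd.DataFrame(rows).to_csv(condition_map_path, sep="\t", header=False, index=False)


def read_gene_list(path: str | Path, class_label: str) -> RegulatorCatalog:
    """Read a plain-text gene list (one id per line, ``#`` comments allowed).

    Every listed gene is tagged with ``class_label``; duplicates collapse.
    An empty file yields an empty catalog with a warning.
    """
    if class_label not in REGULATOR_CLASSES:
        raise FormatError(f"unknown regulator class {class_label!r}")
    genes: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                genes[token] = frozenset({class_label})
    if not genes:
        logger.warning("gene list %s is empty", path)
    return RegulatorCatalog(genes)


# ---------------------------------------------------------------------------
# Score tables and networks
# ---------------------------------------------------------------------------


def write_rif_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a RIF score table as TSV (columns fixed, rows by metric then rank1)."""
    missing = [c for c in RIF_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"RIF table is missing columns: {missing}")
    out = frame[RIF_TABLE_COLUMNS].sort_values(
        ["metric", "rank1", "regulator"], kind="mergesort"
    )
    vals = out[["rif1_raw", "rif2_raw", "rif1_z", "rif2_z"]].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise FormatError("RIF table contains non-finite values")
    out.to_csv(path, sep="\t", index=False)


def read_rif_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "regulator": str,
            "classes": str,
            "metric": str,
            "rank1": int,
            "rank2": int,
            "selected": bool,
        },
        keep_default_na=False,
        na_values=[],
    )
    return df[RIF_TABLE_COLUMNS]


def write_network(net: RegulatorNetwork, edges_path: str | Path, nodes_path: str | Path) -> None:
    """Write a network as an edge-list TSV plus a node-attribute TSV.

    Edges are written with ``node_a < node_b`` lexicographically and sorted,
    so output is byte-stable across runs.
    """
    rows = []
    for a, b, data in net.graph.edges(data=True):
        a, b = (a, b) if a < b else (b, a)
        rows.append((a, b, data.get("direct_correlation", np.nan), net.metric))
    rows.sort()
    pd.DataFrame(
        rows, columns=["node_a", "node_b", "direct_correlation", "metric"]
    ).to_csv(edges_path, sep="\t", index=False)
    node_rows = [
        (
            n,
            net.graph.nodes[n].get("classes", ""),
            net.graph.nodes[n].get("metrics_found_by", net.metric),
        )
        for n in sorted(net.graph.nodes)
    ]
    pd.DataFrame(node_rows, columns=["node", "classes", "metrics_found_by"]).to_csv(
        nodes_path, sep="\t", index=False
    )


def read_network(edges_path: str | Path, nodes_path: str | Path) -> RegulatorNetwork:
    edges = pd.read_csv(edges_path, sep="\t", dtype={"node_a": str, "node_b": str})
    nodes = pd.read_csv(
        nodes_path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    g = nx.Graph()
    for _, row in nodes.iterrows():
        g.add_node(row["node"], classes=row["classes"], metrics_found_by=row["metrics_found_by"])
    metric = ""
    for _, row in edges.iterrows():
        g.add_edge(row["node_a"], row["node_b"], direct_correlation=float(row["direct_correlation"]))
        metric = row["metric"]
    return RegulatorNetwork(g, metric)


def read_de_list(path: str | Path) -> list[str]:
    """Read a precomputed DE gene list (one id per line, ``#`` comments allowed)."""
    genes: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token and token not in seen:
                genes.append(token)
                seen.add(token)
    return genes
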
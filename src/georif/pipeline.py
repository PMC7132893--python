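"""End-to-end analysis: normalize -> DE -> associations -> RIF -> PCIT network.

The workflow is exposed statsmodels-style: :class:`RIFAnalysis` is built
from a :class:`~georif.io.CountMatrix` and a regulator catalog, and
``fit()`` returns a :class:`RIFResults` carrying the DE table, one RIF score
table and one regulator network per association measure, and the
per-measure overlap summary.  ``run_pipeline`` drives the same object from
file paths and a :class:`RunConfig`, writing all outputs as TSV.

The orientation of the contrast (which condition is "condition 1") is an
explicit setting, never inferred: every signed score (PIF, DW, RIF1, RIF2)
flips with it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import de as de_mod
from . import io as io_mod
from . import metrics as metrics_mod
from . import pcit as pcit_mod
from . import rif as rif_mod
from .exceptions import PipelineError
from .io import CountMatrix, RegulatorCatalog, RegulatorNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable run settings (a saved config re-runs identically)."""

    counts_path: str = ""
    condition_map_path: str = ""
    tf_lists: tuple[str, ...] = ()
    ef_lists: tuple[str, ...] = ()
    lncrna_lists: tuple[str, ...] = ()
    de_list_path: str = ""  # optional precomputed DE genes (bypasses the test)
    out_dir: str = "georif_out"
    condition_1: str = ""  # empty = first label encountered
    fdr_cutoff: float = 0.05
    dispersion: str = "tagwise"  # or "common"
    pseudocount: float = 0.5
    metrics: tuple[str, ...] = metrics_mod.METRICS
    sobolev_order: int = 1
    signed_geometric: bool = False
    top_k: int = 10
    rif1_linear_dw: bool = False
    select: str = "abs"
    edge_threshold: float = 0.90
    pcit_metric: str = "pearson"  # or "run": use the RIF measure for PCIT
    min_partial: float | None = None

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if value is None:
                continue
            if isinstance(value, bool):
                lines.append(f"{key} = {str(value).lower()}")
            elif isinstance(value, (int, float)):
                lines.append(f"{key} = {value!r}")
            elif isinstance(value, tuple):
                inner = ", ".join(f'"{v}"' for v in value)
                lines.append(f"{key} = [{inner}]")
            else:
                lines.append(f'{key} = "{value}"')
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        for key in ("tf_lists", "ef_lists", "lncrna_lists", "metrics"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class RIFResults:
    """Fitted results: DE table, per-measure RIF tables and networks."""

    model: "RIFAnalysis"
    norm: de_mod.NormalizedMatrix
    dispersion: de_mod.DispersionEstimate
    de: de_mod.DEResult
    associations: dict[str, metrics_mod.AssociationSet]
    rif_tables: dict[str, rif_mod.RIFTable]
    networks: dict[str, RegulatorNetwork]
    summary_table: pd.DataFrame
    venn_regions: dict[frozenset, int]

    def significant_regulators(self, metric: str) -> set[str]:
        """Node set of the PCIT network for one measure."""
        return self.networks[metric].node_set

    def summary(self) -> str:
        """Human-readable run summary (counts per measure and class)."""
        m = self.model
        lines = [
            "Regulatory impact factor analysis",
            "=" * 49,
            f"genes: {m.counts.n_genes}   samples: {m.counts.n_samples} "
            f"({m.counts.conditions[0]} vs {m.counts.conditions[1]})",
            f"common NB dispersion: {self.dispersion.alpha_common:.4f}",
            f"DE genes at FDR < {self.de.fdr_cutoff:g}: {self.de.n_de}",
            "",
            "Significant regulators per measure (network node sets):",
            self.summary_table.to_string(),
            "",
        ]
        for metric, net in self.networks.items():
            lines.append(
                f"{metric}: {len(net.node_set)} regulators, {net.n_edges} edges"
            )
        return "\n".join(lines)

    def plot_scores(self, metric: str, ax=None):
        """Scatter of RIF1 vs RIF2 z-scores, selected regulators highlighted."""
        import matplotlib.pyplot as plt

        frame = self.rif_tables[metric].frame
        if ax is None:
            _, ax = plt.subplots()
        sel = frame["selected"]
        ax.scatter(frame.loc[~sel, "rif1_z"], frame.loc[~sel, "rif2_z"], s=12, c="grey")
        ax.scatter(frame.loc[sel, "rif1_z"], frame.loc[sel, "rif2_z"], s=20, c="crimson")
        ax.axhline(0, lw=0.5, c="k")
        ax.axvline(0, lw=0.5, c="k")
        ax.set_xlabel("RIF1 (z)")
        ax.set_ylabel("RIF2 (z)")
        ax.set_title(f"RIF scores ({metric})")
        return ax

    def save(self, out_dir: str | Path) -> Path:
        """Write DE table, RIF tables, networks and summaries as TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.de.table.to_csv(out / "de_table.tsv", sep="\t", index=False)
        for metric, table in self.rif_tables.items():
            io_mod.write_rif_table(table.frame, out / f"rif_{metric}.tsv")
        for metric, net in self.networks.items():
            io_mod.write_network(
                net,
                out / f"network_{metric}_edges.tsv",
                out / f"network_{metric}_nodes.tsv",
            )
        self.summary_table.to_csv(out / "summary.tsv", sep="\t")
        regions = sorted(
            ("+".join(sorted(k)), v) for k, v in self.venn_regions.items()
        )
        pd.DataFrame(regions, columns=["metrics", "n_regulators"]).to_csv(
            out / "overlap_regions.tsv", sep="\t", index=False
        )
        return out


class RIFAnalysis:
    """Regulatory impact factor model for a two-condition count experiment.

    Parameters mirror the pipeline stages: DE settings (``fdr_cutoff``,
    ``dispersion``, ``pseudocount``), association measures (``metrics``,
    ``sobolev_order``, ``signed_geometric``), RIF settings (``top_k``,
    ``rif1_linear_dw``, ``select``) and network settings
    (``edge_threshold``, ``pcit_metric``, ``min_partial``).

    Examples
    --------
    >>> model = RIFAnalysis(counts, catalog, metrics=("fisher",))
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        counts: CountMatrix,
        catalog: RegulatorCatalog,
        *,
        de_genes: list[str] | None = None,
        fdr_cutoff: float = 0.05,
        dispersion: str = "tagwise",
        pseudocount: float = 0.5,
        metrics: tuple[str, ...] = metrics_mod.METRICS,
        sobolev_order: int = 1,
        signed_geometric: bool = False,
        top_k: int = 10,
        rif1_linear_dw: bool = False,
        select: str = "abs",
        edge_threshold: float = 0.90,
        pcit_metric: str = "pearson",
        min_partial: float | None = None,
    ) -> None:
        unknown = [m for m in metrics if m not in metrics_mod.METRICS]
        if unknown:
            raise PipelineError(f"config: unknown metrics {unknown}")
        if dispersion not in ("common", "tagwise"):
            raise PipelineError("config: dispersion must be 'common' or 'tagwise'")
        if pcit_metric not in ("pearson", "run"):
            raise PipelineError("config: pcit_metric must be 'pearson' or 'run'")
        self.counts = counts.drop_unexpressed()
        self.catalog = catalog
        self.de_genes = de_genes
        self.fdr_cutoff = fdr_cutoff
        self.dispersion = dispersion
        self.pseudocount = pseudocount
        self.metrics = tuple(metrics)
        self.sobolev_order = sobolev_order
        self.signed_geometric = signed_geometric
        self.top_k = top_k
        self.rif1_linear_dw = rif1_linear_dw
        self.select = select
        self.edge_threshold = edge_threshold
        self.pcit_metric = pcit_metric
        self.min_partial = min_partial

    @classmethod
    def from_files(
        cls,
        counts_path: str | Path,
        condition_map_path: str | Path,
        gene_lists: dict[str, list[str | Path]],
        *,
        condition_1: str = "",
        de_list_path: str | Path | None = None,
        **kwargs,
    ) -> "RIFAnalysis":
        """Build the model from the on-disk formats of :mod:`georif.io`."""
        counts = io_mod.read_counts(counts_path, condition_map_path)
        if condition_1:
            if condition_1 not in counts.conditions:
                raise PipelineError(f"config: condition_1={condition_1!r} not in data")
            other = next(c for c in counts.conditions if c != condition_1)
            counts = counts.with_conditions(condition_1, other)
        catalogs = [
            io_mod.read_gene_list(p, cls_label)
            for cls_label, paths in gene_lists.items()
            for p in paths
        ]
        if not catalogs:
            raise PipelineError("config: at least one regulator gene list required")
        catalog = io_mod.merge_catalogs(*catalogs)
        de_genes = io_mod.read_de_list(de_list_path) if de_list_path else None
        return cls(counts, catalog, de_genes=de_genes, **kwargs)

    def _stage(self, name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    def fit(self) -> RIFResults:
        """Run the full workflow and return the results object."""
        m = self.counts
        factors = self._stage("normalize", de_mod.tmm_factors, m)
        nm = self._stage("normalize", de_mod.log_cpm, m, factors, self.pseudocount)
        disp = self._stage(
            "dispersion",
            de_mod.estimate_common_dispersion,
            m,
            factors,
            tagwise=self.dispersion == "tagwise",
        )
        if self.de_genes is not None:
            de_res = self._stage(
                "de", de_mod.de_result_from_list, m, factors, self.de_genes,
                self.fdr_cutoff, self.pseudocount, nm,
            )
        else:
            pvals = self._stage("de", de_mod.nb_exact_test, m, factors, disp)
            de_res = self._stage(
                "de", de_mod.select_de, m, factors, pvals, self.fdr_cutoff,
                self.pseudocount, nm,
            )
        cond_samples = (m.samples_of(m.conditions[0]), m.samples_of(m.conditions[1]))
        associations: dict[str, metrics_mod.AssociationSet] = {}
        rif_tables: dict[str, rif_mod.RIFTable] = {}
        networks: dict[str, RegulatorNetwork] = {}
        for metric in self.metrics:
            assoc = self._stage(
                f"associations[{metric}]",
                metrics_mod.association_matrices,
                nm, de_res, self.catalog, metric,
                conditions_samples=cond_samples,
                sobolev_order=self.sobolev_order,
                signed_geometric=self.signed_geometric,
            )
            table = self._stage(
                f"rif[{metric}]",
                rif_mod.score_regulators,
                de_res, assoc, self.top_k,
                catalog=self.catalog,
                squared_dw=not self.rif1_linear_dw,
                select=self.select,
            )
            net = self._stage(
                f"network[{metric}]",
                pcit_mod.build_network,
                table, nm, self.edge_threshold,
                catalog=self.catalog,
                corr_metric=metric if self.pcit_metric == "run" else "pearson",
                sobolev_order=self.sobolev_order,
                min_partial=self.min_partial,
            )
            associations[metric] = assoc
            rif_tables[metric] = table
            networks[metric] = net
        summary, regions = overlap_summary(networks, self.catalog)
        return RIFResults(
            self, nm, disp, de_res, associations, rif_tables, networks, summary, regions
        )


def overlap_summary(
    networks: dict[str, RegulatorNetwork], catalog: RegulatorCatalog
) -> tuple[pd.DataFrame, dict[frozenset, int]]:
    """Per-measure significant-regulator counts and Venn-region counts.

    Rows are regulator classes plus ``Sum``; columns are measures plus
    ``Total`` (unique regulators across measures).  A multi-class gene is
    counted once per class it carries, so class counts can sum to more than
    the number of unique nodes.  The region counts partition the union of
    all node sets by the exact subset of measures that found each gene.
    """
    if not networks:
        raise ValueError("need >= 1 network")
    metrics = list(networks)
    node_sets = {m: networks[m].node_set for m in metrics}
    all_nodes = set().union(*node_sets.values())
    rows = []
    for cls in io_mod.REGULATOR_CLASSES:
        row = {
            m: sum(1 for g in node_sets[m] if cls in catalog.classes_of.get(g, ()))
            for m in metrics
        }
        row["Total"] = sum(1 for g in all_nodes if cls in catalog.classes_of.get(g, ()))
        rows.append(pd.Series(row, name=cls))
    sums = {m: len(node_sets[m]) for m in metrics}
    sums["Total"] = len(all_nodes)
    rows.append(pd.Series(sums, name="Sum"))
    summary = pd.DataFrame(rows)
    regions: dict[frozenset, int] = {}
    for k in range(1, len(metrics) + 1):
        for combo in itertools.combinations(metrics, k):
            inside = set(all_nodes)
            for m in combo:
                inside &= node_sets[m]
            for m in metrics:
                if m not in combo:
                    inside -= node_sets[m]
            regions[frozenset(combo)] = len(inside)
    return summary, regions


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the workflow from file inputs; returns the output directory.

    Validates all input paths before any computation (fail-fast), echoes
    every effective setting to ``georif.log`` in the output directory, and
    writes the resolved config next to the outputs so a run can be repeated
    byte-identically.
    """
    paths = [cfg.counts_path, cfg.condition_map_path, *cfg.tf_lists, *cfg.ef_lists,
             *cfg.lncrna_lists]
    if cfg.de_list_path:
        paths.append(cfg.de_list_path)
    for p in paths:
        if not p or not Path(p).exists():
            raise PipelineError(f"config: input path does not exist: {p!r}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out / "georif.log", mode="w", encoding="utf-8")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("georif")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        for key, value in asdict(cfg).items():
            logger.info("config %s = %r", key, value)
        gene_lists = {
            "TF": list(cfg.tf_lists),
            "EF": list(cfg.ef_lists),
            "lncRNA": list(cfg.lncrna_lists),
        }
        gene_lists = {k: v for k, v in gene_lists.items() if v}
        model = RIFAnalysis.from_files(
            cfg.counts_path,
            cfg.condition_map_path,
            gene_lists,
            condition_1=cfg.condition_1,
            de_list_path=cfg.de_list_path or None,
            fdr_cutoff=cfg.fdr_cutoff,
            dispersion=cfg.dispersion,
            pseudocount=cfg.pseudocount,
            metrics=cfg.metrics,
            sobolev_order=cfg.sobolev_order,
            signed_geometric=cfg.signed_geometric,
            top_k=cfg.top_k,
            rif1_linear_dw=cfg.rif1_linear_dw,
            select=cfg.select,
            edge_threshold=cfg.edge_threshold,
            pcit_metric=cfg.pcit_metric,
            min_partial=cfg.min_partial,
        )
        results = model.fit()
        results.save(out)
        resolved = replace(cfg, condition_1=model.counts.conditions[0])
        resolved.to_toml(out / "run_config.toml")
        (out / "summary.txt").write_text(results.summary() + "\n", encoding="utf-8")
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
    return out
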
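"""Cross-dataset consensus and the full driver-gene discovery run.

The consensus panel construction: genes up-regulated in the driver-high
bulk group (NB Wald, padj <= alpha, positive shrunken fold change)
intersected with the genes that are up-markers of driver-positive cells
in EVERY single-cell dataset (Wilcoxon, raw p <= alpha).  Requiring
agreement across d independent datasets shrinks the false-positive set
roughly like N * alpha^(d+1), which is what makes small consensus panels
informative.  The same machinery yields the consensus of
positively-correlated genes across datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .core_io import AnalysisConfig, ExpressionMatrix, GeneSetCollection, ResultTable
from .diffexp import nb_wald_test, pearson_correlate, wilcoxon_markers
from .enrich import ora_hypergeometric
from .stratify import binarize_positive, normalize_cpm, quantile_stratify


def consensus_intersect(sets: list) -> tuple[set[str], dict[str, int]]:
    """Symbol-level intersection of >= 2 gene sets, with Venn region counts.

    Venn counts are emitted for 2 or 3 sets (keys like ``"1&2"`` for the
    genes exactly in sets 1 and 2); for more sets only the full
    intersection count is reported.
    """
    if not sets:
        raise ValueError("no gene sets given")
    if len(sets) < 2:
        raise ValueError("need >= 2 gene sets to intersect")
    sets = [set(g.upper() for g in s) for s in sets]
    inter = set.intersection(*sets)
    if not inter:
        warnings.warn("gene sets have an empty intersection", stacklevel=2)
    venn: dict[str, int] = {}
    if len(sets) <= 3:
        idx = range(1, len(sets) + 1)
        for r in range(1, len(sets) + 1):
            for combo in combinations(idx, r):
                inside = set.intersection(*(sets[i - 1] for i in combo))
                outside = set().union(*(sets[i - 1] for i in idx if i not in combo)) if r < len(sets) else set()
                venn["&".join(map(str, combo))] = len(inside - outside)
    else:
        venn["all"] = len(inter)
    return inter, venn


def consensus_panel(bulk_up: set[str], marker_sets: list) -> set[str]:
    """Bulk up-regulated genes that are up-markers in every sc dataset."""
    bulk_up = {g.upper() for g in bulk_up}
    if len(marker_sets) == 1:
        markers = {g.upper() for g in marker_sets[0]}
    else:
        markers, _ = consensus_intersect(marker_sets)
    return bulk_up & markers


# ---------------------------------------------------------------------------
# Full discovery run
# ---------------------------------------------------------------------------


@dataclass
class DiscoveryReport:
    """Assembled output of a driver-gene discovery run."""

    driver_gene: str
    bulk_groups: dict = field(default_factory=dict)  # name -> StratifiedGroups
    sc_groups: dict = field(default_factory=dict)  # name -> BinaryGroups
    de_tables: dict = field(default_factory=dict)  # name -> ResultTable
    marker_tables: dict = field(default_factory=dict)
    correlation_tables: dict = field(default_factory=dict)
    enrichment_tables: dict = field(default_factory=dict)
    bulk_up: set = field(default_factory=set)
    consensus_markers: set = field(default_factory=set)
    consensus_positive_corr: set = field(default_factory=set)
    panel: set = field(default_factory=set)
    venn_markers: dict = field(default_factory=dict)
    skipped_datasets: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def discovery_run(
    driver: str,
    bulk_datasets: dict[str, ExpressionMatrix],
    sc_datasets: dict[str, ExpressionMatrix],
    gmt: GeneSetCollection | None = None,
    config: AnalysisConfig | None = None,
) -> DiscoveryReport:
    """Run the full discovery pipeline for one driver gene.

    Per bulk dataset: CPM/log normalize, quartile-stratify on the driver,
    NB Wald DE on raw counts (low = control).  Per single-cell dataset:
    binarize on driver positivity, Wilcoxon markers, per-gene Pearson
    correlation with the driver.  Then: consensus up-marker set across sc
    datasets, consensus positively-correlated set, the bulk-up ∩
    consensus-markers panel, and (when a GMT is given) ORA of the panel.
    Datasets missing the driver are skipped with a warning.
    """
    config = config or AnalysisConfig(driver_gene=driver)
    driver = driver.upper()
    report = DiscoveryReport(driver_gene=driver, provenance=config.to_dict())
    alpha = config.alpha

    bulk_use = {}
    for name, m in bulk_datasets.items():
        if driver in m.data.index:
            bulk_use[name] = m
        else:
            warnings.warn(f"driver absent from bulk dataset {name!r}; skipped", stacklevel=2)
            report.skipped_datasets.append(name)
    sc_use = {}
    for name, m in sc_datasets.items():
        if driver in m.data.index:
            sc_use[name] = m
        else:
            warnings.warn(f"driver absent from sc dataset {name!r}; skipped", stacklevel=2)
            report.skipped_datasets.append(name)
    if not bulk_use or not sc_use:
        raise ValueError("need at least one bulk and one single-cell dataset with the driver")

    bulk_up_sets = []
    for name, m in bulk_use.items():
        logm = normalize_cpm(m, log_transform=True)
        groups = quantile_stratify(logm.gene_values(driver), q=config.quartile, driver_gene=driver)
        report.bulk_groups[name] = groups
        de = nb_wald_test(m, groups, alpha=alpha)
        report.de_tables[name] = de
        up = set(de.df.loc[(de.df["padj"] <= alpha) & (de.df["lfc_shrunk"] > 0), "gene"])
        bulk_up_sets.append(up)
        universe = set(m.gene_ids)
        if gmt is not None and up:
            report.enrichment_tables[f"bulk_up_{name}"] = ora_hypergeometric(up, gmt, universe, alpha)
    report.bulk_up = set.intersection(*bulk_up_sets) if bulk_up_sets else set()

    marker_up_sets, pos_corr_sets = [], []
    for name, m in sc_use.items():
        groups = binarize_positive(m, driver)
        report.sc_groups[name] = groups
        markers = wilcoxon_markers(m, groups, alpha=alpha)
        report.marker_tables[name] = markers
        up = set(
            markers.df.loc[(markers.df["p"] <= alpha) & (markers.df["direction"] == "up"), "gene"]
        )
        marker_up_sets.append(up)
        corr = pearson_correlate(m, driver, alpha=alpha)
        report.correlation_tables[name] = corr
        pos_corr_sets.append(set(corr.df.loc[corr.df["positive_significant"], "gene"]))
        if gmt is not None and up:
            report.enrichment_tables[f"markers_up_{name}"] = ora_hypergeometric(
                up, gmt, set(m.gene_ids), alpha
            )

    if len(marker_up_sets) >= 2:
        report.consensus_markers, report.venn_markers = consensus_intersect(marker_up_sets)
    else:
        report.consensus_markers = marker_up_sets[0]
    if len(pos_corr_sets) >= 2:
        report.consensus_positive_corr, _ = consensus_intersect(pos_corr_sets)
    else:
        report.consensus_positive_corr = pos_corr_sets[0]

    report.panel = consensus_panel(report.bulk_up, marker_up_sets)
    if gmt is not None and report.panel:
        shared_universe = set.union(*(set(m.gene_ids) for m in list(bulk_use.values()) + list(sc_use.values())))
        report.enrichment_tables["panel"] = ora_hypergeometric(report.panel, gmt, shared_universe, alpha)
    return report


def report_tables(report: DiscoveryReport) -> dict[str, ResultTable]:
    """Flatten a DiscoveryReport into named ResultTables for writing."""
    out: dict[str, ResultTable] = {}
    for name, t in report.de_tables.items():
        out[f"de_{name}"] = t
    for name, t in report.marker_tables.items():
        out[f"markers_{name}"] = t
    for name, t in report.correlation_tables.items():
        out[f"correlation_{name}"] = t
    for name, t in report.enrichment_tables.items():
        out[f"enrichment_{name}"] = t
    panel_df = pd.DataFrame({"gene": sorted(report.panel)})
    out["panel"] = ResultTable(panel_df, stage="consensus_panel", params=report.provenance)
    return out
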
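"""Domain data model and file I/O shared by every pipeline stage.

The pipeline stratifies expression cohorts (bulk samples or single cells)
by the level of a user-chosen driver gene and runs differential expression,
marker detection, enrichment, signature scoring and survival association
downstream.  This module holds the containers those stages exchange —
expression matrices with an explicit normalization layer, cohort metadata,
GMT-backed gene-set collections, result tables with provenance — plus the
readers and writers for their on-disk forms (dense TSV/CSV, MatrixMarket
triplet, GMT, TSV results with JSON provenance sidecars).

Gene identity throughout the package is the uppercased symbol: matrices
uppercase their row names on read and collapse duplicate rows by summation,
and gene sets uppercase their members, so cross-dataset intersections are
symbol-level by construction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

LAYERS = ("counts", "cpm", "log10cpm1", "normalized")

#: per-column relative tolerance on the 1e6 sum of a CPM layer
_CPM_RTOL = 1e-6


class FormatError(ValueError):
    """A file or matrix violates the expected format."""


class CohortError(ValueError):
    """A cohort operation produced an unusable result (e.g. no samples left)."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene × sample (or gene × cell) expression values with a layer tag.

    Parameters
    ----------
    data
        DataFrame indexed by uppercase gene symbols, columns are sample or
        cell identifiers. Values must be non-negative and finite.
    layer
        One of ``counts`` (non-negative integers), ``cpm`` (columns sum to
        1e6), ``log10cpm1`` (log10(CPM+1)) or ``normalized`` (anything a
        dataset ships pre-normalized).
    """

    data: pd.DataFrame
    layer: str = "counts"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise FormatError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate gene ids (collapse before constructing)")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric entries in expression matrix")
        if not np.all(np.isfinite(values)):
            raise FormatError("non-finite entries in expression matrix")
        if (values < 0).any():
            raise FormatError("negative entries in expression matrix")
        if self.layer == "counts" and not np.allclose(values, np.round(values)):
            raise FormatError("layer=counts requires integer values")
        if self.layer == "cpm":
            colsums = values.sum(axis=0)
            if not np.allclose(colsums, 1e6, rtol=_CPM_RTOL):
                raise FormatError("layer=cpm requires every column to sum to 1e6")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def gene_values(self, gene: str) -> pd.Series:
        return self.data.loc[gene.upper()]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], layer=self.layer)


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Uppercase gene ids; sum rows that collide after uppercasing."""
    df = df.copy()
    df.index = df.index.astype(str).str.strip().str.upper()
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by summation", n_dup)
        df = df.groupby(level=0, sort=False).sum()
    return df


def read_counts(
    path: str | Path,
    format: str | None = None,
    *,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a raw count matrix from dense TSV/CSV or an MTX triplet.

    For ``mtx-triplet``, row (gene) and column (sample) names come from
    companion one-id-per-line files; they default to ``<stem>.genes.txt``
    and ``<stem>.samples.txt`` next to the matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx-triplet"}.get(
            path.suffix.lower(), "tsv"
        )
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
    elif format == "mtx-triplet":
        genes_path = Path(genes_path) if genes_path else path.with_suffix("").with_suffix(".genes.txt")
        samples_path = (
            Path(samples_path) if samples_path else path.with_suffix("").with_suffix(".samples.txt")
        )
        for p in (genes_path, samples_path):
            if not p.exists():
                raise FileNotFoundError(f"companion name file missing: {p}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = [line.strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
        samples = [line.strip() for line in Path(samples_path).read_text().splitlines() if line.strip()]
        if mat.shape != (len(genes), len(samples)):
            raise FormatError(
                f"matrix shape {mat.shape} does not match name files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise FormatError(f"unknown format {format!r}")

    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric entries in {path}: {exc}") from None
    if (df.to_numpy() < 0).any():
        raise FormatError(f"negative counts in {path}")
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix(df, layer="counts")


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as full-precision TSV (round-trip safe)."""
    matrix.data.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# CohortMetadata
# ---------------------------------------------------------------------------

IDH_STATUSES = ("wildtype", "mutant", "unknown")
SUBTYPES = ("classical", "mesenchymal", "proneural", "unknown")
SAMPLE_TYPES = ("primary", "recurrent", "normal")

_META_DEFAULTS: dict[str, object] = {
    "idh_status": "unknown",
    "subtype": "unknown",
    "sample_type": "primary",
    "malignant": "unknown",
    "pediatric": "unknown",
    "os_time": np.nan,
    "os_event": np.nan,
}


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Normalize and validate a per-sample/per-cell annotation table.

    Expects a ``sample_id`` column (or uses the index); missing annotation
    columns are filled with ``unknown``/NaN. Returns a copy indexed by
    sample_id.
    """
    meta = meta.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise FormatError("duplicate sample_id in metadata")
    for col, default in _META_DEFAULTS.items():
        if col not in meta.columns:
            meta[col] = default
    for col, allowed in (("idh_status", IDH_STATUSES), ("subtype", SUBTYPES), ("sample_type", SAMPLE_TYPES)):
        meta[col] = meta[col].fillna("unknown").astype(str).str.lower()
        bad = set(meta[col]) - set(allowed)
        if bad:
            raise FormatError(f"invalid {col} values: {sorted(bad)}")
    os_time = pd.to_numeric(meta["os_time"], errors="coerce")
    if (os_time.dropna() < 0).any():
        raise FormatError("negative os_time")
    meta["os_time"] = os_time
    os_event = pd.to_numeric(meta["os_event"], errors="coerce")
    if not os_event.dropna().isin([0, 1]).all():
        raise FormatError("os_event must be 0 (censored) or 1 (event)")
    meta["os_event"] = os_event
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t"))


#: supported cohort exclusion rules
FILTER_RULES = (
    "drop_idh_mutant",
    "drop_unknown_idh",
    "drop_unknown_subtype",
    "drop_recurrent",
    "drop_pediatric",
    "drop_non_malignant",
)


def filter_cohort(
    meta: pd.DataFrame, rules: Iterable[str]
) -> tuple[list[str], dict[str, int]]:
    """Apply exclusion rules to a metadata table.

    Returns the retained sample ids (input order) and a per-rule counter of
    how many samples each rule would exclude.  Reasons may overlap — a
    sample excluded by several rules is dropped once but increments every
    matching counter, so the counters need not sum to the number dropped.

    Raises :class:`CohortError` when nothing survives.
    """
    rules = set(rules)
    unknown = rules - set(FILTER_RULES)
    if unknown:
        raise ValueError(f"unsupported filter rules: {sorted(unknown)}")
    meta = validate_metadata(meta)

    masks = {
        "drop_idh_mutant": meta["idh_status"] == "mutant",
        "drop_unknown_idh": meta["idh_status"] == "unknown",
        "drop_unknown_subtype": meta["subtype"] == "unknown",
        "drop_recurrent": meta["sample_type"] == "recurrent",
        "drop_pediatric": meta["pediatric"] == True,  # noqa: E712 — column may hold 'unknown'
        "drop_non_malignant": meta["malignant"] == False,  # noqa: E712
    }
    drop = pd.Series(False, index=meta.index)
    counts: dict[str, int] = {}
    for rule in FILTER_RULES:
        if rule in rules:
            mask = masks[rule].astype(bool)
            counts[rule] = int(mask.sum())
            drop |= mask
    retained = list(meta.index[~drop])
    for rule, n in counts.items():
        logger.info("filter_cohort: %s excludes %d samples", rule, n)
    if not retained:
        raise CohortError("no samples left after filtering")
    return retained, counts


# ---------------------------------------------------------------------------
# GeneSetCollection
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-backed); members are uppercase symbols."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, name: str, description: str, genes: Iterable[str]) -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene-set name {name!r}")
        members = frozenset(g.strip().upper() for g in genes if g.strip())
        if not members:
            raise FormatError(f"gene set {name!r} has no members")
        self.sets[name] = GeneSet(name, description, members)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        coll = cls()
        for name, genes in mapping.items():
            coll.add(name, "", genes)
        return coll


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB gene [TAB gene ...]."""
    coll = GeneSetCollection()
    lines = Path(path).read_text().splitlines()
    if not any(line.strip() for line in lines):
        warnings.warn(f"GMT file {path} is empty", stacklevel=2)
        return coll
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
        name, description, *genes = fields
        coll.add(name, description, genes)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# AnalysisConfig and ResultTable
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Run-wide parameters recorded in every result's provenance."""

    driver_gene: str = ""
    quartile: float = 0.25
    alpha: float = 0.05
    nperm: int = 1000
    seed: int = 0
    quantile_convention: str = "type7-strict"

    def __post_init__(self) -> None:
        if not 0 < self.quartile < 0.5:
            raise ValueError("quartile fraction must lie in (0, 0.5)")
        self.driver_gene = self.driver_gene.upper()

    def to_dict(self) -> dict:
        return {
            "driver_gene": self.driver_gene,
            "quartile": self.quartile,
            "alpha": self.alpha,
            "nperm": self.nperm,
            "seed": self.seed,
            "quantile_convention": self.quantile_convention,
        }


@dataclass
class ResultTable:
    """A stage's tabular output plus a provenance snapshot.

    ``df`` must carry a key column first; ``p``/``padj`` columns, when
    present, are checked for the usual sanity constraints.
    """

    df: pd.DataFrame
    stage: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "p" in self.df.columns and len(self.df):
            p = pd.to_numeric(self.df["p"], errors="coerce")
            valid = p.dropna()
            if ((valid < 0) | (valid > 1)).any():
                raise ValueError("p outside [0, 1]")
        if {"p", "padj"} <= set(self.df.columns) and len(self.df):
            both = self.df[["p", "padj"]].dropna()
            if (both["padj"] + 1e-12 < both["p"]).any():
                raise ValueError("padj < p")
            if (both["padj"] > 1 + 1e-12).any():
                raise ValueError("padj > 1")

    @property
    def provenance(self) -> dict:
        return {"stage": self.stage, "params": self.params}


def write_results(table: ResultTable, path: str | Path, allow_empty: bool = False) -> None:
    """Write a ResultTable as TSV plus a JSON provenance sidecar.

    Rows are sorted by adjusted p (when present) then by the key (first)
    column so outputs diff deterministically.
    """
    if table.df.empty and not allow_empty:
        raise ValueError("refusing to write empty table (pass allow_empty=True)")
    df = table.df.copy()
    key = df.columns[0]
    if "padj" in df.columns:
        df = df.sort_values(["padj", key], kind="mergesort", na_position="last")
    else:
        df = df.sort_values(key, kind="mergesort")
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_name(path.name + ".provenance.json")
    sidecar.write_text(json.dumps(table.provenance, indent=2, sort_keys=True, default=str))
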
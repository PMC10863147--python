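"""RT-qPCR relative quantification by the 2^-ΔΔCt method.

Quantification cycles (Cq) are first averaged over technical replicates.
ΔCq normalizes a target gene to the geometric mean of the reference-gene
Cq values within each sample (multi-reference normalization); ΔΔCt then
subtracts the mean ΔCq of a control group, and the fold change is
2^-ΔΔCt.  By construction the geometric mean of the control group's fold
changes is exactly 1.  Group comparison uses a two-sided two-sample
Student's t-test on ΔΔCt.

Because ΔCq is inversely related to expression (more template → earlier
amplification → lower Cq), sample stratification into expression
high/low groups is done on −ΔCq via the shared quartile primitive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .stratify import StratifiedGroups, quantile_stratify

logger = logging.getLogger(__name__)

CQ_COLUMNS = ("sample_id", "gene", "cq")


def validate_cq(cq: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format Cq table (sample_id, gene, cq[, is_reference])."""
    missing = [c for c in CQ_COLUMNS if c not in cq.columns]
    if missing:
        raise ValueError(f"Cq table missing columns: {missing}")
    cq = cq.copy()
    cq["gene"] = cq["gene"].astype(str).str.upper()
    cq["cq"] = pd.to_numeric(cq["cq"])
    if (cq["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")
    return cq


def read_cq(path) -> pd.DataFrame:
    return validate_cq(pd.read_csv(path, sep="\t"))


def delta_cq(cq: pd.DataFrame, gene: str, references: list[str]) -> pd.Series:
    """Per-sample ΔCq of ``gene`` against the geometric mean of references.

    Replicate Cq rows are averaged first.  Samples missing the target or
    any reference are dropped with a log message.
    """
    cq = validate_cq(cq)
    gene = gene.upper()
    references = [r.upper() for r in references]
    if not references:
        raise ValueError("at least one reference gene required")
    means = cq.groupby(["sample_id", "gene"])["cq"].mean().unstack()
    needed = [gene] + references
    missing_cols = [g for g in needed if g not in means.columns]
    if missing_cols:
        raise ValueError(f"genes never measured: {missing_cols}")
    complete = means[needed].notna().all(axis=1)
    dropped = list(means.index[~complete])
    if dropped:
        logger.info("delta_cq: dropping %d samples with missing measurements: %s", len(dropped), dropped)
    means = means.loc[complete]
    geo = np.exp(np.log(means[references]).mean(axis=1))
    out = means[gene] - geo
    out.name = f"dCq_{gene}"
    return out


@dataclass
class FoldChangeResult:
    gene: str
    per_sample: pd.DataFrame  # sample_id index; delta_cq, ddct, fold, is_control
    control_mean_dcq: float
    group_means: dict
    group_sds: dict
    t_statistic: float
    p: float


def ddct_fold(dcq: pd.Series, control_ids, gene: str = "") -> FoldChangeResult:
    """2^-ΔΔCt fold changes against the mean ΔCq of a control group.

    The two-sided Student's t-test compares ΔΔCt between the control group
    and the remaining samples.
    """
    control_ids = [c for c in control_ids if c in dcq.index]
    if not control_ids:
        raise ValueError("control group is empty (no ids match)")
    if len(control_ids) == 1:
        warnings.warn("control group has a single sample; no variance estimate", stacklevel=2)
    control_mean = float(dcq.loc[control_ids].mean())
    ddct = dcq - control_mean
    fold = np.power(2.0, -ddct)
    is_control = dcq.index.isin(control_ids)
    df = pd.DataFrame(
        {"delta_cq": dcq, "ddct": ddct, "fold": fold, "is_control": is_control}
    )
    other = ddct[~is_control]
    if len(other) >= 2 and len(control_ids) >= 2:
        t, p = scipy.stats.ttest_ind(other, ddct[is_control])
    else:
        t, p = np.nan, np.nan
    group_means = {
        "control": float(fold[is_control].mean()),
        "other": float(fold[~is_control].mean()) if (~is_control).any() else np.nan,
    }
    group_sds = {
        "control": float(fold[is_control].std(ddof=1)) if is_control.sum() > 1 else np.nan,
        "other": float(fold[~is_control].std(ddof=1)) if (~is_control).sum() > 1 else np.nan,
    }
    return FoldChangeResult(
        gene=gene.upper(),
        per_sample=df,
        control_mean_dcq=control_mean,
        group_means=group_means,
        group_sds=group_sds,
        t_statistic=float(t) if t == t else np.nan,
        p=float(p) if p == p else np.nan,
    )


def stratify_by_dcq(dcq: pd.Series, q: float = 0.25, gene: str = "") -> StratifiedGroups:
    """Quartile split on −ΔCq so the high group has the higher expression."""
    return quantile_stratify(-dcq, q=q, driver_gene=gene)
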
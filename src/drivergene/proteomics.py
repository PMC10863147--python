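"""TMT proteomics arm: QC filtering, GIS-ratio normalization, s0 testing.

Multiplexed TMT experiments arrive as labeled sets, each a protein ×
channel intensity matrix in which one channel is the Global Internal
Standard (GIS, a pooled reference aliquot shared across sets) and some
channels may be normal tissue.  Processing follows the standard
reporter-ion workflow: drop flagged proteins (contaminant, reverse
database hit, only-identified-by-site), divide each channel by the set's
GIS channel, take log2, join the sets on protein identity, discard the
GIS and normal channels, and median-center every remaining sample so its
log2 ratios have median exactly zero.

Group comparison uses an s0-moderated difference statistic
d = (mean_high − mean_low) / (pooled SE + s0): the small positive s0
keeps low-variance proteins from dominating.  The p-value is a
column-label permutation probability (exhaustive when there are at most
8 columns), with BH adjustment to a q-value.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ResultTable
from .diffexp import bh_adjust
from .stratify import StratifiedGroups, quantile_stratify

logger = logging.getLogger(__name__)

QC_FLAGS = ("contaminant", "reverse", "only_identified_by_site")
CHANNEL_ROLES = ("sample", "normal", "gis")


@dataclass
class TMTSet:
    """One labeled set: protein × channel intensities plus channel roles."""

    name: str
    intensities: pd.DataFrame  # proteins × channels, non-negative
    roles: dict[str, str]  # channel -> sample | normal | gis

    def __post_init__(self) -> None:
        if set(self.roles) != set(self.intensities.columns):
            raise ValueError(f"set {self.name}: roles must cover exactly the channels")
        bad = set(self.roles.values()) - set(CHANNEL_ROLES)
        if bad:
            raise ValueError(f"set {self.name}: unknown channel roles {sorted(bad)}")
        if sum(r == "gis" for r in self.roles.values()) != 1:
            raise ValueError(f"set {self.name}: exactly one GIS channel required")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError(f"set {self.name}: negative intensities")

    @property
    def gis_channel(self) -> str:
        return next(c for c, r in self.roles.items() if r == "gis")


@dataclass
class TMTExperiment:
    sets: list[TMTSet]
    flags: pd.DataFrame = field(default_factory=pd.DataFrame)  # protein × QC flag booleans

    def __post_init__(self) -> None:
        if self.flags.empty:
            proteins = sorted({p for s in self.sets for p in s.intensities.index})
            self.flags = pd.DataFrame(False, index=proteins, columns=list(QC_FLAGS))
        missing = [c for c in QC_FLAGS if c not in self.flags.columns]
        if missing:
            warnings.warn(f"missing QC flag columns treated as False: {missing}", stacklevel=2)
            for c in missing:
                self.flags[c] = False


def filter_proteins(exp: TMTExperiment) -> TMTExperiment:
    """Remove proteins with any true QC flag from every set."""
    flagged = exp.flags.index[exp.flags[list(QC_FLAGS)].any(axis=1)]
    for flag in QC_FLAGS:
        logger.info("filter_proteins: %s flags %d proteins", flag, int(exp.flags[flag].sum()))
    new_sets = [
        TMTSet(s.name, s.intensities.drop(index=flagged, errors="ignore"), s.roles)
        for s in exp.sets
    ]
    return TMTExperiment(new_sets, exp.flags.drop(index=flagged))


def gis_normalize(exp: TMTExperiment, join: str = "inner") -> pd.DataFrame:
    """GIS-ratio normalize, log2, join sets and median-center each sample.

    Returns proteins × sample-channels (GIS and normal channels dropped;
    channel names are prefixed by their set name).  Proteins whose GIS
    intensity is zero in a set are dropped from that set, logged.  After
    joining, each column's median is subtracted, so per-sample medians
    are exactly zero.
    """
    per_set = []
    for s in exp.sets:
        gis = s.intensities[s.gis_channel]
        keep = gis > 0
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("gis_normalize: %s drops %d proteins with zero GIS", s.name, n_drop)
        sample_channels = [c for c, r in s.roles.items() if r == "sample"]
        ratios = s.intensities.loc[keep, sample_channels].div(gis[keep], axis=0)
        with np.errstate(divide="ignore"):
            log2r = np.log2(ratios.where(ratios > 0))
        log2r.columns = [f"{s.name}:{c}" for c in sample_channels]
        per_set.append(log2r)
    joined = pd.concat(per_set, axis=1, join=join)
    if join == "inner":
        joined = joined.dropna()
    joined = joined - joined.median(axis=0)
    return joined


def stratify_by_protein(matrix: pd.DataFrame, protein: str, q: float = 0.25) -> StratifiedGroups:
    """Quartile high/low split of samples by one protein's normalized level."""
    if protein not in matrix.index:
        raise KeyError(f"protein {protein!r} not in matrix")
    return quantile_stratify(matrix.loc[protein], q=q, driver_gene=protein)


def _d_stat(high: np.ndarray, low: np.ndarray, s0: float) -> np.ndarray:
    n1, n2 = high.shape[1], low.shape[1]
    diff = high.mean(axis=1) - low.mean(axis=1)
    sp2 = (high.var(axis=1, ddof=1) * (n1 - 1) + low.var(axis=1, ddof=1) * (n2 - 1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return diff / (se + s0)


def sam_s0_test(
    high: pd.DataFrame,
    low: pd.DataFrame,
    s0: float = 0.1,
    nperm: int = 1000,
    seed: int | None = None,
    fdr: float = 0.05,
) -> ResultTable:
    """s0-moderated two-group test with permutation p and BH q-values.

    ``high`` and ``low`` are protein × sample slices of the normalized
    matrix (shared protein index).  With at most 8 total columns the
    permutation null enumerates every column-label assignment; otherwise
    ``nperm`` seeded random assignments are drawn.
    """
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    n1, n2 = high.shape[1], low.shape[1]
    if n1 < 3 or n2 < 3:
        raise ValueError("need >= 3 columns per group")
    if not high.index.equals(low.index):
        low = low.loc[high.index]
    X = np.concatenate([high.to_numpy(dtype=float), low.to_numpy(dtype=float)], axis=1)
    n = n1 + n2
    d_obs = _d_stat(X[:, :n1], X[:, n1:], s0)
    if s0 == 0 and not np.all(np.isfinite(d_obs)):
        raise ValueError("zero pooled SE with s0=0; use s0 > 0")

    if n <= 8:
        assignments = list(itertools.combinations(range(n), n1))
    else:
        rng = np.random.default_rng(seed)
        assignments = [tuple(rng.choice(n, size=n1, replace=False)) for _ in range(nperm)]
    count = np.zeros(X.shape[0])
    for idx in assignments:
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        d_perm = _d_stat(X[:, mask], X[:, ~mask], s0)
        count += np.abs(d_perm) >= np.abs(d_obs) - 1e-12
    p = count / len(assignments)
    q = bh_adjust(np.clip(p, 0, 1))
    df = pd.DataFrame(
        {
            "protein": high.index,
            "mean_diff": X[:, :n1].mean(axis=1) - X[:, n1:].mean(axis=1),
            "d": d_obs,
            "p": np.clip(p, 0, 1),
            "padj": q,
            "significant": q <= fdr,
        }
    )
    params = {
        "s0": s0,
        "fdr": fdr,
        "nperm": len(assignments),
        "exhaustive": n <= 8,
        "seed": seed,
        "n_high": n1,
        "n_low": n2,
    }
    return ResultTable(df, stage="sam_s0_test", params=params)
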
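"""Differential expression, marker detection and driver correlation.

The bulk engine is a native negative-binomial Wald test: counts are
normalized by median-of-ratios size factors, per-gene dispersions are
estimated by method of moments and shrunk in log space toward a fitted
mean–dispersion trend, a log-link NB GLM with a group coefficient is fit
by iteratively reweighted least squares, and the group coefficient is
tested with a Wald z statistic.  Optionally the reported log2 fold change
is a MAP estimate under a zero-centered normal prior (ridge-style
shrinkage), which pulls noisy estimates from low-information genes toward
zero without ever flipping their sign.

Single-cell markers of driver-positive versus driver-negative cells use a
two-sided Wilcoxon rank-sum test: an exact null distribution (computed by
a shift-algorithm convolution over mid-ranks) when both groups have at
most ``EXACT_MAX`` cells, a tie-corrected normal approximation otherwise.

All stages share Benjamini–Hochberg adjustment via :func:`bh_adjust`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, ResultTable
from .stratify import BinaryGroups, StratifiedGroups

_EPS_DISP = 1e-8
#: both groups at or below this size use the exact rank-sum null
EXACT_MAX = 10


def bh_adjust(p: np.ndarray | list[float] | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped to 1, monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values passed to bh_adjust (mask them out first)")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _bh_with_na(p: np.ndarray) -> np.ndarray:
    """BH over the non-NaN entries only; NaN rows get NaN adjusted values."""
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = bh_adjust(p[mask])
    return out


# ---------------------------------------------------------------------------
# Size factors and dispersions
# ---------------------------------------------------------------------------


def size_factors(m: ExpressionMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios normalization factors (one positive scalar per sample).

    The reference profile is the per-gene geometric mean across samples,
    using only genes with no zero anywhere; each sample's factor is the
    median over those genes of count / reference.  When no gene is
    everywhere-positive, ``pseudo_reference=True`` computes the geometric
    mean over the positive entries of genes expressed in at least half the
    samples instead.
    """
    if m.layer != "counts":
        raise ValueError("size_factors expects raw counts")
    counts = m.data.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if all_pos.any():
        ref = np.exp(np.log(counts[all_pos]).mean(axis=1))
        ratios = counts[all_pos] / ref[:, None]
        factors = np.median(ratios, axis=0)
    elif pseudo_reference:
        expressed = (counts > 0).mean(axis=1) >= 0.5
        if not expressed.any():
            raise ValueError("no gene expressed in at least half the samples")
        sub = counts[expressed]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        ref = np.exp(np.nanmean(logs, axis=1))
        ratios = np.where(sub > 0, sub / ref[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        raise ValueError(
            "no gene has positive counts in every sample; "
            "retry with pseudo_reference=True"
        )
    if (factors <= 0).any() or np.isnan(factors).any():
        raise ValueError("non-positive size factor estimated")
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def _moment_dispersions(norm: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Within-group method-of-moments dispersion per gene (var = mu + a mu^2)."""
    means, var_within = [], []
    dfs = 0.0
    pooled_num = np.zeros(norm.shape[0])
    for grp in (0, 1):
        cols = norm[:, x == grp]
        n = cols.shape[1]
        pooled_num += cols.var(axis=1, ddof=1) * (n - 1)
        dfs += n - 1
        means.append(cols.mean(axis=1))
    var_w = pooled_num / dfs
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_w - mu) / mu**2
    alpha[~np.isfinite(alpha)] = _EPS_DISP
    return np.maximum(alpha, _EPS_DISP)


def _shrink_dispersions(
    alpha_mom: np.ndarray, base_mean: np.ndarray, n_samples: int, prior_var: float = 0.25
) -> np.ndarray:
    """Shrink log dispersions toward a fitted a1/mean + a0 trend.

    The trend is fit by robust (Huber) regression of the moment estimates on
    1/mean; each gene's log dispersion is then averaged with the trend using
    a weight derived from the rough sampling variance 2/n of a log
    dispersion estimate against the fixed prior variance.
    """
    ok = (base_mean > 0) & (alpha_mom > _EPS_DISP)
    trend = np.full_like(alpha_mom, max(np.median(alpha_mom), _EPS_DISP))
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
        try:
            import statsmodels.api as sm

            fit = sm.RLM(alpha_mom[ok], X, M=sm.robust.norms.HuberT()).fit()
            a0, a1 = fit.params
        except Exception:  # singular designs on tiny fixtures
            a0, a1 = np.linalg.lstsq(X, alpha_mom[ok], rcond=None)[0]
        a0 = max(a0, _EPS_DISP)
        a1 = max(a1, 0.0)
        with np.errstate(divide="ignore"):
            trend = np.where(base_mean > 0, a0 + a1 / np.maximum(base_mean, 1e-12), a0)
    trend = np.maximum(trend, _EPS_DISP)
    s2_lik = 2.0 / max(n_samples, 3)
    w_trend = s2_lik / (s2_lik + prior_var)
    log_shrunk = (1 - w_trend) * np.log(alpha_mom) + w_trend * np.log(trend)
    return np.exp(log_shrunk)


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

LN2 = math.log(2.0)


@dataclass
class DEResult:
    """Column contract of the differential-expression table."""

    columns = ("gene", "base_mean", "lfc", "lfc_shrunk", "se", "wald_z", "p", "padj", "significant")


def _irls_nb(
    y: np.ndarray, sf: np.ndarray, x: np.ndarray, alpha: np.ndarray, n_iter: int = 60, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-gene NB GLM log mu = log sf + b0 + b1 x.

    Returns (b0, b1, se_b1) in natural-log units.
    """
    n1 = (x == 1).sum()
    n0 = (x == 0).sum()
    pseudo = 0.5
    mean0 = (y[:, x == 0] / sf[x == 0]).mean(axis=1)
    mean1 = (y[:, x == 1] / sf[x == 1]).mean(axis=1)
    b0 = np.log(mean0 + pseudo)
    b1 = np.log(mean1 + pseudo) - b0
    a = alpha[:, None]
    for _ in range(n_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -30, 30)
        mu = sf[None, :] * np.exp(eta)
        W = mu / (1.0 + a * mu)
        z = eta + (y - mu) / mu
        Sw = W.sum(axis=1)
        Sw1 = (W * x).sum(axis=1)
        Swz = (W * z).sum(axis=1)
        Swxz = (W * x * z).sum(axis=1)
        det = Sw1 * (Sw - Sw1)
        det = np.where(det <= 0, np.nan, det)
        new_b1 = (Sw * Swxz - Sw1 * Swz) / det
        new_b0 = (Swz - Swxz) / np.maximum(Sw - Sw1, 1e-300)
        shift = np.nanmax(np.abs(new_b1 - b1)) if len(b1) else 0.0
        b0, b1 = new_b0, new_b1
        if shift < tol:
            break
    eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -30, 30)
    mu = sf[None, :] * np.exp(eta)
    W = mu / (1.0 + a * mu)
    Sw = W.sum(axis=1)
    Sw1 = (W * x).sum(axis=1)
    det = Sw1 * (Sw - Sw1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_b1 = np.sqrt(Sw / det)
    return b0, b1, se_b1


def nb_wald_test(
    m: ExpressionMatrix,
    groups: StratifiedGroups,
    alpha: float = 0.05,
    shrink_lfc: bool = True,
    prior_var_disp: float = 0.25,
) -> ResultTable:
    """Negative-binomial Wald differential expression, high vs low.

    The low group is the control: positive log2 fold changes mean higher
    expression in the driver-high group.  Middle samples are ignored.
    Genes with zero counts everywhere are reported with NaN statistics and
    excluded from the BH denominator.
    """
    if m.layer != "counts":
        raise ValueError("nb_wald_test requires raw counts")
    if len(groups.low_ids) < 3 or len(groups.high_ids) < 3:
        raise ValueError("need >= 3 samples per group")
    cols = list(groups.low_ids) + list(groups.high_ids)
    sub = m.subset_samples(cols)
    x = np.array([0] * len(groups.low_ids) + [1] * len(groups.high_ids))
    sf = size_factors(sub, pseudo_reference=True).to_numpy()
    y = sub.data.to_numpy(dtype=float)
    norm = y / sf[None, :]

    nonzero = y.sum(axis=1) > 0
    base_mean = norm.mean(axis=1)

    alpha_mom = _moment_dispersions(norm, x)
    alpha_hat = _shrink_dispersions(alpha_mom, base_mean, y.shape[1], prior_var_disp)

    b0 = np.full(y.shape[0], np.nan)
    b1 = np.full(y.shape[0], np.nan)
    se = np.full(y.shape[0], np.nan)
    if nonzero.any():
        b0nz, b1nz, senz = _irls_nb(y[nonzero], sf, x, alpha_hat[nonzero])
        b0[nonzero], b1[nonzero], se[nonzero] = b0nz, b1nz, senz

    with np.errstate(invalid="ignore", divide="ignore"):
        wald_z = b1 / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(wald_z))
    p[~np.isfinite(wald_z)] = np.nan
    padj = _bh_with_na(p)

    lfc = b1 / LN2
    se2 = se / LN2
    if shrink_lfc:
        obs = np.abs(lfc[np.isfinite(lfc)])
        scale = np.quantile(obs, 0.95) / scipy.stats.norm.ppf(0.95) if obs.size else 1.0
        scale = max(scale, 1e-3)
        with np.errstate(invalid="ignore"):
            lfc_shrunk = lfc * scale**2 / (scale**2 + se2**2)
    else:
        lfc_shrunk = lfc.copy()

    df = pd.DataFrame(
        {
            "gene": sub.gene_ids,
            "base_mean": base_mean,
            "lfc": lfc,
            "lfc_shrunk": lfc_shrunk,
            "se": se2,
            "wald_z": wald_z,
            "p": p,
            "padj": padj,
            "significant": (padj <= alpha) & ~np.isnan(padj),
        }
    )
    params = {
        "alpha": alpha,
        "shrink_lfc": shrink_lfc,
        "prior_var_disp": prior_var_disp,
        "n_low": len(groups.low_ids),
        "n_high": len(groups.high_ids),
        "control_group": "low",
    }
    return ResultTable(df, stage="nb_wald_test", params=params)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum markers
# ---------------------------------------------------------------------------


def _exact_ranksum_p(pos: np.ndarray, neg: np.ndarray) -> float:
    """Exact two-sided rank-sum p by shift-algorithm convolution.

    Works on doubled mid-ranks (integers even with .5 ties); the p-value is
    the permutation probability of a rank-sum at least as far from its mean
    as observed.
    """
    combined = np.concatenate([pos, neg])
    ranks = scipy.stats.rankdata(combined)
    r2 = np.rint(2 * ranks).astype(int)
    n1 = len(pos)
    w_obs = int(r2[:n1].sum())
    total = int(r2.sum())
    n = len(combined)
    mean2 = n1 * total / n
    dev = abs(w_obs - mean2)

    max_sum = int(np.sort(r2)[::-1][:n1].sum())
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    counts = dp[n1]
    sums = np.arange(max_sum + 1)
    extreme = np.abs(sums - mean2) >= dev - 1e-9
    return float(counts[extreme].sum() / counts.sum())


def wilcoxon_markers(
    m: ExpressionMatrix, groups: BinaryGroups, alpha: float = 0.05
) -> ResultTable:
    """Two-sided Wilcoxon rank-sum marker test, positive vs negative cells.

    Per the protocol the marker cut-off is applied on the RAW p-value
    (``marker`` column: p <= alpha); the BH-adjusted column is reported
    alongside so users can re-threshold.  Genes constant across all cells
    get p = 1 and an undefined direction.
    """
    pos_ids, neg_ids = list(groups.positive_ids), list(groups.negative_ids)
    if len(pos_ids) < 2 or len(neg_ids) < 2:
        raise ValueError("need >= 2 cells in each group")
    pos = m.data[pos_ids].to_numpy(dtype=float)
    neg = m.data[neg_ids].to_numpy(dtype=float)
    mean_pos = pos.mean(axis=1)
    mean_neg = neg.mean(axis=1)
    n_genes = pos.shape[0]
    p = np.ones(n_genes)
    constant = np.array(
        [np.all(row == row[0]) for row in np.concatenate([pos, neg], axis=1)]
    )
    use_exact = len(pos_ids) <= EXACT_MAX and len(neg_ids) <= EXACT_MAX
    if use_exact:
        for g in range(n_genes):
            if not constant[g]:
                p[g] = _exact_ranksum_p(pos[g], neg[g])
    else:
        idx = ~constant
        if idx.any():
            res = scipy.stats.mannwhitneyu(
                pos[idx], neg[idx], axis=1, alternative="two-sided", method="asymptotic"
            )
            p[idx] = res.pvalue
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)
    direction = np.where(mean_pos > mean_neg, "up", "down")
    direction = np.where(constant, "NA", direction)
    df = pd.DataFrame(
        {
            "gene": m.gene_ids,
            "mean_positive": mean_pos,
            "mean_negative": mean_neg,
            "direction": direction,
            "p": p,
            "padj": padj,
            "marker": p <= alpha,
        }
    )
    params = {
        "alpha": alpha,
        "n_positive": len(pos_ids),
        "n_negative": len(neg_ids),
        "exact": use_exact,
        "cutoff_on": "raw_p",
    }
    return ResultTable(df, stage="wilcoxon_markers", params=params)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


def pearson_correlate(m: ExpressionMatrix, driver: str, alpha: float = 0.05) -> ResultTable:
    """Pearson correlation of every gene against the driver gene's profile."""
    driver = driver.upper()
    if driver not in m.data.index:
        raise KeyError(f"driver gene {driver!r} not in matrix")
    n = m.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples")
    d = m.data.loc[driver].to_numpy(dtype=float)
    if np.all(d == d[0]):
        raise ValueError("driver gene has zero variance")
    X = m.data.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    dc = d - d.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (dc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ dc) / denom
    r = np.clip(r, -1.0, 1.0)
    zero_var = (Xc**2).sum(axis=1) == 0
    r[zero_var] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(r)] = np.nan
    p = np.where(np.isnan(p), np.nan, np.clip(p, 0.0, 1.0))
    padj = _bh_with_na(p)
    df = pd.DataFrame(
        {
            "gene": m.gene_ids,
            "coefficient": r,
            "p": p,
            "padj": padj,
            "method": "pearson",
            "stratum": "all",
            "positive_significant": (r > 0) & (p <= alpha),
        }
    )
    df["positive_significant"] = df["positive_significant"].fillna(False)
    return ResultTable(df, stage="pearson_correlate", params={"driver": driver, "alpha": alpha})


def spearman_by_stratum(
    driver: pd.Series, scores: pd.DataFrame, strata: pd.Series, min_n: int = 4
) -> ResultTable:
    """Spearman correlation of signature scores with the driver, per stratum.

    ``scores`` is signature × sample.  Strata with fewer than ``min_n``
    samples are skipped with a warning.
    """
    rows = []
    for stratum in pd.unique(strata):
        ids = strata.index[strata == stratum]
        ids = [i for i in ids if i in driver.index and i in scores.columns]
        if len(ids) < min_n:
            warnings.warn(f"stratum {stratum!r} has {len(ids)} samples; skipped", stacklevel=2)
            continue
        d = driver.loc[ids].to_numpy(dtype=float)
        for sig in scores.index:
            s = scores.loc[sig, ids].to_numpy(dtype=float)
            rho, p = scipy.stats.spearmanr(d, s)
            rows.append({"signature": sig, "stratum": stratum, "coefficient": rho, "p": p})
    df = pd.DataFrame(rows, columns=["signature", "stratum", "coefficient", "p"])
    if len(df):
        df["padj"] = _bh_with_na(df["p"].to_numpy(dtype=float))
    else:
        df["padj"] = pd.Series(dtype=float)
    df["method"] = "spearman"
    return ResultTable(df, stage="spearman_by_stratum", params={"min_n": min_n})
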
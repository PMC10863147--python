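"""Per-sample signature scoring and survival association.

Signature scores follow the GSVA recipe with empirical-CDF statistics:
each gene's expression is converted to its within-gene ECDF value across
samples, genes are re-ranked per sample, and a weighted KS-like random
walk over each sample's ranking (set genes step up by their normalized
symmetric-rank weight, others step down by 1/(N-K)) yields the score —
either the sum of the maximal positive and negative deviations (maxdiff)
or the single signed extreme.

Survival association reproduces the optimal-cutoff workflow: for a gene
or signature, every observed value inside an inner quantile range is a
candidate cutpoint; the standardized two-group log-rank statistic is
maximized over candidates, and the p-value of the maximum is an improved
Bonferroni upper bound over the correlated candidate statistics (the
correlation between nested rank-sum statistics has the closed form
sqrt(m_j (n - m_k) / (m_k (n - m_j)))).  Because a maximally selected
statistic is selection-biased, the bound — not the naive log-rank p of
the chosen split — is what the report carries.

Kaplan-Meier estimation and the two-group log-rank test are delegated to
lifelines behind this module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .core_io import ExpressionMatrix, GeneSetCollection


# ---------------------------------------------------------------------------
# GSVA-style scoring
# ---------------------------------------------------------------------------


def gsva_score(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    tau: float = 1.0,
    variant: str = "maxdiff",
) -> pd.DataFrame:
    """Per-sample gene-set signature scores (signatures × samples).

    Sets with fewer than two member genes present in the matrix are
    skipped with a warning; a set covering every gene has no miss step and
    is an error.
    """
    if variant not in ("maxdiff", "extreme"):
        raise ValueError("variant must be 'maxdiff' or 'extreme'")
    n_samples = m.shape[1]
    if n_samples < 3:
        raise ValueError("gsva_score needs >= 3 samples")
    X = m.data.to_numpy(dtype=float)
    N = X.shape[0]
    genes = np.array(m.gene_ids)

    # per-gene ECDF statistic of each sample across samples
    ecdf = scipy.stats.rankdata(X, axis=1) / n_samples

    # per-sample decreasing ranking of genes; ECDF values tie across genes
    # (multiples of 1/n_samples), so the raw expression value breaks ties —
    # keeping the ordering exactly reversible under decreasing transforms —
    # with the gene symbol as the final deterministic tie-break
    order_key = np.lexsort(
        (genes[None, :].repeat(n_samples, 0), -X.T, -ecdf.T), axis=1
    )
    # order_key[j] = gene indices sorted by decreasing ecdf for sample j
    ranks = np.arange(1, N + 1)
    rank_weight = np.abs(ranks - (N + 1) / 2.0) ** tau

    scores = {}
    for gs in sets:
        member_mask = np.isin(genes, list(gs.genes))
        K = int(member_mask.sum())
        if K < 2:
            warnings.warn(f"set {gs.name!r}: fewer than 2 member genes present; skipped", stacklevel=2)
            continue
        if K == N:
            raise ValueError(f"set {gs.name!r} covers every gene in the matrix")
        miss_step = 1.0 / (N - K)
        per_sample = np.empty(n_samples)
        for j in range(n_samples):
            hit = member_mask[order_key[j]]
            w = rank_weight.copy()
            hit_total = w[hit].sum()
            steps = np.where(hit, w / hit_total, -miss_step)
            walk = np.cumsum(steps)
            if variant == "maxdiff":
                per_sample[j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
            else:
                per_sample[j] = walk[np.argmax(np.abs(walk))]
        scores[gs.name] = per_sample
    return pd.DataFrame(scores, index=m.sample_ids).T


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


@dataclass
class SurvivalFit:
    """Product-limit estimate for one group."""

    label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # NaN when the curve never crosses 0.5

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events, label: str = "") -> SurvivalFit:
    """Kaplan-Meier product-limit estimator (censored-after-events convention)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or "group")
    table = kmf.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    at_risk = table["at_risk"].to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    return SurvivalFit(label=label, times=grid, survival=surv, at_risk=at_risk, median=median)


def logrank_test(group_a: tuple, group_b: tuple) -> tuple[float, float]:
    """Two-group Mantel-Cox log-rank test; returns (chi2, p) with 1 df."""
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Maximally selected log-rank cutoff
# ---------------------------------------------------------------------------


@dataclass
class CutpointResult:
    cutoff: float
    statistic: float  # maximal standardized |log-rank| statistic M
    p: float  # improved-Bonferroni upper bound
    candidate_range: tuple[float, float]
    n_candidates: int = 0
    per_candidate: pd.DataFrame | None = field(default=None, repr=False)


def _logrank_scores(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Log-rank (Peto) scores a_i = event_i − Nelson-Aalen H(t_i), centered."""
    n = len(times)
    order = np.argsort(times, kind="mergesort")
    t_sorted = times[order]
    e_sorted = events[order]
    # cumulative hazard evaluated at each sorted observation (ties share H)
    H = np.zeros(n)
    cum = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        d = e_sorted[i:j].sum()
        at_risk = n - i
        cum += d / at_risk
        H[i:j] = cum
        i = j
    scores_sorted = e_sorted - H
    scores = np.empty(n)
    scores[order] = scores_sorted
    return scores - scores.mean()


def _bivar_tail(b: float, rho: float) -> float:
    """P(|X| >= b, |Y| >= b) for standard bivariate normal with corr rho."""
    rho = float(np.clip(rho, -0.999999, 0.999999))
    mvn = scipy.stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    phi_b = scipy.stats.norm.cdf(b)
    upper_pp = 1.0 - 2.0 * phi_b + mvn.cdf([b, b])
    mvn_neg = scipy.stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, -rho], [-rho, 1.0]])
    upper_pm = 1.0 - 2.0 * phi_b + mvn_neg.cdf([b, b])
    return float(np.clip(2.0 * (upper_pp + upper_pm), 0.0, 1.0))


def _hl_pvalue(b: float, ms: np.ndarray, n: int) -> float:
    """Improved-Bonferroni bound on P(max_k |T_k| >= b) over nested cutpoints.

    ``ms`` are the below-cutoff group sizes of the ordered candidates; the
    correlation of adjacent standardized statistics is
    sqrt(m_{k-1}(n - m_k) / (m_k (n - m_{k-1}))).
    """
    if b <= 0:
        return 1.0
    p1 = 2.0 * scipy.stats.norm.sf(b)
    total = p1
    for k in range(1, len(ms)):
        m_prev, m_k = ms[k - 1], ms[k]
        rho = np.sqrt(m_prev * (n - m_k) / (m_k * (n - m_prev)))
        joint = _bivar_tail(b, rho)
        total += max(0.0, p1 - min(joint, p1))
    return float(np.clip(total, 0.0, 1.0))


def maxstat_cutoff(
    values, times, events, candidate_range: tuple[float, float] = (0.1, 0.9)
) -> CutpointResult:
    """Optimal survival cutpoint by maximally selected log-rank statistics.

    Candidates are the distinct observed values whose below-or-equal group
    proportion falls inside ``candidate_range``.  The returned p-value is
    the improved-Bonferroni upper bound for the maximum of the correlated
    standardized statistics; ties at the maximum resolve to the smallest
    cutoff.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(values)
    if n < 10 or events.sum() < 3:
        raise ValueError("need >= 10 samples with >= 3 events")
    if np.all(values == values[0]):
        raise ValueError("degenerate values: all identical")

    scores = _logrank_scores(times, events)
    ssq = (scores**2).sum()
    if ssq == 0:
        raise ValueError("log-rank scores are degenerate (no usable events)")

    distinct = np.unique(values)
    lo, hi = candidate_range
    stats, cuts, ms = [], [], []
    for c in distinct[:-1]:  # splitting at the max leaves an empty group
        mask = values <= c
        m_ = int(mask.sum())
        if not (lo <= m_ / n <= hi):
            continue
        S = scores[mask].sum()
        var = m_ * (n - m_) / (n * (n - 1)) * ssq
        stats.append(S / np.sqrt(var))
        cuts.append(float(c))
        ms.append(m_)
    if not cuts:
        raise ValueError("no candidate cutoffs inside the quantile range")
    stats_arr = np.abs(np.array(stats))
    best = int(np.argmax(stats_arr))  # argmax returns the first (smallest cutoff) tie
    M = float(stats_arr[best])
    p = _hl_pvalue(M, np.array(ms, dtype=float), n)
    per = pd.DataFrame({"cutoff": cuts, "m_below": ms, "abs_statistic": stats_arr})
    return CutpointResult(
        cutoff=cuts[best],
        statistic=M,
        p=p,
        candidate_range=candidate_range,
        n_candidates=len(cuts),
        per_candidate=per,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class SurvivalReport:
    feature: str
    cutpoint: CutpointResult
    n_high: int
    n_low: int
    fit_high: SurvivalFit
    fit_low: SurvivalFit
    logrank_chi2: float
    logrank_p_naive: float
    p: float  # selection-corrected (improved-Bonferroni) p — the reported one
    driver_comparison_p: float | None
    driver_comparison_flag: str


def survival_by_feature(
    feature_values: pd.Series,
    clinical: pd.DataFrame,
    driver_values: pd.Series | None = None,
    feature_name: str = "",
    is_driver: bool = False,
    candidate_range: tuple[float, float] = (0.1, 0.9),
) -> SurvivalReport:
    """Optimal-cutoff survival association for a gene or signature.

    ``clinical`` needs ``os_time`` and ``os_event`` columns indexed by
    sample id.  The report includes the Kaplan-Meier fits of the two
    groups, the naive log-rank test of the chosen split, the
    selection-corrected p-value, and — when ``driver_values`` is supplied
    — a rank-sum comparison of driver expression between the groups
    (flagged degenerate rather than tested when the feature IS the
    driver, since then high > low by construction).
    """
    ids = [i for i in feature_values.index if i in clinical.index]
    if len(ids) < 10:
        raise ValueError(f"only {len(ids)} samples joinable with clinical data")
    v = feature_values.loc[ids].to_numpy(dtype=float)
    times = clinical.loc[ids, "os_time"].to_numpy(dtype=float)
    events = clinical.loc[ids, "os_event"].to_numpy(dtype=int)

    cp = maxstat_cutoff(v, times, events, candidate_range)
    high = v > cp.cutoff
    fit_high = km_estimate(times[high], events[high], label="high")
    fit_low = km_estimate(times[~high], events[~high], label="low")
    chi2, p_naive = logrank_test((times[high], events[high]), (times[~high], events[~high]))

    if is_driver:
        flag, comp_p = "degenerate: feature is the driver (high > low by construction)", None
    elif driver_values is not None:
        d = driver_values.loc[ids].to_numpy(dtype=float)
        comp_p = float(scipy.stats.mannwhitneyu(d[high], d[~high], alternative="two-sided").pvalue)
        flag = "tested"
    else:
        flag, comp_p = "not available", None

    return SurvivalReport(
        feature=feature_name,
        cutpoint=cp,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        fit_high=fit_high,
        fit_low=fit_low,
        logrank_chi2=chi2,
        logrank_p_naive=p_naive,
        p=cp.p,
        driver_comparison_p=comp_p,
        driver_comparison_flag=flag,
    )
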
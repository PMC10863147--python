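"""Gene-set enrichment: hypergeometric ORA and preranked weighted-KS GSEA.

Over-representation analysis tests each set for overlap with a query list
against a stated universe using the upper-tail hypergeometric probability
P(X >= k).  Preranked GSEA walks the ranked gene list, adding the
normalized |score|^p weight at set members and subtracting 1/(N-K)
elsewhere; the enrichment score is the signed extreme deviation of that
walk.  Significance comes from a gene-label permutation null (the only
well-defined null for a preranked list), with sign-matched mean
normalization for NES and a +1-smoothed empirical p-value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .core_io import GeneSetCollection, ResultTable
from .diffexp import bh_adjust


def ora_hypergeometric(
    query: set[str] | list[str],
    sets: GeneSetCollection,
    universe: set[str] | list[str],
    alpha: float = 0.05,
) -> ResultTable:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Query genes outside the universe are dropped with a warning; set
    members are intersected with the universe before testing.  Sets with
    zero overlap are reported with p = 1.
    """
    universe = {g.upper() for g in universe}
    if len(universe) < 2:
        raise ValueError("universe must contain >= 2 genes")
    query_raw = {g.upper() for g in query}
    query_in = query_raw & universe
    if len(query_in) < len(query_raw):
        warnings.warn(
            f"{len(query_raw) - len(query_in)} query genes outside universe dropped",
            stacklevel=2,
        )
    if not query_in:
        raise ValueError("query is empty after intersecting with the universe")
    N, n = len(universe), len(query_in)
    rows = []
    for gs in sets:
        members = gs.genes & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query_in)
        # P(X >= k) for X ~ Hypergeom(N, K, n); k = 0 gives exactly 1
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set": gs.name,
                "overlap_k": k,
                "set_size_K": K,
                "query_n": n,
                "universe_N": N,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows, columns=["set", "overlap_k", "set_size_K", "query_n", "universe_N", "p"])
    df["padj"] = bh_adjust(df["p"].to_numpy()) if len(df) else pd.Series(dtype=float)
    if len(df):
        df["significant"] = df["padj"] <= alpha
    return ResultTable(df, stage="ora_hypergeometric", params={"alpha": alpha})


def _running_es(weights_hit: np.ndarray, is_hit: np.ndarray, miss_step: float) -> tuple[float, int, np.ndarray]:
    """Signed extreme of the weighted-KS walk; returns (ES, argextreme, walk)."""
    steps = np.where(is_hit, weights_hit, -miss_step)
    walk = np.cumsum(steps)
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i]), i, walk


def gsea_preranked(
    ranked: dict[str, float] | pd.Series,
    sets: GeneSetCollection,
    weight: float = 1.0,
    nperm: int = 1000,
    seed: int | None = None,
    min_size: int = 5,
    alpha: float = 0.05,
) -> ResultTable:
    """Preranked GSEA over a gene → score map.

    Genes are sorted by decreasing score (ties broken by symbol for
    determinism).  Per set, hits add |score|^weight normalized by the
    set's total hit weight and misses subtract 1/(N-K); ES is the signed
    extreme deviation.  NES and the empirical p come from ``nperm``
    seeded gene-label permutations, normalizing by the mean |null ES| of
    matching sign with +1 smoothing.
    """
    s = pd.Series(ranked, dtype=float)
    s.index = s.index.astype(str).str.upper()
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("ranked scores must be finite")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    scores = s.loc[order].to_numpy()
    genes = np.array(order)
    N = len(genes)
    w_all = np.abs(scores) ** weight
    rng = np.random.default_rng(seed)

    rows = []
    leading: dict[str, list[str]] = {}
    for gs in sets:
        members = gs.genes & set(genes)
        K = len(members)
        if K < min_size:
            continue
        if K == N:
            raise ValueError(f"set {gs.name!r} covers every ranked gene")
        is_hit = np.isin(genes, list(members))
        miss_step = 1.0 / (N - K)
        hit_total = w_all[is_hit].sum()
        hit_w = w_all / hit_total if hit_total > 0 else np.full(N, 1.0 / K)
        es, i_ext, walk = _running_es(hit_w, is_hit, miss_step)

        null_es = np.empty(nperm)
        for b in range(nperm):
            perm_hit = np.zeros(N, dtype=bool)
            perm_hit[rng.choice(N, size=K, replace=False)] = True
            tot = w_all[perm_hit].sum()
            hw = w_all / tot if tot > 0 else np.full(N, 1.0 / K)
            null_es[b], _, _ = _running_es(hw, perm_hit, miss_step)

        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        denom = np.abs(same_sign).mean() if len(same_sign) else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        n_extreme = int((np.abs(same_sign) >= abs(es)).sum())
        p = (1 + n_extreme) / (1 + len(same_sign)) if len(same_sign) else 1.0

        if es >= 0:
            lead = [g for g, h in zip(genes[: i_ext + 1], is_hit[: i_ext + 1]) if h]
        else:
            lead = [g for g, h in zip(genes[i_ext:], is_hit[i_ext:]) if h]
        leading[gs.name] = lead
        rows.append(
            {"set": gs.name, "set_size_K": K, "es": es, "nes": nes, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows, columns=["set", "set_size_K", "es", "nes", "p"])
    df["padj"] = bh_adjust(df["p"].to_numpy()) if len(df) else pd.Series(dtype=float)
    if len(df):
        df["significant"] = df["padj"] <= alpha
        df["leading_edge"] = [",".join(leading[name]) for name in df["set"]]
    params = {"weight": weight, "nperm": nperm, "seed": seed, "min_size": min_size, "alpha": alpha}
    return ResultTable(df, stage="gsea_preranked", params=params)
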
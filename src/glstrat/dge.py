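"""Two-group differential expression on counts and preranked GSEA.

Differential expression is a Welch t-test on log2(CPM + pseudo) with a
mean-CPM log2 fold change and BH adjustment — deliberately a light test,
since downstream use is ranking and pre-filtering rather than inference on
individual genes.  Preranked GSEA computes the classic weighted
running-sum enrichment statistic with a gene-label permutation null,
sign-matched NES, and the sign-stratified NES-ratio FDR.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, GeneSetCollection
from .scoring import cpm_normalize

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    counts: CountMatrix, samples_a: list[str], samples_b: list[str], pseudo: float = 1.0
) -> pd.DataFrame:
    """Per-feature log2 fold change (B over A, mean-CPM scale) with Welch p.

    log2FC = log2((meanCPM_B + pseudo) / (meanCPM_A + pseudo)); p from a
    two-sided Welch t-test on log2(CPM + pseudo); q by Benjamini-Hochberg.
    """
    sa, sb = set(samples_a), set(samples_b)
    if sa & sb:
        raise ValueError("groups must be disjoint")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs >= 2 samples (variance undefined otherwise)")
    cpm = cpm_normalize(counts).values
    A = cpm.loc[:, samples_a].to_numpy(dtype=float)
    B = cpm.loc[:, samples_b].to_numpy(dtype=float)
    log2fc = np.log2(B.mean(axis=1) + pseudo) - np.log2(A.mean(axis=1) + pseudo)
    la, lb = np.log2(A + pseudo), np.log2(B + pseudo)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance in both groups, equal means
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q},
        index=pd.Index(counts.feature_ids, name="feature_id"),
    )


def rank_by_logfc(deg: pd.DataFrame) -> pd.Series:
    """Features ordered by descending log2FC, ties broken by feature id."""
    order = deg.sort_index().sort_values("log2fc", ascending=False, kind="stable")
    return order["log2fc"]


def consistent_deg_selection(
    deg_32: pd.DataFrame,
    deg_21: pd.DataFrame,
    up_fc: float = 1.5,
    down_fc: float = 0.7,
    q_max: float = 1e-4,
) -> tuple[list[str], list[str]]:
    """Features consistently up- (FC > up_fc) or down-regulated (FC < down_fc)
    at q < q_max in BOTH the 3-vs-2 and 2-vs-1 comparisons (all strict)."""
    if set(deg_32.index) != set(deg_21.index):
        raise ValueError("DEG tables cover different feature universes")
    d21 = deg_21.reindex(deg_32.index)
    up = (
        (deg_32["log2fc"] > np.log2(up_fc))
        & (deg_32["q"] < q_max)
        & (d21["log2fc"] > np.log2(up_fc))
        & (d21["q"] < q_max)
    )
    down = (
        (deg_32["log2fc"] < np.log2(down_fc))
        & (deg_32["q"] < q_max)
        & (d21["log2fc"] < np.log2(down_fc))
        & (d21["q"] < q_max)
    )
    return list(deg_32.index[up]), list(deg_32.index[down])


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_universe: int
) -> np.ndarray:
    """Signed maximum-deviation enrichment score for each row of hit positions.

    ``positions`` (n_rows x m) are 0-based indices into the descending-ranked
    list, sorted ascending within each row; ``weights`` are the matching
    |score|^w values.  The running sum increments by weight/total at a hit and
    decrements by 1/(N - m) at a miss; extrema can only occur immediately
    before or after a hit.
    """
    n_rows, m = positions.shape
    wsum = weights.sum(axis=1, keepdims=True)
    wsum = np.where(wsum == 0, 1.0, wsum)  # degenerate all-zero scores
    cum = np.cumsum(weights, axis=1) / wsum
    k = np.arange(1, m + 1)
    miss = 1.0 / (n_universe - m)
    after = cum - (positions + 1 - k) * miss
    before = np.concatenate([np.zeros((n_rows, 1)), cum[:, :-1]], axis=1)
    before = before - (positions - (k - 1)) * miss
    # interleave in walk order (before hit 1, after hit 1, before hit 2, ...)
    # so an exact |ES| tie resolves to the extremum reached first
    cand = np.empty((n_rows, 2 * m))
    cand[:, 0::2] = before
    cand[:, 1::2] = after
    # earliest extremum within a small tolerance of the maximum deviation
    # wins, so sign ties (e.g. +-2/7) resolve deterministically despite
    # floating-point accumulation noise
    m_abs = np.abs(cand)
    thresh = m_abs.max(axis=1, keepdims=True) - 1e-9
    idx = np.argmax(m_abs >= thresh, axis=1)
    return cand[np.arange(n_rows), idx]


def gsea_preranked(
    ranked_scores: pd.Series,
    gene_sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a descending-ordered score vector.

    The null distribution permutes set membership over the ranked universe
    (gene-label permutation).  NES = ES / mean |null ES| of matching sign;
    the nominal p is one-sided within sign; FDR q follows the sign-stratified
    NES-ratio procedure of the original method.
    """
    scores = ranked_scores.to_numpy(dtype=float)
    if np.any(np.diff(scores) > 0):
        raise ValueError("ranked_scores must be sorted descending")
    universe = list(ranked_scores.index)
    pos_of = {g: i for i, g in enumerate(universe)}
    N = len(universe)
    w_all = np.abs(scores) ** weight
    rng = np.random.default_rng(seed)

    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name in gene_sets.names():
        members = sorted(gene_sets[name] & set(universe))
        m = len(members)
        if m < 2:
            logger.warning("set %r has %d members in the universe; skipped", name, m)
            continue
        if m >= N:
            logger.warning("set %r covers the whole universe; skipped", name)
            continue
        obs_pos = np.sort(np.asarray([pos_of[g] for g in members]))
        es = float(_es_from_positions(obs_pos[None, :], w_all[obs_pos][None, :], N)[0])

        # gene-label permutation null: random size-m subsets of the universe
        keys = rng.random((n_perm, N))
        perm_pos = np.sort(np.argpartition(keys, m - 1, axis=1)[:, :m], axis=1)
        null_es = _es_from_positions(perm_pos, w_all[perm_pos], N)

        pos_null = null_es[null_es >= 0]
        neg_null = null_es[null_es < 0]
        if es >= 0:
            denom = pos_null.mean() if len(pos_null) else np.nan
            nominal_p = (np.sum(pos_null >= es) + 1) / (len(pos_null) + 1)
        else:
            denom = np.abs(neg_null).mean() if len(neg_null) else np.nan
            nominal_p = (np.sum(neg_null <= es) + 1) / (len(neg_null) + 1)
        nes = es / denom if denom and not np.isnan(denom) else np.nan
        null_nes = np.concatenate(
            [
                pos_null / pos_null.mean() if len(pos_null) else np.empty(0),
                -np.abs(neg_null) / np.abs(neg_null).mean() if len(neg_null) else np.empty(0),
            ]
        )
        null_nes_pool.append(null_nes)
        rows.append({"set": name, "size": m, "es": es, "nes": nes, "p": nominal_p})

    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "es", "nes", "p", "q"]
    )
    if len(out):
        pooled = np.concatenate(null_nes_pool)
        obs_nes = out["nes"].to_numpy()
        qs = np.empty(len(out))
        for i, nes in enumerate(obs_nes):
            if np.isnan(nes):
                qs[i] = np.nan
                continue
            if nes >= 0:
                null_frac = np.mean(pooled[pooled >= 0] >= nes) if (pooled >= 0).any() else 0.0
                obs_frac = np.mean(obs_nes[obs_nes >= 0] >= nes)
            else:
                null_frac = np.mean(pooled[pooled < 0] <= nes) if (pooled < 0).any() else 0.0
                obs_frac = np.mean(obs_nes[obs_nes < 0] <= nes)
            qs[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan
        out["q"] = qs
    return out
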
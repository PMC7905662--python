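"""Survival curves and the statistical tests used to characterize clusters.

Kaplan-Meier estimation and the k-group log-rank test are delegated to
lifelines; Kruskal-Wallis and Fisher's exact test to scipy.  Dunn's post hoc
pairwise test and the ANOVA effect-size screen are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class SurvivalFit:
    """Product-limit survival estimate for one group."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    group: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(times, events, group: str = "") -> SurvivalFit:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be binary")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    return SurvivalFit(timeline, survival, at_risk, group)


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi2, df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("log-rank test needs >= 2 non-empty groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    res = multivariate_logrank_test(times, groups, events)
    df = len(uniq) - 1
    return float(res.test_statistic), df, float(res.p_value)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction, chi-square p."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if (counts == 0).any() or len(uniq) < 2:
        raise ValueError("need >= 2 non-empty groups")
    samples = [values[groups == g] for g in uniq]
    if np.all(values == values[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*samples)
    return float(H), float(p)


def dunn_posthoc(values, groups, adjust: str = "fdr_bh") -> pd.DataFrame:
    """Dunn's pairwise z-tests on rank means with tie-corrected variance.

    Returns a table with one row per group pair: z, raw p, adjusted p.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    N = len(values)
    ranks = sps.rankdata(values)
    # tie correction term
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))
    var_unit = N * (N + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[groups == g].mean() for g in uniq}
    ns = {g: (groups == g).sum() for g in uniq}
    rows = []
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            se = np.sqrt(var_unit * (1.0 / ns[a] + 1.0 / ns[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p"], method=adjust)[1]
    return out


@dataclass
class EnrichmentResult:
    feature_id: str
    a: int  # in-focus mutated
    b: int  # in-focus wild-type
    c: int  # out-of-focus mutated
    d: int  # out-of-focus wild-type
    odds_ratio: float
    p: float
    enriched_in: object
    note: str = ""


def fisher_enrichment(
    binary_matrix: pd.DataFrame, labels: pd.Series, focus, p_max: float = 0.01
) -> list[EnrichmentResult]:
    """Two-sided Fisher's exact test of each binary feature vs focus cluster.

    Returns features with p strictly below ``p_max``; constant features are
    retained with p = 1 and a note.  Direction is recorded via the odds
    ratio (> 1 means enriched in the focus cluster).
    """
    samples = [s for s in binary_matrix.columns if s in set(labels.index)]
    lab = labels.loc[samples].to_numpy()
    M = binary_matrix.loc[:, samples].to_numpy()
    in_focus = lab == focus
    if in_focus.sum() == 0 or (~in_focus).sum() == 0:
        raise ValueError("focus cluster or its complement is empty")
    results = []
    for i, feat in enumerate(binary_matrix.index):
        mut = M[i].astype(bool)
        a = int(np.sum(mut & in_focus))
        b = int(np.sum(~mut & in_focus))
        c = int(np.sum(mut & ~in_focus))
        d = int(np.sum(~mut & ~in_focus))
        note = ""
        if mut.all() or (~mut).all():
            p, odds = 1.0, np.nan
            note = "constant feature"
        else:
            odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if p < p_max or note:
            results.append(
                EnrichmentResult(str(feat), a, b, c, d, float(odds), float(p), focus, note)
            )
    return results


def anova_effect_screen(
    values_matrix: pd.DataFrame,
    labels: pd.Series,
    es_min: float = 0.5,
    p_max: float | None = None,
    effect: str = "cohen_f",
) -> pd.DataFrame:
    """One-way ANOVA per feature with an effect-size selection screen.

    ``effect`` is one of ``cohen_f`` (default), ``eta_squared``, or
    ``max_cohen_d`` (largest pairwise standardized mean difference).
    Selection keeps features with effect size strictly above ``es_min`` and,
    when ``p_max`` is given, p strictly below it.  Features with zero
    within-group variance everywhere have infinite effect size and are
    flagged.
    """
    if effect not in ("cohen_f", "eta_squared", "max_cohen_d"):
        raise ValueError(f"unknown effect-size statistic {effect!r}")
    samples = [s for s in values_matrix.columns if s in set(labels.index)]
    lab = labels.loc[samples].to_numpy()
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    V = values_matrix.loc[:, samples].to_numpy(dtype=float)
    rows = []
    for i, feat in enumerate(values_matrix.index):
        v = V[i]
        groups = [v[lab == g] for g in uniq]
        grand = v.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        sst = ssb + ssw
        if ssw == 0:
            eta2 = 1.0 if ssb > 0 else 0.0
            F, p, es = np.inf if ssb > 0 else 0.0, 0.0 if ssb > 0 else 1.0, np.inf if ssb > 0 else 0.0
            flagged = ssb > 0
        else:
            F, p = sps.f_oneway(*groups)
            eta2 = ssb / sst if sst > 0 else 0.0
            flagged = False
            if effect == "eta_squared":
                es = eta2
            elif effect == "cohen_f":
                es = np.sqrt(eta2 / (1.0 - eta2)) if eta2 < 1 else np.inf
            else:
                es = _max_pairwise_d(groups)
        if effect == "eta_squared" and ssw == 0:
            es = eta2
        selected = bool(es > es_min) and (p_max is None or bool(p < p_max))
        rows.append(
            {
                "feature_id": str(feat),
                "F": float(F),
                "p": float(p),
                "effect_size": float(es),
                "selected": selected,
                "zero_within_variance": bool(flagged),
            }
        )
    columns = ["feature_id", "F", "p", "effect_size", "selected", "zero_within_variance"]
    return pd.DataFrame(rows, columns=columns).set_index("feature_id")


def _max_pairwise_d(groups: list[np.ndarray]) -> float:
    best = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            na, nb = len(a), len(b)
            pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            if pooled == 0:
                if a.mean() != b.mean():
                    return np.inf
                continue
            best = max(best, abs(a.mean() - b.mean()) / np.sqrt(pooled))
    return best
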
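"""Normalization, expression filtering, and rank-based per-sample scoring.

Houses CPM normalization, the expressed-gene filter, single-sample GSEA
(ssGSEA) scoring of gene sets, immune-infiltration scoring over marker sets,
analytic rank-based (aREA-style) TF activity, and the cytoplasm/nucleus
relative concentration index (RCI).

All scores are rank-based within a sample, so they are invariant under any
strictly monotone transform of that sample's expression values; in particular
scoring raw CPM and log CPM gives identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CountMatrix, GeneSetCollection, RegulonCollection

logger = logging.getLogger(__name__)

CPM = "cpm"
LOG2CPM = "log2cpm"


class ScoringError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Feature x sample matrix of CPM (or log2(CPM+1)) values with a scale tag."""

    values: pd.DataFrame
    scale: str = CPM

    def __post_init__(self) -> None:
        if self.scale not in (CPM, LOG2CPM):
            raise ScoringError(f"unknown scale tag {self.scale!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def log2(self, pseudo: float = 1.0) -> "ExpressionMatrix":
        if self.scale == LOG2CPM:
            return self
        return ExpressionMatrix(np.log2(self.values + pseudo), LOG2CPM)


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------


def cpm_normalize(counts: CountMatrix) -> ExpressionMatrix:
    """Counts-per-million normalization: count / library size * 1e6."""
    lib = counts.values.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero) > 0:
        raise ScoringError(f"sample {zero.index[0]!r} has zero library size")
    cpm = counts.values / lib * 1e6
    return ExpressionMatrix(cpm.astype(float), CPM)


def expression_filter(
    counts: CountMatrix, min_count: int = 10, min_fraction: float = 0.9
) -> list[str]:
    """Features with count > ``min_count`` in strictly more than
    ``min_fraction`` of samples (both inequalities strict)."""
    if counts.values.size == 0:
        raise ScoringError("empty count matrix")
    frac = (counts.values > min_count).mean(axis=1)
    return list(counts.values.index[frac > min_fraction])


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------


def _ssgsea_raw(
    values: pd.DataFrame, member_mask: np.ndarray, weight_exponent: float
) -> np.ndarray:
    """Barbie-style integrated ECDF-difference score, one value per sample.

    Per sample: features are ranked by expression (ascending ranks, average
    ties); the score is the sum over the descending-ranked list of the
    difference between the weighted in-set ECDF (weights = rank^exponent) and
    the unweighted out-of-set ECDF.
    """
    arr = values.to_numpy(dtype=float)
    n_features, n_samples = arr.shape
    m = int(member_mask.sum())
    out = np.empty(n_samples)
    for j in range(n_samples):
        ranks = rankdata(arr[:, j], method="average")
        # descending expression; ties broken by feature order for determinism
        order = np.lexsort((np.arange(n_features), -ranks))
        in_set = member_mask[order]
        w = ranks[order] ** weight_exponent
        w_hit = np.where(in_set, w, 0.0)
        p_in = np.cumsum(w_hit) / w_hit.sum()
        p_out = np.cumsum(~in_set) / (n_features - m)
        out[j] = np.sum(p_in - p_out)
    return out


def ssgsea_score(
    expr: ExpressionMatrix,
    gene_set: set[str],
    weight_exponent: float = 0.25,
    normalize: bool = True,
    score_name: str = "score",
) -> pd.Series:
    """Single-sample GSEA enrichment score of one gene set per sample.

    With ``normalize`` the raw scores are divided by their range across the
    samples (the convention of range-normalized ssGSEA output); scores of a
    single sample, or of samples with identical scores, are left unscaled.
    """
    members = [f for f in expr.feature_ids if f in gene_set]
    if len(members) < 2:
        raise ScoringError(
            f"gene set has {len(members)} members in the expression universe; need >= 2"
        )
    if len(members) == len(expr.feature_ids):
        raise ScoringError("gene set equals the expression universe (empty complement)")
    mask = np.asarray([f in gene_set for f in expr.feature_ids])
    raw = _ssgsea_raw(expr.values, mask, weight_exponent)
    if normalize:
        rng_ = raw.max() - raw.min()
        if rng_ > 0:
            raw = raw / rng_
    return pd.Series(raw, index=expr.sample_ids, name=score_name)


class GeneSetScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping a samples x features matrix to samples x gene-set
    ssGSEA scores.  Stateless apart from validated parameters."""

    def __init__(self, gene_sets=None, weight_exponent: float = 0.25, normalize: bool = True):
        self.gene_sets = gene_sets
        self.weight_exponent = weight_exponent
        self.normalize = normalize

    def fit(self, X, y=None):
        if not self.gene_sets:
            raise ScoringError("gene_sets must be provided")
        self.feature_names_in_ = np.asarray(X.columns if hasattr(X, "columns") else [])
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(X, "columns"):
            raise ScoringError("GeneSetScorer requires a DataFrame with feature columns")
        expr = ExpressionMatrix(X.T.astype(float), CPM)
        sets = self.gene_sets.sets if isinstance(self.gene_sets, GeneSetCollection) else self.gene_sets
        cols = {}
        for name, members in sets.items():
            cols[name] = ssgsea_score(
                expr, members, self.weight_exponent, self.normalize, score_name=name
            )
        return pd.DataFrame(cols)


def immune_infiltration_scores(
    expr: ExpressionMatrix,
    marker_sets: GeneSetCollection,
    weight_exponent: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-cell-type ssGSEA infiltration scores (cell type x sample)."""
    rows = {}
    for cell_type in marker_sets.names():
        try:
            rows[cell_type] = ssgsea_score(
                expr,
                marker_sets[cell_type],
                weight_exponent,
                normalize,
                score_name=cell_type,
            )
        except ScoringError as exc:
            raise ScoringError(f"marker set {cell_type!r}: {exc}") from exc
    if not rows:
        return pd.DataFrame(index=[], columns=expr.sample_ids, dtype=float)
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# aREA-style TF activity
# ---------------------------------------------------------------------------


def area_tf_activity(
    expr: ExpressionMatrix, regulons: RegulonCollection, min_targets: int = 5
) -> pd.DataFrame:
    """Analytic rank-based TF activity (TF x sample).

    Within each sample, feature ranks are mapped to standard-normal quantiles
    q_i = Phi^-1(rank_i / (n + 1)); a regulon of m targets with modes s_t
    scores (sum_t s_t q_t) / sqrt(m), approximately N(0, 1) under exchangeable
    ranks.  Regulons with fewer than ``min_targets`` present targets are
    skipped with a warning.
    """
    arr = expr.values.to_numpy(dtype=float)
    n_features, n_samples = arr.shape
    ranks = np.empty_like(arr)
    for j in range(n_samples):
        ranks[:, j] = rankdata(arr[:, j], method="average")
    quantiles = norm.ppf(ranks / (n_features + 1))
    index = {f: i for i, f in enumerate(expr.feature_ids)}

    rows, names = [], []
    for tf in regulons.names():
        present = [(index[t], mode) for t, mode in regulons[tf] if t in index]
        if len(present) < min_targets:
            logger.warning(
                "regulon %r has %d present targets (< %d); skipped", tf, len(present), min_targets
            )
            continue
        idx = np.asarray([i for i, _ in present])
        modes = np.asarray([m for _, m in present], dtype=float)
        rows.append(modes @ quantiles[idx, :] / np.sqrt(len(present)))
        names.append(tf)
    return pd.DataFrame(rows, index=names, columns=expr.sample_ids)


# ---------------------------------------------------------------------------
# relative concentration index
# ---------------------------------------------------------------------------


def rci(
    cyt: ExpressionMatrix, nuc: ExpressionMatrix, pseudo: float = 1.0
) -> pd.Series:
    """Relative concentration index per feature.

    RCI = log2((mean cytoplasmic CPM + pseudo) / (mean nuclear CPM + pseudo)).
    Positive values indicate cytoplasm-biased transcripts, negative nuclear.
    """
    if list(cyt.feature_ids) != list(nuc.feature_ids):
        raise ScoringError("cytoplasmic and nuclear matrices have mismatched features")
    if cyt.scale != CPM or nuc.scale != CPM:
        raise ScoringError("RCI requires cpm-tagged matrices")
    c = cyt.values.mean(axis=1)
    u = nuc.values.mean(axis=1)
    return pd.Series(
        np.log2((c + pseudo) / (u + pseudo)), index=cyt.feature_ids, name="rci"
    )
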
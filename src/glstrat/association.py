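"""Correlation-based lncRNA selection and partial-correlation linkage.

Implements per-feature Pearson association of expression with a per-sample
score (BH-adjusted), threshold selection of glycolysis-associated lncRNAs,
the first-order partial correlation used to remove a conditioning lncRNA's
effect, the Kolmogorov-Smirnov comparison of raw vs adjusted correlation
distributions, and the covariate-adjusted (CNV + methylation) multivariate
linear association.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """A correlation is +/-1, making conditioning undefined."""


# ---------------------------------------------------------------------------
# Pearson association with FDR
# ---------------------------------------------------------------------------


def pearson_with_fdr(
    score: pd.Series, expr: pd.DataFrame, features: list[str] | None = None
) -> pd.DataFrame:
    """Per-feature Pearson r of expression against a per-sample score.

    Two-sided p-values use the exact t-distribution with n-2 df; q is
    Benjamini-Hochberg across tested features.  Zero-variance features get
    r = NaN and are excluded from the BH adjustment.
    """
    if features is None:
        features = list(expr.index)
    samples = [s for s in expr.columns if s in set(score.index)]
    if len(samples) < 4:
        raise ValueError(f"need >= 4 aligned samples, have {len(samples)}")
    x = score.loc[samples].to_numpy(dtype=float)
    F = expr.loc[features, samples].to_numpy(dtype=float)
    n = len(samples)

    xc = x - x.mean()
    Fc = F - F.mean(axis=1, keepdims=True)
    xnorm = np.sqrt((xc**2).sum())
    fnorm = np.sqrt((Fc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Fc @ xc) / (fnorm * xnorm)
    r = np.clip(r, -1.0, 1.0)
    zero_var = fnorm == 0
    if xnorm == 0:
        zero_var[:] = True
    r[zero_var] = np.nan
    if zero_var.any():
        logger.warning("%d zero-variance features excluded from BH", zero_var.sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p[np.isnan(r)] = np.nan

    q = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    return pd.DataFrame(
        {"r": r, "p": p, "q": q, "n": n}, index=pd.Index(features, name="feature_id")
    )


def select_associated_features(
    table: pd.DataFrame, r_min: float = 0.3, q_max: float = 0.05
) -> pd.DataFrame:
    """Features with |r| strictly above ``r_min`` and q strictly below
    ``q_max``, annotated with the correlation sign."""
    keep = (table["r"].abs() > r_min) & (table["q"] < q_max)
    keep = keep.fillna(False)
    out = table.loc[keep].copy()
    out["sign"] = np.sign(out["r"]).astype(int)
    return out


# backwards-friendly alias matching the analysis vocabulary
select_glycolysis_lncrnas = select_associated_features


# ---------------------------------------------------------------------------
# first-order partial correlation
# ---------------------------------------------------------------------------


def partial_corr_from_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y given z from pairwise r's:

        r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))
    """
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise DegenerateInputError(
            "conditioning variable perfectly correlated with x or y"
        )
    denom = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    return float((r_xy - r_xz * r_yz) / denom)


def first_order_partial_correlation(x, y, z) -> float:
    """Partial correlation of aligned vectors x and y conditioned on z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(x) == len(y) == len(z)):
        raise ValueError("x, y, z must be aligned on identical samples")
    if len(x) < 4:
        raise ValueError("need n >= 4 samples")
    r_xy = _pearson(x, y)
    r_xz = _pearson(x, z)
    r_yz = _pearson(y, z)
    return partial_corr_from_r(r_xy, r_xz, r_yz)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    if denom == 0:
        raise DegenerateInputError("zero-variance input to Pearson correlation")
    return float(np.clip((ac * bc).sum() / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# KS comparison of raw vs lncRNA-adjusted correlation distributions
# ---------------------------------------------------------------------------


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS test requires non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def partial_correlation_shift(
    score: pd.Series, gene_exprs: pd.DataFrame, lnc_expr: pd.Series
) -> dict:
    """Raw vs lncRNA-adjusted correlations of genes with the glycolysis score.

    For every gene y in ``gene_exprs`` (rows = genes, pre-restricted by the
    caller to score-associated genes), computes the raw Pearson r(score, y)
    and the first-order partial correlation conditioning on the lncRNA, then
    compares the two coefficient distributions with a two-sample KS test.
    """
    samples = [s for s in gene_exprs.columns if s in set(score.index) and s in set(lnc_expr.index)]
    x = score.loc[samples].to_numpy(dtype=float)
    z = lnc_expr.loc[samples].to_numpy(dtype=float)
    G = gene_exprs.loc[:, samples].to_numpy(dtype=float)
    if G.shape[0] < 10:
        logger.warning("fewer than 10 genes supplied; KS comparison is weak")
    r_xz = _pearson(x, z)
    raw = np.empty(G.shape[0])
    adjusted = np.empty(G.shape[0])
    for i in range(G.shape[0]):
        y = G[i]
        r_xy = _pearson(x, y)
        r_yz = _pearson(y, z)
        raw[i] = r_xy
        adjusted[i] = partial_corr_from_r(r_xy, r_xz, r_yz)
    D, p = ks_two_sample(raw, adjusted)
    return {
        "raw": pd.Series(raw, index=gene_exprs.index, name="r"),
        "adjusted": pd.Series(adjusted, index=gene_exprs.index, name="r_adjusted"),
        "ks_statistic": D,
        "ks_p": p,
    }


# ---------------------------------------------------------------------------
# covariate-adjusted multivariate association
# ---------------------------------------------------------------------------


def multivariate_adjusted_association(
    gene_exprs: pd.DataFrame,
    lnc_expr: pd.Series,
    cnv_row: pd.Series,
    meth_row: pd.Series,
    coef_min: float = 0.3,
    q_max: float = 1e-6,
) -> pd.DataFrame:
    """Per-gene lncRNA coefficient adjusted for CNV and methylation.

    All variables are standardized to unit variance before fitting
    gene ~ lncRNA + cnv + methylation by least squares, so the lncRNA
    coefficient is on a partial-correlation-like scale comparable to an
    |r| > 0.3 threshold.  p is the coefficient's t-test; q is BH across
    genes; ``selected`` applies strict |coef| > coef_min and q < q_max.
    """
    samples = [
        s
        for s in gene_exprs.columns
        if s in set(lnc_expr.index) and s in set(cnv_row.index) and s in set(meth_row.index)
    ]
    n = len(samples)
    if n <= 5:
        raise ValueError("need n > 5 aligned samples")

    def standardize(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError("zero-variance covariate")
        return (v - v.mean()) / sd

    z = standardize(lnc_expr.loc[samples].to_numpy(dtype=float))
    c = standardize(cnv_row.loc[samples].to_numpy(dtype=float))
    m = standardize(meth_row.loc[samples].to_numpy(dtype=float))
    X = np.column_stack([np.ones(n), z, c, m])
    cond = np.linalg.cond(X)
    if cond > 1e8:
        corr = np.corrcoef(np.column_stack([z, c, m]), rowvar=False)
        names = ["lncRNA", "cnv", "methylation"]
        iu = np.triu_indices(3, k=1)
        worst = np.argmax(np.abs(corr[iu]))
        pair = (names[iu[0][worst]], names[iu[1][worst]])
        raise ValueError(f"collinear covariates (condition number {cond:.2e}): {pair}")

    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    G = gene_exprs.loc[:, samples].to_numpy(dtype=float)
    G = (G - G.mean(axis=1, keepdims=True)) / G.std(axis=1, ddof=1, keepdims=True)
    betas = H @ G.T  # 4 x genes
    resid = G.T - X @ betas
    df = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    coef = betas[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"coefficient": coef, "p": p, "q": q, "n": n}, index=gene_exprs.index
    )
    out["selected"] = (out["coefficient"].abs() > coef_min) & (out["q"] < q_max)
    return out
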
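"""Negative-binomial differential expression for count matrices.

Implements median-of-ratios size factors, method-of-moments dispersion with
trend shrinkage, a per-feature NB GLM Wald test (log link, two-group design
with optional pair covariates), Benjamini-Hochberg adjustment, and the
per-layer calling rules (gene/miRNA: adjusted p < 0.05 and |log2FC| > 1;
circRNA: adjusted p < 0.05 plus a junction-read support rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LAYERS = ("gene", "circ", "mirna")

P_ADJ_CUTOFF = 0.05
LFC_CUTOFF = 1.0
JUNCTION_MIN_READS = 2
JUNCTION_MIN_SAMPLES = 2


def size_factors(counts: np.ndarray | pd.DataFrame, allow_pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios per-sample scaling factors, rescaled to geometric mean 1.

    Uses features with all-positive counts as the reference set.  If none
    exist, raises unless ``allow_pseudo_reference`` is set, in which case
    features positive in every sample after adding 0.5 are used.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("counts must be a 2-D features x samples matrix")
    if (x < 0).any():
        raise ValueError("negative counts")
    positive = (x > 0).all(axis=1)
    if not positive.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no feature with all-positive counts; rerun with "
                "allow_pseudo_reference=True to use a 0.5-pseudocount reference"
            )
        x = x + 0.5
        positive = np.ones(x.shape[0], dtype=bool)
    ref = x[positive]
    log_geomean = np.log(ref).mean(axis=1)
    log_ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def _dispersion_trend(mean: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Fit alpha_tr(mu) = a1/mu + a0 by least squares on usable features."""
    use = (mean > 0) & np.isfinite(alpha_mom)
    if use.sum() < 2:
        return 0.0, float(np.nanmedian(alpha_mom[use])) if use.any() else 0.0
    X = np.column_stack([1.0 / mean[use], np.ones(use.sum())])
    coef, *_ = np.linalg.lstsq(X, alpha_mom[use], rcond=None)
    a1, a0 = float(coef[0]), float(coef[1])
    return max(a1, 0.0), max(a0, 0.0)


def estimate_dispersion(
    counts: np.ndarray | pd.DataFrame,
    factors: np.ndarray,
    condition: np.ndarray | None = None,
    prior_df: float = 25.0,
) -> np.ndarray:
    """Per-feature NB dispersion: method-of-moments estimate shrunk toward a
    fitted mean-dispersion trend by precision-weighted averaging.

    All-zero features get NaN (flagged, excluded from testing downstream).
    When ``condition`` is given the moments are pooled within groups so a
    real fold change does not inflate the estimate.
    """
    x = np.asarray(counts, dtype=float) / np.asarray(factors, dtype=float)[None, :]
    n = x.shape[1]
    if n < 4:
        raise ValueError("need >= 2 samples per group")
    if condition is None:
        mean = x.mean(axis=1)
        var = x.var(axis=1, ddof=1)
    else:
        condition = np.asarray(condition)
        groups = [x[:, condition == g] for g in np.unique(condition)]
        mean = np.mean([g.mean(axis=1) for g in groups], axis=0)
        # pooled within-group variance
        dfs = np.array([g.shape[1] - 1 for g in groups], dtype=float)
        var = sum((g.var(axis=1, ddof=1) * (g.shape[1] - 1) for g in groups)) / dfs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var - mean) / mean**2
    alpha_mom = np.where(mean > 0, np.maximum(alpha_mom, 0.0), np.nan)
    a1, a0 = _dispersion_trend(mean, alpha_mom)
    with np.errstate(divide="ignore"):
        alpha_tr = np.where(mean > 0, a1 / mean + a0, np.nan)
    resid_df = float(n - 2)
    shrunk = (resid_df * alpha_mom + prior_df * alpha_tr) / (resid_df + prior_df)
    return np.where(np.isnan(alpha_mom), np.nan, shrunk)


def _irls_nb(
    Y: np.ndarray,
    X: np.ndarray,
    alpha: np.ndarray,
    log_sf: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-feature NB GLMs sharing one design matrix.

    Returns (beta, se_last_coef); the coefficient of interest is the last
    design column.
    """
    m, n = Y.shape
    p = X.shape[1]
    alpha = np.where(np.isfinite(alpha), np.maximum(alpha, 1e-8), 1e-8)[:, None]

    # init: intercept at log of mean normalized count, 0 elsewhere
    beta = np.zeros((m, p))
    norm_mean = np.maximum((Y / np.exp(log_sf)[None, :]).mean(axis=1), 1e-8)
    beta[:, 0] = np.log(norm_mean)

    ridge = 1e-6 * np.eye(p)
    for _ in range(max_iter):
        eta = beta @ X.T + log_sf[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - log_sf[None, :]) + (Y - mu) / mu
        A = np.einsum("ni,mn,nj->mij", X, W, X) + ridge[None, :, :]
        b = np.einsum("ni,mn,mn->mi", X, W, z)
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.abs(new_beta - beta).max()
        beta = new_beta
        if delta < tol:
            break
    eta = np.clip(beta @ X.T + log_sf[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha * mu)
    A = np.einsum("ni,mn,nj->mij", X, W, X) + 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(A)
    se = np.sqrt(np.maximum(cov[:, -1, -1], 0.0))
    return beta, se


def nb_wald_test(
    counts: pd.DataFrame,
    factors: np.ndarray,
    alpha: np.ndarray,
    condition: np.ndarray,
    pairs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-feature NB Wald test of the tumor-vs-normal coefficient.

    ``condition`` is 0/1 (1 = tumor); ``pairs`` optionally adds pair
    indicator covariates.  Returns a frame with baseMean, log2FC, SE, p.
    Features that are all-zero (or have undefined dispersion) get
    log2FC = 0, p = 1 and ``tested`` = False.
    """
    from scipy import stats

    Y = counts.to_numpy(dtype=float)
    condition = np.asarray(condition, dtype=float)
    for g in (0.0, 1.0):
        if (condition == g).sum() < 2:
            raise ValueError("each group needs n >= 2")
    cols = [np.ones_like(condition)]
    if pairs is not None:
        pairs = np.asarray(pairs)
        uniq = np.unique(pairs)
        for pid in uniq[1:]:  # drop first level for identifiability
            cols.append((pairs == pid).astype(float))
    cols.append(condition)
    X = np.column_stack(cols)

    testable = ~np.isnan(alpha) & (Y.sum(axis=1) > 0)
    log_sf = np.log(np.asarray(factors, dtype=float))

    log2fc = np.zeros(Y.shape[0])
    se_l2 = np.full(Y.shape[0], np.nan)
    pvals = np.ones(Y.shape[0])
    if testable.any():
        beta, se = _irls_nb(Y[testable], X, alpha[testable], log_sf)
        ln2 = np.log(2.0)
        lfc = beta[:, -1] / ln2
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, beta[:, -1] / se, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        log2fc[testable] = lfc
        se_l2[testable] = se / ln2
        pvals[testable] = p

    base_mean = (Y / np.exp(log_sf)[None, :]).mean(axis=1)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "SE": se_l2,
            "p": pvals,
            "tested": testable,
        },
        index=counts.index,
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def call_de(
    result: pd.DataFrame,
    layer: str,
    counts: pd.DataFrame | None = None,
    p_adj_cutoff: float = P_ADJ_CUTOFF,
    lfc_cutoff: float = LFC_CUTOFF,
    junction_min_reads: int = JUNCTION_MIN_READS,
    junction_min_samples: int = JUNCTION_MIN_SAMPLES,
) -> pd.Series:
    """Per-layer up/down/ns calls.

    gene/mirna: p_adj < cutoff and |log2FC| > lfc_cutoff.  circ: p_adj <
    cutoff and BSJ count >= junction_min_reads in >= junction_min_samples
    samples (no fold-change cutoff).
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    sig = result["p_adj"] < p_adj_cutoff
    if layer == "circ":
        if counts is None:
            raise ValueError("circ layer needs the count matrix for junction support")
        support = (counts.to_numpy() >= junction_min_reads).sum(axis=1) >= junction_min_samples
        passing = sig & pd.Series(support, index=result.index)
    else:
        passing = sig & (result["log2FC"].abs() > lfc_cutoff)
    calls = pd.Series("ns", index=result.index, dtype=object)
    calls[passing & (result["log2FC"] > 0)] = "up"
    calls[passing & (result["log2FC"] < 0)] = "down"
    return calls


@dataclass
class DELayerResult:
    """Full differential-expression result for one layer."""

    layer: str
    table: pd.DataFrame  # baseMean, log2FC, SE, p, p_adj, call
    size_factors: np.ndarray


def run_de(
    counts: pd.DataFrame,
    condition: np.ndarray,
    layer: str,
    pairs: np.ndarray | None = None,
    **call_kwargs,
) -> DELayerResult:
    """Normalize, estimate dispersion, test, adjust, and call one layer."""
    try:
        sf = size_factors(counts)
    except ValueError:
        warnings.warn(f"{layer}: no all-positive feature; using pseudo-reference size factors")
        sf = size_factors(counts, allow_pseudo_reference=True)
    alpha = estimate_dispersion(counts, sf, condition=np.asarray(condition))
    res = nb_wald_test(counts, sf, alpha, condition, pairs=pairs)
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    res["call"] = call_de(res, layer, counts=counts if layer == "circ" else None, **call_kwargs)
    if layer == "circ":
        res["max_junction_reads"] = counts.max(axis=1).astype(int)
    return DELayerResult(layer=layer, table=res, size_factors=sf)
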
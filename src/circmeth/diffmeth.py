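"""Beta-to-M transformation and moderated-t differential methylation.

M = log2(beta / (1 - beta)).  Testing follows the standard empirical-Bayes
scheme: per-probe two-group residual variances are shrunk toward a prior
fitted by moment matching on log s^2 (digamma/trigamma equations), and the
moderated t is referred to a Student t with augmented degrees of freedom.
Calls: hyper iff dM > 0.5 and p_adj < 0.05; hypo iff dM < -0.5 and
p_adj < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .diffexpr import bh_adjust

BETA_EPS = 1e-6
DM_CUTOFF = 0.5
P_ADJ_CUTOFF = 0.05


def beta_to_m(beta: np.ndarray | float, eps: float = BETA_EPS) -> np.ndarray:
    """Logit (base 2) of methylation fraction, clamped away from {0, 1}."""
    b = np.asarray(beta, dtype=float)
    if ((b < 0) | (b > 1)).any():
        raise ValueError("beta values outside [0, 1]")
    b = np.clip(b, eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def m_to_beta(m: np.ndarray | float) -> np.ndarray:
    """Inverse of :func:`beta_to_m` (before clamping)."""
    x = np.exp2(np.asarray(m, dtype=float))
    return x / (1.0 + x)


def delta_m(M: np.ndarray | pd.DataFrame, condition: np.ndarray) -> np.ndarray:
    """Mean M over tumor samples minus mean M over normal samples."""
    X = np.asarray(M, dtype=float)
    cond = np.asarray(condition, dtype=bool)
    if cond.sum() == 0 or (~cond).sum() == 0:
        raise ValueError("both groups must be nonempty")
    return X[:, cond].mean(axis=1) - X[:, ~cond].mean(axis=1)


def _solve_trigamma_inverse(y: float) -> float:
    """x with trigamma(x) = y (Newton on 1/trigamma, standard approach)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to the
    observed residual variances on the log scale.

    Returns (d0, s0sq); d0 = inf when the observed spread of log s^2 does
    not exceed the chi-square sampling spread (no extra variance to model).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        warnings.warn("too few positive variances; falling back to d0=inf")
        return np.inf, float(np.nanmedian(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        d0 = np.inf
        s0sq = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * _solve_trigamma_inverse(evar)
        if not np.isfinite(d0):
            warnings.warn("variance-prior fit did not converge; using d0=inf")
            s0sq = float(np.exp(np.mean(e)))
        else:
            s0sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderated_t(
    M: pd.DataFrame | np.ndarray,
    condition: np.ndarray,
    d0: float | None = None,
    s0sq: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t per probe.

    The pooled residual variance s^2 (df = n1 + n2 - 2) is replaced by the
    posterior (d0*s0^2 + df*s^2) / (d0 + df); t is referred to t_{d0+df}.
    Pass d0/s0sq to override the fitted prior (d0=0 gives the ordinary t).
    """
    X = np.asarray(M, dtype=float)
    cond = np.asarray(condition, dtype=bool)
    n1, n2 = int(cond.sum()), int((~cond).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    g1, g2 = X[:, cond], X[:, ~cond]
    df = float(n1 + n2 - 2)
    s2 = (g1.var(axis=1, ddof=1) * (n1 - 1) + g2.var(axis=1, ddof=1) * (n2 - 1)) / df
    dm = g1.mean(axis=1) - g2.mean(axis=1)

    if d0 is None:
        d0_fit, s0sq_fit = fit_variance_prior(s2, df)
        d0 = d0_fit
        s0sq = s0sq_fit if s0sq is None else s0sq
    elif s0sq is None and d0 > 0:
        _, s0sq = fit_variance_prior(s2, df)

    if d0 == 0:
        post = s2
        total_df = df
    elif np.isinf(d0):
        post = np.full_like(s2, s0sq)
        total_df = np.inf
    else:
        post = (d0 * s0sq + df * s2) / (d0 + df)
        total_df = d0 + df

    sed = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sed > 0, dm / sed, 0.0)
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    flagged = sed == 0
    p = np.where(flagged, 1.0, p)

    idx = M.index if isinstance(M, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    return pd.DataFrame(
        {"dM": dm, "t": t, "df": np.full_like(dm, total_df), "p": p, "s2_post": post},
        index=idx,
    )


def call_dm(
    result: pd.DataFrame,
    dm_cutoff: float = DM_CUTOFF,
    p_adj_cutoff: float = P_ADJ_CUTOFF,
) -> pd.Series:
    calls = pd.Series("ns", index=result.index, dtype=object)
    sig = result["p_adj"] < p_adj_cutoff
    calls[sig & (result["dM"] > dm_cutoff)] = "hyper"
    calls[sig & (result["dM"] < -dm_cutoff)] = "hypo"
    return calls


@dataclass
class DMResult:
    table: pd.DataFrame  # dM, t, df, p, p_adj, call
    d0: float
    s0sq: float


def run_dm(
    betas: pd.DataFrame,
    condition: np.ndarray,
    eps: float = BETA_EPS,
    dm_cutoff: float = DM_CUTOFF,
    p_adj_cutoff: float = P_ADJ_CUTOFF,
) -> DMResult:
    """Full differential-methylation pass over a beta-value matrix."""
    M = pd.DataFrame(beta_to_m(betas.to_numpy(), eps=eps), index=betas.index, columns=betas.columns)
    cond = np.asarray(condition, dtype=bool)
    n1, n2 = int(cond.sum()), int((~cond).sum())
    df = float(n1 + n2 - 2)
    g1, g2 = M.to_numpy()[:, cond], M.to_numpy()[:, ~cond]
    s2 = (g1.var(axis=1, ddof=1) * (n1 - 1) + g2.var(axis=1, ddof=1) * (n2 - 1)) / df
    d0, s0sq = fit_variance_prior(s2, df)
    res = moderated_t(M, condition, d0=d0, s0sq=s0sq)
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    res["call"] = call_dm(res, dm_cutoff=dm_cutoff, p_adj_cutoff=p_adj_cutoff)
    return DMResult(table=res, d0=d0, s0sq=s0sq)
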
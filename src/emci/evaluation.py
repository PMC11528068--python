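"""Deconvolution benchmark metrics: per-type PCC, SSIM, RMSE, JSD, and APS.

All four metrics compare one cell type's predicted spot-proportion column with
the ground-truth column. SSIM scales each column by its own maximum and uses
population (1/n) moments with stabilizers alpha = 0.01, beta = 0.03; RMSE is
computed on z-scored columns (population scaling); JSD normalizes columns to
probability vectors and uses base-2 logs so its range is [0, 1]. APS is the
mean rank ("performance level") across the four metrics among Q compared
methods: best PCC/SSIM and lowest RMSE/JSD get level Q; ties get mean rank.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["pcc_per_type", "ssim", "rmse", "jsd", "aps", "evaluate_proportions"]

SSIM_ALPHA = 0.01
SSIM_BETA = 0.03

METRICS = ("PCC", "SSIM", "RMSE", "JSD")
#: metrics where larger is better (ranked so the best gets level Q)
HIGHER_BETTER = {"PCC": True, "SSIM": True, "RMSE": False, "JSD": False}


def _pair(p, truth, min_len: int = 2) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape[0]} vs {t.shape[0]}")
    if p.shape[0] < min_len:
        raise ValueError(f"need at least {min_len} spots")
    return p, t


def pcc_per_type(p, truth) -> float:
    """Sample Pearson correlation over spots; constant columns give 0 (flagged)."""
    p, t = _pair(p, truth, min_len=3)
    dp = p - p.mean()
    dt = t - t.mean()
    sp = np.sqrt(dp @ dp)
    st = np.sqrt(dt @ dt)
    if sp == 0 or st == 0:
        logger.debug("pcc_per_type: constant column, returning 0")
        return 0.0
    return float((dp @ dt) / (sp * st))


def ssim(p, truth) -> float:
    """Structural similarity on max-scaled proportion columns."""
    p, t = _pair(p, truth)
    if np.any(p < 0) or np.any(t < 0):
        raise ValueError("columns must be nonnegative")
    if p.max() == 0 or t.max() == 0:
        raise ValueError("all-zero column: max-scaling undefined")
    ps = p / p.max()
    ts = t / t.max()
    mu_p, mu_t = ps.mean(), ts.mean()
    var_p = ps.var()  # population moments
    var_t = ts.var()
    cov = ((ps - mu_p) * (ts - mu_t)).mean()
    a2 = SSIM_ALPHA**2
    b2 = SSIM_BETA**2
    num = (2 * mu_p * mu_t + a2) * (2 * cov + b2)
    den = (mu_p**2 + mu_t**2 + a2) * (var_p + var_t + b2)
    return float(num / den)


def rmse(p, truth) -> float:
    """Root-mean-square difference of z-scored columns (population scaling).

    A zero-variance column z-scores to all zeros (flagged) rather than NaN.
    """
    p, t = _pair(p, truth)

    def _z(v: np.ndarray) -> np.ndarray:
        s = v.std()  # population
        if s == 0:
            logger.debug("rmse: zero-variance column z-scored to 0")
            return np.zeros_like(v)
        return (v - v.mean()) / s

    zp, zt = _z(p), _z(t)
    return float(np.sqrt(np.mean((zp - zt) ** 2)))


def jsd(p, truth) -> float:
    """Jensen-Shannon divergence (base 2) of spot-normalized columns, in [0, 1]."""
    p, t = _pair(p, truth)
    if np.any(p < 0) or np.any(t < 0):
        raise ValueError("columns must be nonnegative")
    if p.sum() == 0 or t.sum() == 0:
        raise ValueError("zero-sum column cannot be normalized to a distribution")
    P = p / p.sum()
    T = t / t.sum()
    M = 0.5 * (P + T)

    def _kl(a: np.ndarray, b: np.ndarray) -> float:
        nz = a > 0
        return float(np.sum(a[nz] * np.log2(a[nz] / b[nz])))

    return 0.5 * _kl(P, M) + 0.5 * _kl(T, M)


def aps(values: pd.DataFrame) -> pd.DataFrame:
    """Performance levels and APS for one cell type across Q methods.

    ``values`` is indexed by method with columns PCC, SSIM, RMSE, JSD. Returns
    the input plus ``PL_<metric>`` columns and ``APS`` (mean of the four
    levels, in [1, Q]).
    """
    missing = [m for m in METRICS if m not in values.columns]
    if missing:
        raise ValueError(f"missing metric column(s): {missing}")
    if len(values) < 2:
        raise ValueError("need at least 2 methods to rank")
    out = values.copy()
    for m in METRICS:
        out[f"PL_{m}"] = values[m].rank(ascending=HIGHER_BETTER[m], method="average")
    out["APS"] = out[[f"PL_{m}" for m in METRICS]].mean(axis=1)
    return out


def evaluate_proportions(
    pred: pd.DataFrame, truth: pd.DataFrame
) -> pd.DataFrame:
    """All four metrics for every shared cell-type column (spots matched by id)."""
    common_types = [c for c in truth.columns if c in pred.columns]
    if not common_types:
        raise ValueError("no shared cell-type columns between prediction and truth")
    spots = [s for s in truth.index if s in pred.index]
    if len(spots) < 3:
        raise ValueError("fewer than 3 shared spots")
    rows = []
    for t in common_types:
        p = pred.loc[spots, t].to_numpy(float)
        g = truth.loc[spots, t].to_numpy(float)
        rows.append(
            {
                "type": str(t),
                "PCC": pcc_per_type(p, g),
                "SSIM": ssim(p, g) if p.max() > 0 and g.max() > 0 else np.nan,
                "RMSE": rmse(p, g),
                "JSD": jsd(p, g) if p.sum() > 0 and g.sum() > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("type")
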
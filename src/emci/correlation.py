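"""Spot-cell similarity metrics and the 3-layer correlation tensor.

Three metrics compare a cell's expression vector u with a spot's vector v over
the common genes:

* Gaussian mutual information: ``-0.5 * ln(1 - rho^2)`` with rho the sample
  Pearson correlation, equivalently ``0.5 * ln(var(u) var(v) / det(Sigma))``
  for the 2x2 sample covariance Sigma. rho^2 is clamped at ``1 - RHO2_CLAMP_EPS``
  so collinear pairs stay finite.
* coefficient of determination, treating v as a direct prediction of u:
  ``1 - sum((u - v)^2) / sum((u - mean(u))^2)`` (asymmetric, may be negative).
* Pearson correlation with the (m - 1) denominator.

Degenerate (constant) vectors yield 0 for all three metrics rather than NaN.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RHO2_CLAMP_EPS",
    "MI_MAX",
    "CorrelationTensor",
    "mutual_information",
    "r_squared",
    "pearson",
    "build_tensor",
]

#: squared correlation is clamped at 1 - RHO2_CLAMP_EPS before the log
RHO2_CLAMP_EPS = 1e-12

#: resulting upper bound on mutual information (nats)
MI_MAX = -0.5 * np.log(RHO2_CLAMP_EPS)

METRIC_NAMES = ("MI", "R2", "PCC")


def _check_pair(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape[0]} vs {v.shape[0]}")
    if u.shape[0] < 3:
        raise ValueError(f"vectors must have length >= 3, got {u.shape[0]}")
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("inputs must be finite")
    return u, v


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Sample Pearson correlation; 0 (flagged) when either vector is constant."""
    u, v = _check_pair(u, v)
    du = u - u.mean()
    dv = v - v.mean()
    su = np.sqrt(du @ du)
    sv = np.sqrt(dv @ dv)
    if su == 0.0 or sv == 0.0:
        logger.debug("pearson: constant input vector, returning 0")
        return 0.0
    return float((du @ dv) / (su * sv))


def mutual_information(u: np.ndarray, v: np.ndarray) -> float:
    """Gaussian closed-form mutual information in nats.

    Equals ``-0.5 * ln(1 - rho^2)`` with rho the sample Pearson correlation;
    rho^2 is clamped at ``1 - RHO2_CLAMP_EPS`` so perfectly collinear vectors
    return the finite maximum ``MI_MAX``. Constant vectors return 0.
    """
    rho = pearson(u, v)
    rho2 = min(rho * rho, 1.0 - RHO2_CLAMP_EPS)
    return float(-0.5 * np.log1p(-rho2))


def r_squared(u: np.ndarray, v: np.ndarray) -> float:
    """Coefficient of determination with v as a direct prediction of u.

    Asymmetric in its arguments and unbounded below; constant u returns 0
    (flagged) since the total-variation denominator vanishes.
    """
    u, v = _check_pair(u, v)
    du = u - u.mean()
    denom = du @ du
    if denom == 0.0:
        logger.debug("r_squared: constant u, returning 0")
        return 0.0
    resid = u - v
    return float(1.0 - (resid @ resid) / denom)


@dataclass
class CorrelationTensor:
    """3 x n_cells x n_spots stack of similarity matrices, layer order (MI, R2, PCC)."""

    values: np.ndarray
    cell_ids: list[str]
    spot_ids: list[str]
    metric_names: tuple[str, ...] = METRIC_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3, len(self.cell_ids), len(self.spot_ids)):
            raise ValueError(
                f"tensor shape {self.values.shape} != "
                f"(3, {len(self.cell_ids)}, {len(self.spot_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def layer(self, name: str) -> np.ndarray:
        return self.values[self.metric_names.index(name)]

    def save(self, outdir: str | Path) -> None:
        """Serialize as three dense CSVs plus a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, name in enumerate(self.metric_names):
            pd.DataFrame(
                self.values[i], index=self.cell_ids, columns=self.spot_ids
            ).to_csv(outdir / f"W_{name}.csv")
        sidecar = {
            "metric_order": list(self.metric_names),
            "rho2_clamp_eps": RHO2_CLAMP_EPS,
            "n_cells": self.n_cells,
            "n_spots": self.n_spots,
        }
        (outdir / "tensor.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, indir: str | Path) -> "CorrelationTensor":
        indir = Path(indir)
        sidecar = json.loads((indir / "tensor.json").read_text())
        layers = []
        cell_ids: list[str] = []
        spot_ids: list[str] = []
        for name in sidecar["metric_order"]:
            df = pd.read_csv(indir / f"W_{name}.csv", index_col=0)
            layers.append(df.to_numpy(float))
            cell_ids = [str(i) for i in df.index]
            spot_ids = [str(c) for c in df.columns]
        return cls(np.stack(layers), cell_ids, spot_ids)


def build_tensor(sc, st) -> CorrelationTensor:
    """Compute all three metrics for every (cell, spot) pair, vectorized.

    Agrees with the scalar functions to floating-point roundoff (<= 1e-9).
    Requires the two matrices to be gene-aligned (identical gene id order).
    """
    if list(sc.gene_ids) != list(st.gene_ids):
        raise ValueError("matrices are not gene-aligned; run filter_and_align first")
    U = np.asarray(sc.values, dtype=float)  # (n1, m)
    V = np.asarray(st.values, dtype=float)  # (n2, m)
    m = U.shape[1]
    if m < 3:
        raise ValueError("need at least 3 common genes")

    dU = U - U.mean(axis=1, keepdims=True)
    dV = V - V.mean(axis=1, keepdims=True)
    su = np.sqrt(np.einsum("ij,ij->i", dU, dU))  # (n1,)
    sv = np.sqrt(np.einsum("ij,ij->i", dV, dV))  # (n2,)

    # PCC with constant-vector convention 0
    cross = dU @ dV.T  # (n1, n2)
    denom = np.outer(su, sv)
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), 0.0)
    np.clip(pcc, -1.0, 1.0, out=pcc)

    rho2 = np.minimum(pcc * pcc, 1.0 - RHO2_CLAMP_EPS)
    mi = -0.5 * np.log1p(-rho2)

    # R2: 1 - sum((u - v)^2) / sum((u - mean u)^2), expanded over pairs
    ss_u = np.einsum("ij,ij->i", U, U)
    ss_v = np.einsum("ij,ij->i", V, V)
    sq_resid = ss_u[:, None] + ss_v[None, :] - 2.0 * (U @ V.T)
    tot = su * su  # (n1,)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(
            tot[:, None] > 0,
            1.0 - sq_resid / np.where(tot[:, None] > 0, tot[:, None], 1.0),
            0.0,
        )
    # expanded sum-of-squares can go slightly negative / above 1 by roundoff
    np.minimum(r2, 1.0, out=r2)

    values = np.stack([mi, r2, pcc])
    return CorrelationTensor(values, list(sc.cell_ids), list(st.spot_ids))
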
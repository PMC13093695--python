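"""Conventional diffusion tensor fit (log-linear OLS/WLS) and tensor metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import GradientScheme
from .forward import B_SCALE, nmse

__all__ = ["TensorFit", "FitError", "fit_dti", "tensor_metrics", "dti_design_matrix"]

SIGNAL_FLOOR = 1e-6  # relative to s0, applied before the log transform


class FitError(RuntimeError):
    pass


@dataclass
class TensorFit:
    eigenvalues: np.ndarray   # (3,) sorted descending, um^2/ms
    eigenvectors: np.ndarray  # (3, 3), columns paired with eigenvalues
    s0_hat: float
    residual_nmse: float

    @property
    def principal_direction(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


def dti_design_matrix(scheme: GradientScheme) -> np.ndarray:
    """K x 7 design for log S = log s0 - b g'Dg.

    Columns: [1, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] coefficients with diffusivity
    in um^2/ms (b scaled by 1e-3).
    """
    b = scheme.bvals * B_SCALE
    g = scheme.bvecs
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def _tensor_from_coef(coef: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = coef
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def fit_dti(signals: np.ndarray, scheme: GradientScheme,
            weighting: str = "wls") -> TensorFit:
    """Log-linear tensor fit.

    OLS solves the log-signal normal equations directly; WLS runs a second
    pass weighted by the squared first-pass predicted signals (the standard
    heteroskedasticity correction for log-transformed Rician data).
    """
    signals = np.asarray(signals, dtype=float).ravel()
    if signals.shape[0] != scheme.K:
        raise FitError(f"{signals.shape[0]} signals for K={scheme.K}")
    if scheme.K < 7:
        raise FitError("need at least 7 volumes for a tensor fit")
    if not np.any(scheme.b0_mask):
        raise FitError("no b0 volume in scheme")
    if weighting not in ("ols", "wls"):
        raise ValueError(f"unknown weighting {weighting!r}")

    s0_obs = float(np.mean(signals[scheme.b0_mask]))
    if s0_obs <= 0:
        raise FitError("non-positive mean b0 signal")
    y = np.log(np.maximum(signals, SIGNAL_FLOOR * s0_obs))
    X = dti_design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise FitError("rank-deficient design: too few non-colinear directions")

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    if weighting == "wls":
        w = np.exp(X @ coef)  # first-pass predicted signals (relative)
        Xw = X * w[:, np.newaxis]
        coef, *_ = np.linalg.lstsq(Xw, y * w, rcond=None)

    D = _tensor_from_coef(coef[1:])
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    predicted = np.exp(X @ coef)
    return TensorFit(
        eigenvalues=evals,
        eigenvectors=evecs,
        s0_hat=float(np.exp(coef[0])),
        residual_nmse=nmse(signals, predicted),
    )


def tensor_metrics(eigenvalues) -> dict[str, float]:
    """FA / MD / AD / RD from a sorted eigenvalue triple.

    FA is clamped to [0, 1] and defined as 0 for an all-zero tensor.
    Negative eigenvalues (possible under noise) are accepted as-is.
    """
    l1, l2, l3 = (float(v) for v in eigenvalues)
    md = (l1 + l2 + l3) / 3.0
    ssq = l1 * l1 + l2 * l2 + l3 * l3
    if ssq == 0.0:
        fa = 0.0
    else:
        fa = np.sqrt(0.5 * ((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2) / ssq)
        fa = float(np.clip(fa, 0.0, 1.0))
    return {"FA": fa, "MD": md, "AD": l1, "RD": (l2 + l3) / 2.0}
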
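"""Forward signal model: anisotropic tensors plus an isotropic diffusivity spectrum.

The voxel signal at gradient k is

    S_k = s0 * [ sum_i f_i exp(-b_k l_perp_i) exp(-b_k (l_par_i - l_perp_i) cos^2 psi_ik)
                 + sum_j w_j exp(-b_k D_j) ]

where psi_ik is the angle between fiber i and gradient k, and the isotropic
integral over the spectrum f(D) on [a, b] is discretized as a non-negative
sum on a fixed diffusivity grid.  Units: b in s/mm^2, diffusivities in
um^2/ms, so b*D carries a factor 1e-3 (b=1000 with D=1 gives exponent 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import GradientScheme

__all__ = [
    "AnisoCompartment",
    "IsoSpectrum",
    "VoxelModel",
    "predict_signal",
    "aniso_signal",
    "iso_atoms",
    "add_noise",
    "nmse",
]

B_SCALE = 1e-3  # (s/mm^2) * (um^2/ms) -> dimensionless


@dataclass(frozen=True)
class AnisoCompartment:
    """One axially symmetric anisotropic tensor compartment."""

    f: float
    lambda_par: float   # axial diffusivity, um^2/ms
    lambda_perp: float  # radial diffusivity, um^2/ms
    direction: np.ndarray

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError(f"negative fraction {self.f}")
        if not 0 <= self.lambda_perp <= self.lambda_par:
            raise ValueError(
                f"need 0 <= lambda_perp <= lambda_par, got "
                f"({self.lambda_par}, {self.lambda_perp})"
            )
        d = np.asarray(self.direction, dtype=float).ravel()
        if d.shape != (3,) or abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError("direction must be a unit 3-vector")
        object.__setattr__(self, "direction", d)


@dataclass
class IsoSpectrum:
    """Discretized isotropic diffusivity spectrum on [a, b] um^2/ms."""

    a: float
    b: float
    D_grid: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.D_grid = np.asarray(self.D_grid, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.a < self.b:
            raise ValueError("need a < b")
        if np.any(np.diff(self.D_grid) <= 0):
            raise ValueError("D_grid must be strictly increasing")
        if self.D_grid[0] < self.a - 1e-12 or self.D_grid[-1] > self.b + 1e-12:
            raise ValueError("D_grid outside [a, b]")
        if self.weights.shape != self.D_grid.shape:
            raise ValueError("weights/D_grid length mismatch")
        if np.any(self.weights < 0):
            raise ValueError("negative spectrum weight")

    @classmethod
    def linear(cls, a: float = 0.0, b: float = 3.0, m: int = 40,
               weights: np.ndarray | None = None) -> "IsoSpectrum":
        grid = np.linspace(a, b, m)
        if weights is None:
            weights = np.zeros(m)
        return cls(a=a, b=b, D_grid=grid, weights=weights)

    @classmethod
    def delta(cls, D: float, weight: float, a: float = 0.0, b: float = 3.0,
              m: int = 40) -> "IsoSpectrum":
        """All mass at the grid point nearest ``D`` (for building phantoms)."""
        spec = cls.linear(a=a, b=b, m=m)
        spec.weights[np.argmin(np.abs(spec.D_grid - D))] = weight
        return spec


@dataclass
class VoxelModel:
    """Full voxel: N_aniso tensor compartments + isotropic spectrum + s0."""

    aniso: list[AnisoCompartment] = field(default_factory=list)
    iso: IsoSpectrum = field(default_factory=IsoSpectrum.linear)
    s0: float = 1.0

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")

    @property
    def total_fraction(self) -> float:
        return float(sum(c.f for c in self.aniso) + self.iso.weights.sum())


def aniso_signal(lambda_par: float, lambda_perp: float, direction: np.ndarray,
                 scheme: GradientScheme) -> np.ndarray:
    """Unit-amplitude signal of one anisotropic compartment (length K)."""
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-6:
        raise ValueError("direction must be unit norm")
    b = scheme.bvals * B_SCALE
    cos2 = (scheme.bvecs @ d) ** 2
    return np.exp(-b * lambda_perp) * np.exp(-b * (lambda_par - lambda_perp) * cos2)


def iso_atoms(D_grid: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """K x M matrix of isotropic signal atoms exp(-b_k D_j)."""
    return np.exp(-np.outer(scheme.bvals * B_SCALE, np.asarray(D_grid, dtype=float)))


def predict_signal(model: VoxelModel, scheme: GradientScheme) -> np.ndarray:
    """Noise-free signal vector (length K) of a voxel model."""
    s = np.zeros(scheme.K)
    for comp in model.aniso:
        s += comp.f * aniso_signal(comp.lambda_par, comp.lambda_perp,
                                   comp.direction, scheme)
    s += iso_atoms(model.iso.D_grid, scheme) @ model.iso.weights
    return model.s0 * s


def add_noise(signal: np.ndarray, snr: float, seed: int,
              s0: float | None = None, kind: str = "rician") -> np.ndarray:
    """Corrupt a signal with Rician (default) or Gaussian noise.

    sigma = s0 / snr; ``s0`` defaults to the signal maximum, which is the b0
    level for any physical protocol.  Rician: the output is the magnitude of
    the complex signal (S + n1, n2) with iid Gaussian n1, n2.
    """
    signal = np.asarray(signal, dtype=float)
    if snr <= 0:
        raise ValueError(f"snr must be positive, got {snr}")
    if s0 is None:
        s0 = float(np.max(signal))
    sigma = s0 / snr
    if not np.isfinite(sigma) or sigma == 0.0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    if kind == "rician":
        n1 = rng.normal(0.0, sigma, size=signal.shape)
        n2 = rng.normal(0.0, sigma, size=signal.shape)
        return np.hypot(signal + n1, n2)
    if kind == "gaussian":
        return signal + rng.normal(0.0, sigma, size=signal.shape)
    raise ValueError(f"unknown noise kind {kind!r}")


def nmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Normalized mean square error: sum((obs-pred)^2) / sum(obs^2)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("length mismatch")
    denom = float(np.sum(observed**2))
    if denom == 0.0:
        raise ZeroDivisionError("NMSE undefined for an all-zero observed signal")
    return float(np.sum((observed - predicted) ** 2) / denom)
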
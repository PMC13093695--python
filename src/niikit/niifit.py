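"""Per-voxel inversion of the multi-compartment model and the seven derived indices.

Two solvers are provided:

* ``hybrid`` — variable projection: the swarm/simplex global optimizer
  searches the nonlinear axial/radial diffusivities of each anisotropic
  compartment (directions held fixed from a preliminary orientation
  estimate) while all linear weights (fiber amplitudes and the isotropic
  spectrum) are solved by NNLS inside the objective.
* ``rnnls`` — Tikhonov-regularized non-negative least squares over a fixed
  dictionary of anisotropic atoms on a diffusivity lattice plus the
  isotropic spectrum atoms, with each direction's atoms collapsed to one
  compartment by weight-averaging.  This is the reference method the hybrid
  solver is compared against.

Derived indices from the fitted voxel model (fractions normalized to 1):
RF (restricted, D <= 0.3 um^2/ms), HR (hindered share of the non-restricted
isotropic signal, 0.3 < D <= 2.5), FF (summed anisotropic fraction), and
fraction-weighted AD/RD with MD and FA from the axially symmetric tensor
(AD, RD, RD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import nnls

from .acquisition import GradientScheme, Volume4D
from .dti import fit_dti, tensor_metrics, FitError
from .forward import (AnisoCompartment, IsoSpectrum, VoxelModel, aniso_signal,
                      iso_atoms, nmse, predict_signal)
from .optimize import SwarmConfig, minimize_hybrid

__all__ = [
    "NIIFitConfig",
    "NIIFitResult",
    "MetricVolume",
    "METRIC_NAMES",
    "estimate_fiber_directions",
    "solve_rnnls",
    "fit_nii_voxel",
    "derived_metrics",
    "fit_nii_volume",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("HR", "RF", "FF", "AD", "RD", "MD", "FA")

# fixed orientation dictionary for the two-fiber peak search
_N_PEAK_DIRS = 100
_PEAK_SEED = 42
_STICK_LAMBDA_PAR = 1.7
_STICK_LAMBDA_PERP = 0.2
_LOW_FA_THRESHOLD = 0.05


@dataclass
class NIIFitConfig:
    n_aniso_max: int = 1
    spectrum_m: int = 40
    spectrum_a: float = 0.0
    spectrum_b: float = 3.0
    d_restricted: float = 0.3      # um^2/ms, restricted/hindered cutoff
    d_hindered: float = 2.5        # um^2/ms, hindered/free cutoff
    lambda_par_bounds: tuple[float, float] = (0.1, 3.0)
    lambda_perp_bounds: tuple[float, float] = (0.0, 2.0)
    mu: float = 1e-3               # Tikhonov weight for the RNNLS solver
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    solver: str = "hybrid"
    hr_definition: str = "ratio"   # "ratio": w_h/(w_h+w_f); "absolute": w_h
    rnnls_par_grid: int = 12
    rnnls_perp_grid: int = 9

    def __post_init__(self) -> None:
        if not 0 < self.d_restricted < self.d_hindered <= self.spectrum_b:
            raise ValueError("need 0 < d_restricted < d_hindered <= spectrum_b")
        if self.solver not in ("hybrid", "rnnls"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.hr_definition not in ("ratio", "absolute"):
            raise ValueError(f"unknown hr_definition {self.hr_definition!r}")
        if self.n_aniso_max not in (0, 1, 2):
            raise ValueError("n_aniso_max must be 0, 1 or 2")

    def spectrum_grid(self) -> np.ndarray:
        return np.linspace(self.spectrum_a, self.spectrum_b, self.spectrum_m)


@dataclass
class NIIFitResult:
    model: VoxelModel
    metrics: dict[str, float]
    nmse: float
    solver_used: str
    low_anisotropy: bool = False


@dataclass
class MetricVolume:
    """One scalar metric as a 3-D map with mask and voxel-grid metadata."""

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    name: str


def _normalize_b0(signals: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    s0 = float(np.mean(signals[scheme.b0_mask]))
    if s0 <= 0:
        raise FitError("non-positive mean b0 signal")
    return signals / s0


_peak_dirs_cache: dict[int, np.ndarray] = {}


def _peak_directions() -> np.ndarray:
    if _N_PEAK_DIRS not in _peak_dirs_cache:
        from .acquisition import sphere_points
        _peak_dirs_cache[_N_PEAK_DIRS] = sphere_points(_N_PEAK_DIRS, seed=_PEAK_SEED)
    return _peak_dirs_cache[_N_PEAK_DIRS]


def estimate_fiber_directions(signals: np.ndarray, scheme: GradientScheme,
                              n_aniso_max: int = 1,
                              config: NIIFitConfig | None = None):
    """Principal fiber axes for the voxel: (directions, low_anisotropy flag).

    n=1 uses the DTI principal eigenvector.  n=2 fits an NNLS stick
    dictionary over a fixed orientation set, takes the two strongest
    antipodally distinct peaks (second kept only at >= 20% of the first
    weight) and refines each by a weighted mean over its 15-degree cone.
    Near-isotropic voxels (DTI FA < 0.05) return a fixed axis and the flag.
    """
    config = config or NIIFitConfig()
    signals = np.asarray(signals, dtype=float).ravel()
    tensor = fit_dti(signals, scheme, weighting="ols")
    fa = tensor_metrics(tensor.eigenvalues)["FA"]
    if fa < _LOW_FA_THRESHOLD:
        return [np.array([1.0, 0.0, 0.0])], True
    if n_aniso_max <= 1:
        return [tensor.principal_direction], False

    dirs = _peak_directions()
    snorm = _normalize_b0(signals, scheme)
    atoms = [aniso_signal(_STICK_LAMBDA_PAR, _STICK_LAMBDA_PERP, d, scheme)
             for d in dirs]
    A = np.column_stack(atoms + [iso_atoms(config.spectrum_grid(), scheme)])
    w, _ = nnls(A, snorm)
    w = w[:len(dirs)]
    first = int(np.argmax(w))
    if w[first] <= 0:
        return [tensor.principal_direction], False

    def refine(center_idx: int) -> np.ndarray:
        center = dirs[center_idx]
        cone = np.abs(dirs @ center) > np.cos(np.radians(15.0))
        sel = dirs[cone] * np.sign(dirs[cone] @ center)[:, None]
        v = (w[cone][:, None] * sel).sum(axis=0)
        nv = np.linalg.norm(v)
        return v / nv if nv > 0 else center

    peaks = [refine(first)]
    away = np.abs(dirs @ dirs[first]) < np.cos(np.radians(30.0))
    if away.any():
        second = int(np.flatnonzero(away)[np.argmax(w[away])])
        if w[second] >= 0.2 * w[first]:
            peaks.append(refine(second))
    return peaks, False


def solve_rnnls(signals: np.ndarray, scheme: GradientScheme,
                directions: list[np.ndarray],
                config: NIIFitConfig | None = None) -> VoxelModel:
    """Regularized NNLS over a fixed dictionary; signals must be b0-normalized.

    Per direction: anisotropic atoms on a lambda_par x lambda_perp lattice
    (lambda_perp <= lambda_par), plus the isotropic spectrum atoms; solves
    min ||Ax - S||^2 + mu ||x||^2, x >= 0 via the augmented system, then
    collapses each direction's atoms to one compartment with weight-averaged
    diffusivities.
    """
    config = config or NIIFitConfig()
    signals = np.asarray(signals, dtype=float).ravel()
    par_grid = np.linspace(*config.lambda_par_bounds, config.rnnls_par_grid)
    perp_grid = np.linspace(*config.lambda_perp_bounds, config.rnnls_perp_grid)
    atoms, atom_meta = [], []  # meta: (direction index, l_par, l_perp)
    for di, d in enumerate(directions):
        for lp in par_grid:
            for lt in perp_grid:
                if lt <= lp:
                    atoms.append(aniso_signal(lp, lt, d, scheme))
                    atom_meta.append((di, lp, lt))
    grid = config.spectrum_grid()
    A_iso = iso_atoms(grid, scheme)
    if not atoms and A_iso.size == 0:
        raise ValueError("empty dictionary")
    A = np.column_stack(atoms + [A_iso]) if atoms else A_iso
    n_atoms = len(atoms)
    # Tikhonov via augmentation
    A_aug = np.vstack([A, np.sqrt(config.mu) * np.eye(A.shape[1])])
    y_aug = np.concatenate([signals, np.zeros(A.shape[1])])
    x, _ = nnls(A_aug, y_aug)

    compartments = []
    for di, d in enumerate(directions):
        sel = [j for j, m in enumerate(atom_meta) if m[0] == di]
        wsum = float(np.sum(x[sel]))
        if wsum <= 0:
            continue
        lp = float(np.sum([x[j] * atom_meta[j][1] for j in sel]) / wsum)
        lt = float(np.sum([x[j] * atom_meta[j][2] for j in sel]) / wsum)
        compartments.append(AnisoCompartment(f=wsum, lambda_par=lp,
                                             lambda_perp=min(lt, lp), direction=d))
    iso = IsoSpectrum(a=config.spectrum_a, b=config.spectrum_b,
                      D_grid=grid, weights=x[n_atoms:])
    return VoxelModel(aniso=compartments, iso=iso, s0=1.0)


def derived_metrics(model: VoxelModel, config: NIIFitConfig | None = None) -> dict[str, float]:
    """The seven scalar indices from a fitted voxel model.

    Fractions are normalized by the model's total signal fraction; with
    FF = 0 the tensor-derived indices (AD/RD/MD/FA) are NaN, not zero.
    """
    config = config or NIIFitConfig()
    total = model.total_fraction
    out = dict.fromkeys(METRIC_NAMES, np.nan)
    if total <= 0:
        out.update(HR=0.0, RF=0.0, FF=0.0)
        return out
    w = model.iso.weights / total
    D = model.iso.D_grid
    w_r = float(w[D <= config.d_restricted].sum())
    w_h = float(w[(D > config.d_restricted) & (D <= config.d_hindered)].sum())
    w_f = float(w[D > config.d_hindered].sum())
    ff = float(sum(c.f for c in model.aniso) / total)
    if config.hr_definition == "ratio":
        hr = w_h / (w_h + w_f) if (w_h + w_f) > 0 else 0.0
    else:
        hr = w_h
    out.update(HR=hr, RF=w_r, FF=ff)
    if ff > 0:
        fsum = sum(c.f for c in model.aniso)
        ad = float(sum(c.f * c.lambda_par for c in model.aniso) / fsum)
        rd = float(sum(c.f * c.lambda_perp for c in model.aniso) / fsum)
        tm = tensor_metrics((ad, rd, rd))
        out.update(AD=ad, RD=rd, MD=tm["MD"], FA=tm["FA"])
    return out


def _hybrid_solve(snorm: np.ndarray, scheme: GradientScheme,
                  directions: list[np.ndarray], config: NIIFitConfig) -> VoxelModel:
    grid = config.spectrum_grid()
    A_iso = iso_atoms(grid, scheme)
    n_dirs = len(directions)

    def build_dictionary(params: np.ndarray) -> np.ndarray:
        cols = []
        for i, d in enumerate(directions):
            lp = params[2 * i]
            lt = min(params[2 * i + 1], lp)
            cols.append(aniso_signal(lp, lt, d, scheme))
        return np.column_stack(cols + [A_iso])

    def objective(params: np.ndarray) -> float:
        A = build_dictionary(params)
        w, rnorm = nnls(A, snorm)
        return float(rnorm**2)

    bounds = [config.lambda_par_bounds, config.lambda_perp_bounds] * n_dirs
    # physics-informed swarm seeds: the DTI eigenvalue estimate plus the
    # canonical healthy white-matter tensor
    try:
        tensor = fit_dti(snorm, scheme, weighting="ols")
        dti_start = [float(tensor.eigenvalues[0]),
                     float(max(tensor.eigenvalues[1:].mean(), 0.0))]
    except FitError:
        dti_start = [1.7, 0.3]
    init = np.array([dti_start * n_dirs, [1.7, 0.3] * n_dirs])
    result = minimize_hybrid(objective, bounds, config.swarm, init_points=init)
    A = build_dictionary(result.x)
    w, _ = nnls(A, snorm)
    compartments = []
    for i, d in enumerate(directions):
        lp = float(result.x[2 * i])
        lt = float(min(result.x[2 * i + 1], lp))
        if w[i] > 0:
            compartments.append(AnisoCompartment(f=float(w[i]), lambda_par=lp,
                                                 lambda_perp=lt, direction=d))
    iso = IsoSpectrum(a=config.spectrum_a, b=config.spectrum_b,
                      D_grid=grid, weights=w[n_dirs:])
    return VoxelModel(aniso=compartments, iso=iso, s0=1.0)


def _iso_only_solve(snorm: np.ndarray, scheme: GradientScheme,
                    config: NIIFitConfig) -> VoxelModel:
    grid = config.spectrum_grid()
    w, _ = nnls(iso_atoms(grid, scheme), snorm)
    iso = IsoSpectrum(a=config.spectrum_a, b=config.spectrum_b,
                      D_grid=grid, weights=w)
    return VoxelModel(aniso=[], iso=iso, s0=1.0)


def fit_nii_voxel(signals: np.ndarray, scheme: GradientScheme,
                  config: NIIFitConfig | None = None,
                  seed: int | None = None) -> NIIFitResult:
    """Fit one voxel and derive the seven indices plus the NMSE.

    Signals are normalized by the mean b0 before fitting, so all fractions
    are relative to unity.  ``seed`` overrides the swarm seed (used for
    voxelwise decorrelation of the stochastic search).
    """
    config = config or NIIFitConfig()
    if seed is not None:
        config = replace(config, swarm=replace(config.swarm, seed=seed))
    signals = np.asarray(signals, dtype=float).ravel()
    if not np.any(scheme.b0_mask):
        raise FitError("scheme has no b0 volume")
    snorm = _normalize_b0(signals, scheme)

    if config.n_aniso_max == 0:
        directions, low_aniso = [], True
    else:
        directions, low_aniso = estimate_fiber_directions(
            signals, scheme, config.n_aniso_max, config)
        if low_aniso:
            directions = []

    if not directions:
        model = _iso_only_solve(snorm, scheme, config)
        solver = "iso-nnls"
    elif config.solver == "rnnls":
        model = solve_rnnls(snorm, scheme, directions, config)
        solver = "rnnls"
    else:
        model = _hybrid_solve(snorm, scheme, directions, config)
        solver = "hybrid"
    fit_nmse = nmse(snorm, predict_signal(model, scheme))
    return NIIFitResult(model=model, metrics=derived_metrics(model, config),
                        nmse=fit_nmse, solver_used=solver,
                        low_anisotropy=low_aniso)


def fit_nii_volume(vol: Volume4D, scheme: GradientScheme,
                   config: NIIFitConfig | None = None) -> dict[str, MetricVolume]:
    """Voxelwise fit over the mask; returns the seven metric maps plus NMSE.

    Out-of-mask voxels hold NaN.  Failed voxels are logged and skipped.
    Voxels are independent, so processing order cannot affect the maps.
    """
    config = config or NIIFitConfig()
    if vol.mask is None:
        raise ValueError("volume mask is required")
    if vol.n_volumes != scheme.K:
        raise ValueError(f"volume has {vol.n_volumes} volumes, scheme K={scheme.K}")
    maps = {name: np.full(vol.spatial_shape, np.nan) for name in METRIC_NAMES}
    maps["NMSE"] = np.full(vol.spatial_shape, np.nan)
    coords = np.argwhere(vol.mask)
    for count, (i, j, k) in enumerate(coords):
        try:
            # decorrelate the stochastic search across voxels; keyed on the
            # voxel coordinate so processing order cannot change the maps
            voxel_seed = (config.swarm.seed * 1000003
                          + i * 73856093 + j * 19349663 + k * 83492791) % (2**31 - 1)
            res = fit_nii_voxel(vol.data[i, j, k, :], scheme, config,
                                seed=voxel_seed)
        except Exception as exc:  # noqa: BLE001 - per-voxel failures are non-fatal
            logger.warning("voxel (%d,%d,%d) failed: %s", i, j, k, exc)
            continue
        for name in METRIC_NAMES:
            maps[name][i, j, k] = res.metrics[name]
        maps["NMSE"][i, j, k] = res.nmse
        if (count + 1) % 200 == 0:
            logger.info("fitted %d/%d voxels", count + 1, len(coords))
    return {name: MetricVolume(data=arr, affine=vol.affine, mask=vol.mask,
                               name=f"nii_{name}")
            for name, arr in maps.items()}
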
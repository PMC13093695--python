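"""Synthetic data: signal phantoms with ground truth, and two-group cohorts
of skeleton metric maps with planted effects and clinical-score structure.

The cohort generator emulates the study design it is tested against: two
groups of 67 subjects (patients and matched controls), metric maps on a
white-matter-like mask where patients have lower restricted fraction (RF),
lower hindered ratio (HR) and higher fiber fraction (FF) inside an affected
blob, demographically matched covariates, and clinical scores generated as
linear functions of subject-mean metrics plus Gaussian noise.  Maps are
generated directly in metric space (smooth subject baseline + group effect
+ voxel noise); an end-to-end signals-to-fits mode is available for small
grids via ``make_phantom`` + the volume fitter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .acquisition import GradientScheme, Volume4D, study_scheme
from .forward import VoxelModel, add_noise, predict_signal
from .niifit import NIIFitConfig, derived_metrics

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "ScoreModel",
    "SubjectRecord",
    "make_phantom",
    "make_cohort",
    "cohort_table",
    "stack_metric_maps",
    "impute_by_age_group",
    "default_blob",
]

logger = logging.getLogger(__name__)


@dataclass
class PhantomSpec:
    """Regions of known voxel models on a 3-D grid, with acquisition noise."""

    shape: tuple[int, int, int]
    regions: list[tuple[np.ndarray, VoxelModel]]
    snr: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        occupancy = np.zeros(self.shape, dtype=int)
        for mask, _ in self.regions:
            if mask.shape != tuple(self.shape):
                raise ValueError("region mask shape mismatch")
            occupancy += mask.astype(int)
        if np.any(occupancy > 1):
            raise ValueError("regions overlap")


def make_phantom(spec: PhantomSpec, scheme: GradientScheme | None = None,
                 config: NIIFitConfig | None = None):
    """Simulate signals for every region; returns (Volume4D, truth maps).

    Ground-truth maps are the derived indices of each region's generating
    model.  Noise is Rician at ``spec.snr`` (infinite SNR = noise-free),
    seeded per spec and voxel.
    """
    scheme = scheme or study_scheme(0)
    config = config or NIIFitConfig()
    data = np.zeros(spec.shape + (scheme.K,), dtype=float)
    mask = np.zeros(spec.shape, dtype=bool)
    from .niifit import METRIC_NAMES
    truth = {name: np.full(spec.shape, np.nan) for name in METRIC_NAMES}
    rng = np.random.default_rng(spec.seed)
    for region_mask, model in spec.regions:
        signal = predict_signal(model, scheme)
        metrics = derived_metrics(model, config)
        coords = np.argwhere(region_mask)
        for (i, j, k) in coords:
            if np.isfinite(spec.snr):
                voxel_seed = int(rng.integers(0, 2**31 - 1))
                data[i, j, k] = add_noise(signal, spec.snr, seed=voxel_seed,
                                          s0=model.s0)
            else:
                data[i, j, k] = signal
        mask |= region_mask
        for name in METRIC_NAMES:
            truth[name][region_mask] = metrics[name]
    vol = Volume4D(data=data, affine=np.eye(4), mask=mask)
    return vol, truth


@dataclass
class ScoreModel:
    """score = intercept + slope * subject-mean(metric) + N(0, noise_sd)."""

    metric: str
    slope: float
    intercept: float
    noise_sd: float
    lo: float
    hi: float
    integer: bool = False
    patients_only: bool = False


def _default_score_models() -> dict[str, ScoreModel]:
    # slopes are positive on RF for the mental/physical scores so that the
    # planted lower-RF patient group scores lower, mirroring the direction
    # of the in-vivo metric-score associations
    return {
        "MCS": ScoreModel("nii_RF", slope=300.0, intercept=20.0, noise_sd=4.0,
                          lo=0.0, hi=100.0),
        "PCS": ScoreModel("nii_RF", slope=300.0, intercept=18.0, noise_sd=5.0,
                          lo=0.0, hi=100.0),
        "PSQI": ScoreModel("nii_FF", slope=60.0, intercept=-27.0, noise_sd=2.0,
                           lo=0.0, hi=21.0, integer=True),
        "BDS": ScoreModel("nii_RF", slope=700.0, intercept=0.0, noise_sd=10.0,
                          lo=0.0, hi=100.0, integer=True),
        "severity": ScoreModel("nii_FF", slope=25.0, intercept=-12.0, noise_sd=0.7,
                               lo=1.0, hi=5.0, integer=True, patients_only=True),
    }


def default_blob(shape: tuple[int, int, int], radius: float = 3.0) -> np.ndarray:
    """Spherical affected region centered in the grid."""
    center = (np.asarray(shape) - 1) / 2.0
    grid = np.indices(shape).astype(float)
    dist2 = sum((grid[ax] - center[ax]) ** 2 for ax in range(3))
    return dist2 <= radius**2


@dataclass
class CohortSpec:
    """Study conditions for a synthetic two-group cohort."""

    n_per_group: int = 67
    n_groups: int = 2
    shape: tuple[int, int, int] = (12, 12, 12)
    skeleton: np.ndarray | None = None       # default: full grid
    blob: np.ndarray | None = None           # default: central r=3 sphere
    effects: dict[str, float] = field(default_factory=lambda: {
        "nii_RF": -0.05, "nii_HR": -0.05, "nii_FF": +0.05})
    baselines: dict[str, float] = field(default_factory=lambda: {
        "nii_RF": 0.10, "nii_HR": 0.60, "nii_FF": 0.55})
    subject_sd: float = 0.03     # smooth between-subject baseline variation
    voxel_sd: float = 0.055      # iid within-map noise
    smooth_sigma: float = 2.0    # voxels, for the subject baseline field
    p_female: float = 0.80
    met_missing_rate: float = 0.08
    score_models: dict[str, ScoreModel] = field(default_factory=_default_score_models)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("need at least 3 subjects per group")
        if self.skeleton is None:
            self.skeleton = np.ones(self.shape, dtype=bool)
        if self.blob is None:
            self.blob = default_blob(self.shape)
        for metric, delta in self.effects.items():
            base = self.baselines.get(metric, 0.5)
            if not 0.0 <= base + delta <= 1.0 or not 0.0 <= base <= 1.0:
                raise ValueError(
                    f"effect {delta:+g} on {metric} pushes the mean outside [0, 1]")


@dataclass
class SubjectRecord:
    id: str
    group: str
    covariates: dict[str, float]
    scores: dict[str, float]
    maps: dict[str, np.ndarray]


def _smooth_field(rng: np.random.Generator, shape, sigma: float, sd: float) -> np.ndarray:
    noise = rng.normal(size=shape)
    smoothed = ndimage.gaussian_filter(noise, sigma=sigma)
    s = smoothed.std()
    return smoothed * (sd / s) if s > 0 else smoothed


def make_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the cohort; deterministic per spec seed.

    Group 0 is "control"; groups >= 1 are "patient" (or "patient-g" for more
    than two groups) and receive the planted effects inside the blob.
    Covariates are drawn from the same distributions in every group (matched
    by construction) except the anxiety/depression scores, which are shifted
    in patients as in the study population.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    metrics = sorted(set(spec.baselines) | set(spec.effects))
    subject_idx = 0
    for g in range(spec.n_groups):
        if g == 0:
            group = "control"
        elif spec.n_groups == 2:
            group = "patient"
        else:
            group = f"patient-{g}"
        is_patient = g > 0
        for _ in range(spec.n_per_group):
            subject_idx += 1
            cov = {
                "sex": float(rng.uniform() < spec.p_female),  # 1 = female
                "age": float(rng.integers(19, 66)),
                "BMI": float(np.clip(rng.normal(24.5, 3.5), 17.0, 35.5)),
                "MET": float(np.clip(rng.normal(1.35, 0.2), 1.0, 1.9)),
                "anxiety": float(np.clip(rng.normal(8 if is_patient else 4, 3),
                                         0, 21)),
                "depression": float(np.clip(rng.normal(6 if is_patient else 1.5, 2.5),
                                            0, 21)),
            }
            if rng.uniform() < spec.met_missing_rate:
                cov["MET"] = np.nan
            maps: dict[str, np.ndarray] = {}
            for metric in metrics:
                base = spec.baselines.get(metric, 0.5)
                field_map = np.full(spec.shape, base)
                field_map += _smooth_field(rng, spec.shape, spec.smooth_sigma,
                                           spec.subject_sd)
                if is_patient and metric in spec.effects:
                    field_map[spec.blob] += spec.effects[metric]
                field_map += rng.normal(0.0, spec.voxel_sd, size=spec.shape)
                field_map[~spec.skeleton] = np.nan
                maps[metric] = field_map
            scores: dict[str, float] = {}
            for name, sm in spec.score_models.items():
                if sm.patients_only and not is_patient:
                    scores[name] = np.nan
                    continue
                mean_metric = float(np.nanmean(maps[sm.metric])) \
                    if sm.metric in maps else 0.0
                val = sm.intercept + sm.slope * mean_metric \
                    + rng.normal(0.0, sm.noise_sd)
                clipped = float(np.clip(val, sm.lo, sm.hi))
                if clipped != val:
                    logger.debug("score %s clipped (%.2f -> %.2f)", name, val, clipped)
                scores[name] = round(clipped) if sm.integer else clipped
            if is_patient:
                scores["duration"] = float(np.clip(rng.lognormal(2.0, 0.8), 0.75, 45))
            else:
                scores["duration"] = np.nan
            records.append(SubjectRecord(
                id=f"sub-{subject_idx:03d}", group=group,
                covariates=cov, scores=scores, maps=maps))
    return records


def cohort_table(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"id": r.id, "group": r.group}
        row.update(r.covariates)
        row.update(r.scores)
        rows.append(row)
    return pd.DataFrame(rows)


def stack_metric_maps(records: list[SubjectRecord], metric: str,
                      mask: np.ndarray) -> np.ndarray:
    """Voxels x subjects data matrix for the in-mask voxels (C order)."""
    return np.column_stack([r.maps[metric][mask] for r in records])


def impute_by_age_group(table: pd.DataFrame, column: str,
                        bins=(18, 30, 40, 50, 60, 70),
                        age_column: str = "age") -> pd.DataFrame:
    """Replace missing values by the mean of the subject's age bin.

    Bins are right-exclusive decade bins over 18-65 by default.  A bin with
    no observed values falls back to the global mean (logged).
    """
    out = table.copy()
    ages = out[age_column].to_numpy(dtype=float)
    vals = out[column].to_numpy(dtype=float)
    if np.nanmin(ages) < bins[0] or np.nanmax(ages) >= bins[-1]:
        raise ValueError("age bins do not cover the observed ages")
    missing = np.isnan(vals)
    if not missing.any():
        return out
    global_mean = float(np.nanmean(vals))
    bin_idx = np.digitize(ages, bins) - 1
    filled = vals.copy()
    for b in np.unique(bin_idx[missing]):
        in_bin = bin_idx == b
        observed = vals[in_bin & ~missing]
        if observed.size == 0:
            logger.warning("age bin [%g, %g) has no observed %s; using global mean",
                           bins[b], bins[b + 1], column)
            fill = global_mean
        else:
            fill = float(observed.mean())
        filled[in_bin & missing] = fill
    out[column] = filled
    return out
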
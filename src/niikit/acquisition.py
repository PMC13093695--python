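"""Gradient tables, image volumes, and the multi-shell acquisition scheme.

The pipeline works on 4D diffusion-weighted volumes paired with FSL-dialect
``.bval``/``.bvec`` text files: the b-value file is a single whitespace
separated row of K numbers, and the b-vector file is three rows (x, y, z)
of K numbers each, expressed in the image coordinate frame.  No sign
flipping or reorientation is applied anywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GradientScheme",
    "Volume4D",
    "GradientFormatError",
    "DimensionError",
    "read_gradient_scheme",
    "write_gradient_scheme",
    "study_scheme",
    "sphere_points",
    "read_volume",
    "write_volume",
]

DEFAULT_B0_THRESHOLD = 50.0  # s/mm^2; tolerates vendor "b=5" pseudo-b0 volumes


class GradientFormatError(ValueError):
    """Malformed or inconsistent bval/bvec files."""


class DimensionError(ValueError):
    """Array shapes inconsistent with the paired scheme or mask."""


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    b=0 volumes may carry a zero direction vector.  Directions of
    diffusion-weighted volumes must be unit norm.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise GradientFormatError(f"bvecs must be (K, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise GradientFormatError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) disagree on K"
            )
        if np.any(bvals < 0):
            raise GradientFormatError("negative b-value")
        norms = np.linalg.norm(bvecs, axis=1)
        dw = bvals > self.b0_threshold
        if np.any(np.abs(norms[dw] - 1.0) > 1e-6):
            raise GradientFormatError("non-unit direction on a diffusion-weighted volume")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def K(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    def shell_counts(self, round_to: float = 1.0) -> dict[float, int]:
        """Volume count per shell; b0 volumes are pooled under key 0."""
        keys = np.where(self.b0_mask, 0.0, np.round(self.bvals / round_to) * round_to)
        uniq, counts = np.unique(keys, return_counts=True)
        return {float(u): int(c) for u, c in zip(uniq, counts)}


@dataclass
class Volume4D:
    """A 4D image (x, y, z, volume) with its affine and an optional mask."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise DimensionError(f"expected 3D or 4D data, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise DimensionError("affine must be 4x4")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise DimensionError(
                    f"mask shape {self.mask.shape} != spatial shape {self.data.shape[:3]}"
                )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def _parse_rows(path: str | Path) -> list[list[float]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise GradientFormatError(f"{path}: non-numeric token ({exc})") from exc
    return rows


def read_gradient_scheme(
    bval_path: str | Path,
    bvec_path: str | Path,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> GradientScheme:
    """Read FSL-style bval/bvec files; non-b0 directions are renormalized."""
    bval_rows = _parse_rows(bval_path)
    if len(bval_rows) != 1:
        raise GradientFormatError(f"{bval_path}: expected one row, got {len(bval_rows)}")
    bvals = np.asarray(bval_rows[0])
    bvec_rows = _parse_rows(bvec_path)
    if len(bvec_rows) != 3:
        raise GradientFormatError(f"{bvec_path}: expected three rows, got {len(bvec_rows)}")
    if len({len(r) for r in bvec_rows}) != 1 or len(bvec_rows[0]) != len(bvals):
        raise GradientFormatError(
            f"column-count mismatch between {bval_path} and {bvec_path}"
        )
    bvecs = np.asarray(bvec_rows).T.astype(float)
    norms = np.linalg.norm(bvecs, axis=1)
    dw = (bvals > b0_threshold) & (norms > 0)
    bvecs[dw] /= norms[dw, np.newaxis]
    return GradientScheme(bvals=bvals, bvecs=bvecs, b0_threshold=b0_threshold)


def write_gradient_scheme(
    scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path
) -> None:
    Path(bval_path).write_text(" ".join(f"{b:.6g}" for b in scheme.bvals) + "\n")
    lines = [" ".join(f"{v:.9f}" for v in scheme.bvecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


def sphere_points(n: int, seed: int = 0, n_iter: int = 300) -> np.ndarray:
    """``n`` directions spread on the sphere by electrostatic repulsion.

    Pairwise 1/d^2 Coulomb forces with antipodal symmetry (each point repels
    every other point and its antipode), tangential projection, and a fixed
    iteration budget.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.1
    for it in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            d = x[:, np.newaxis, :] - sign * x[np.newaxis, :, :]
            r2 = np.sum(d * d, axis=-1)
            if sign > 0:
                np.fill_diagonal(r2, np.inf)
            force += np.sum(d / (r2[..., np.newaxis] ** 1.5 + 1e-12), axis=1)
        # keep only the tangential component so points stay on the sphere
        force -= np.sum(force * x, axis=1, keepdims=True) * x
        fmax = np.max(np.linalg.norm(force, axis=1))
        x = x + step / (1.0 + it / 50.0) * force / max(fmax, 1e-12)
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def study_scheme(seed: int = 0, b0_threshold: float = DEFAULT_B0_THRESHOLD) -> GradientScheme:
    """The study's multi-shell protocol: 8 b0, 27 directions at b=1000,
    62 directions at b=2500 s/mm^2 (97 volumes).

    Direction tables are generated by electrostatic-repulsion spacing from
    the seed; the protocol's exact vendor table is not public, so this is an
    emulation with the stated shell structure.
    """
    bvals = np.concatenate([np.zeros(8), np.full(27, 1000.0), np.full(62, 2500.0)])
    bvecs = np.concatenate(
        [np.zeros((8, 3)), sphere_points(27, seed=seed), sphere_points(62, seed=seed + 1)]
    )
    return GradientScheme(bvals=bvals, bvecs=bvecs, b0_threshold=b0_threshold)


def min_pairwise_angle(directions: np.ndarray) -> float:
    """Smallest pairwise angular separation (degrees), antipodally symmetric."""
    d = np.asarray(directions, dtype=float)
    cosangles = np.abs(d @ d.T)
    np.fill_diagonal(cosangles, 0.0)
    return math.degrees(math.acos(min(np.max(cosangles), 1.0)))


def read_volume(path: str | Path, mask: np.ndarray | None = None) -> Volume4D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    return Volume4D(data=data, affine=img.affine, mask=mask)


def write_volume(vol: Volume4D, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0


def write_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))
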
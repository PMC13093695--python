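import itertools

import numpy as np
import pytest

from niikit.acquisition import study_scheme
from niikit.forward import AnisoCompartment, IsoSpectrum, VoxelModel


@pytest.fixture(scope="session")
def scheme():
    """The study's 97-volume two-shell scheme (8 b0 + 27 @ b1000 + 62 @ b2500)."""
    return study_scheme(0)


def mixture_voxel(ff: float, rf: float, axis: int = 0,
                  lambda_par: float = 1.7, lambda_perp: float = 0.3,
                  d_restricted: float = 0.1, d_hindered: float = 1.0) -> VoxelModel:
    """Three-compartment voxel: fiber + restricted + hindered pools.

    Fractions are renormalized to sum to 1 so every (ff, rf) pair is a
    physically valid mixture (hindered takes the non-negative remainder).
    """
    hind = max(0.0, 1.0 - ff - rf)
    total = ff + rf + hind
    ff, rf, hind = ff / total, rf / total, hind / total
    direction = np.zeros(3)
    direction[axis] = 1.0
    iso = IsoSpectrum.linear()
    iso.weights[np.argmin(np.abs(iso.D_grid - d_restricted))] = rf
    iso.weights[np.argmin(np.abs(iso.D_grid - d_hindered))] += hind
    aniso = []
    if ff > 0:
        aniso = [AnisoCompartment(f=ff, lambda_par=lambda_par,
                                  lambda_perp=lambda_perp, direction=direction)]
    return VoxelModel(aniso=aniso, iso=iso)


def factorial_cells():
    """The recovery factorial: FF x RF x orientation axis (27 cells)."""
    return list(itertools.product([0.2, 0.5, 0.8], [0.0, 0.1, 0.3], [0, 1, 2]))
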
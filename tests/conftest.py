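"""Shared fixtures: schemes, phantom fields, and pre-fitted posteriors.

Expensive MCMC fits are session-scoped so the acceptance tests and unit
tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from fibertrace.fixtures import standard_fixtures
from fibertrace.orientation_model import fit_ball_and_sticks
from fibertrace.phantom import (
    GroundTruthField,
    make_scheme,
    simulate_signal,
)

S0 = 100.0
D_TRUE = 0.0017


@pytest.fixture(scope="session")
def scheme60():
    return make_scheme(n_directions=60, bvalue=1000.0, n_b0=1, seed=0)


def make_voxel_field(n_vox, fracs, orients, s0=S0, d=D_TRUE) -> GroundTruthField:
    """n_vox identical voxels with the given stick populations (grid (n,1,1))."""
    F = np.zeros((n_vox, 1, 1, 3))
    O = np.zeros((n_vox, 1, 1, 3, 3))
    for p, (f, o) in enumerate(zip(fracs, orients)):
        F[:, 0, 0, p] = f
        O[:, 0, 0, p] = np.asarray(o, dtype=float)
    return GroundTruthField(orientations=O, fractions=F, affine=np.eye(4), s0=s0, d=d)


def make_voxel_dwi(scheme, n_vox, fracs, orients, snr=0.0, seed=0):
    field = make_voxel_field(n_vox, fracs, orients)
    sigma = 0.0 if snr == 0 else S0 / snr
    return simulate_signal(field, scheme, noise_sigma=sigma, rng_seed=seed)


def angle_deg(u, v) -> float:
    """Axial (sign-free) angle between two orientations, in degrees."""
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(min(1.0, c))))


@pytest.fixture(scope="session")
def single_stick_posterior(scheme60):
    """50 voxels, one stick f=0.6 along x, SNR 30: shared recovery target."""
    truth = np.array([1.0, 0.0, 0.0])
    dwi = make_voxel_dwi(scheme60, 50, [0.6], [truth], snr=30, seed=11)
    post = fit_ball_and_sticks(dwi, rng_seed=12)
    return post, truth


@pytest.fixture(scope="session")
def crossing_posterior(scheme60):
    """20 voxels with sticks f=(0.4, 0.3) at 90 degrees, SNR 30."""
    truths = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    dwi = make_voxel_dwi(scheme60, 20, [0.4, 0.3], truths, snr=30, seed=21)
    post = fit_ball_and_sticks(dwi, rng_seed=22)
    return post, truths


@pytest.fixture(scope="session")
def bowtie_fitted(scheme60):
    """Bowtie fixture with a posterior fitted from simulated data (desk scale)."""
    from scipy import ndimage

    from fibertrace.orientation_model import fit_tensor

    fx = standard_fixtures("bowtie")
    dwi = fx.simulate(scheme60, snr=30, rng_seed=101)
    tensor = fit_tensor(dwi)
    wm = ndimage.binary_dilation((tensor.fa > 0.15) & tensor.valid, iterations=1)
    wm |= fx.seed_mask
    post = fit_ball_and_sticks(
        dwi, mask=wm, n_burn=200, n_post=50, thin=5, rng_seed=102
    )
    return fx, post


@pytest.fixture(scope="session")
def crossing_fitted(scheme60):
    """Crossing fixture with a fitted posterior."""
    from scipy import ndimage

    from fibertrace.orientation_model import fit_tensor

    fx = standard_fixtures("crossing")
    dwi = fx.simulate(scheme60, snr=30, rng_seed=301)
    tensor = fit_tensor(dwi)
    wm = ndimage.binary_dilation((tensor.fa > 0.15) & tensor.valid, iterations=1)
    wm |= fx.seed_mask
    post = fit_ball_and_sticks(
        dwi, mask=wm, n_burn=200, n_post=50, thin=5, rng_seed=302
    )
    return fx, post


@pytest.fixture(scope="session")
def parallel_fitted(scheme60):
    """parallel_tracts fixture with a fitted posterior."""
    from scipy import ndimage

    from fibertrace.orientation_model import fit_tensor

    fx = standard_fixtures("parallel_tracts")
    dwi = fx.simulate(scheme60, snr=30, rng_seed=201)
    tensor = fit_tensor(dwi)
    wm = ndimage.binary_dilation((tensor.fa > 0.15) & tensor.valid, iterations=1)
    for m in fx.seed_masks.values():
        wm |= m
    post = fit_ball_and_sticks(
        dwi, mask=wm, n_burn=200, n_post=50, thin=5, rng_seed=202
    )
    return fx, post
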
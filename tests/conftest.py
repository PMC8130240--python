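"""Shared fixtures: tiny deterministic volumes and session-scoped phantom runs.

The expensive end-to-end registrations (full-size phantom, pyramid-benefit
study) are computed once per session and shared by the evaluation and
acceptance tests that consume them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import lkdose as lk

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")
from lkdose.evaluation import GammaParams
from lkdose.phantom import PhantomSpec, make_case, smooth_spec
from lkdose.pipeline import register_case
from lkdose.preregister import compose_affine_field


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """A 9x12x12 textured volume with unit spacing."""
    data = rng.normal(0.0, 50.0, (9, 12, 12))
    return lk.ImageVolume(data, (1.0, 1.0, 1.0))


@pytest.fixture
def ramp_pair():
    """Reference = 3x ramp; floating = same ramp shifted by 0.5 voxel along x."""
    z, y, x = np.meshgrid(*(np.arange(n, dtype=float) for n in (9, 20, 20)), indexing="ij")
    ref = lk.ImageVolume(3.0 * x, (1.0, 1.0, 1.0))
    flt = lk.ImageVolume(3.0 * (x - 0.5), (1.0, 1.0, 1.0))
    return ref, flt


def analytic_bump_image(shape=(32, 96, 96), spacing=(2.5, 1.0, 1.0), seed=1, n_bumps=40):
    """Smooth analytic multi-bump image, evaluable at arbitrary world points.

    Affine parameter-recovery oracles need a floating image constructed
    without resampling (resampling narrowband texture biases the MSE optimum
    away from the generating transform), so this returns the evaluator
    function together with the grid world coordinates.
    """
    from lkdose.core import Geometry, _identity_coords, voxel_to_world

    geom = Geometry(spacing)
    idx = np.moveaxis(_identity_coords(shape), 0, -1)
    world = voxel_to_world(geom, idx)
    c = np.array([(n - 1) / 2 * s for n, s in zip(shape, spacing)])
    rng = np.random.default_rng(seed)
    centers = c + (rng.random((n_bumps, 3)) - 0.5) * np.array([50.0, 70.0, 70.0])
    widths = 4.0 + 6.0 * rng.random(n_bumps)
    amps = 200.0 * (rng.random(n_bumps) - 0.5)

    def evaluate(p):
        out = np.zeros(p.shape[:-1])
        for ctr, w, a in zip(centers, widths, amps):
            out += a * np.exp(-np.sum((p - ctr) ** 2, axis=-1) / (2.0 * w * w))
        return out

    return evaluate, world, geom, c


@pytest.fixture(scope="session")
def default_case():
    """Default full-structure phantom (bumps + noise + rods), 64x128x128."""
    return make_case(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def registered_default_case(default_case):
    """The full registration chain run once on the default phantom."""
    bundle, truth = default_case
    res = register_case(bundle, gamma_params=GammaParams(gamma_cap=1.5))
    total = compose_affine_field(res.affine, res.field)
    return bundle, truth, res, total


@pytest.fixture(scope="session")
def pyramid_benefit_fields():
    """Single-level vs two-level LK on the smooth phantom shifted 6 voxels."""
    spec = smooth_spec(shift_voxels=(0.0, 0.0, 6.0), shape=(32, 96, 96), seed=3)
    bundle, truth = make_case(spec)
    fields = {
        levels: lk.pyramid_lk_register(
            bundle.reference_ct,
            bundle.floating_ct,
            lk.LKParams(pyramid_levels=levels, window_radius_voxels=3),
        )
        for levels in (1, 2)
    }
    return bundle, truth, fields
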
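"""Shared fixtures: geometries, patch sets and transport runs reused
across test modules to keep the suite fast. All runs are seeded."""

import numpy as np
import pytest

import cavidose as cv


@pytest.fixture(scope="session")
def sphere48():
    """48.5-ml spherical bladder (inner radius 22.62 mm)."""
    return cv.make_bladder_shape("sphere", 48.5)


@pytest.fixture(scope="session")
def sphere48_patches(sphere48):
    return cv.tessellate_surface(sphere48, 200)


@pytest.fixture(scope="session")
def absorbing_map():
    """Clear void, perfectly absorbing wall (inverse-square oracle)."""
    preset = cv.preset_properties()
    return cv.PropertyMap(
        void=preset.void,
        wall=cv.OpticalProperties(mu_a=1000.0, mu_s=0.0, g=0.0, n=1.37),
        adipose=preset.adipose,
    )


@pytest.fixture(scope="session")
def central_source():
    return cv.SourceSpec(position=(0.0, 0.0, 0.0), power=2500.0)


@pytest.fixture(scope="session")
def absorbing_run(sphere48, sphere48_patches, absorbing_map, central_source):
    """2e5-packet clear-void absorbing-wall run on the 48.5-ml sphere."""
    return cv.run_transport(
        sphere48,
        absorbing_map,
        central_source,
        sphere48_patches,
        cv.TransportConfig(n_packets=200_000, seed=101),
    )


@pytest.fixture(scope="session")
def preset_run(sphere48, sphere48_patches, central_source):
    """1e5-packet run with the realistic 525-nm preset (wall albedo 0.97)."""
    return cv.run_transport(
        sphere48,
        cv.preset_properties(),
        central_source,
        sphere48_patches,
        cv.TransportConfig(n_packets=100_000, seed=55),
    )


@pytest.fixture(scope="session")
def thick_wall_run(central_source):
    """Thick-wall sphere for depth-profile work (12-mm wall)."""
    geom = cv.make_bladder_shape("sphere", 173.0, wall_thickness_mm=12.0)
    patches = cv.tessellate_surface(geom, 100)
    dm = cv.run_transport(
        geom,
        cv.preset_properties(),
        central_source,
        patches,
        cv.TransportConfig(n_packets=100_000, seed=77, weight_cutoff=1e-5),
    )
    return geom, dm


@pytest.fixture(scope="session")
def diffuse_crossing_log(sphere48_patches):
    """Synthetic crossing log of a uniform Lambertian field, E0 = 50.

    Crossing points are area-distributed over the patches and crossing
    directions cosine-weighted about each patch's outward normal — the
    flux distribution a uniform diffuse field produces. Total weight
    equals E0 * area, so the true irradiance everywhere is E0.
    """
    p = sphere48_patches
    rng = np.random.default_rng(12345)
    n = 800_000
    e0 = 50.0  # mW cm^-2
    ids = rng.choice(p.n_patches, size=n, p=p.patch_areas / p.total_area)
    ct = np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    st = np.sqrt(1.0 - ct**2)
    nrm = p.patch_normals[ids]
    helper = np.where(
        np.abs(nrm[:, 2:3]) < 0.9,
        np.tile([0.0, 0.0, 1.0], (n, 1)),
        np.tile([1.0, 0.0, 0.0], (n, 1)),
    )
    t1 = np.cross(nrm, helper)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(nrm, t1)
    dirs = (
        ct[:, None] * nrm
        + st[:, None] * (np.cos(phi)[:, None] * t1 + np.sin(phi)[:, None] * t2)
    )
    w = np.full(n, e0 * p.total_area / 100.0 / n)  # mW per crossing
    return (ids, dirs, w), e0
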
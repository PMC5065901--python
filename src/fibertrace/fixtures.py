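"""Standard phantom fixtures with documented ground truth.

Every fixture is fully synthetic and parameter-free to construct, so the
whole analysis chain is testable without any external data:

* ``straight`` — one straight bundle, a 1-voxel seed at one end, no
  exclusions.
* ``crossing`` — two orthogonal straight bundles crossing at the grid
  center (the crossing voxel carries two populations at 90 degrees).
* ``parallel_tracts`` — two parallel, non-contacting bundles with one seed
  mask each; their voxel sets are disjoint by construction, so their
  tractograms must separate.
* ``bowtie`` — six sub-bundles packed into a narrow waist that fan out
  toward two endpoint zones; a seed mask at the waist allocates a designed
  number of seed voxels to each sub-bundle (6, 5, ..., 1), which fixes the
  ground-truth ordering of the six ROI connection strengths on the endpoint
  surface (roi1 strongest ... roi6 weakest). Axial and coronal exclusion
  planes sit clear of the bundles.

All fixtures use a 1 mm isotropic grid with an identity-scaled affine, so
world mm coordinates coincide with voxel indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import (
    AcquisitionScheme,
    Bundle,
    DWIDataset,
    D_IN_VIVO,
    GroundTruthField,
    PhantomSpec,
    build_orientation_field,
    make_scheme,
    simulate_signal,
    straight_bundle,
)
from .surface_fingerprint import ROIAtlas, SurfaceMesh

__all__ = ["Fixture", "standard_fixtures", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("straight", "crossing", "bowtie", "parallel_tracts")


@dataclass
class Fixture:
    """A phantom spec plus masks, surfaces and documented ground truth."""

    name: str
    spec: PhantomSpec
    seed_masks: dict[str, np.ndarray]
    exclusion_masks: list[np.ndarray]
    termination_mask: np.ndarray
    mesh: SurfaceMesh | None
    atlas: ROIAtlas | None
    ground_truth: dict
    s0: float = 100.0
    d: float = D_IN_VIVO
    snr: float = 30.0  # fixtures expose SNR; the source data's SNR is unknown

    @property
    def seed_mask(self) -> np.ndarray:
        """The primary seed mask (first entry)."""
        return next(iter(self.seed_masks.values()))

    def build_field(self) -> GroundTruthField:
        return build_orientation_field(self.spec, s0=self.s0, d=self.d)

    def make_scheme(self, n_directions: int = 60, bvalue: float = 1000.0,
                    n_b0: int = 1, seed: int = 0) -> AcquisitionScheme:
        return make_scheme(n_directions, bvalue, n_b0, seed)

    def simulate(
        self,
        scheme: AcquisitionScheme | None = None,
        snr: float | None = None,
        rng_seed: int = 0,
    ) -> DWIDataset:
        """Forward-simulate DWI for this fixture at the given SNR."""
        if scheme is None:
            scheme = self.make_scheme()
        field = self.build_field()
        snr = self.snr if snr is None else snr
        sigma = 0.0 if snr == 0 else self.s0 / snr
        return simulate_signal(field, scheme, noise_sigma=sigma, rng_seed=rng_seed)


def _empty(shape):
    return np.zeros(shape, dtype=bool)


def _straight_fixture() -> Fixture:
    shape = (16, 8, 8)
    bundle = straight_bundle((1, 4, 4), (14, 4, 4), radius=0.45,
                             volume_fraction=0.7, name="main")
    spec = PhantomSpec(grid_shape=shape, bundles=(bundle,))
    seed = _empty(shape)
    seed[2, 4, 4] = True
    return Fixture(
        name="straight",
        spec=spec,
        seed_masks={"seed": seed},
        exclusion_masks=[],
        termination_mask=np.ones(shape, dtype=bool),
        mesh=None,
        atlas=None,
        ground_truth={
            "bundle_axis": "x",
            "bundle_voxels": [[x, 4, 4] for x in range(1, 15)],
            "seed_voxel": [2, 4, 4],
        },
    )


def _crossing_fixture() -> Fixture:
    shape = (16, 16, 8)
    a = straight_bundle((1, 8, 4), (14, 8, 4), radius=0.45,
                        volume_fraction=0.35, name="along_x")
    b = straight_bundle((8, 1, 4), (8, 14, 4), radius=0.45,
                        volume_fraction=0.35, name="along_y")
    spec = PhantomSpec(grid_shape=shape, bundles=(a, b))
    seed = _empty(shape)
    seed[2, 8, 4] = True
    return Fixture(
        name="crossing",
        spec=spec,
        seed_masks={"seed": seed},
        exclusion_masks=[],
        termination_mask=np.ones(shape, dtype=bool),
        ground_truth={"crossing_voxel": [8, 8, 4], "crossing_angle_deg": 90.0},
        mesh=None,
        atlas=None,
    )


def _parallel_fixture() -> Fixture:
    shape = (24, 16, 8)
    a = straight_bundle((2, 4, 4), (21, 4, 4), radius=0.45,
                        volume_fraction=0.7, name="tract_a")
    b = straight_bundle((2, 11, 4), (21, 11, 4), radius=0.45,
                        volume_fraction=0.7, name="tract_b")
    spec = PhantomSpec(grid_shape=shape, bundles=(a, b))
    seed_a = _empty(shape)
    seed_a[11, 4, 4] = seed_a[12, 4, 4] = True
    seed_b = _empty(shape)
    seed_b[11, 11, 4] = seed_b[12, 11, 4] = True
    return Fixture(
        name="parallel_tracts",
        spec=spec,
        seed_masks={"seed_a": seed_a, "seed_b": seed_b},
        exclusion_masks=[],
        termination_mask=np.ones(shape, dtype=bool),
        ground_truth={
            "tract_a_voxels": [[x, 4, 4] for x in range(2, 22)],
            "tract_b_voxels": [[x, 11, 4] for x in range(2, 22)],
            "separation_mm": 7.0,
        },
        mesh=None,
        atlas=None,
    )


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _bowtie_bundle(waist_y, end_y, x0, x1, xc, z, radius, f, name):
    def path(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        x = x0 + t * (x1 - x0)
        u = np.abs(x - xc) / (x1 - xc)
        y = waist_y + _smoothstep(u) * (end_y - waist_y)
        return np.stack([x, y, np.full_like(x, float(z))], axis=1)

    return Bundle(path, radius, f, name)


def _plane_mesh(x, ys, zs):
    """Rectangular triangulated plane at constant x."""
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    verts = np.stack([np.full(yy.size, float(x)), yy.ravel(), zz.ravel()], axis=1)
    ny, nz = len(ys), len(zs)
    faces = []
    for i in range(ny - 1):
        for j in range(nz - 1):
            a = i * nz + j
            b = (i + 1) * nz + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return verts, np.asarray(faces, dtype=int)


# bow-tie layout constants: waist rows, endpoint rows, seed voxels per bundle.
# Tubes are 0.9 mm radius so each is 1-2 voxels wide and tolerant of the
# lateral drift probabilistic tracking accumulates; waist spacing 2 mm keeps
# the tubes disjoint while still much narrower than the 3 mm endpoint fan.
_BOWTIE_WAIST_Y = [4, 6, 8, 10, 12, 14]
_BOWTIE_END_Y = [1, 4, 7, 10, 13, 16]
_BOWTIE_SEED_COUNTS = [6, 5, 4, 3, 2, 1]
_BOWTIE_RADIUS = 0.9
_BOWTIE_Z = 4
_BOWTIE_X0, _BOWTIE_X1, _BOWTIE_XC = 2.0, 29.0, 15.5


def _bowtie_fixture() -> Fixture:
    shape = (32, 20, 9)
    bundles = []
    for k, (wy, ey) in enumerate(zip(_BOWTIE_WAIST_Y, _BOWTIE_END_Y)):
        bundles.append(
            _bowtie_bundle(
                wy, ey, _BOWTIE_X0, _BOWTIE_X1, _BOWTIE_XC, _BOWTIE_Z,
                radius=_BOWTIE_RADIUS, f=0.7, name=f"sub{k + 1}",
            )
        )
    spec = PhantomSpec(grid_shape=shape, bundles=tuple(bundles))

    seed = _empty(shape)
    seed_x0 = 13
    for k, (wy, n_seed) in enumerate(zip(_BOWTIE_WAIST_Y, _BOWTIE_SEED_COUNTS)):
        seed[seed_x0 : seed_x0 + n_seed, wy, _BOWTIE_Z] = True

    # exclusion planes clear of the bundles (z extremes, far coronal slice)
    ex_bottom = _empty(shape)
    ex_bottom[:, :, 0] = True
    ex_top = _empty(shape)
    ex_top[:, :, 8] = True
    ex_coronal = _empty(shape)
    ex_coronal[:, 19, :] = True

    ys = np.arange(0.0, 18.0)
    zs = np.arange(1.0, 8.0)
    v_plus, f_plus = _plane_mesh(28.0, ys, zs)
    v_minus, f_minus = _plane_mesh(3.0, ys, zs)
    vertices = np.vstack([v_plus, v_minus])
    faces = np.vstack([f_plus, f_minus + v_plus.shape[0]])
    mesh = SurfaceMesh(vertices=vertices, faces=faces)

    labels = np.zeros(vertices.shape[0], dtype=int)
    names = {}
    for k, ey in enumerate(_BOWTIE_END_Y):
        lid = k + 1
        names[lid] = f"roi{lid}"
        on_plus = vertices[:, 0] == 28.0
        patch = (
            on_plus
            & (np.abs(vertices[:, 1] - ey) <= 1.0)
            & (np.abs(vertices[:, 2] - _BOWTIE_Z) <= 1.0)
        )
        labels[patch] = lid
    atlas = ROIAtlas(labels=labels, names=names)

    return Fixture(
        name="bowtie",
        spec=spec,
        seed_masks={"seed": seed},
        exclusion_masks=[ex_bottom, ex_top, ex_coronal],
        termination_mask=np.ones(shape, dtype=bool),
        mesh=mesh,
        atlas=atlas,
        ground_truth={
            "waist_x_range": [seed_x0, seed_x0 + max(_BOWTIE_SEED_COUNTS) - 1],
            "waist_y": _BOWTIE_WAIST_Y,
            "end_y": _BOWTIE_END_Y,
            "seed_voxels_per_roi": {
                f"roi{k + 1}": n for k, n in enumerate(_BOWTIE_SEED_COUNTS)
            },
            "designed_roi_order": [f"roi{k + 1}" for k in range(6)],
        },
    )


_BUILDERS = {
    "straight": _straight_fixture,
    "crossing": _crossing_fixture,
    "bowtie": _bowtie_fixture,
    "parallel_tracts": _parallel_fixture,
}


def standard_fixtures(name: str) -> Fixture:
    """Build one of the documented phantom fixtures by name."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()
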
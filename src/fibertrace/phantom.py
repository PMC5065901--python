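"""Synthetic diffusion-weighted phantoms.

Builds ground-truth fiber geometry from parametric bundle centerlines,
voxelizes it into an orientation field, and simulates the ball-and-sticks
forward signal with Rician magnitude noise.

Conventions: world coordinates in mm, voxel indices 0-based, the affine maps
voxel index to world mm (NIfTI convention). A voxel belongs to a bundle when
its center lies within ``radius`` mm of the bundle centerline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AcquisitionScheme",
    "Bundle",
    "PhantomSpec",
    "GroundTruthField",
    "DWIDataset",
    "isotropic_directions",
    "make_scheme",
    "straight_bundle",
    "arc_bundle",
    "curved_bundle",
    "build_orientation_field",
    "ball_and_sticks_signal",
    "simulate_signal",
    "D_IN_VIVO",
    "D_EX_VIVO",
]

#: default in vivo diffusivity (mm^2/s)
D_IN_VIVO = 0.0017
#: ex vivo diffusivity; 4x lower, paired with 4x larger b so bd is matched
D_EX_VIVO = D_IN_VIVO / 4.0

MAX_POPULATIONS = 3


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume diffusion weightings and unit gradient directions.

    b = 0 volumes carry zero direction vectors; all other directions are
    unit-norm.
    """

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.bvalues, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        if g.ndim != 2 or g.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        if b.shape[0] != g.shape[0]:
            raise ValueError(
                f"bvalues ({b.shape[0]}) and directions ({g.shape[0]}) lengths differ"
            )
        norms = np.linalg.norm(g, axis=1)
        dw = b > 0
        if (~dw).sum() < 1:
            raise ValueError("scheme needs at least one b = 0 volume")
        if np.any(np.abs(norms[dw] - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit-norm")
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "directions", g)

    @property
    def n_volumes(self) -> int:
        return self.bvalues.shape[0]

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvalues == 0))

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    def flipped(self) -> "AcquisitionScheme":
        """Scheme with all gradient signs inverted (antipodal test helper)."""
        return AcquisitionScheme(self.bvalues.copy(), -self.directions)


def isotropic_directions(n: int, seed: int = 0, n_iter: int = 300) -> np.ndarray:
    """Near-uniform antipodally symmetric unit vectors by electrostatic repulsion.

    Charges interact with both each other and their antipodes, the standard
    construction for isotropically distributed diffusion directions.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    eye = np.eye(n)
    for it in range(n_iter):
        lr = 0.05 * (1.0 - it / n_iter) + 0.002
        diff = v[:, None, :] - v[None, :, :]
        summ = v[:, None, :] + v[None, :, :]
        d2 = (diff**2).sum(-1) + eye
        s2 = (summ**2).sum(-1) + 1e-12
        force = (diff / d2[..., None] ** 1.5).sum(axis=1)
        force += (summ / s2[..., None] ** 1.5).sum(axis=1)
        force -= (force * v).sum(-1, keepdims=True) * v  # tangent projection
        v += lr * force / n
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def make_scheme(
    n_directions: int = 60,
    bvalue: float = 1000.0,
    n_b0: int = 1,
    seed: int = 0,
) -> AcquisitionScheme:
    """Single-shell scheme: ``n_b0`` b = 0 volumes then one shell."""
    dirs = isotropic_directions(n_directions, seed=seed)
    b = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bvalue))])
    g = np.vstack([np.zeros((n_b0, 3)), dirs])
    return AcquisitionScheme(b, g)


@dataclass(frozen=True)
class Bundle:
    """A fiber bundle: parametric centerline plus tube radius and stick fraction.

    ``centerline`` maps an array of parameters t in [0, 1] to (n, 3) world-mm
    points; the local orientation is the (numerically differentiated) tangent.
    """

    centerline: Callable[[np.ndarray], np.ndarray]
    radius: float
    volume_fraction: float
    name: str = "bundle"

    def __post_init__(self):
        if not (0.0 < self.volume_fraction <= 1.0):
            raise ValueError(f"volume_fraction must be in (0, 1], got {self.volume_fraction}")
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")

    def sample(self, n: int = 400) -> tuple[np.ndarray, np.ndarray]:
        """Return (points, unit tangents) at n parameter values."""
        t = np.linspace(0.0, 1.0, n)
        pts = np.asarray(self.centerline(t), dtype=float)
        h = 1.0 / (n - 1)
        tang = np.gradient(pts, h, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        return pts, tang


def straight_bundle(
    start: Sequence[float],
    end: Sequence[float],
    radius: float,
    volume_fraction: float,
    name: str = "straight",
) -> Bundle:
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)

    def line(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return p0[None, :] + t[:, None] * (p1 - p0)[None, :]

    return Bundle(line, radius, volume_fraction, name)


def arc_bundle(
    center: Sequence[float],
    arc_radius: float,
    radius: float,
    volume_fraction: float,
    theta0: float = 0.0,
    theta1: float = np.pi / 2,
    plane: tuple[int, int] = (0, 1),
    name: str = "arc",
) -> Bundle:
    """Circular arc in an axis-aligned plane, from angle theta0 to theta1."""
    c = np.asarray(center, dtype=float)
    i, j = plane

    def arc(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        th = theta0 + t * (theta1 - theta0)
        pts = np.tile(c, (t.shape[0], 1))
        pts[:, i] += arc_radius * np.cos(th)
        pts[:, j] += arc_radius * np.sin(th)
        return pts

    return Bundle(arc, radius, volume_fraction, name)


def curved_bundle(
    start: Sequence[float],
    end: Sequence[float],
    radius: float,
    volume_fraction: float,
    axis: int = 0,
    name: str = "curved",
) -> Bundle:
    """Smoothstep path: runs along ``axis`` while easing the transverse
    coordinates from start to end (tangent continuous, mostly axial)."""
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)

    def path(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        s = t * t * (3.0 - 2.0 * t)  # smoothstep easing for transverse axes
        pts = p0[None, :] + s[:, None] * (p1 - p0)[None, :]
        pts[:, axis] = p0[axis] + t * (p1[axis] - p0[axis])
        return pts

    return Bundle(path, radius, volume_fraction, name)


@dataclass(frozen=True)
class PhantomSpec:
    """Grid geometry plus the bundles living on it."""

    grid_shape: tuple[int, int, int]
    voxel_size: float = 1.0
    affine: np.ndarray | None = None
    bundles: tuple[Bundle, ...] = ()

    def __post_init__(self):
        shape = tuple(int(s) for s in self.grid_shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        aff = self.affine
        if aff is None:
            aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff = np.asarray(aff, dtype=float)
        if aff.shape != (4, 4) or abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "grid_shape", shape)
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "bundles", tuple(self.bundles))

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) world-mm coordinates of every voxel center."""
        nx, ny, nz = self.grid_shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).astype(float)
        return np.einsum("ab,ijkb->ijka", self.affine, idx)[..., :3]


@dataclass
class GroundTruthField:
    """Voxelized fiber populations: up to 3 (orientation, fraction) pairs."""

    orientations: np.ndarray  # (nx, ny, nz, 3, 3) unit vectors, zero if absent
    fractions: np.ndarray  # (nx, ny, nz, 3), zero if absent
    affine: np.ndarray
    s0: float = 100.0
    d: float = D_IN_VIVO

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fractions.shape[:3]

    @property
    def n_populations(self) -> np.ndarray:
        return (self.fractions > 0).sum(axis=-1)

    @property
    def free_fraction(self) -> np.ndarray:
        return 1.0 - self.fractions.sum(axis=-1)

    def white_matter_mask(self) -> np.ndarray:
        return self.n_populations > 0


@dataclass
class DWIDataset:
    """4-D diffusion-weighted signal with its scheme, affine and brain mask."""

    signal: np.ndarray  # (nx, ny, nz, n_volumes), non-negative
    scheme: AcquisitionScheme
    affine: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self):
        if self.signal.shape[-1] != self.scheme.n_volumes:
            raise ValueError(
                f"signal has {self.signal.shape[-1]} volumes but scheme has "
                f"{self.scheme.n_volumes}"
            )
        if self.brain_mask.shape != self.signal.shape[:3]:
            raise ValueError("brain_mask shape does not match signal grid")


def build_orientation_field(
    spec: PhantomSpec,
    s0: float = 100.0,
    d: float = D_IN_VIVO,
    n_centerline_samples: int = 600,
) -> GroundTruthField:
    """Voxelize bundles into per-voxel orientation/fraction populations.

    Membership: distance from voxel center to the (densely sampled)
    centerline <= bundle radius; the orientation is the tangent at the
    nearest centerline sample. Fractions are constant within the tube.
    """
    nx, ny, nz = spec.grid_shape
    centers = spec.voxel_centers().reshape(-1, 3)
    orient = np.zeros((nx * ny * nz, MAX_POPULATIONS, 3))
    frac = np.zeros((nx * ny * nz, MAX_POPULATIONS))
    count = np.zeros(nx * ny * nz, dtype=int)

    for bundle in spec.bundles:
        pts, tang = bundle.sample(n_centerline_samples)
        tree = cKDTree(pts)
        dist, idx = tree.query(centers)
        inside = dist <= bundle.radius
        over = inside & (count >= MAX_POPULATIONS)
        if over.any():
            flat = int(np.nonzero(over)[0][0])
            vox = np.unravel_index(flat, (nx, ny, nz))
            raise ValueError(
                f"more than {MAX_POPULATIONS} bundles overlap voxel {vox} "
                f"(adding bundle {bundle.name!r})"
            )
        which = np.nonzero(inside)[0]
        orient[which, count[which], :] = tang[idx[which]]
        frac[which, count[which]] = bundle.volume_fraction
        count[which] += 1

    total = frac.sum(axis=1)
    if np.any(total > 1.0 + 1e-9):
        bad = int(np.argmax(total))
        vox = np.unravel_index(bad, (nx, ny, nz))
        raise ValueError(f"stick fractions sum to {total[bad]:.3f} > 1 at voxel {vox}")

    return GroundTruthField(
        orientations=orient.reshape(nx, ny, nz, MAX_POPULATIONS, 3),
        fractions=frac.reshape(nx, ny, nz, MAX_POPULATIONS),
        affine=spec.affine.copy(),
        s0=s0,
        d=d,
    )


def ball_and_sticks_signal(
    s0: np.ndarray | float,
    d: np.ndarray | float,
    fractions: np.ndarray,
    orientations: np.ndarray,
    scheme: AcquisitionScheme,
) -> np.ndarray:
    """Noise-free ball-and-sticks signal.

    S = S0 [ (1 - sum f_i) e^(-b d) + sum_i f_i e^(-b d (g . v_i)^2) ]

    ``fractions``: (..., P); ``orientations``: (..., P, 3). Returns
    (..., n_volumes).
    """
    b = scheme.bvalues
    g = scheme.directions
    fractions = np.asarray(fractions, dtype=float)
    orientations = np.asarray(orientations, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    d = np.asarray(d, dtype=float)

    ball = np.exp(-b * d[..., None])  # (..., M)
    dots2 = np.einsum("...pc,mc->...pm", orientations, g) ** 2
    sticks = np.exp(-b * d[..., None, None] * dots2)  # (..., P, M)
    fsum = fractions.sum(axis=-1)
    sig = (1.0 - fsum)[..., None] * ball + np.einsum(
        "...p,...pm->...m", fractions, sticks
    )
    return s0[..., None] * sig


def add_rician_noise(
    signal: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Magnitude of (S + e1, e2) with e ~ N(0, sigma^2) i.i.d."""
    e1 = rng.normal(0.0, sigma, size=signal.shape)
    e2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


def simulate_signal(
    field: GroundTruthField,
    scheme: AcquisitionScheme,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    brain_mask: np.ndarray | None = None,
) -> DWIDataset:
    """Forward-simulate a DWI dataset from a ground-truth field.

    ``noise_sigma`` is on the S0 scale (SNR = S0 / sigma); 0 gives the exact
    closed form. Reproducible for a given ``rng_seed``.
    """
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    clean = ball_and_sticks_signal(
        field.s0, field.d, field.fractions, field.orientations, scheme
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        signal = add_rician_noise(clean, noise_sigma, rng)
    else:
        signal = clean
    if brain_mask is None:
        brain_mask = np.ones(field.shape, dtype=bool)
    return DWIDataset(
        signal=signal, scheme=scheme, affine=field.affine.copy(), brain_mask=brain_mask
    )
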
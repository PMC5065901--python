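"""Probabilistic streamline tractography.

Streamlines are propagated from seed-voxel centers by repeatedly drawing a
fiber orientation from the voxel-wise posterior (nearest-voxel lookup, no
interpolation) and taking Euler steps of fixed length. Propagation stops on
the curvature constraint (minimum cosine between consecutive steps), on
reaching ``max_steps``, on leaving the termination mask / grid, or when no
population is eligible. Streamlines touching any exclusion mask are discarded
whole (``rejected_exclusion``); every other streamline is ``accepted`` with
its termination reason recorded.

Each streamline owns an independent RNG stream derived from
``(rng_seed, streamline_index)``, which makes runs reproducible and makes
visitation counts monotone under exclusion-mask growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .orientation_model import OrientationPosterior

__all__ = [
    "TrackingParams",
    "Streamline",
    "StreamlineSet",
    "VisitationMap",
    "PosteriorField",
    "draw_orientation",
    "propagate_streamline",
    "track_from_mask",
]


@dataclass(frozen=True)
class TrackingParams:
    n_samples_per_voxel: int = 5000
    step_size: float = 0.5  # mm
    max_steps: int = 2000
    curvature_threshold: float = 0.2  # minimum cosine of the inter-step angle
    fraction_threshold: float = 0.05
    bidirectional: bool = True
    jitter: bool = False  # uniform intra-voxel seed offset
    rng_seed: int = 0

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError(f"step_size must be positive, got {self.step_size}")
        if self.max_steps < 1:
            raise ValueError(f"max_steps must be >= 1, got {self.max_steps}")
        if not (0.0 <= self.curvature_threshold <= 1.0):
            raise ValueError(
                f"curvature_threshold must be in [0, 1], got {self.curvature_threshold}"
            )
        if self.n_samples_per_voxel < 1:
            raise ValueError(
                f"n_samples_per_voxel must be >= 1, got {self.n_samples_per_voxel}"
            )


@dataclass
class Streamline:
    """Ordered world-space points plus acceptance status.

    ``status`` is ``"accepted"`` or ``"rejected_exclusion"``; the stopping
    reason of the (forward) half is one of ``curvature``, ``max_steps``,
    ``left_mask``, ``no_orientation``. For bidirectional streamlines the
    backward half's reason is kept separately.
    """

    points: np.ndarray
    status: str
    reason: str | None = None
    reason_backward: str | None = None

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class StreamlineSet:
    streamlines: list[Streamline]
    affine: np.ndarray

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    @property
    def n_accepted(self) -> int:
        return sum(1 for s in self.streamlines if s.accepted)

    @property
    def n_rejected(self) -> int:
        return sum(1 for s in self.streamlines if s.status == "rejected_exclusion")

    def accepted_streamlines(self) -> list[Streamline]:
        return [s for s in self.streamlines if s.accepted]


@dataclass
class VisitationMap:
    """Per-voxel count of accepted streamlines visiting the voxel.

    A streamline increments a voxel at most once regardless of how many of
    its points fall inside, so every count is bounded by ``n_accepted``.
    """

    counts: np.ndarray
    n_attempted: int
    n_accepted: int
    affine: np.ndarray


class PosteriorField:
    """Dense posterior arrays plus the voxel geometry needed for tracking.

    ``prepare`` caches flat eligibility tables for a fraction threshold so
    the propagation loop runs on scalar reads instead of numpy slicing.
    """

    def __init__(self, post: OrientationPosterior):
        self.shape = post.shape
        self.affine = np.asarray(post.affine, dtype=float)
        self.inv_affine = np.linalg.inv(self.affine)
        self.frac = post.dense_fraction_samples()  # (nx, ny, nz, K, S)
        self.orient = post.dense_orientation_samples()  # (nx, ny, nz, K, S, 3)
        self.n_post = post.n_post
        self.max_populations = post.max_populations
        self._prep_threshold: float | None = None

    def prepare(self, threshold: float) -> None:
        if self._prep_threshold == threshold:
            return
        K, S = self.max_populations, self.n_post
        frac2 = self.frac.reshape(-1, K, S)
        # a zero fraction is never eligible, even at threshold 0
        elig = (frac2 >= threshold) & (frac2 > 0)
        self._elig = elig
        self._elig_count = elig.sum(axis=1).astype(np.int8)
        self._ffl = np.asarray(frac2, dtype=np.float64)
        self._ofl = np.ascontiguousarray(
            self.orient.reshape(-1, K, S, 3), dtype=np.float64
        ).reshape(-1)
        self._prep_threshold = threshold

    def voxel_of(self, point) -> tuple[int, int, int]:
        """Nearest voxel index of a world point; ties round half-up."""
        m = self.inv_affine
        x, y, z = point
        i = math.floor(m[0, 0] * x + m[0, 1] * y + m[0, 2] * z + m[0, 3] + 0.5)
        j = math.floor(m[1, 0] * x + m[1, 1] * y + m[1, 2] * z + m[1, 3] + 0.5)
        k = math.floor(m[2, 0] * x + m[2, 1] * y + m[2, 2] * z + m[2, 3] + 0.5)
        return i, j, k

    def inside(self, vox) -> bool:
        nx, ny, nz = self.shape
        return 0 <= vox[0] < nx and 0 <= vox[1] < ny and 0 <= vox[2] < nz

    def _draw_flat(self, flat: int, s: int, prev_dir, rng):
        """Orientation draw at flat voxel index for posterior sample ``s``.

        Among eligible populations, follows the one best aligned with
        ``prev_dir`` (max |dot|), sign-flipped to continue forward; with no
        ``prev_dir`` (seeding) picks one with probability proportional to its
        sampled fraction. Returns an (x, y, z) float tuple or None.
        """
        if self._elig_count[flat, s] == 0:
            return None
        K, S = self.max_populations, self.n_post
        elig_row = self._elig[flat]
        base_vox = (flat * K) * S * 3
        if prev_dir is None:
            total = 0.0
            for p in range(K):
                if elig_row[p, s]:
                    total += self._ffl[flat, p, s]
            u = rng.random() * total
            acc = 0.0
            chosen = -1
            for p in range(K):
                if elig_row[p, s]:
                    acc += self._ffl[flat, p, s]
                    chosen = p
                    if u < acc:
                        break
            base = base_vox + (chosen * S + s) * 3
            return (self._ofl[base], self._ofl[base + 1], self._ofl[base + 2])
        px, py, pz = prev_dir
        best = -1.0
        bx = by = bz = 0.0
        for p in range(K):
            if not elig_row[p, s]:
                continue
            base = base_vox + (p * S + s) * 3
            ox = self._ofl[base]
            oy = self._ofl[base + 1]
            oz = self._ofl[base + 2]
            dot = ox * px + oy * py + oz * pz
            score = dot if dot >= 0 else -dot
            if score > best:
                best = score
                if dot < 0:
                    bx, by, bz = -ox, -oy, -oz
                else:
                    bx, by, bz = ox, oy, oz
        return (bx, by, bz)

    def draw(self, vox, prev_dir, rng, fraction_threshold: float):
        """One orientation draw at a voxel; None when nothing is eligible.

        A posterior sample index is drawn uniformly; see ``_draw_flat`` for
        the population choice rule.
        """
        self.prepare(fraction_threshold)
        nx, ny, nz = self.shape
        flat = (vox[0] * ny + vox[1]) * nz + vox[2]
        s = int(rng.integers(self.n_post))
        out = self._draw_flat(flat, s, None if prev_dir is None else tuple(prev_dir), rng)
        return None if out is None else np.asarray(out)


def _as_field(post) -> PosteriorField:
    return post if isinstance(post, PosteriorField) else PosteriorField(post)


def draw_orientation(
    post,
    voxel,
    prev_dir,
    rng,
    fraction_threshold: float = 0.05,
):
    """Public wrapper around :meth:`PosteriorField.draw`."""
    fld = _as_field(post)
    if not fld.inside(voxel):
        raise ValueError(f"voxel {tuple(voxel)} outside posterior field {fld.shape}")
    return fld.draw(tuple(voxel), prev_dir, rng, fraction_threshold)


def _combine_masks(shape, masks) -> np.ndarray | None:
    if not masks:
        return None
    out = np.zeros(shape, dtype=bool)
    for m in masks:
        if m.shape != shape:
            raise ValueError(f"mask shape {m.shape} does not match grid {shape}")
        out |= m.astype(bool)
    return out


def _propagate_half(
    fld: PosteriorField,
    seed_point,
    init_prev,
    params: TrackingParams,
    exclusion: np.ndarray | None,
    termination: np.ndarray | None,
    rng,
):
    """Propagate one direction; returns (points, reason, touched_exclusion).

    Hot loop: runs on scalar arithmetic over the field's flat caches; sample
    indices for the whole half are drawn up front in one vectorized call.
    """
    step = params.step_size
    curv = params.curvature_threshold
    fld.prepare(params.fraction_threshold)
    nx, ny, nz = fld.shape
    m = fld.inv_affine
    m00, m01, m02, m03 = m[0]
    m10, m11, m12, m13 = m[1]
    m20, m21, m22, m23 = m[2]
    exc_flat = exclusion.reshape(-1) if exclusion is not None else None
    term_flat = termination.reshape(-1) if termination is not None else None

    x, y, z = (float(seed_point[0]), float(seed_point[1]), float(seed_point[2]))
    prev = None if init_prev is None else (
        float(init_prev[0]), float(init_prev[1]), float(init_prev[2])
    )
    points = [(x, y, z)]
    i = math.floor(m00 * x + m01 * y + m02 * z + m03 + 0.5)
    j = math.floor(m10 * x + m11 * y + m12 * z + m13 + 0.5)
    k = math.floor(m20 * x + m21 * y + m22 * z + m23 + 0.5)
    flat = (i * ny + j) * nz + k
    excluded = bool(exc_flat is not None and exc_flat[flat])
    reason = "max_steps"
    samples = rng.integers(0, fld.n_post, size=params.max_steps)
    for n in range(params.max_steps):
        v = fld._draw_flat(flat, int(samples[n]), prev, rng)
        if v is None:
            reason = "no_orientation"
            break
        if prev is not None:
            cosang = v[0] * prev[0] + v[1] * prev[1] + v[2] * prev[2]
            if cosang < curv:
                reason = "curvature"
                break
        x += step * v[0]
        y += step * v[1]
        z += step * v[2]
        points.append((x, y, z))
        i = math.floor(m00 * x + m01 * y + m02 * z + m03 + 0.5)
        j = math.floor(m10 * x + m11 * y + m12 * z + m13 + 0.5)
        k = math.floor(m20 * x + m21 * y + m22 * z + m23 + 0.5)
        if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
            reason = "left_mask"
            break
        flat = (i * ny + j) * nz + k
        if exc_flat is not None and exc_flat[flat]:
            excluded = True
            break
        if term_flat is not None and not term_flat[flat]:
            reason = "left_mask"
            break
        prev = v
    return points, reason, excluded


def propagate_streamline(
    seed_point,
    post,
    params: TrackingParams,
    exclusion_masks=(),
    termination_mask: np.ndarray | None = None,
    rng=None,
) -> Streamline:
    """Propagate a single streamline from a world-space seed point.

    In bidirectional mode the backward half restarts from the seed with the
    initial direction flipped; the two halves are concatenated (reversed
    backward half + forward half) and the exclusion verdict applies to the
    whole streamline.
    """
    fld = _as_field(post)
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    seed_vox = fld.voxel_of(seed_point)
    if not fld.inside(seed_vox):
        raise ValueError(
            f"seed point {tuple(seed_point)} (voxel {seed_vox}) outside tracking domain"
        )
    exclusion = _combine_masks(fld.shape, list(exclusion_masks))
    if termination_mask is not None and termination_mask.shape != fld.shape:
        raise ValueError("termination mask shape does not match grid")
    return _propagate_one(fld, seed_point, params, exclusion, termination_mask, rng)


def _visitation_counts(fld: PosteriorField, streamlines) -> np.ndarray:
    counts = np.zeros(fld.shape, dtype=np.int64)
    nx, ny, nz = fld.shape
    inv = fld.inv_affine
    for sl in streamlines:
        if not sl.accepted:
            continue
        pts = np.hstack([sl.points, np.ones((sl.n_points, 1))])
        vox = np.floor((pts @ inv.T)[:, :3] + 0.5).astype(np.int64)
        ok = (
            (vox[:, 0] >= 0) & (vox[:, 0] < nx)
            & (vox[:, 1] >= 0) & (vox[:, 1] < ny)
            & (vox[:, 2] >= 0) & (vox[:, 2] < nz)
        )
        vox = vox[ok]
        if vox.shape[0] == 0:
            continue
        flat = np.unique(np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), fld.shape))
        counts.reshape(-1)[flat] += 1
    return counts


def track_from_mask(
    seed_mask: np.ndarray,
    post,
    params: TrackingParams,
    exclusion_masks=(),
    termination_mask: np.ndarray | None = None,
) -> tuple[StreamlineSet, VisitationMap]:
    """Seed ``n_samples_per_voxel`` streamlines from every seed-mask voxel.

    Seeds are voxel centers (optionally jittered). Streamline ``i`` draws
    from ``default_rng((rng_seed, i))``, so results are fully reproducible
    and independent across streamlines. Visitation counts accumulate accepted
    streamlines only, once per streamline per voxel.
    """
    fld = _as_field(post)
    seed_mask = np.asarray(seed_mask).astype(bool)
    if seed_mask.shape != fld.shape:
        raise ValueError("seed mask shape does not match posterior grid")
    seeds = np.argwhere(seed_mask)
    if seeds.shape[0] == 0:
        raise ValueError("seed mask is empty")
    exclusion = _combine_masks(fld.shape, list(exclusion_masks))

    streamlines: list[Streamline] = []
    aff = fld.affine
    index = 0
    for vox in seeds:
        center = aff @ np.array([vox[0], vox[1], vox[2], 1.0])
        for _ in range(params.n_samples_per_voxel):
            rng = np.random.default_rng((params.rng_seed, index))
            index += 1
            seed_pt = center[:3]
            if params.jitter:
                offs = rng.uniform(-0.5, 0.5, size=3)
                seed_pt = (aff @ np.array([vox[0] + offs[0], vox[1] + offs[1], vox[2] + offs[2], 1.0]))[:3]
            sl = _propagate_one(
                fld, seed_pt, params, exclusion, termination_mask, rng
            )
            streamlines.append(sl)

    counts = _visitation_counts(fld, streamlines)
    sset = StreamlineSet(streamlines=streamlines, affine=aff.copy())
    vmap = VisitationMap(
        counts=counts,
        n_attempted=len(streamlines),
        n_accepted=sset.n_accepted,
        affine=aff.copy(),
    )
    return sset, vmap


def _propagate_one(fld, seed_pt, params, exclusion, termination_mask, rng):
    """propagate_streamline without re-validating/re-combining masks."""
    fwd_pts, fwd_reason, fwd_exc = _propagate_half(
        fld, seed_pt, None, params, exclusion, termination_mask, rng
    )
    bwd_reason = None
    points = fwd_pts
    excluded = fwd_exc
    if params.bidirectional and len(fwd_pts) > 1:
        p0, p1 = np.asarray(fwd_pts[0]), np.asarray(fwd_pts[1])
        d0 = (p1 - p0) / params.step_size
        bwd_pts, bwd_reason, bwd_exc = _propagate_half(
            fld, seed_pt, -d0, params, exclusion, termination_mask, rng
        )
        excluded = excluded or bwd_exc
        points = bwd_pts[:0:-1] + fwd_pts
    status = "rejected_exclusion" if excluded else "accepted"
    return Streamline(
        points=np.asarray(points, dtype=float),
        status=status,
        reason=fwd_reason,
        reason_backward=bwd_reason,
    )
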
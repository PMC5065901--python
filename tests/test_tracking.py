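"""Streamline propagation rules, visitation maps, determinism, monotonicity."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from fibertrace.fixtures import standard_fixtures
from fibertrace.orientation_model import OrientationPosterior
from fibertrace.phantom import GroundTruthField
from fibertrace.tracking import (
    PosteriorField,
    Streamline,
    TrackingParams,
    draw_orientation,
    propagate_streamline,
    track_from_mask,
)

from conftest import make_voxel_field


def uniform_field(shape, orientation, f=0.7):
    """Every voxel carries one zero-spread population along ``orientation``."""
    O = np.zeros((*shape, 3, 3))
    F = np.zeros((*shape, 3))
    O[..., 0, :] = np.asarray(orientation, dtype=float)
    F[..., 0] = f
    return GroundTruthField(orientations=O, fractions=F, affine=np.eye(4))


def jittered_posterior(field, spread=0.15, n_post=50, seed=0):
    """Posterior whose samples scatter around the ground-truth orientation."""
    post = OrientationPosterior.from_field(field, n_post=n_post)
    rng = np.random.default_rng(seed)
    o = post.orientation_samples + spread * rng.normal(
        size=post.orientation_samples.shape
    )
    o /= np.linalg.norm(o, axis=-1, keepdims=True)
    post.orientation_samples = o
    return post


class TestDrawOrientation:
    def test_sign_aligned_with_previous(self):
        field = make_voxel_field(1, [0.6], [[-1.0, 0, 0]])
        post = OrientationPosterior.from_field(field)
        rng = np.random.default_rng(0)
        v = draw_orientation(post, (0, 0, 0), np.array([1.0, 0, 0]), rng)
        assert_allclose(v, [1.0, 0, 0])

    def test_argmax_dot_selects_aligned_population(self):
        field = make_voxel_field(1, [0.4, 0.4], [[1.0, 0, 0], [0, 0, 1.0]])
        post = OrientationPosterior.from_field(field)
        rng = np.random.default_rng(0)
        v = draw_orientation(post, (0, 0, 0), np.array([0.0, 0, 1.0]), rng)
        assert_allclose(v, [0, 0, 1.0])

    def test_none_when_all_below_threshold(self):
        field = make_voxel_field(1, [0.03, 0.02], [[1.0, 0, 0], [0, 1.0, 0]])
        post = OrientationPosterior.from_field(field)
        rng = np.random.default_rng(0)
        assert draw_orientation(post, (0, 0, 0), None, rng) is None

    def test_seeding_weighted_by_fraction(self):
        field = make_voxel_field(1, [0.69, 0.01], [[1.0, 0, 0], [0, 1.0, 0]])
        post = OrientationPosterior.from_field(field)
        rng = np.random.default_rng(0)
        draws = [draw_orientation(post, (0, 0, 0), None, rng) for _ in range(50)]
        # the 0.01 population is below the default threshold: never chosen
        for v in draws:
            assert_allclose(v, [1.0, 0, 0])

    def test_outside_field_rejected(self):
        field = make_voxel_field(1, [0.6], [[1.0, 0, 0]])
        post = OrientationPosterior.from_field(field)
        with pytest.raises(ValueError, match="outside"):
            draw_orientation(post, (5, 0, 0), None, np.random.default_rng(0))


class TestPropagateStreamline:
    def test_straight_unidirectional_path(self):
        field = uniform_field((16, 16, 16), [1.0, 0, 0])
        post = OrientationPosterior.from_field(field)
        params = TrackingParams(
            step_size=0.5, max_steps=10, bidirectional=False, rng_seed=0
        )
        sl = propagate_streamline((4.0, 8.0, 8.0), post, params)
        assert sl.n_points == 11
        assert_allclose(sl.points[:, 1], 8.0)
        assert_allclose(sl.points[:, 2], 8.0)
        assert_allclose(np.diff(sl.points[:, 0]), 0.5, atol=1e-9)
        assert sl.reason == "max_steps"
        assert sl.accepted

    def test_orthogonal_switch_terminates_on_curvature(self):
        field = uniform_field((16, 8, 8), [1.0, 0, 0])
        field.orientations[10:, :, :, 0, :] = [0.0, 0, 1.0]
        post = OrientationPosterior.from_field(field)
        params = TrackingParams(
            step_size=0.5, max_steps=100, curvature_threshold=0.2,
            bidirectional=False, rng_seed=0,
        )
        sl = propagate_streamline((2.0, 4.0, 4.0), post, params)
        assert sl.reason == "curvature"
        assert sl.accepted  # curvature terminates, it does not reject

    def test_exclusion_rejects_whole_streamline(self):
        field = uniform_field((16, 8, 8), [1.0, 0, 0])
        post = OrientationPosterior.from_field(field)
        exclusion = np.zeros((16, 8, 8), dtype=bool)
        exclusion[10, :, :] = True
        params = TrackingParams(step_size=0.5, max_steps=100, rng_seed=0)
        sl = propagate_streamline((4.0, 4.0, 4.0), post, params, [exclusion])
        assert sl.status == "rejected_exclusion"
        assert not sl.accepted

    def test_seed_outside_domain_is_an_error(self):
        field = uniform_field((8, 8, 8), [1.0, 0, 0])
        post = OrientationPosterior.from_field(field)
        params = TrackingParams(rng_seed=0)
        with pytest.raises(ValueError, match="outside"):
            propagate_streamline((50.0, 0.0, 0.0), post, params)

    def test_bidirectional_covers_both_sides(self):
        field = uniform_field((16, 8, 8), [1.0, 0, 0])
        post = OrientationPosterior.from_field(field)
        params = TrackingParams(step_size=0.5, max_steps=6, rng_seed=0)
        sl = propagate_streamline((8.0, 4.0, 4.0), post, params)
        assert sl.points[:, 0].min() < 8.0 < sl.points[:, 0].max()
        assert_allclose(
            np.linalg.norm(np.diff(sl.points, axis=0), axis=1), 0.5, atol=1e-6
        )


class TestTrackFromMask:
    def test_attempted_count(self):
        field = uniform_field((16, 8, 8), [1.0, 0, 0])
        post = OrientationPosterior.from_field(field)
        seed = np.zeros((16, 8, 8), dtype=bool)
        seed[4, 4, 4] = seed[5, 4, 4] = True
        params = TrackingParams(n_samples_per_voxel=7, max_steps=10, rng_seed=0)
        sset, vmap = track_from_mask(seed, post, params)
        assert vmap.n_attempted == 14
        assert len(sset) == 14

    def test_empty_seed_is_an_error(self):
        field = uniform_field((8, 8, 8), [1.0, 0, 0])
        post = OrientationPosterior.from_field(field)
        with pytest.raises(ValueError, match="empty"):
            track_from_mask(np.zeros((8, 8, 8), dtype=bool), post, TrackingParams())

    def test_zero_spread_matches_brute_force_enumeration(self):
        # independent oracle: walk the deterministic path by hand on the
        # straight fixture's ground truth (identity affine: world == index)
        fx = standard_fixtures("straight")
        from fibertrace.phantom import build_orientation_field

        field = build_orientation_field(fx.spec)
        post = OrientationPosterior.from_field(field)
        params = TrackingParams(
            n_samples_per_voxel=9, step_size=0.5, max_steps=100, rng_seed=3
        )
        sset, vmap = track_from_mask(fx.seed_mask, post, params)

        def oracle_walk(start, direction, step, shape, has_fiber):
            visited = set()
            pos = np.asarray(start, dtype=float)
            vox = tuple(int(np.floor(c + 0.5)) for c in pos)
            visited.add(vox)
            while True:
                if not has_fiber(vox):
                    break
                pos = pos + step * np.asarray(direction)
                vox = tuple(int(np.floor(c + 0.5)) for c in pos)
                if not all(0 <= v < s for v, s in zip(vox, shape)):
                    break
                visited.add(vox)
            return visited

        wm = field.white_matter_mask()
        seed_vox = tuple(np.argwhere(fx.seed_mask)[0])
        shape = field.shape
        expect = oracle_walk(seed_vox, (1, 0, 0), 0.5, shape, lambda v: wm[v])
        expect |= oracle_walk(seed_vox, (-1, 0, 0), 0.5, shape, lambda v: wm[v])
        expected_counts = np.zeros(shape, dtype=np.int64)
        for vox in expect:
            expected_counts[vox] = params.n_samples_per_voxel
        assert_allclose(vmap.counts, expected_counts)

    def test_determinism_same_seed(self, parallel_fitted):
        fx, post = parallel_fitted
        params = TrackingParams(n_samples_per_voxel=20, max_steps=80, rng_seed=77)
        _, a = track_from_mask(fx.seed_masks["seed_a"], post, params)
        _, b = track_from_mask(fx.seed_masks["seed_a"], post, params)
        assert a.counts.tobytes() == b.counts.tobytes()

    def test_status_partition(self, parallel_fitted):
        fx, post = parallel_fitted
        exclusion = np.zeros(post.shape, dtype=bool)
        exclusion[18:, :, :] = True
        params = TrackingParams(n_samples_per_voxel=25, max_steps=80, rng_seed=5)
        sset, vmap = track_from_mask(
            fx.seed_masks["seed_a"], post, params, [exclusion]
        )
        assert sset.n_accepted + sset.n_rejected == vmap.n_attempted

    def test_step_and_curvature_invariants(self, parallel_fitted):
        fx, post = parallel_fitted
        params = TrackingParams(n_samples_per_voxel=25, max_steps=80, rng_seed=6)
        sset, _ = track_from_mask(fx.seed_masks["seed_b"], post, params)
        checked = 0
        for sl in sset.accepted_streamlines():
            if sl.n_points < 3:
                continue
            steps = np.diff(sl.points, axis=0)
            lengths = np.linalg.norm(steps, axis=1)
            assert_allclose(lengths, params.step_size, atol=1e-6)
            units = steps / lengths[:, None]
            cos = np.einsum("ij,ij->i", units[:-1], units[1:])
            assert (cos >= params.curvature_threshold - 1e-9).all()
            checked += 1
        assert checked > 0

    def test_exclusion_monotonicity(self):
        field = uniform_field((20, 12, 12), [1.0, 0, 0])
        post = jittered_posterior(field, spread=0.2, seed=8)
        seed = np.zeros((20, 12, 12), dtype=bool)
        seed[3, 6, 6] = True
        small = np.zeros((20, 12, 12), dtype=bool)
        small[15, :6, :] = True
        large = small.copy()
        large[15, :, :] = True
        params = TrackingParams(n_samples_per_voxel=60, max_steps=60, rng_seed=9)
        _, vm_small = track_from_mask(seed, post, params, [small])
        _, vm_large = track_from_mask(seed, post, params, [large])
        assert (vm_large.counts <= vm_small.counts).all()

    def test_counts_bounded_by_accepted(self, parallel_fitted):
        fx, post = parallel_fitted
        params = TrackingParams(n_samples_per_voxel=25, max_steps=80, rng_seed=10)
        sset, vmap = track_from_mask(fx.seed_masks["seed_a"], post, params)
        assert vmap.counts.max() <= sset.n_accepted

    def test_half_plane_exclusion_blanks_far_side(self):
        fx = standard_fixtures("straight")
        from fibertrace.phantom import build_orientation_field

        field = build_orientation_field(fx.spec)
        post = OrientationPosterior.from_field(field)
        exclusion = np.zeros(field.shape, dtype=bool)
        exclusion[8:, :, :] = True  # whole far half of the domain
        params = TrackingParams(n_samples_per_voxel=10, max_steps=100, rng_seed=2)
        sset, vmap = track_from_mask(fx.seed_mask, post, params, [exclusion])
        assert vmap.counts[8:, :, :].sum() == 0


class TestTrackingParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"step_size": 0.0},
            {"max_steps": 0},
            {"curvature_threshold": 1.5},
            {"n_samples_per_voxel": 0},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            TrackingParams(**kwargs)
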
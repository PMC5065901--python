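"""Mesh crossings, vertex normalization, population threshold, fingerprints."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from fibertrace.surface_fingerprint import (
    Fingerprint,
    ROIAtlas,
    SurfaceMesh,
    VertexTractogram,
    connectivity_fingerprint,
    normalize_vertex_map,
    population_threshold,
    surface_hits,
)
from fibertrace.tracking import Streamline


def single_triangle_mesh():
    # triangle in the x = 1 plane
    return SurfaceMesh(
        vertices=np.array([[1.0, 0.0, 0.0], [1.0, 4.0, 0.0], [1.0, 0.0, 4.0]]),
        faces=np.array([[0, 1, 2]]),
    )


def line_streamline(points, status="accepted"):
    return Streamline(points=np.asarray(points, dtype=float), status=status)


class TestSurfaceHits:
    def test_single_crossing_hits_nearest_vertex(self):
        mesh = single_triangle_mesh()
        # crosses the triangle at (1, 0.5, 0.5): nearest vertex is index 0
        sl = line_streamline([[0.0, 0.5, 0.5], [2.0, 0.5, 0.5]])
        vt = surface_hits([sl], mesh)
        assert vt.counts.tolist() == [1, 0, 0]

    def test_no_crossing_no_counts(self):
        mesh = single_triangle_mesh()
        sl = line_streamline([[2.0, 0.5, 0.5], [3.0, 0.5, 0.5]])
        vt = surface_hits([sl], mesh)
        assert vt.counts.sum() == 0

    def test_two_streamlines_additive(self):
        mesh = single_triangle_mesh()
        sls = [
            line_streamline([[0.0, 0.5, 0.5], [2.0, 0.5, 0.5]]),
            line_streamline([[0.0, 0.6, 0.4], [2.0, 0.6, 0.4]]),
        ]
        vt = surface_hits(sls, mesh)
        assert vt.counts[0] == 2

    def test_additive_over_disjoint_subsets(self):
        mesh = single_triangle_mesh()
        sls = [
            line_streamline([[0.0, 0.5, 0.5], [2.0, 0.5, 0.5]]),
            line_streamline([[0.0, 3.0, 0.3], [2.0, 3.0, 0.3]]),
            line_streamline([[0.0, 0.3, 3.0], [2.0, 0.3, 3.0]]),
        ]
        whole = surface_hits(sls, mesh).counts
        parts = (
            surface_hits(sls[:1], mesh).counts + surface_hits(sls[1:], mesh).counts
        )
        assert_allclose(whole, parts)

    def test_at_most_once_per_streamline_per_vertex(self):
        mesh = single_triangle_mesh()
        # zig-zag: crosses the same triangle twice near the same vertex
        sl = line_streamline(
            [[0.0, 0.5, 0.5], [2.0, 0.5, 0.5], [0.0, 0.6, 0.6], [0.5, 0.55, 0.55]]
        )
        vt = surface_hits([sl], mesh)
        assert vt.counts[0] == 1

    def test_rejected_streamlines_ignored(self):
        mesh = single_triangle_mesh()
        sl = line_streamline(
            [[0.0, 0.5, 0.5], [2.0, 0.5, 0.5]], status="rejected_exclusion"
        )
        vt = surface_hits([sl], mesh)
        assert vt.counts.sum() == 0

    def test_terminal_only_counts_last_crossing(self):
        mesh = SurfaceMesh(
            vertices=np.array(
                [
                    [1.0, 0, 0], [1.0, 4, 0], [1.0, 0, 4],
                    [3.0, 0, 0], [3.0, 4, 0], [3.0, 0, 4],
                ]
            ),
            faces=np.array([[0, 1, 2], [3, 4, 5]]),
        )
        sl = line_streamline([[0.0, 0.5, 0.5], [2.0, 0.5, 0.5], [4.0, 0.5, 0.5]])
        vt_all = surface_hits([sl], mesh)
        vt_term = surface_hits([sl], mesh, terminal_only=True)
        assert vt_all.counts.sum() == 2
        assert vt_term.counts.tolist() == [0, 0, 0, 1, 0, 0]

    def test_empty_mesh_is_an_error(self):
        mesh = SurfaceMesh(vertices=np.zeros((3, 3)), faces=np.zeros((0, 3), int))
        with pytest.raises(ValueError, match="no faces"):
            surface_hits([], mesh)


class TestNormalizeVertexMap:
    def test_closed_form(self):
        vt = VertexTractogram(counts=np.array([0, 9, 99]), n_streamlines=108)
        out = normalize_vertex_map(vt)
        assert_allclose(out.normalized, [0.0, 0.5, 1.0])

    def test_all_zero_is_an_error(self):
        vt = VertexTractogram(counts=np.zeros(4, dtype=int), n_streamlines=0)
        with pytest.raises(ValueError):
            normalize_vertex_map(vt)


class TestPopulationThreshold:
    def _maps(self, nonzero_subjects, n_subjects=6, nv=3):
        maps = []
        for s in range(n_subjects):
            counts = np.zeros(nv, dtype=int)
            if s < nonzero_subjects:
                counts[0] = 5
            counts[1] = 1  # vertex 1 nonzero everywhere
            maps.append(VertexTractogram(counts=counts, n_streamlines=6))
        return maps

    def test_four_of_six_kept(self):
        kept = population_threshold(self._maps(4), 0.5)
        assert kept[0]

    def test_three_of_six_not_kept(self):
        kept = population_threshold(self._maps(3), 0.5)
        assert not kept[0]  # strict > 50 %

    def test_all_subjects_kept(self):
        kept = population_threshold(self._maps(6), 0.5)
        assert kept[0] and kept[1] and not kept[2]

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            population_threshold(self._maps(1, n_subjects=1), 0.5)


def _atlas3():
    # 9 vertices, three ROIs of 3 vertices each
    labels = np.repeat([1, 2, 3], 3)
    return ROIAtlas(labels=labels, names={1: "A", 2: "B", 3: "C"})


def _vt(values):
    values = np.asarray(values, dtype=float)
    return VertexTractogram(
        counts=(values > 0).astype(int), n_streamlines=1, normalized=values
    )


class TestConnectivityFingerprint:
    def test_min_max_scaling(self):
        vals = np.repeat([0.2, 0.5, 0.8], 3)
        fp = connectivity_fingerprint(
            [_vt(vals)], _atlas3(), ["A", "B", "C"], use_population_threshold=False
        )
        assert_allclose(fp.raw_strengths, [0.2, 0.5, 0.8])
        assert_allclose(fp.scaled_strengths, [0.0, 0.5, 1.0])
        assert not fp.degenerate

    def test_global_bracket_ratio(self):
        vals = np.repeat([0.4, 0.8, 0.6], 3)
        fp = connectivity_fingerprint(
            [_vt(vals)], _atlas3(), ["A", "B", "C"], use_population_threshold=False
        )
        # strongest vertex value is 0.8: ROI A (raw 0.4) brackets at 50
        assert fp.global_bracket[0] == pytest.approx(50.0)
        assert fp.global_bracket.max() <= 100.0 + 1e-9

    def test_degenerate_all_equal(self):
        vals = np.full(9, 0.5)
        fp = connectivity_fingerprint(
            [_vt(vals)], _atlas3(), ["A", "B", "C"], use_population_threshold=False
        )
        assert fp.degenerate
        assert_allclose(fp.scaled_strengths, 0.0)

    def test_ordering_preserved(self):
        rng = np.random.default_rng(0)
        vals = np.repeat(rng.random(3), 3)
        fp = connectivity_fingerprint(
            [_vt(vals)], _atlas3(), ["A", "B", "C"], use_population_threshold=False
        )
        assert (np.argsort(fp.scaled_strengths) == np.argsort(fp.raw_strengths)).all()

    def test_roi_order_invariance(self):
        vals = np.repeat([0.1, 0.9, 0.4], 3)
        fp1 = connectivity_fingerprint(
            [_vt(vals)], _atlas3(), ["A", "B", "C"], use_population_threshold=False
        )
        fp2 = connectivity_fingerprint(
            [_vt(vals)], _atlas3(), ["C", "A", "B"], use_population_threshold=False
        )
        for name in "ABC":
            i1 = fp1.roi_names.index(name)
            i2 = fp2.roi_names.index(name)
            assert fp1.raw_strengths[i1] == pytest.approx(fp2.raw_strengths[i2])
            assert fp1.scaled_strengths[i1] == pytest.approx(fp2.scaled_strengths[i2])

    def test_standard_errors_across_subjects(self):
        maps = [_vt(np.repeat([0.2, 0.5, 0.8], 3)), _vt(np.repeat([0.4, 0.5, 0.6], 3))]
        fp = connectivity_fingerprint(
            maps, _atlas3(), ["A", "B", "C"], use_population_threshold=False
        )
        assert fp.standard_errors[1] == pytest.approx(0.0, abs=1e-12)
        assert fp.standard_errors[0] > 0

    def test_unknown_roi(self):
        with pytest.raises(ValueError, match="unknown ROI"):
            connectivity_fingerprint([_vt(np.ones(9))], _atlas3(), ["Z"])

    def test_unnormalized_input_rejected(self):
        vt = VertexTractogram(counts=np.ones(9, int), n_streamlines=1)
        with pytest.raises(ValueError, match="normalized"):
            connectivity_fingerprint([vt], _atlas3(), ["A"])


class TestAtlas:
    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="no ROI name"):
            ROIAtlas(labels=np.array([0, 1, 7]), names={1: "A"})

    def test_vertices_of(self):
        atlas = _atlas3()
        assert atlas.vertices_of("B").tolist() == [3, 4, 5]


class TestPlot:
    def test_polar_png_written(self, tmp_path):
        from fibertrace.surface_fingerprint import plot_fingerprint

        fp = Fingerprint(
            roi_names=["A", "B", "C"],
            raw_strengths=np.array([0.2, 0.5, 0.8]),
            scaled_strengths=np.array([0.0, 0.5, 1.0]),
            global_bracket=np.array([25.0, 62.5, 100.0]),
            standard_errors=np.zeros(3),
        )
        out = tmp_path / "fp.png"
        plot_fingerprint(fp, out)
        assert out.stat().st_size > 0
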
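"""Surface projection of streamlines and ROI connectivity fingerprints.

Streamline/mesh crossings are found with the Möller–Trumbore segment-triangle
test; each crossing increments the count of the nearest vertex of the
intersected triangle, at most once per streamline per vertex. Vertex counts
are normalized with the same log/max rule as volume tractograms, then ROI
fingerprints average within-ROI per subject and across subjects, min–max
scale over the selected ROIs, and also report each ROI relative to the
strongest vertex in the whole brain (scaled to 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SurfaceMesh",
    "ROIAtlas",
    "VertexTractogram",
    "Fingerprint",
    "surface_hits",
    "normalize_vertex_map",
    "population_threshold",
    "connectivity_fingerprint",
    "plot_fingerprint",
]


@dataclass
class SurfaceMesh:
    """Triangulated surface: world-mm vertices and face index triples."""

    vertices: np.ndarray  # (nv, 3) float
    faces: np.ndarray  # (nf, 3) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (n, 3) index array")
        if self.faces.size and self.faces.max() >= self.vertices.shape[0]:
            raise ValueError("face indices exceed vertex count")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]


@dataclass
class ROIAtlas:
    """Per-vertex integer labels; 0 means unlabeled."""

    labels: np.ndarray  # (nv,) int
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        known = set(self.names) | {0}
        present = set(np.unique(self.labels).tolist())
        missing = present - known
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no ROI name")

    def vertices_of(self, roi_name: str) -> np.ndarray:
        ids = [lid for lid, nm in self.names.items() if nm == roi_name]
        if not ids:
            raise ValueError(f"unknown ROI {roi_name!r}")
        return np.nonzero(np.isin(self.labels, ids))[0]


@dataclass
class VertexTractogram:
    counts: np.ndarray  # (nv,) int
    n_streamlines: int
    normalized: np.ndarray | None = None  # (nv,) in [0, 1]


@dataclass
class Fingerprint:
    roi_names: list[str]
    raw_strengths: np.ndarray  # group-mean normalized vertex value per ROI
    scaled_strengths: np.ndarray  # min-max over the selected ROIs
    global_bracket: np.ndarray  # raw scaled so the strongest vertex = 100
    standard_errors: np.ndarray  # across subjects
    degenerate: bool = False  # all ROI strengths equal


def _segment_triangle_hits(origins, vectors, mesh: SurfaceMesh, eps=1e-12):
    """All (segment, face, t) crossings for a batch of segments.

    ``origins``/``vectors``: (ns, 3); a crossing requires barycentric
    coordinates inside the triangle and segment parameter t in [0, 1].
    """
    v0 = mesh.vertices[mesh.faces[:, 0]]
    e1 = mesh.vertices[mesh.faces[:, 1]] - v0
    e2 = mesh.vertices[mesh.faces[:, 2]] - v0
    h = np.cross(vectors[:, None, :], e2[None, :, :])  # (ns, nf, 3)
    a = np.einsum("fc,sfc->sf", e1, h)
    ok = np.abs(a) > eps
    inv_a = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = origins[:, None, :] - v0[None, :, :]
    u = inv_a * np.einsum("sfc,sfc->sf", s, h)
    q = np.cross(s, e1[None, :, :])
    v = inv_a * np.einsum("sc,sfc->sf", vectors, q)
    t = inv_a * np.einsum("fc,sfc->sf", e2, q)
    hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t >= 0.0) & (t <= 1.0)
    seg_idx, face_idx = np.nonzero(hit)
    return seg_idx, face_idx, t[seg_idx, face_idx]


def surface_hits(
    streamlines,
    mesh: SurfaceMesh,
    terminal_only: bool = False,
) -> VertexTractogram:
    """Count accepted-streamline crossings of the mesh per nearest vertex.

    ``terminal_only`` keeps only each streamline's last crossing (the paper
    leaves this unstated; all crossings is the default). Counts increment at
    most once per streamline per vertex.
    """
    if mesh.n_faces == 0:
        raise ValueError("mesh has no faces")
    counts = np.zeros(mesh.n_vertices, dtype=np.int64)
    lo = mesh.vertices.min(axis=0) - 1e-9
    hi = mesh.vertices.max(axis=0) + 1e-9

    accepted = [s for s in streamlines if getattr(s, "accepted", True)]
    for sl in accepted:
        pts = np.asarray(sl.points, dtype=float)
        if pts.shape[0] < 2:
            continue
        a, b = pts[:-1], pts[1:]
        # bounding-box prefilter: segment must touch the mesh's AABB
        seg_lo = np.minimum(a, b)
        seg_hi = np.maximum(a, b)
        near = np.all(seg_hi >= lo, axis=1) & np.all(seg_lo <= hi, axis=1)
        if not near.any():
            continue
        seg_idx, face_idx, t = _segment_triangle_hits(a[near], b[near] - a[near], mesh)
        if seg_idx.size == 0:
            continue
        if terminal_only:
            seg_order = np.nonzero(near)[0][seg_idx]
            last = np.lexsort((t, seg_order))[-1]
            seg_idx, face_idx, t = seg_idx[[last]], face_idx[[last]], t[[last]]
        origins = a[near][seg_idx]
        pts_hit = origins + t[:, None] * (b[near] - a[near])[seg_idx]
        tri_verts = mesh.faces[face_idx]  # (nh, 3)
        d = np.linalg.norm(
            mesh.vertices[tri_verts] - pts_hit[:, None, :], axis=2
        )  # (nh, 3)
        nearest = tri_verts[np.arange(len(face_idx)), d.argmin(axis=1)]
        counts[np.unique(nearest)] += 1
    return VertexTractogram(
        counts=counts, n_streamlines=len(accepted), normalized=None
    )


def normalize_vertex_map(vt: VertexTractogram) -> VertexTractogram:
    """Same rule as the volume normalizer: log1p(count) / log1p(max)."""
    counts = np.asarray(vt.counts)
    max_count = int(counts.max()) if counts.size else 0
    if max_count == 0:
        raise ValueError("cannot normalize an all-zero vertex tractogram")
    return VertexTractogram(
        counts=counts,
        n_streamlines=vt.n_streamlines,
        normalized=np.log1p(counts) / np.log1p(max_count),
    )


def population_threshold(
    vertex_maps: list[VertexTractogram], level: float = 0.5
) -> np.ndarray:
    """Vertices nonzero in strictly more than ``level`` of subjects."""
    if len(vertex_maps) < 2:
        raise ValueError("population_threshold needs >= 2 subjects")
    nv = vertex_maps[0].counts.shape[0]
    for vm in vertex_maps[1:]:
        if vm.counts.shape[0] != nv:
            raise ValueError("vertex maps live on different meshes")
    nonzero = np.stack([vm.counts > 0 for vm in vertex_maps])
    return nonzero.mean(axis=0) > level


def connectivity_fingerprint(
    vertex_maps: list[VertexTractogram],
    atlas: ROIAtlas,
    roi_names: list[str],
    population_level: float = 0.5,
    use_population_threshold: bool = True,
) -> Fingerprint:
    """ROI fingerprint from per-subject normalized vertex tractograms.

    raw(ROI) = mean over subjects of the mean normalized value over the ROI's
    vertices (restricted to population-thresholded vertices when >= 2
    subjects); scaled = min-max over the selected ROIs; global_bracket = 100 x
    raw / (max group-mean vertex value over the whole surface). An ROI whose
    vertices are all removed by the population threshold contributes 0.
    """
    if len(vertex_maps) < 1:
        raise ValueError("need at least one subject")
    for vm in vertex_maps:
        if vm.normalized is None:
            raise ValueError("vertex maps must be normalized first")
    nv = vertex_maps[0].counts.shape[0]
    if atlas.labels.shape[0] != nv:
        raise ValueError("atlas and vertex maps have different vertex counts")

    keep = np.ones(nv, dtype=bool)
    if use_population_threshold and len(vertex_maps) >= 2:
        keep = population_threshold(vertex_maps, population_level)

    per_subject = np.zeros((len(vertex_maps), len(roi_names)))
    for r, name in enumerate(roi_names):
        verts = atlas.vertices_of(name)
        if verts.size == 0:
            raise ValueError(f"ROI {name!r} has no vertices in the atlas")
        verts = verts[keep[verts]]
        if verts.size == 0:
            continue  # thresholded away entirely -> strength 0
        for s, vm in enumerate(vertex_maps):
            per_subject[s, r] = vm.normalized[verts].mean()

    raw = per_subject.mean(axis=0)
    n_sub = len(vertex_maps)
    se = per_subject.std(axis=0, ddof=1) / np.sqrt(n_sub) if n_sub > 1 else np.zeros_like(raw)

    lo, hi = raw.min(), raw.max()
    degenerate = bool(np.isclose(hi, lo))
    scaled = np.zeros_like(raw) if degenerate else (raw - lo) / (hi - lo)

    group_vertex = np.mean([vm.normalized for vm in vertex_maps], axis=0)
    brain_max = group_vertex.max()
    bracket = 100.0 * raw / brain_max if brain_max > 0 else np.zeros_like(raw)

    return Fingerprint(
        roi_names=list(roi_names),
        raw_strengths=raw,
        scaled_strengths=scaled,
        global_bracket=bracket,
        standard_errors=se,
        degenerate=degenerate,
    )


def plot_fingerprint(fp: Fingerprint, path: str) -> None:
    """Polar (radar) plot of the scaled fingerprint with error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(fp.roi_names)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ang = np.concatenate([angles, angles[:1]])
    val = np.concatenate([fp.scaled_strengths, fp.scaled_strengths[:1]])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.plot(ang, val, "o-", lw=2)
    ax.fill(ang, val, alpha=0.2)
    denom = np.ptp(fp.raw_strengths)
    if denom > 0:
        ax.errorbar(
            angles,
            fp.scaled_strengths,
            yerr=fp.standard_errors / denom,
            fmt="none",
            ecolor="gray",
        )
    ax.set_xticks(angles)
    ax.set_xticklabels(
        [f"{n_} [{b:.0f}]" for n_, b in zip(fp.roi_names, fp.global_bracket)]
    )
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
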
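"""File formats: NIfTI volumes, FSL bval/bvec, TrackVis streamlines,
ASCII meshes/labels, posterior sample directories, YAML manifests."""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .orientation_model import OrientationPosterior
from .phantom import AcquisitionScheme, DWIDataset
from .surface_fingerprint import ROIAtlas, SurfaceMesh
from .tracking import Streamline, StreamlineSet

__all__ = [
    "read_volume",
    "write_volume",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "write_dwi",
    "read_dwi",
    "read_streamlines",
    "write_streamlines",
    "read_mesh_ascii",
    "write_mesh_ascii",
    "read_labels",
    "write_labels",
    "save_posterior",
    "load_posterior",
    "write_manifest",
    "read_manifest",
    "file_sha256",
]

_STATUS_CODES = {"accepted": 1, "rejected_exclusion": 0}
_CODE_STATUS = {v: k for k, v in _STATUS_CODES.items()}


# -- volumes ----------------------------------------------------------------

def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine) without dtype coercion."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed header, wrong magic, truncation
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    return data, img.affine


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path


# -- gradient schemes -------------------------------------------------------

def write_bvals_bvecs(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """FSL dialect: one row of b-values; three rows of direction components."""
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")


def read_bvals_bvecs(bval_path, bvec_path) -> AcquisitionScheme:
    b = np.loadtxt(bval_path).reshape(-1)
    g = np.loadtxt(bvec_path)
    if g.shape[0] == 3 and g.shape != (3, 3):
        g = g.T
    return AcquisitionScheme(b, g)


def write_dwi(dwi: DWIDataset, out_dir, stem: str = "dwi") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dwi": write_volume(dwi.signal.astype(np.float32), dwi.affine, out_dir / f"{stem}.nii.gz"),
        "mask": write_volume(dwi.brain_mask.astype(np.uint8), dwi.affine, out_dir / f"{stem}_mask.nii.gz"),
    }
    write_bvals_bvecs(dwi.scheme, out_dir / f"{stem}.bval", out_dir / f"{stem}.bvec")
    paths["bval"] = out_dir / f"{stem}.bval"
    paths["bvec"] = out_dir / f"{stem}.bvec"
    return paths


def read_dwi(dwi_path, bval_path, bvec_path, mask_path=None) -> DWIDataset:
    signal, affine = read_volume(dwi_path)
    scheme = read_bvals_bvecs(bval_path, bvec_path)
    if mask_path is not None:
        mask = read_volume(mask_path)[0].astype(bool)
    else:
        mask = np.ones(signal.shape[:3], dtype=bool)
    return DWIDataset(signal=np.asarray(signal, dtype=float), scheme=scheme,
                      affine=affine, brain_mask=mask)


# -- streamlines ------------------------------------------------------------

def write_streamlines(sset: StreamlineSet, path) -> Path:
    """TrackVis .trk with world-mm points and a per-streamline status code."""
    from nibabel.streamlines import Tractogram, TrkFile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    points = [np.asarray(s.points, dtype=np.float32) for s in sset.streamlines]
    status = np.array(
        [[_STATUS_CODES[s.status]] for s in sset.streamlines], dtype=np.float32
    )
    tg = Tractogram(
        points,
        data_per_streamline={"status": status},
        affine_to_rasmm=np.eye(4),
    )
    TrkFile(tg).save(str(path))
    return path


def read_streamlines(path, affine=None) -> StreamlineSet:
    from nibabel.streamlines import TrkFile

    try:
        trk = TrkFile.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read streamline file {path}: {exc}") from exc
    tg = trk.tractogram
    status = tg.data_per_streamline.get("status")
    out = []
    for i, pts in enumerate(tg.streamlines):
        code = int(status[i][0]) if status is not None else 1
        out.append(Streamline(points=np.asarray(pts, dtype=float),
                              status=_CODE_STATUS.get(code, "accepted")))
    if affine is None:
        affine = np.eye(4)
    return StreamlineSet(streamlines=out, affine=np.asarray(affine, dtype=float))


# -- meshes and labels ------------------------------------------------------

def write_mesh_ascii(mesh: SurfaceMesh, path) -> Path:
    """Plain-text mesh: 'nv nf' header, vertex rows, then face rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"{mesh.n_vertices} {mesh.n_faces}\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.8f} {v[1]:.8f} {v[2]:.8f}\n")
        for f in mesh.faces:
            fh.write(f"{f[0]} {f[1]} {f[2]}\n")
    return path


def read_mesh_ascii(path) -> SurfaceMesh:
    with open(path) as fh:
        first = fh.readline().split()
        if len(first) != 2:
            raise ValueError(f"malformed mesh header in {path}")
        nv, nf = int(first[0]), int(first[1])
        verts = np.array([fh.readline().split() for _ in range(nv)], dtype=float)
        faces = np.array([fh.readline().split() for _ in range(nf)], dtype=int)
    return SurfaceMesh(vertices=verts, faces=faces)


def write_labels(atlas: ROIAtlas, path) -> Path:
    """Two-column text 'vertex label'; ROI names in '# id name' comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for lid in sorted(atlas.names):
            fh.write(f"# {lid} {atlas.names[lid]}\n")
        for i, lab in enumerate(atlas.labels):
            fh.write(f"{i} {lab}\n")
    return path


def read_labels(path) -> ROIAtlas:
    names: dict[int, str] = {}
    rows: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split(None, 1)
                names[int(parts[0])] = parts[1].strip()
            else:
                a, b = line.split()
                rows.append((int(a), int(b)))
    labels = np.zeros(max(r[0] for r in rows) + 1, dtype=int)
    for idx, lab in rows:
        labels[idx] = lab
    return ROIAtlas(labels=labels, names=names)


# -- posterior sample directories ------------------------------------------

def save_posterior(post: OrientationPosterior, out_dir) -> Path:
    """4-D NIfTI per population (orientation samples and fraction samples)
    plus a YAML manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    K, S = post.max_populations, post.n_post
    dense_f = post.dense_fraction_samples()
    dense_o = post.dense_orientation_samples()
    for k in range(K):
        write_volume(dense_f[..., k, :], post.affine, out_dir / f"frac_pop{k + 1}.nii.gz")
        o = dense_o[:, :, :, k].reshape(*post.shape, S * 3)
        write_volume(o, post.affine, out_dir / f"orient_pop{k + 1}.nii.gz")
    manifest = {
        "max_populations": int(K),
        "n_post": int(S),
        "shape": [int(s) for s in post.shape],
        "n_voxels": int(post.n_voxels),
    }
    write_manifest(manifest, out_dir / "posterior.yaml")
    return out_dir


def load_posterior(in_dir) -> OrientationPosterior:
    in_dir = Path(in_dir)
    manifest = read_manifest(in_dir / "posterior.yaml")
    K, S = manifest["max_populations"], manifest["n_post"]
    shape = tuple(manifest["shape"])
    fracs, orients = [], []
    affine = None
    for k in range(K):
        f, affine = read_volume(in_dir / f"frac_pop{k + 1}.nii.gz")
        o = read_volume(in_dir / f"orient_pop{k + 1}.nii.gz")[0]
        fracs.append(np.asarray(f))
        orients.append(np.asarray(o).reshape(*shape, S, 3))
    frac = np.stack(fracs, axis=3)  # (nx, ny, nz, K, S)
    orient = np.stack(orients, axis=3)  # (nx, ny, nz, K, S, 3)
    fitted = frac.sum(axis=(3, 4)) > 0
    idx = np.argwhere(fitted)
    ix, iy, iz = idx.T
    mean_frac = frac[ix, iy, iz].mean(axis=2)
    return OrientationPosterior(
        shape=shape,
        affine=affine,
        voxel_indices=idx,
        orientation_samples=orient[ix, iy, iz].astype(float),
        fraction_samples=frac[ix, iy, iz].astype(float),
        mean_fractions=mean_frac,
        retained=mean_frac > 0,
        s0_mean=np.zeros(idx.shape[0]),
        d_mean=np.zeros(idx.shape[0]),
    )


# -- manifests --------------------------------------------------------------

def write_manifest(data: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
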
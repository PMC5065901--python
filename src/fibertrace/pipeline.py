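"""End-to-end pipeline: simulate -> fit -> track -> postprocess -> project
-> fingerprint, driven by a YAML config.

The config's single global ``rng_seed`` is expanded into independent
per-stage seeds (counter-based on the stage name), so any stage can be rerun
in isolation with the same randomness. Identical config + seed produces
byte-identical text outputs. Default fitting/tracking sizes are desk-scale
(hundreds of streamlines per voxel, short burn-in); the full-size values
from the source protocols remain expressible through the same fields.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import io as ftio
from .fixtures import standard_fixtures
from .orientation_model import fit_ball_and_sticks, fit_tensor
from .phantom import make_scheme
from .surface_fingerprint import (
    connectivity_fingerprint,
    normalize_vertex_map,
    plot_fingerprint,
    surface_hits,
)
from .tracking import TrackingParams, track_from_mask
from .tractogram_analysis import (
    center_of_gravity,
    max_intensity_projection,
    normalize_tractogram,
    threshold_map,
)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("fibertrace")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0])


@dataclass
class PipelineConfig:
    out_dir: str
    rng_seed: int = 0
    fixture: str | None = "bowtie"
    inputs: dict = field(default_factory=dict)  # file-based alternative
    scheme: dict = field(
        default_factory=lambda: {"n_directions": 60, "bvalue": 1000.0, "n_b0": 1, "seed": 0}
    )
    snr: float = 30.0
    fit: dict = field(
        default_factory=lambda: {
            "max_populations": 3,
            "n_burn": 200,
            "n_post": 50,
            "thin": 5,
            "prune_threshold": 0.05,
            "fa_threshold": 0.15,
        }
    )
    tracking: dict = field(
        default_factory=lambda: {
            "n_samples_per_voxel": 250,
            "step_size": 0.5,
            "max_steps": 200,
            "curvature_threshold": 0.2,
            "fraction_threshold": 0.05,
            "bidirectional": True,
        }
    )
    post: dict = field(default_factory=lambda: {"threshold_level": 0.5})
    fingerprint: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if "out_dir" not in data:
            raise ValueError("config missing required field 'out_dir'")
        cfg = cls(out_dir=data["out_dir"])
        for key in ("rng_seed", "fixture", "snr"):
            if key in data:
                setattr(cfg, key, data[key])
        for key in ("scheme", "fit", "tracking", "post", "fingerprint", "inputs"):
            if key in data:
                getattr(cfg, key).update(data[key])
        if cfg.fixture is None and not cfg.inputs:
            raise ValueError("config needs either 'fixture' or 'inputs'")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "rng_seed": int(self.rng_seed),
            "fixture": self.fixture,
            "inputs": dict(self.inputs),
            "scheme": dict(self.scheme),
            "snr": float(self.snr),
            "fit": dict(self.fit),
            "tracking": dict(self.tracking),
            "post": dict(self.post),
            "fingerprint": dict(self.fingerprint),
        }


def _load_inputs(cfg: PipelineConfig):
    """File-based input mode: read DWI, masks and optional surface data."""
    for key in ("dwi", "bvals", "bvecs", "seed_mask"):
        if key not in cfg.inputs:
            raise ValueError(f"config missing required input '{key}'")
    dwi = ftio.read_dwi(
        cfg.inputs["dwi"], cfg.inputs["bvals"], cfg.inputs["bvecs"],
        cfg.inputs.get("brain_mask"),
    )
    seed_masks = {"seed": ftio.read_volume(cfg.inputs["seed_mask"])[0].astype(bool)}
    exclusions = [
        ftio.read_volume(p)[0].astype(bool)
        for p in cfg.inputs.get("exclusion_masks", [])
    ]
    termination = None
    if "termination_mask" in cfg.inputs:
        termination = ftio.read_volume(cfg.inputs["termination_mask"])[0].astype(bool)
    mesh = atlas = None
    if "mesh" in cfg.inputs:
        mesh = ftio.read_mesh_ascii(cfg.inputs["mesh"])
    if "labels" in cfg.inputs:
        atlas = ftio.read_labels(cfg.inputs["labels"])
    return dwi, seed_masks, exclusions, termination, mesh, atlas


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) a manifest of all outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": {}}
    stage = "setup"
    try:
        if config.fixture is not None:
            stage = "simulate"
            fixture = standard_fixtures(config.fixture)
            sch = {k: v for k, v in config.scheme.items()}
            scheme = make_scheme(
                n_directions=sch.get("n_directions", 60),
                bvalue=sch.get("bvalue", 1000.0),
                n_b0=sch.get("n_b0", 1),
                seed=sch.get("seed", 0),
            )
            sim_seed = stage_seed(config.rng_seed, "simulate")
            dwi = fixture.simulate(scheme, snr=config.snr, rng_seed=sim_seed)
            seed_masks = fixture.seed_masks
            exclusions = fixture.exclusion_masks
            termination = fixture.termination_mask
            mesh, atlas = fixture.mesh, fixture.atlas
            paths = ftio.write_dwi(dwi, out)
            manifest["outputs"].update({k: str(p) for k, p in paths.items()})
            ftio.write_manifest(
                {"fixture": fixture.name, "ground_truth": _yamlable(fixture.ground_truth),
                 "snr": float(config.snr), "rng_seed": sim_seed},
                out / "ground_truth.yaml",
            )
            manifest["stages"]["simulate"] = {"rng_seed": sim_seed}
            for mname, m in seed_masks.items():
                ftio.write_volume(m.astype(np.uint8), dwi.affine, out / f"{mname}.nii.gz")
        else:
            stage = "load_inputs"
            dwi, seed_masks, exclusions, termination, mesh, atlas = _load_inputs(config)

        stage = "fit"
        fit_seed = stage_seed(config.rng_seed, "fit")
        tensor = fit_tensor(dwi)
        wm = (tensor.fa > config.fit.get("fa_threshold", 0.15)) & tensor.valid
        wm = ndimage.binary_dilation(wm, iterations=1)
        for m in seed_masks.values():
            wm |= m
        wm &= dwi.brain_mask
        post = fit_ball_and_sticks(
            dwi,
            mask=wm,
            max_populations=config.fit.get("max_populations", 3),
            n_burn=config.fit.get("n_burn", 200),
            n_post=config.fit.get("n_post", 50),
            thin=config.fit.get("thin", 5),
            prune_threshold=config.fit.get("prune_threshold", 0.05),
            rng_seed=fit_seed,
        )
        ftio.save_posterior(post, out / "posterior")
        ftio.write_volume(tensor.fa.astype(np.float32), dwi.affine, out / "fa.nii.gz")
        manifest["stages"]["fit"] = {"rng_seed": fit_seed, "n_voxels": int(post.n_voxels)}
        manifest["outputs"]["posterior"] = str(out / "posterior")
        manifest["outputs"]["fa"] = str(out / "fa.nii.gz")

        stage = "track"
        track_seed = stage_seed(config.rng_seed, "track")
        tp = TrackingParams(
            n_samples_per_voxel=config.tracking.get("n_samples_per_voxel", 250),
            step_size=config.tracking.get("step_size", 0.5),
            max_steps=config.tracking.get("max_steps", 200),
            curvature_threshold=config.tracking.get("curvature_threshold", 0.2),
            fraction_threshold=config.tracking.get("fraction_threshold", 0.05),
            bidirectional=config.tracking.get("bidirectional", True),
            rng_seed=track_seed,
        )
        level = config.post.get("threshold_level", 0.5)
        first_sset = None
        for mname, smask in seed_masks.items():
            sset, vmap = track_from_mask(smask, post, tp, exclusions, termination)
            if first_sset is None:
                first_sset = sset
            ftio.write_streamlines(sset, out / f"streamlines_{mname}.trk")
            ftio.write_volume(
                vmap.counts.astype(np.int32), vmap.affine, out / f"visitation_{mname}.nii.gz"
            )
            acct = {
                "n_attempted": vmap.n_attempted,
                "n_accepted": vmap.n_accepted,
                "n_rejected": vmap.n_attempted - vmap.n_accepted,
            }
            log.info("tracking %s: %s", mname, acct)
            manifest["stages"][f"track_{mname}"] = {"rng_seed": track_seed, **acct}

            stage = "postprocess"
            norm = normalize_tractogram(vmap)
            ftio.write_volume(
                norm.values.astype(np.float32), norm.affine, out / f"norm_{mname}.nii.gz"
            )
            binary = threshold_map(norm, level)
            ftio.write_volume(
                binary.astype(np.uint8), norm.affine, out / f"thresh_{mname}.nii.gz"
            )
            for axis in "xyz":
                np.savetxt(
                    out / f"mip_{mname}_{axis}.txt",
                    max_intensity_projection(norm, axis),
                    fmt="%.6f",
                )
            cog = center_of_gravity(smask, dwi.affine)
            manifest["stages"][f"postprocess_{mname}"] = {
                "seed_center_of_gravity_mm": [float(c) for c in cog],
                "threshold_level": float(level),
            }
            manifest["outputs"][f"visitation_{mname}"] = str(out / f"visitation_{mname}.nii.gz")
            manifest["outputs"][f"norm_{mname}"] = str(out / f"norm_{mname}.nii.gz")
            stage = "track"

        if mesh is not None:
            stage = "project"
            vt = surface_hits(first_sset.accepted_streamlines(), mesh)
            vt = normalize_vertex_map(vt)
            pd.DataFrame(
                {"vertex": np.arange(mesh.n_vertices), "count": vt.counts,
                 "normalized": vt.normalized}
            ).to_csv(out / "vertex_tractogram.csv", index=False, float_format="%.10g")
            ftio.write_mesh_ascii(mesh, out / "mesh.txt")
            manifest["outputs"]["vertex_tractogram"] = str(out / "vertex_tractogram.csv")

            if atlas is not None:
                stage = "fingerprint"
                roi_names = config.fingerprint.get(
                    "roi_names", [atlas.names[k] for k in sorted(atlas.names)]
                )
                fp = connectivity_fingerprint(
                    [vt], atlas, roi_names, use_population_threshold=False
                )
                pd.DataFrame(
                    {
                        "roi": fp.roi_names,
                        "raw": fp.raw_strengths,
                        "scaled": fp.scaled_strengths,
                        "global_bracket": fp.global_bracket,
                        "se": fp.standard_errors,
                    }
                ).to_csv(out / "fingerprint.csv", index=False, float_format="%.10g")
                plot_fingerprint(fp, out / "fingerprint.png")
                ftio.write_labels(atlas, out / "labels.txt")
                manifest["outputs"]["fingerprint"] = str(out / "fingerprint.csv")

        stage = "manifest"
        for key, p in list(manifest["outputs"].items()):
            if Path(p).is_file():
                manifest["outputs"][key] = {"path": p, "sha256": ftio.file_sha256(p)}
        ftio.write_manifest(manifest, out / "manifest.yaml")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _yamlable(obj):
    if isinstance(obj, dict):
        return {str(k): _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
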
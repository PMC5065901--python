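# fibertrace

Probabilistic crossing-fiber tractography on synthetic diffusion-MRI
phantoms, end to end:

1. **phantom** — parametric fiber bundles voxelized into ground-truth
   orientation fields; ball-and-sticks forward signal
   `S = S0[(1−Σfᵢ)e^(−bd) + Σfᵢe^(−bd(g·vᵢ)²)]` with Rician magnitude
   noise; electrostatic-repulsion gradient schemes.
2. **fixtures** — four documented phantoms (`straight`, `crossing`,
   `parallel_tracts`, `bowtie`) with seed/exclusion/termination masks,
   boundary surface meshes, ROI atlases and designed ground truth.
3. **orientation_model** — weighted-least-squares diffusion tensor fit
   (FA/MD/principal direction) and Metropolis–Hastings sampling of the
   ball-and-sticks posterior (up to 3 sticks per voxel, vectorized across
   voxels, fraction pruning plus weak shrinkage on secondary sticks).
4. **tracking** — probabilistic streamline propagation: orientations drawn
   from the voxel-wise posterior, Euler steps, curvature threshold
   (minimum inter-step cosine, default 0.2), termination masks, and
   exclusion masks that discard whole streamlines on contact. Visitation
   maps count accepted streamlines once per voxel.
5. **tractogram_analysis** — log/max normalization to [0, 1], strict
   thresholding, rank (quantile) thresholding, group averaging, percentage
   overlap maps, centers of gravity, maximum-intensity "glass brain"
   projections.
6. **surface_fingerprint** — segment–triangle mesh crossings projected to
   nearest vertices, log/max vertex normalization, population thresholds,
   and min–max-scaled ROI connectivity fingerprints with whole-brain
   bracket values and polar plots.
7. **io / pipeline / cli** — NIfTI + FSL bval/bvec, TrackVis `.trk`, ASCII
   meshes/labels, YAML manifests, and a seeded, fully deterministic
   pipeline driver.

## CLI

```bash
fibertrace simulate --fixture bowtie --out out/sim --snr 30 --rng 1
fibertrace fit --dwi out/sim/dwi.nii.gz --bvals out/sim/dwi.bval \
    --bvecs out/sim/dwi.bvec --out out/post --rng 2
fibertrace track --seed out/sim/seed.nii.gz --posterior out/post \
    --exclude out/sim/exclusion_0.nii.gz --step 0.3125 --max-steps 3200 \
    --curvature 0.2 --nsamples 5000 --rng 42 --out out/trk
fibertrace postprocess normalize out/trk/visitation.nii.gz --out out/norm.nii.gz
fibertrace postprocess threshold out/norm.nii.gz --level 0.5 --out out/bin.nii.gz
fibertrace project --trk out/trk/streamlines.trk --mesh out/sim/mesh.txt \
    --out out/vertex.csv
fibertrace fingerprint --vertex-map out/vertex.csv --labels out/sim/labels.txt \
    --out out/fingerprint.csv --plot out/fingerprint.png
```

Or run everything from a YAML config (seeded, reproducible; identical
config + seed gives byte-identical outputs):

```bash
fibertrace run --config config.yaml
```

```yaml
# config.yaml
out_dir: out/run1
rng_seed: 42
fixture: bowtie
snr: 30
scheme: {n_directions: 60, bvalue: 1000.0, n_b0: 1}
fit: {max_populations: 3, n_burn: 200, n_post: 50, thin: 5}
tracking: {n_samples_per_voxel: 250, step_size: 0.5, max_steps: 200,
           curvature_threshold: 0.2, bidirectional: true}
post: {threshold_level: 0.5}
```

## Conventions

World coordinates in mm; voxel indices 0-based; affines map voxel indices
to world mm (NIfTI convention). Streamline points are world-mm; points map
to voxels by nearest index with half-up tie-breaking. SNR is defined as
S0/σ with Rician noise of scale σ.
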
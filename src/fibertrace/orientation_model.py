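"""Voxel-wise orientation estimation.

Two estimators share the data model of :mod:`fibertrace.phantom`:

* :func:`fit_tensor` — weighted linear least-squares diffusion tensor fit
  (eigenvalues, principal direction, FA, MD).
* :func:`fit_ball_and_sticks` — Metropolis–Hastings sampling of the
  ball-and-sticks posterior, up to three stick populations per voxel, run
  vectorized across all masked voxels. The retained samples form the
  :class:`OrientationPosterior` that probabilistic tracking draws from.

The likelihood is Gaussian on magnitudes (documented approximation, valid at
the simulated SNRs); orientation priors are uniform on the sphere, the first
stick's fraction prior is uniform on the simplex, and scale parameters carry
flat positive priors (Jeffreys 1/sigma for the noise level). Secondary stick
fractions get a weak shrinkage prior (density ~ 1/(f + f0)) so duplicate
sticks decay instead of splitting the fraction of a single true fiber; model
complexity is then finalized by pruning populations whose posterior-mean
fraction falls below ``prune_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DWIDataset, GroundTruthField

__all__ = [
    "TensorFit",
    "OrientationPosterior",
    "fit_tensor",
    "fit_ball_and_sticks",
    "posterior_summary",
    "dyadic_mean",
]


@dataclass
class TensorFit:
    """Per-voxel diffusion tensor fit results on the full grid."""

    tensors: np.ndarray  # (nx, ny, nz, 3, 3), mm^2/s
    eigenvalues: np.ndarray  # (nx, ny, nz, 3), descending
    principal_direction: np.ndarray  # (nx, ny, nz, 3), unit
    fa: np.ndarray  # (nx, ny, nz)
    md: np.ndarray  # (nx, ny, nz)
    s0: np.ndarray  # (nx, ny, nz)
    valid: np.ndarray  # (nx, ny, nz) bool: voxel entered the fit
    affine: np.ndarray


def _design_matrix(scheme) -> np.ndarray:
    b = scheme.bvalues
    g = scheme.directions
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ]
    )


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA from eigenvalues (last axis length 3)."""
    ev = np.asarray(eigenvalues, dtype=float)
    mean = ev.mean(axis=-1, keepdims=True)
    num = ((ev - mean) ** 2).sum(axis=-1)
    den = (ev**2).sum(axis=-1)
    out = np.zeros_like(num)
    nz = den > 0
    out[nz] = np.sqrt(1.5 * num[nz] / den[nz])
    return np.clip(out, 0.0, 1.0)


def fit_tensor(dwi: DWIDataset, mask: np.ndarray | None = None) -> TensorFit:
    """Weighted linear least-squares tensor fit of log(S) = log(S0) - b g'Dg.

    One WLS pass with weights S^2 after an OLS warm start. Voxels with any
    non-positive signal are flagged invalid and excluded from the fit.
    Deterministic.
    """
    scheme = dwi.scheme
    dw_dirs = scheme.directions[scheme.bvalues > 0]
    if len(np.unique(np.round(dw_dirs, 6), axis=0)) < 6:
        raise ValueError("tensor fit needs >= 6 unique non-zero gradient directions")
    if scheme.n_b0 < 1:
        raise ValueError("tensor fit needs >= 1 b = 0 volume")

    shape = dwi.signal.shape[:3]
    if mask is None:
        mask = dwi.brain_mask
    signal = dwi.signal.reshape(-1, scheme.n_volumes)
    fit_mask = mask.reshape(-1) & (signal > 0).all(axis=1)

    A = _design_matrix(scheme)  # (M, 7)
    S = signal[fit_mask]
    y = np.log(S)

    def _wls(weights):
        # weights: (V, M); solve (A' W A) x = A' W y per voxel
        atw = A.T[None, :, :] * weights[:, None, :]  # (V, 7, M)
        lhs = atw @ A  # (V, 7, 7)
        rhs = np.einsum("vpm,vm->vp", atw, y)
        return np.linalg.solve(lhs, rhs[..., None])[..., 0]

    coef = _wls(np.ones_like(S))  # OLS warm start
    coef = _wls(np.exp(A @ coef.T).T ** 2)  # weights = fitted signal squared

    n_fit = coef.shape[0]
    D = np.empty((n_fit, 3, 3))
    D[:, 0, 0] = coef[:, 1]
    D[:, 1, 1] = coef[:, 2]
    D[:, 2, 2] = coef[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = coef[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = coef[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = coef[:, 6]

    evals, evecs = np.linalg.eigh(D)  # ascending
    evals = evals[:, ::-1]
    principal = evecs[:, :, ::-1][:, :, 0]

    nvox = int(np.prod(shape))
    tensors = np.zeros((nvox, 3, 3))
    eigenvalues = np.zeros((nvox, 3))
    pdir = np.zeros((nvox, 3))
    fa = np.zeros(nvox)
    md = np.zeros(nvox)
    s0 = np.zeros(nvox)
    tensors[fit_mask] = D
    eigenvalues[fit_mask] = evals
    pdir[fit_mask] = principal
    fa[fit_mask] = fractional_anisotropy(evals)
    md[fit_mask] = evals.mean(axis=1)
    s0[fit_mask] = np.exp(coef[:, 0])

    return TensorFit(
        tensors=tensors.reshape(*shape, 3, 3),
        eigenvalues=eigenvalues.reshape(*shape, 3),
        principal_direction=pdir.reshape(*shape, 3),
        fa=fa.reshape(shape),
        md=md.reshape(shape),
        s0=s0.reshape(shape),
        valid=fit_mask.reshape(shape),
        affine=dwi.affine.copy(),
    )


@dataclass
class OrientationPosterior:
    """Posterior orientation/fraction samples for the voxels of a grid.

    Arrays are stored compactly over the V fitted voxels; ``dense_*``
    expand to full-grid float32 arrays for the tracker. Pruned populations
    have ``retained`` False and all-zero fraction samples, which makes them
    ineligible under any positive fraction threshold downstream.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    voxel_indices: np.ndarray  # (V, 3) int
    orientation_samples: np.ndarray  # (V, K, n_post, 3)
    fraction_samples: np.ndarray  # (V, K, n_post)
    mean_fractions: np.ndarray  # (V, K)
    retained: np.ndarray  # (V, K) bool
    s0_mean: np.ndarray  # (V,)
    d_mean: np.ndarray  # (V,)

    @property
    def n_voxels(self) -> int:
        return self.voxel_indices.shape[0]

    @property
    def n_post(self) -> int:
        return self.fraction_samples.shape[2]

    @property
    def max_populations(self) -> int:
        return self.fraction_samples.shape[1]

    def dense_fraction_samples(self) -> np.ndarray:
        out = np.zeros((*self.shape, self.max_populations, self.n_post), dtype=np.float32)
        ix, iy, iz = self.voxel_indices.T
        out[ix, iy, iz] = self.fraction_samples
        return out

    def dense_orientation_samples(self) -> np.ndarray:
        out = np.zeros(
            (*self.shape, self.max_populations, self.n_post, 3), dtype=np.float32
        )
        ix, iy, iz = self.voxel_indices.T
        out[ix, iy, iz] = self.orientation_samples
        return out

    @classmethod
    def from_field(
        cls, field: GroundTruthField, n_post: int = 1
    ) -> "OrientationPosterior":
        """Zero-spread posterior that reproduces a ground-truth field exactly.

        Every posterior sample equals the true orientation/fraction; useful
        for deterministic tracking tests and oracle comparisons.
        """
        wm = field.white_matter_mask()
        idx = np.argwhere(wm)
        ix, iy, iz = idx.T
        orient = np.repeat(
            field.orientations[ix, iy, iz][:, :, None, :], n_post, axis=2
        )
        frac = np.repeat(field.fractions[ix, iy, iz][:, :, None], n_post, axis=2)
        mean_frac = frac.mean(axis=2)
        return cls(
            shape=field.shape,
            affine=field.affine.copy(),
            voxel_indices=idx,
            orientation_samples=orient,
            fraction_samples=frac,
            mean_fractions=mean_frac,
            retained=mean_frac > 0,
            s0_mean=np.full(idx.shape[0], field.s0),
            d_mean=np.full(idx.shape[0], field.d),
        )


def _spherical_to_unit(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), np.cos(theta) * np.ones_like(phi), st * np.sin(phi)], axis=-1)


def _unit_to_spherical(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = np.arccos(np.clip(v[..., 1], -1.0, 1.0))
    phi = np.arctan2(v[..., 2], v[..., 0])
    return theta, phi


class _BallSticksChains:
    """Component-wise random-walk MH over all voxels simultaneously.

    Parameters per voxel: S0, d, (f_k, theta_k, phi_k) x K, sigma. Caches the
    per-stick attenuation so each single-parameter proposal costs O(V * M).
    Step sizes adapt toward 0.4 acceptance during burn-in only.
    """

    D_MAX = 0.02  # mm^2/s, generous upper bound for brain tissue
    ARD_F0 = 1e-3

    def __init__(self, signal, scheme, k_max, init, rng, ard_weight=1.0):
        self.ard_weight = float(ard_weight)
        self.S = signal  # (V, M)
        self.b = scheme.bvalues  # (M,)
        self.g = scheme.directions  # (M, 3)
        self.K = k_max
        self.M = signal.shape[1]
        self.V = signal.shape[0]
        self.rng = rng

        self.s0 = init["s0"].copy()
        self.d = init["d"].copy()
        self.f = init["f"].copy()  # (V, K)
        self.theta, self.phi = _unit_to_spherical(init["v"])  # (V, K)
        self.sigma = init["sigma"].copy()

        # caches
        self._refresh_all()

        self.n_params = 3 + 3 * self.K  # s0, d, sigma + K*(f, th, ph)
        self.steps = np.empty((self.V, self.n_params))
        self.steps[:, 0] = 0.05 * self.s0
        self.steps[:, 1] = 0.1 * self.d
        self.steps[:, 2] = np.maximum(0.1 * self.sigma, 1e-3)
        for k in range(self.K):
            self.steps[:, 3 + 3 * k] = 0.05
            self.steps[:, 4 + 3 * k] = 0.2
            self.steps[:, 5 + 3 * k] = 0.2
        self.acc = np.zeros((self.V, self.n_params))

    # -- cache management ---------------------------------------------------
    def _stick_attenuation(self, theta, phi, d):
        v = _spherical_to_unit(theta, phi)  # (V, 3) for one stick
        dots2 = (v @ self.g.T) ** 2  # (V, M)
        return np.exp(-self.b[None, :] * d[:, None] * dots2)

    def _refresh_all(self):
        self.ball = np.exp(-self.b[None, :] * self.d[:, None])  # (V, M)
        self.sticks = np.empty((self.V, self.K, self.M))
        for k in range(self.K):
            self.sticks[:, k] = self._stick_attenuation(
                self.theta[:, k], self.phi[:, k], self.d
            )
        self._rebuild_base()

    def _rebuild_base(self):
        fsum = self.f.sum(axis=1)
        self.base = (1.0 - fsum)[:, None] * self.ball + np.einsum(
            "vk,vkm->vm", self.f, self.sticks
        )
        self.ss = ((self.S - self.s0[:, None] * self.base) ** 2).sum(axis=1)

    def _log_noise(self, ss, sigma):
        # Gaussian likelihood + Jeffreys prior on sigma
        return -(self.M + 1) * np.log(sigma) - 0.5 * ss / sigma**2

    def _ss_of(self, base, s0):
        return ((self.S - s0[:, None] * base) ** 2).sum(axis=1)

    def _accept(self, delta, valid, pidx):
        logu = np.log(self.rng.random(self.V))
        acc = valid & (logu < delta)
        self.acc[acc, pidx] += 1
        return acc

    # -- single-parameter sweeps -------------------------------------------
    def _update_s0(self):
        prop = self.s0 + self.steps[:, 0] * self.rng.standard_normal(self.V)
        valid = prop > 0
        ssp = self._ss_of(self.base, np.where(valid, prop, self.s0))
        delta = self._log_noise(ssp, self.sigma) - self._log_noise(self.ss, self.sigma)
        acc = self._accept(delta, valid, 0)
        self.s0[acc] = prop[acc]
        self.ss[acc] = ssp[acc]

    def _update_d(self):
        prop = self.d + self.steps[:, 1] * self.rng.standard_normal(self.V)
        valid = (prop > 1e-6) & (prop < self.D_MAX)
        dp = np.where(valid, prop, self.d)
        ballp = np.exp(-self.b[None, :] * dp[:, None])
        # sticks scale as exp(-b d dots2): recompute via log of cached sticks
        ratio = (dp / self.d)[:, None, None]
        sticksp = np.exp(np.log(np.maximum(self.sticks, 1e-300)) * ratio)
        fsum = self.f.sum(axis=1)
        basep = (1.0 - fsum)[:, None] * ballp + np.einsum(
            "vk,vkm->vm", self.f, sticksp
        )
        ssp = self._ss_of(basep, self.s0)
        delta = self._log_noise(ssp, self.sigma) - self._log_noise(self.ss, self.sigma)
        acc = self._accept(delta, valid, 1)
        self.d[acc] = prop[acc]
        self.ball[acc] = ballp[acc]
        self.sticks[acc] = sticksp[acc]
        self.base[acc] = basep[acc]
        self.ss[acc] = ssp[acc]

    def _update_sigma(self):
        prop = self.sigma + self.steps[:, 2] * self.rng.standard_normal(self.V)
        valid = prop > 1e-8
        sp = np.where(valid, prop, self.sigma)
        delta = self._log_noise(self.ss, sp) - self._log_noise(self.ss, self.sigma)
        acc = self._accept(delta, valid, 2)
        self.sigma[acc] = prop[acc]

    def _update_fraction(self, k):
        pidx = 3 + 3 * k
        prop = self.f[:, k] + self.steps[:, pidx] * self.rng.standard_normal(self.V)
        fsum_others = self.f.sum(axis=1) - self.f[:, k]
        valid = (prop >= 0.0) & (fsum_others + prop <= 1.0)
        fp = np.where(valid, prop, self.f[:, k])
        dfk = fp - self.f[:, k]
        basep = self.base + dfk[:, None] * (self.sticks[:, k] - self.ball)
        ssp = self._ss_of(basep, self.s0)
        delta = self._log_noise(ssp, self.sigma) - self._log_noise(self.ss, self.sigma)
        if k >= 1 and self.ard_weight > 0:
            # shrinkage prior on secondary sticks, density ~ (f + f0)^-w:
            # duplicates of stick 1 decay to zero instead of splitting mass
            delta = delta + self.ard_weight * (
                np.log(self.f[:, k] + self.ARD_F0) - np.log(fp + self.ARD_F0)
            )
        acc = self._accept(delta, valid, pidx)
        self.f[acc, k] = prop[acc]
        self.base[acc] = basep[acc]
        self.ss[acc] = ssp[acc]

    def _update_angle(self, k, which):
        pidx = (4 if which == "theta" else 5) + 3 * k
        cur = self.theta[:, k] if which == "theta" else self.phi[:, k]
        prop = cur + self.steps[:, pidx] * self.rng.standard_normal(self.V)
        thp = prop if which == "theta" else self.theta[:, k]
        php = prop if which == "phi" else self.phi[:, k]
        sticksp = self._stick_attenuation(thp, php, self.d)
        basep = self.base + self.f[:, k, None] * (sticksp - self.sticks[:, k])
        ssp = self._ss_of(basep, self.s0)
        delta = self._log_noise(ssp, self.sigma) - self._log_noise(self.ss, self.sigma)
        if which == "theta":
            # uniform-on-sphere prior: density proportional to |sin theta|
            delta = delta + np.log(np.abs(np.sin(thp)) + 1e-300)
            delta = delta - np.log(np.abs(np.sin(self.theta[:, k])) + 1e-300)
        acc = self._accept(delta, np.ones(self.V, dtype=bool), pidx)
        if which == "theta":
            self.theta[acc, k] = prop[acc]
        else:
            self.phi[acc, k] = prop[acc]
        self.sticks[acc, k] = sticksp[acc]
        self.base[acc] = basep[acc]
        self.ss[acc] = ssp[acc]

    def sweep(self):
        self._update_s0()
        self._update_d()
        for k in range(self.K):
            self._update_fraction(k)
            self._update_angle(k, "theta")
            self._update_angle(k, "phi")
        self._update_sigma()

    def adapt(self, window: int):
        rate = self.acc / window
        self.steps *= np.exp(rate - 0.4)
        self.steps = np.clip(self.steps, 1e-6, None)
        self.acc[:] = 0.0

    def orientations(self) -> np.ndarray:
        return _spherical_to_unit(self.theta, self.phi)  # (V, K, 3)


def fit_ball_and_sticks(
    dwi: DWIDataset,
    mask: np.ndarray | None = None,
    max_populations: int = 3,
    n_burn: int = 1000,
    n_post: int = 50,
    thin: int = 25,
    prune_threshold: float = 0.05,
    ard_weight: float = 1.0,
    rng_seed: int = 0,
) -> OrientationPosterior:
    """Sample the ball-and-sticks posterior in every masked voxel.

    Chains are initialized from the tensor fit (stick 1 along the principal
    direction, remaining sticks along the minor eigenvectors with small
    fractions) and run with component-wise adaptive random-walk MH; after
    ``n_burn`` iterations, ``n_post`` samples are retained every ``thin``
    sweeps. Populations with posterior-mean fraction below
    ``prune_threshold`` are pruned. No convergence diagnostics are attempted.
    Reproducible for a given ``rng_seed``.
    """
    if max_populations not in (1, 2, 3):
        raise ValueError(f"max_populations must be 1, 2 or 3, got {max_populations}")
    if n_post < 50:
        raise ValueError(f"n_post must be >= 50, got {n_post}")

    scheme = dwi.scheme
    if mask is None:
        mask = dwi.brain_mask
    tensor = fit_tensor(dwi, mask=mask)
    fit_mask = mask & tensor.valid
    idx = np.argwhere(fit_mask)
    ix, iy, iz = idx.T
    V = idx.shape[0]
    K = max_populations
    signal = dwi.signal[ix, iy, iz].astype(float)  # (V, M)

    # initialization from the tensor fit
    evecs = np.linalg.eigh(tensor.tensors[ix, iy, iz])[1][:, :, ::-1]  # descending
    v0 = np.empty((V, K, 3))
    f0 = np.empty((V, K))
    v0[:, 0] = evecs[:, :, 0]
    f0[:, 0] = np.clip(tensor.fa[ix, iy, iz], 0.1, 0.8)
    for k in range(1, K):
        v0[:, k] = evecs[:, :, min(k, 2)]
        f0[:, k] = 0.01  # below prune threshold; grows only if the data demand
    over = f0.sum(axis=1) > 0.95
    f0[over] *= (0.95 / f0[over].sum(axis=1))[:, None]

    s0_init = dwi.signal[ix, iy, iz][:, scheme.b0_mask].mean(axis=1)
    d_init = np.clip(tensor.md[ix, iy, iz], 1e-5, _BallSticksChains.D_MAX * 0.9)
    sigma_init = np.maximum(0.05 * s0_init, 1e-3)

    rng = np.random.default_rng(rng_seed)
    chains = _BallSticksChains(
        signal,
        scheme,
        K,
        {"s0": s0_init, "d": d_init, "f": f0, "v": v0, "sigma": sigma_init},
        rng,
        ard_weight=ard_weight,
    )

    window = 50
    for it in range(n_burn):
        chains.sweep()
        if (it + 1) % window == 0:
            chains.adapt(window)

    orient_samples = np.empty((V, K, n_post, 3))
    frac_samples = np.empty((V, K, n_post))
    for s in range(n_post):
        for _ in range(thin):
            chains.sweep()
        orient_samples[:, :, s, :] = chains.orientations()
        frac_samples[:, :, s] = chains.f

    mean_frac = frac_samples.mean(axis=2)
    retained = mean_frac >= prune_threshold
    frac_samples = np.where(retained[:, :, None], frac_samples, 0.0)

    return OrientationPosterior(
        shape=dwi.signal.shape[:3],
        affine=dwi.affine.copy(),
        voxel_indices=idx,
        orientation_samples=orient_samples,
        fraction_samples=frac_samples,
        mean_fractions=mean_frac,
        retained=retained,
        s0_mean=chains.s0.copy(),
        d_mean=chains.d.copy(),
    )


def dyadic_mean(samples: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean orientation and angular dispersion of axial (sign-free) samples.

    The mean is the leading eigenvector of E[v v']; dispersion is
    1 - leading eigenvalue (0 for perfectly concentrated samples, 2/3 for
    uniform-on-sphere samples).
    """
    v = np.asarray(samples, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
        raise ValueError("samples must be a non-empty (n, 3) array")
    scatter = (v[:, :, None] * v[:, None, :]).mean(axis=0)
    evals, evecs = np.linalg.eigh(scatter)
    return evecs[:, -1], float(1.0 - evals[-1])


def posterior_summary(post: OrientationPosterior) -> dict[str, np.ndarray]:
    """Per-population mean dyadic orientation and dispersion.

    Returns dense-per-voxel compact arrays aligned with ``post.voxel_indices``:
    ``mean_orientation`` (V, K, 3) and ``dispersion`` (V, K); entries of
    pruned populations are zero / NaN respectively.
    """
    V, K = post.mean_fractions.shape
    if post.n_post < 1:
        raise ValueError("posterior has no retained samples")
    mean_orient = np.zeros((V, K, 3))
    dispersion = np.full((V, K), np.nan)
    for vidx in range(V):
        for k in range(K):
            if not post.retained[vidx, k]:
                continue
            mo, disp = dyadic_mean(post.orientation_samples[vidx, k])
            mean_orient[vidx, k] = mo
            dispersion[vidx, k] = disp
    return {"mean_orientation": mean_orient, "dispersion": dispersion}
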
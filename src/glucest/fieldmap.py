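"""Per-voxel B0 and relative-B1 field estimation.

B0 is estimated from a WASSR stack (low-power, short saturation z-spectrum
whose direct-saturation dip tracks the water frequency).  Because the
direct-saturation lineshape is symmetric about the water line regardless of
its width, maximum-symmetry estimators remain accurate when the dip is
narrow relative to the offset sampling.  Three estimators are available:

* ``mscf`` (default): maximum-symmetry center frequency by even-function
  projection.  For a candidate center ``delta`` the sampled spectrum is
  least-squares fitted with an even cubic B-spline in ``|offset - delta|``
  (a basis of symmetric lineshapes of arbitrary width); the center
  minimizing the residual is the water frequency.  The projection form
  avoids the interpolation asymmetry that biases reflection-based variants
  when the dip is undersampled.
* ``mirror``: the classic reflection variant — samples are compared with
  the cubic-spline interpolant evaluated at their mirror positions
  ``2*delta - offset``.
* ``spline_min``: the offset minimizing a cubic-spline interpolant of the
  spectrum on a fine grid.  Simplest, but biased when the dip is
  undersampled.

Relative B1 (kappa) is estimated from three images acquired after square
saturation pulses of nominal flip angles alpha_i, which follow
``S_i = S0 * cos(kappa * alpha_i)``.  For each candidate kappa the amplitude
S0 is profiled out in closed form and kappa is located by a coarse-to-fine
grid search with a final parabolic refinement; ties (the cosine model is not
injective at large kappa*alpha) are broken toward the value nearest 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline, CubicSpline

from .simulate import SaturationScheme

__all__ = [
    "OffsetStack",
    "FieldMaps",
    "infer_mask",
    "fit_b0_wassr",
    "fit_b1_multiflip",
    "estimate_field_maps",
]


@dataclass
class OffsetStack:
    """An image stack with one 2-D frame per saturation offset.

    ``data`` has shape ``spatial + (n_offsets,)``; offsets are in ppm,
    ascending and unique.  ``mask`` marks foreground voxels (inferred from
    signal level when not given).
    """

    data: np.ndarray
    offsets: np.ndarray
    scheme: SaturationScheme
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.ndim != 1:
            raise ValueError("offsets must be 1-D")
        if self.data.ndim < 2:
            raise ValueError("data must have a trailing offsets axis over >=1 spatial dim")
        if self.data.shape[-1] != self.offsets.size:
            raise ValueError(
                f"frame count {self.data.shape[-1]} does not match offset count "
                f"{self.offsets.size}"
            )
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing and unique")
        if self.mask is None:
            self.mask = infer_mask(self.data)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:-1]:
                raise ValueError("mask shape must match the spatial shape")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]

    def frame(self, offset: float) -> np.ndarray:
        idx = np.nonzero(np.isclose(self.offsets, offset))[0]
        if idx.size == 0:
            raise KeyError(f"offset {offset} ppm not present in stack")
        return self.data[..., idx[0]]


@dataclass
class FieldMaps:
    """Per-voxel static-field shift (ppm) and relative transmit factor."""

    b0_ppm: np.ndarray
    kappa: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.b0_ppm = np.asarray(self.b0_ppm, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.b0_ppm.shape == self.kappa.shape == self.valid.shape):
            raise ValueError("b0_ppm, kappa and valid must share one shape")
        if self.valid.any():
            b0v = self.b0_ppm[self.valid]
            kv = self.kappa[self.valid]
            if np.any(~np.isfinite(b0v)) or np.any(np.abs(b0v) > 1.5):
                raise ValueError("valid B0 values must be finite and within +-1.5 ppm")
            if np.any(~np.isfinite(kv)) or np.any(kv < 0.3) or np.any(kv > 2.0):
                raise ValueError("valid kappa values must lie in [0.3, 2.0]")


def infer_mask(data: np.ndarray, rel_threshold: float = 0.05) -> np.ndarray:
    """Background rule: voxels whose mean signal across offsets is below
    ``rel_threshold`` of the stack's 99th percentile are background."""
    data = np.asarray(data, dtype=float)
    mean = np.nanmean(data, axis=-1)
    ref = np.nanpercentile(data, 99)
    if not np.isfinite(ref) or ref <= 0:
        return np.zeros(data.shape[:-1], dtype=bool)
    return mean >= rel_threshold * ref


def _eval_spline_pervoxel(spline: CubicSpline, x: np.ndarray) -> np.ndarray:
    """Evaluate a vector-valued cubic spline at per-voxel abscissae.

    ``spline`` interpolates columns (one per voxel) along axis 0; ``x`` has
    shape ``(n_points, n_vox)``.  Returns values of the voxel's own column at
    the voxel's own points, shape ``(n_points, n_vox)``.
    """
    breaks = spline.x
    c = spline.c  # (4, n_seg, n_vox)
    idx = np.clip(np.searchsorted(breaks, x, side="right") - 1, 0, len(breaks) - 2)
    t = x - breaks[idx]
    vox = np.broadcast_to(np.arange(x.shape[1]), x.shape)
    out = c[0, idx, vox]
    for k in range(1, 4):
        out = out * t + c[k, idx, vox]
    return out


def _mirror_cost(
    offsets: np.ndarray,
    z: np.ndarray,
    spline: CubicSpline,
    deltas: np.ndarray,
) -> np.ndarray:
    """Mean squared mirror mismatch, vectorized over voxels.

    ``deltas`` has shape ``(n_cand, n_vox)`` (per-voxel candidate centers);
    returns cost of the same shape.
    """
    lo, hi = offsets[0], offsets[-1]
    n_cand = deltas.shape[0]
    cost = np.empty_like(deltas)
    for j in range(n_cand):
        mirror = 2.0 * deltas[j][None, :] - offsets[:, None]  # (n_off, n_vox)
        inside = (mirror >= lo) & (mirror <= hi)
        vals = _eval_spline_pervoxel(spline, np.clip(mirror, lo, hi))
        diff = np.where(inside, vals - z, 0.0)
        cnt = inside.sum(axis=0)
        cost[j] = np.einsum("ij,ij->j", diff, diff) / np.maximum(cnt, 1)
    return cost


def _even_basis_knots(offsets: np.ndarray) -> np.ndarray:
    """Knot layout of the even-lineshape basis: dense near the dip core,
    sparse on the wings, spanning every reachable |offset - delta|."""
    reach = float(offsets[-1] - offsets[0]) / 2.0 + 0.5
    core = np.array([0.0, 0.1, 0.2, 0.35, 0.55, 0.9, 1.4])
    core = core[core < reach]
    return np.append(core, reach)


def _even_design(offsets: np.ndarray, deltas: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design matrices of the even cubic B-spline basis.

    ``deltas`` has shape ``(...,)``; returns ``(..., n_off, n_basis)``.
    """
    u = np.abs(offsets - np.asarray(deltas)[..., None])
    t = np.concatenate([[knots[0]] * 3, knots, [knots[-1]] * 3])
    flat = np.clip(u.reshape(-1), knots[0], knots[-1])
    design = BSpline.design_matrix(flat, t, 3).toarray()
    return design.reshape(u.shape + (design.shape[-1],))


def _even_fit_cost(z: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residual sum of squares of the even-basis least-squares fit.

    ``z`` is ``(n_vox, n_off)``; ``design`` is ``(n_vox, n_off, n_basis)``
    (per-voxel candidate centers).  Solved through the normal equations with
    a tiny ridge for rank safety.
    """
    g = np.einsum("vib,vic->vbc", design, design)
    y = np.einsum("vib,vi->vb", design, z)
    g = g + 1e-12 * np.eye(g.shape[-1])
    coef = np.linalg.solve(g, y[..., None])[..., 0]
    return np.einsum("vi,vi->v", z, z) - np.einsum("vb,vb->v", y, coef)


def fit_b0_wassr(
    wassr: OffsetStack,
    method: str = "mscf",
    search_ppm: float = 0.5,
    grid_step: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the per-voxel water-line displacement from a WASSR stack.

    Returns ``(b0_ppm, valid)`` maps over the stack's spatial shape.
    Background voxels and voxels with non-positive or non-finite spectra are
    marked invalid (never raised).  The search window is ``+-search_ppm``.
    """
    offsets = wassr.offsets
    if offsets.size < 7:
        raise ValueError("WASSR requires at least 7 offsets")
    if not np.allclose(offsets + offsets[::-1], 0.0, atol=1e-9):
        raise ValueError("WASSR offsets must span 0 symmetrically")
    if method not in ("mscf", "mirror", "spline_min"):
        raise ValueError(f"unknown B0 method {method!r}")

    spatial = wassr.spatial_shape
    flat = wassr.data.reshape(-1, offsets.size)
    mask = wassr.mask.reshape(-1)
    usable = mask & np.all(np.isfinite(flat), axis=1) & np.any(flat > 0, axis=1)

    b0 = np.full(flat.shape[0], np.nan)
    valid = np.zeros(flat.shape[0], dtype=bool)
    if usable.any():
        z = flat[usable].T  # (n_off, n_vox)
        if method == "spline_min":
            spline = CubicSpline(offsets, z, axis=0, bc_type="natural")
            grid = np.arange(offsets[0], offsets[-1] + grid_step / 2, grid_step)
            dense = spline(grid)  # (n_grid, n_vox)
            est = grid[np.argmin(dense, axis=0)]
        elif method == "mirror":
            spline = CubicSpline(offsets, z, axis=0, bc_type="natural")
            est = _fit_mirror(offsets, z, spline, search_ppm)
        else:
            est = _fit_symmetry(offsets, flat[usable], search_ppm)
        b0[usable] = est
        valid[usable] = np.abs(est) <= min(1.5, abs(offsets[-1]))
        b0[~valid & usable] = np.nan
        valid &= usable
    return b0.reshape(spatial), valid.reshape(spatial)


def _fit_mirror(
    offsets: np.ndarray, z: np.ndarray, spline: CubicSpline, search_ppm: float
) -> np.ndarray:
    n_vox = z.shape[1]
    coarse = np.arange(-search_ppm, search_ppm + 1e-12, 0.005)
    cost = _mirror_cost(offsets, z, spline, np.broadcast_to(coarse[:, None], (coarse.size, n_vox)))
    center = coarse[np.argmin(cost, axis=0)]
    for half, step in ((0.006, 0.001), (0.0012, 0.0002)):
        rel = np.arange(-half, half + step / 2, step)
        cand = center[None, :] + rel[:, None]
        cost = _mirror_cost(offsets, z, spline, cand)
        center = cand[np.argmin(cost, axis=0), np.arange(n_vox)]
    return center


_COARSE_STEP = 0.01
_PROJECTION_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _coarse_projections(offsets: np.ndarray, search_ppm: float):
    """Data-independent QR projections of the even basis on the coarse grid."""
    key = (offsets.tobytes(), round(search_ppm, 9))
    if key not in _PROJECTION_CACHE:
        knots = _even_basis_knots(offsets)
        coarse = np.arange(-search_ppm, search_ppm + 1e-12, _COARSE_STEP)
        designs = _even_design(offsets, coarse, knots)  # (n_coarse, n_off, nb)
        q, _ = np.linalg.qr(designs)
        _PROJECTION_CACHE[key] = (coarse, q)
    return _PROJECTION_CACHE[key]


def _fit_symmetry(offsets: np.ndarray, z: np.ndarray, search_ppm: float) -> np.ndarray:
    """Even-projection maximum-symmetry center fit (``z``: (n_vox, n_off))."""
    n_vox = z.shape[0]
    knots = _even_basis_knots(offsets)
    coarse, q_stack = _coarse_projections(offsets, search_ppm)
    cost = np.empty((coarse.size, n_vox))
    zt = z.T
    for j in range(coarse.size):
        q = q_stack[j]
        r = zt - q @ (q.T @ zt)
        cost[j] = np.einsum("iv,iv->v", r, r)
    center = coarse[np.argmin(cost, axis=0)]
    rows = np.arange(n_vox)
    # single per-voxel refinement pass, then a parabolic vertex
    step = 0.002
    rel = np.arange(-5, 6) * step  # covers the coarse half-step plus bias
    cand = center[None, :] + rel[:, None]  # (n_rel, n_vox)
    cost = np.empty_like(cand)
    for j in range(rel.size):
        design = _even_design(offsets, cand[j], knots)  # (n_vox, n_off, nb)
        cost[j] = _even_fit_cost(z, design)
    jbest = np.argmin(cost, axis=0)
    center = cand[jbest, rows]
    jm = np.clip(jbest, 1, cost.shape[0] - 2)
    c0, cp, cm = cost[jm, rows], cost[jm + 1, rows], cost[jm - 1, rows]
    denom = cp - 2 * c0 + cm
    shift = np.where(np.abs(denom) > 0, 0.5 * (cm - cp) / np.where(denom == 0, 1, denom), 0.0)
    interior = (jbest > 0) & (jbest < cost.shape[0] - 1)
    return np.where(interior, cand[jm, rows] + np.clip(shift, -1, 1) * step, center)


def fit_b1_multiflip(
    images: np.ndarray,
    angles_deg: tuple[float, float, float] = (20.0, 40.0, 80.0),
    kappa_bounds: tuple[float, float] = (0.3, 2.0),
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate relative B1 from three flip-angle calibration images.

    ``images`` stacks the three frames on the trailing axis.  Per voxel,
    kappa minimizes ``sum_i (S_i - S0 cos(kappa alpha_i))^2`` with S0
    profiled out in closed form; the search covers ``kappa_bounds`` and ties
    are broken toward the value nearest 1.  Returns ``(kappa, valid)``.
    """
    images = np.asarray(images, dtype=float)
    angles = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if angles.size != 3 or images.shape[-1] != 3:
        raise ValueError("exactly three flip-angle images are required")
    if np.any(np.diff(angles) <= 0):
        raise ValueError("nominal flip angles must be strictly increasing")
    lo, hi = kappa_bounds
    if not (0 < lo < hi <= 2.0 + 1e-9):
        raise ValueError("kappa_bounds must satisfy 0 < lo < hi <= 2")

    spatial = images.shape[:-1]
    s = images.reshape(-1, 3)
    finite = np.all(np.isfinite(s), axis=1)
    nonzero = np.any(s != 0, axis=1)
    usable = finite & nonzero
    if mask is not None:
        usable &= np.asarray(mask, dtype=bool).reshape(-1)

    kappa = np.full(s.shape[0], np.nan)
    valid = np.zeros(s.shape[0], dtype=bool)
    if usable.any():
        sv = s[usable]
        # coarse pass on a shared grid, amplitude profiled out:
        # residual(kappa) = |S|^2 - (S.c)^2 / |c|^2, so maximize gain (S.c)^2/|c|^2
        n_coarse = int(round((hi - lo) / 1e-3)) + 1
        grid = np.linspace(lo, hi, n_coarse)
        cos_g = np.cos(grid[None, :] * angles[:, None])  # (3, n_k)
        gain = (sv @ cos_g) ** 2 / (cos_g**2).sum(axis=0)[None, :]
        gmax = gain.max(axis=1, keepdims=True)
        near = gain >= gmax - 1e-12 * np.maximum(gmax, 1e-300)
        penalty = np.where(near, np.abs(grid[None, :] - 1.0), np.inf)
        best = grid[np.argmin(penalty, axis=1)]
        # fine pass around each voxel's coarse optimum, then parabolic vertex
        rel = np.arange(-10, 11) * 1e-4
        cand = np.clip(best[:, None] + rel[None, :], lo, hi)  # (n_vox, 21)
        cos_c = np.cos(cand[..., None] * angles[None, None, :])
        gain_f = np.einsum("vi,vki->vk", sv, cos_c) ** 2 / (cos_c**2).sum(axis=-1)
        j = np.argmin(np.where(
            gain_f >= gain_f.max(axis=1, keepdims=True) - 1e-12 * np.maximum(gain_f.max(axis=1, keepdims=True), 1e-300),
            np.abs(cand - 1.0), np.inf), axis=1)
        rows = np.arange(cand.shape[0])
        k_best = cand[rows, j]
        jm = np.clip(j, 1, cand.shape[1] - 2)
        g0, gp, gm = gain_f[rows, jm], gain_f[rows, jm + 1], gain_f[rows, jm - 1]
        denom = gp - 2 * g0 + gm
        shift = np.where(np.abs(denom) > 0, 0.5 * (gm - gp) / np.where(denom == 0, 1, denom), 0.0)
        refined = cand[rows, jm] + np.clip(shift, -1.0, 1.0) * 1e-4
        k_best = np.where((j > 0) & (j < cand.shape[1] - 1), refined, k_best)
        kappa[usable] = np.clip(k_best, lo, hi)
        valid[usable] = True
    return kappa.reshape(spatial), valid.reshape(spatial)


def estimate_field_maps(
    wassr: OffsetStack,
    b1_images: np.ndarray,
    angles_deg: tuple[float, float, float] = (20.0, 40.0, 80.0),
    b0_method: str = "mscf",
) -> FieldMaps:
    """Joint per-voxel B0 (WASSR) and relative-B1 (multi-flip) estimation."""
    b0, b0_valid = fit_b0_wassr(wassr, method=b0_method)
    kappa, k_valid = fit_b1_multiflip(b1_images, angles_deg, mask=wassr.mask)
    valid = b0_valid & k_valid
    b0 = np.where(valid, b0, np.nan)
    kappa = np.where(valid, kappa, np.nan)
    return FieldMaps(b0_ppm=b0, kappa=kappa, valid=valid)
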
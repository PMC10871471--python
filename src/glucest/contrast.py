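"""B0- and B1-corrected GluCEST percent-contrast maps.

The contrast is the magnetization-transfer-ratio asymmetry about the water
line at the amine resonance, normalized to the negative-offset image:

    GluCEST% = 100 * (Z(-3.0) - Z(+3.0)) / Z(-3.0)

B0 correction interpolates each voxel's z-spectrum along the offset axis
(cubic spline per sign branch, natural boundary, never extrapolating) and
reads it off at the voxel's true +-3.0 ppm, i.e. at ``+-3.0 + b0``.

B1 correction rescales the contrast by a simulation-derived lookup:
``corrected = raw * C(1) / C(kappa)`` where C is the calibration curve of
simulated contrast versus relative B1 (see
:func:`glucest.simulate.b1_calibration_curve`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .fieldmap import OffsetStack, _eval_spline_pervoxel

__all__ = ["GluCESTMap", "correct_b0", "compute_glucest", "correct_b1"]


@dataclass
class GluCESTMap:
    """Per-voxel percent contrast with a validity mask.

    Invalid voxels carry NaN and are excluded from all downstream statistics.
    ``meta`` records correction settings and calibration provenance.
    """

    percent: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.percent = np.asarray(self.percent, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.percent.shape != self.valid.shape:
            raise ValueError("percent and valid must share one shape")
        if self.valid.any() and not np.all(np.isfinite(self.percent[self.valid])):
            raise ValueError("valid voxels must carry finite contrast values")
        self.percent = np.where(self.valid, self.percent, np.nan)


def _branch(offsets: np.ndarray, data: np.ndarray, sign: int):
    sel = offsets < 0 if sign < 0 else offsets > 0
    if sel.sum() < 4:
        raise ValueError("each sign branch needs at least 4 sampled offsets")
    return offsets[sel], data[..., sel]


def correct_b0(
    cest: OffsetStack,
    b0_ppm: np.ndarray,
    b0_valid: np.ndarray | None = None,
    target_ppm: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read off Z at the voxel's true ``+-target_ppm`` given its B0 shift.

    Interpolation runs separately on the negative- and positive-offset
    branches; a voxel is invalidated (never extrapolated) when an evaluation
    point ``+-target + b0`` leaves the sampled magnitude range of its branch.
    Returns ``(z_neg, z_pos, valid)``.
    """
    offsets = cest.offsets
    b0 = np.asarray(b0_ppm, dtype=float)
    if b0.shape != cest.spatial_shape:
        raise ValueError("B0 map shape must match the stack's spatial shape")
    valid = np.isfinite(b0) & cest.mask
    if b0_valid is not None:
        valid = valid & np.asarray(b0_valid, dtype=bool)

    out = []
    for sign in (-1, +1):
        br_off, br_data = _branch(offsets, cest.data, sign)
        lo, hi = np.abs(br_off).min(), np.abs(br_off).max()
        target = sign * target_ppm + b0
        inside = (np.abs(target) >= lo - 1e-12) & (np.abs(target) <= hi + 1e-12)
        inside &= np.sign(target) == sign
        valid = valid & inside
        flat = br_data.reshape(-1, br_off.size).T  # (n_off, n_vox)
        spline = CubicSpline(br_off, flat, axis=0, bc_type="natural")
        x = np.clip(target.reshape(1, -1), br_off[0], br_off[-1])
        z = _eval_spline_pervoxel(spline, x)[0].reshape(cest.spatial_shape)
        out.append(z)
    z_neg, z_pos = out
    z_neg = np.where(valid, z_neg, np.nan)
    z_pos = np.where(valid, z_pos, np.nan)
    return z_neg, z_pos, valid


def compute_glucest(
    z_neg: np.ndarray,
    z_pos: np.ndarray,
    valid: np.ndarray | None = None,
    meta: dict | None = None,
) -> GluCESTMap:
    """Percent asymmetry ``100 (z_neg - z_pos) / z_neg`` per valid voxel.

    Voxels with non-positive or non-finite ``z_neg`` are invalidated.
    """
    z_neg = np.asarray(z_neg, dtype=float)
    z_pos = np.asarray(z_pos, dtype=float)
    if z_neg.shape != z_pos.shape:
        raise ValueError("z_neg and z_pos maps must be aligned")
    ok = np.isfinite(z_neg) & np.isfinite(z_pos) & (z_neg > 0)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        percent = 100.0 * (z_neg - z_pos) / z_neg
    percent = np.where(ok, percent, np.nan)
    return GluCESTMap(percent=percent, valid=ok, meta=dict(meta or {}))


def correct_b1(
    raw: GluCESTMap,
    kappa: np.ndarray,
    calibration: pd.DataFrame,
    kappa_limits: tuple[float, float] = (0.5, 1.5),
) -> GluCESTMap:
    """Rescale contrast by the simulation-derived B1 lookup ratio.

    ``corrected = raw * C(1) / C(kappa)`` with C linearly interpolated from
    the calibration table.  Voxels whose kappa falls outside
    ``kappa_limits`` or outside the table's span are invalidated.
    """
    kappa = np.asarray(kappa, dtype=float)
    if kappa.shape != raw.percent.shape:
        raise ValueError("kappa map shape must match the contrast map")
    if not {"kappa", "glucest_percent"} <= set(calibration.columns):
        raise ValueError("calibration table needs 'kappa' and 'glucest_percent' columns")
    tab = calibration.sort_values("kappa")
    kg = tab["kappa"].to_numpy(dtype=float)
    cg = tab["glucest_percent"].to_numpy(dtype=float)
    lo, hi = kappa_limits
    if kg[0] > lo + 1e-12 or kg[-1] < hi - 1e-12:
        raise ValueError(
            f"calibration table spans [{kg[0]:g}, {kg[-1]:g}] but must cover "
            f"[{lo:g}, {hi:g}]"
        )
    dif = np.diff(cg)
    if not (np.all(dif > 0) or np.all(dif < 0)):
        raise ValueError("calibration curve must be monotone over its span")
    if not (kg[0] <= 1.0 <= kg[-1]):
        raise ValueError("calibration table must cover kappa = 1")

    ok = raw.valid & np.isfinite(kappa) & (kappa >= lo) & (kappa <= hi)
    c_kappa = np.interp(np.where(ok, kappa, 1.0), kg, cg)
    c_one = float(np.interp(1.0, kg, cg))
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = raw.percent * (c_one / c_kappa)
    meta = dict(raw.meta)
    meta.update(b1_corrected=True, kappa_limits=list(kappa_limits),
                calibration_points=len(kg))
    return GluCESTMap(percent=np.where(ok, corrected, np.nan), valid=ok, meta=meta)
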
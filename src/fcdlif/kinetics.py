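"""Downstream kinetic quantification: plasma conversion, Patlak, 2TCM fits.

The Patlak plot linearizes irreversible tracer uptake: for times past the
distribution phase, y = C_t(T)/C_p(T) against x = int_0^T C_p dt / C_p(T)
is a line whose slope is the net influx rate Ki = K1*k3/(k2+k3).  All Ki
values are reported per minute.  The region-wise alternative fits the full
irreversible two-tissue compartment model by nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .formats_io import BloodCurve, DynamicPETImage
from .phantom import KineticParams, simulate_2tcm

#: Default start of the Patlak linear phase: the beginning of the 300-s
#: frames, past the distribution phase whose signal Patlak discards.
DEFAULT_T_STAR_S: float = 600.0


@dataclass(frozen=True)
class PatlakResult:
    """Slope (Ki, per min), intercept (unitless), fit r^2 and frames used."""

    Ki: float
    intercept: float
    r_squared: float
    t_star: float
    frames_used: int


def blood_to_plasma(curve: BloodCurve, ratio_model=1.0) -> BloodCurve:
    """Convert a whole-blood curve to a plasma input function.

    ``ratio_model`` is the plasma-to-whole-blood concentration ratio: a
    positive constant, or a ``(times_s, ratios)`` table interpolated
    linearly at the curve's sample times (clamped at the table ends).

    .. warning::
       The default ratio of 1.0 is a placeholder.  The plasma/whole-blood
       ratio is tracer- and species-specific (for FDG in mice it is time
       dependent); supply a measured ratio model for real studies.
    """
    if np.isscalar(ratio_model):
        ratios = np.full(len(curve), float(ratio_model))
    else:
        table_t, table_r = (np.asarray(a, dtype=float) for a in ratio_model)
        if table_t.ndim != 1 or table_t.shape != table_r.shape:
            raise ValueError("ratio table must be two matching 1-D arrays")
        ratios = np.interp(curve.times, table_t, table_r)
    if np.any(ratios <= 0):
        raise ValueError("plasma/whole-blood ratio must be positive everywhere")
    return BloodCurve(times=curve.times, values=curve.values * ratios, kind="plasma")


def _patlak_xy(tissue_values: np.ndarray, plasma: BloodCurve, t_star: float):
    """Shared Patlak coordinates; tissue_values has frames on the first axis."""
    t = plasma.times
    cp = plasma.values
    # cumulative trapezoid from t = 0 with the curve anchored at (0, 0)
    t0 = np.concatenate([[0.0], t])
    cp0 = np.concatenate([[0.0], cp])
    integral = np.cumsum(np.diff(t0) * (cp0[1:] + cp0[:-1]) / 2.0)
    use = t >= t_star
    if use.sum() < 2:
        raise ValueError(f"fewer than 2 frames at or after t* = {t_star} s")
    if np.any(cp[use] <= 0):
        raise ValueError("plasma concentration must be positive on the frames used")
    x = integral[use] / cp[use]
    y = tissue_values[..., use] / cp[use]
    return x, y, int(use.sum())


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Least-squares slope/intercept/r^2 of y (…, n) against x (n,)."""
    xm = x - x.mean()
    ym = y - y.mean(axis=-1, keepdims=True)
    sxx = float(np.dot(xm, xm))
    sxy = ym @ xm
    slope = sxy / sxx
    intercept = y.mean(axis=-1) - slope * x.mean()
    ss_res = np.sum((ym - slope[..., None] * xm) ** 2, axis=-1)
    ss_tot = np.sum(ym * ym, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return slope, intercept, r2


def patlak_fit(tissue: BloodCurve, plasma: BloodCurve, t_star: float = DEFAULT_T_STAR_S) -> PatlakResult:
    """Patlak graphical analysis of one tissue curve.

    Frames with midpoint >= ``t_star`` enter an ordinary least-squares fit
    of y = C_t/C_p against x = (int_0^T C_p)/C_p; the slope, converted to
    per-minute, is Ki.
    """
    if len(tissue) != len(plasma) or not np.allclose(tissue.times, plasma.times):
        raise ValueError("tissue and plasma curves must share one time grid")
    # run the batched code path with one row so voxel maps agree bit for bit
    x, y, n_used = _patlak_xy(np.asarray(tissue.values, dtype=float)[None], plasma, t_star)
    slope, intercept, r2 = _ols_line(x, y)
    return PatlakResult(
        Ki=float(slope[0]) * 60.0,
        intercept=float(intercept[0]),
        r_squared=float(r2[0]),
        t_star=float(t_star),
        frames_used=n_used,
    )


def patlak_image(
    image: DynamicPETImage,
    plasma: BloodCurve,
    t_star: float = DEFAULT_T_STAR_S,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise Ki (per min) and intercept maps; unmasked/failed voxels are NaN.

    Each masked voxel's time-activity curve goes through the same
    arithmetic as :func:`patlak_fit`, so a voxel map entry and a
    single-curve fit on that voxel's TAC agree bit for bit.
    """
    if image.n_frames != len(plasma):
        raise ValueError("image frame count and plasma curve length differ")
    spatial = image.spatial_shape
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    if mask.shape != spatial:
        raise ValueError(f"mask shape {mask.shape} does not match spatial shape {spatial}")

    ki_map = np.full(spatial, np.nan)
    intercept_map = np.full(spatial, np.nan)
    tacs = np.asarray(image.values, dtype=float)[:, mask].T  # (n_voxels, T)
    x, y, _ = _patlak_xy(tacs, plasma, t_star)
    slope, intercept, _ = _ols_line(x, y)
    ki_map[mask] = slope * 60.0
    intercept_map[mask] = intercept
    return ki_map, intercept_map


def fit_2tcm(
    tissue: BloodCurve,
    plasma: BloodCurve,
    init: KineticParams,
    bounds: tuple[KineticParams, KineticParams] | None = None,
    fit_vb: bool = False,
    weights: np.ndarray | None = None,
) -> tuple[KineticParams, dict]:
    """Fit the irreversible 2TCM to a tissue curve by nonlinear least squares.

    Returns the fitted parameters and diagnostics (``converged``,
    ``residual_norm``, ``n_evaluations``).  Residuals are uniformly
    weighted unless ``weights`` is given.  ``bounds`` defaults to
    [0, 10] on each rate and [0, 1] on vB; the initial guess must lie
    inside them.
    """
    if len(tissue) != len(plasma) or not np.allclose(tissue.times, plasma.times):
        raise ValueError("tissue and plasma curves must share one time grid")
    cp = plasma.interpolator()
    t = tissue.times
    target = np.asarray(tissue.values, dtype=float)
    w = np.ones_like(target) if weights is None else np.asarray(weights, dtype=float)

    if bounds is None:
        lo = KineticParams(0.0, 0.0, 0.0, vB=0.0)
        hi = KineticParams(10.0, 10.0, 10.0, vB=1.0)
    else:
        lo, hi = bounds
    names = ["K1", "k2", "k3"] + (["vB"] if fit_vb else [])
    x0 = np.array([getattr(init, n) for n in names])
    lb = np.array([getattr(lo, n) for n in names])
    ub = np.array([getattr(hi, n) for n in names])
    if np.any(lb < 0):
        raise ValueError("bounds must be non-negative")
    if np.any(x0 < lb) or np.any(x0 > ub):
        raise ValueError("initial guess lies outside the bounds")

    def unpack(x) -> KineticParams:
        vb = x[3] if fit_vb else init.vB
        return KineticParams(K1=x[0], k2=x[1], k3=x[2], vB=float(vb))

    def residuals(x):
        model = simulate_2tcm(unpack(x), cp, t)
        return w * (model - target)

    result = least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12, gtol=1e-12)
    fitted = unpack(result.x)
    diagnostics = {
        "converged": bool(result.success),
        "residual_norm": float(np.linalg.norm(result.fun)),
        "n_evaluations": int(result.nfev),
    }
    return fitted, diagnostics
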
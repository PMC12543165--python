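"""Radon-transform line-scan velocimetry and Patlak / Renkin-Crone
permeability.

Velocity convention: in a space-time image with rows = scan lines and
columns = space, a shadow moving at v traces a streak whose slope is
v*dt/dx pixels per line; the streak angle theta is measured from the
time axis, so v = (dx/dt) * tan(theta) and stationary shadows give
theta = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.transform import radon, resize

from .phantom import LineScan

DEFAULT_HEMATOCRIT = 0.45


class FlowLimitedError(ValueError):
    """Ktrans >= F_p: extraction is flow-limited and PS is undefined."""


@dataclass
class VelocityWindow:
    start_line: int
    theta_deg: float
    v_mm_s: float
    valid: bool
    reason: str = ""


@dataclass
class PermeabilityResult:
    segment_id: int
    Ktrans: float               # min^-1 (Patlak slope, reported raw)
    v_b: float                  # intercept, dimensionless
    r2: float
    negative_slope: bool = False
    PS: float = np.nan          # min^-1
    F_p_um3_s: float = np.nan   # raw plasma flow surrogate
    F_p_per_min: float = np.nan # after ROI-volume normalization
    Hct: float = DEFAULT_HEMATOCRIT
    area_um2: float = np.nan
    fit_start_min: float = 0.0
    flow_limited: bool = False


# ----------------------------------------------------------------------
# velocimetry
# ----------------------------------------------------------------------

def _refine_peak(sob: np.ndarray, t0: float, half_width: float,
                 fine_step: float) -> float:
    """Fine local angle grid around t0 plus parabolic peak refinement."""
    fine = np.arange(t0 - half_width, t0 + half_width + 1e-9, fine_step)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        var_f = radon(sob, theta=fine % 180.0).var(axis=0)
    i = int(np.argmax(var_f))
    t_star = fine[i]
    if 0 < i < len(fine) - 1:
        a, b, c = var_f[i - 1], var_f[i], var_f[i + 1]
        denom = a - 2 * b + c
        if denom < 0:
            t_star = fine[i] + 0.5 * (a - c) / denom * fine_step
    return float(t_star)


def _sobel_square(img: np.ndarray, resize_to: int) -> np.ndarray:
    sq = resize(img.astype(float), (resize_to, resize_to), order=1, anti_aliasing=True)
    sob = ndimage.sobel(sq, axis=1)
    return sob - sob.mean()


def _radon_peak_angle(img: np.ndarray, resize_to: int = 256,
                      coarse_step: float = 1.0, fine_step: float = 0.05) -> tuple[float, float]:
    """Dominant streak angle (deg) of a square-resized patch via the
    variance-of-Radon-projection sharpness functional. The coarse sweep
    runs on a half-resolution copy; the fine local grid and parabolic
    refinement on the full patch. Returns (theta_deg, sharpness)."""
    sob_small = _sobel_square(img, resize_to // 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        thetas = np.arange(-90 + coarse_step, 90.0, coarse_step)
        var = radon(sob_small, theta=thetas % 180.0).var(axis=0)
    t0 = thetas[int(np.argmax(var))]
    sharpness = float(var.max() / max(np.median(var), 1e-30))
    sob = _sobel_square(img, resize_to)
    t_star = _refine_peak(sob, t0, 2 * coarse_step, fine_step)
    return t_star, sharpness


def _window_angle(win: np.ndarray) -> tuple[float, float]:
    """Streak slope (px per line) of one space-time window.

    The window is resampled to a square before the Radon sweep so that
    fast, nearly horizontal streaks stay well conditioned; the returned
    slope is corrected back to original pixel units. Slow flows benefit
    from taller windows (more displacement per window), which the caller
    controls via ``window_lines``. Returns (slope, peak_sharpness).
    """
    n_lines, n_space = win.shape
    theta, sharpness = _radon_peak_angle(win)
    slope = float(np.tan(np.deg2rad(theta)) * n_space / n_lines)
    return slope, sharpness


def radon_velocity(
    linescan: LineScan,
    window_lines: int = 40,
    overlap: float = 0.5,
    min_sharpness: float = 1.5,
) -> list[VelocityWindow]:
    """Per-window streak angle and velocity from a space-time image.

    Windows with a flat variance spectrum (no streaks) or an implied
    per-line displacement exceeding half the spatial window are marked
    invalid rather than reported.
    """
    img = np.asarray(linescan.image, float)
    n_lines, n_space = img.shape
    if window_lines > n_lines:
        raise ValueError("window taller than the image")
    step = max(int(window_lines * (1 - overlap)), 1)
    results = []
    for start in range(0, n_lines - window_lines + 1, step):
        win = img[start : start + window_lines]
        if win.std() < 1e-12:
            results.append(VelocityWindow(start, 0.0, 0.0, False, "flat window"))
            continue
        slope, sharpness = _window_angle(win)
        v_mm_s = slope * linescan.dx_um / linescan.dt_line_s / 1000.0
        theta = float(np.degrees(np.arctan(slope)))
        if sharpness < min_sharpness:
            results.append(VelocityWindow(start, theta, v_mm_s, False, "no streak peak"))
            continue
        if abs(slope) > n_space / 2:
            results.append(VelocityWindow(start, theta, v_mm_s, False, "aliasing guard"))
            continue
        results.append(VelocityWindow(start, theta, v_mm_s, True))
    return results


def median_velocity(windows: list[VelocityWindow]) -> float:
    vals = [w.v_mm_s for w in windows if w.valid]
    if not vals:
        raise ValueError("no valid velocimetry windows")
    return float(np.median(vals))


# ----------------------------------------------------------------------
# Patlak
# ----------------------------------------------------------------------

def patlak_ktrans(
    F_peri: np.ndarray,
    F_iv: np.ndarray,
    t_min: np.ndarray,
    fit_start_min: float = 5.0,
) -> tuple[float, float, float]:
    """Patlak linear regression of perivascular vs intravascular signal.

    y = F_peri/F_iv is regressed on x = (integral of F_iv)/F_iv over
    frames with t >= fit_start; the slope is Ktrans (min^-1) and the
    intercept the distribution volume fraction v_b. Returns
    (Ktrans, v_b, r2); negative slopes are returned raw.
    """
    F_peri = np.asarray(F_peri, float)
    F_iv = np.asarray(F_iv, float)
    t_min = np.asarray(t_min, float)
    sel = t_min >= fit_start_min
    if sel.sum() < 5:
        raise ValueError("need at least 5 frames in the fit window")
    if np.any(F_iv[sel] <= 0):
        raise ValueError("F_iv must be positive on the fit window")
    integral = np.concatenate([[0.0], np.cumsum(
        0.5 * (F_iv[1:] + F_iv[:-1]) * np.diff(t_min))])
    x = integral[sel] / F_iv[sel]
    y = F_peri[sel] / F_iv[sel]
    if np.ptp(x) <= 0:
        raise ValueError("degenerate Patlak abscissa (constant x)")
    if np.allclose(y, y[0]):
        # exactly constant ratio: slope 0, intercept = that ratio
        return 0.0, float(y[0]), 1.0 if np.all(y == 0) else 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ----------------------------------------------------------------------
# flow and Renkin-Crone
# ----------------------------------------------------------------------

def plasma_flow(
    diameter_um: float,
    velocity_mm_s: float,
    Hct: float = DEFAULT_HEMATOCRIT,
    roi_volume_um3: float | None = None,
) -> dict:
    """Plasma flow surrogate F_p = v * A * (1 - Hct).

    Returned in um^3/s; when ``roi_volume_um3`` (the perivascular
    distribution volume) is given, also normalized to min^-1 so F_p
    shares Ktrans units.
    """
    if diameter_um <= 0 or velocity_mm_s <= 0:
        raise ValueError("diameter and velocity must be positive")
    if not (0 <= Hct < 1):
        raise ValueError("hematocrit must be in [0, 1)")
    area = np.pi * (diameter_um / 2.0) ** 2
    fp_um3_s = velocity_mm_s * 1000.0 * area * (1.0 - Hct)
    out = {"area_um2": float(area), "F_p_um3_s": float(fp_um3_s)}
    if roi_volume_um3 is not None:
        if roi_volume_um3 <= 0:
            raise ValueError("ROI volume must be positive")
        out["F_p_per_min"] = float(fp_um3_s / roi_volume_um3 * 60.0)
    return out


def renkin_crone_ps(Ktrans: float, F_p: float) -> float:
    """Invert Ktrans = F_p*(1 - exp(-PS/F_p)) for PS (same units).

    Raises :class:`FlowLimitedError` when Ktrans >= F_p, where the
    extraction fraction saturates and PS is undefined.
    """
    if Ktrans < 0:
        raise ValueError("Ktrans must be >= 0")
    if F_p <= 0:
        raise ValueError("F_p must be positive")
    if Ktrans >= F_p:
        raise FlowLimitedError(
            f"Ktrans={Ktrans:.4g} >= F_p={F_p:.4g}: flow-limited regime, PS undefined"
        )
    return float(-F_p * np.log1p(-Ktrans / F_p))


def permeability_for_segment(
    segment_id: int,
    F_peri: np.ndarray,
    F_iv: np.ndarray,
    t_min: np.ndarray,
    diameter_um: float,
    velocity_mm_s: float,
    roi_volume_um3: float,
    Hct: float = DEFAULT_HEMATOCRIT,
    fit_start_min: float = 5.0,
) -> PermeabilityResult:
    """Full per-segment permeability record: Patlak slope, plasma flow,
    and flow-normalized PS (flagged, not clipped, when out of domain)."""
    ktrans, vb, r2 = patlak_ktrans(F_peri, F_iv, t_min, fit_start_min)
    flow = plasma_flow(diameter_um, velocity_mm_s, Hct, roi_volume_um3)
    res = PermeabilityResult(
        segment_id=segment_id, Ktrans=ktrans, v_b=vb, r2=r2,
        negative_slope=ktrans < 0,
        F_p_um3_s=flow["F_p_um3_s"], F_p_per_min=flow["F_p_per_min"],
        Hct=Hct, area_um2=flow["area_um2"], fit_start_min=fit_start_min,
    )
    if ktrans >= 0:
        try:
            res.PS = renkin_crone_ps(ktrans, flow["F_p_per_min"])
        except FlowLimitedError:
            res.flow_limited = True
    return res
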
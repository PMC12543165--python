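"""Image conditioning: Gaussian smoothing, rolling-ball background
subtraction, MIP-based flat-field normalization, affine 3D registration.

Background subtraction and flat-field division are restricted to
structural stacks by default: applying them to quantitative leakage
frames would distort the faint extravasation halos being measured, so
a ``LEAKAGE``-role stack is refused unless ``allow_leakage=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import ChannelRole, ImageStack4D, fwhm_to_sigma_px


class RoleError(ValueError):
    """A structure-only operation was applied to a leakage stack."""


class RegistrationError(RuntimeError):
    def __init__(self, message: str, final_metric: float | None = None):
        super().__init__(message)
        self.final_metric = final_metric


@dataclass
class FlatfieldReference:
    """Smoothed-MIP illumination field, mean-normalized to 1."""

    field: np.ndarray  # 2D (y, x), strictly positive
    smoothing_fwhm_um: float = 20.0
    pial_exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.field <= 0):
            raise ValueError("flat-field must be strictly positive (division hazard)")


def _check_role(stack: ImageStack4D, allow_leakage: bool, op: str) -> None:
    if stack.channel_role == ChannelRole.LEAKAGE and not allow_leakage:
        raise RoleError(
            f"{op} is restricted to structural images; pass allow_leakage=True "
            "to override (this will distort quantitative leakage signals)"
        )


def gaussian_smooth(stack: ImageStack4D, fwhm_um: float) -> ImageStack4D:
    """Per-frame 3D Gaussian smoothing with a physical FWHM.

    sigma per axis = fwhm / (2*sqrt(2 ln 2)) / voxel_size; reflective
    boundaries conserve total intensity up to border effects.
    """
    sigma = fwhm_to_sigma_px(fwhm_um, stack.voxel_size_um)
    out = np.empty_like(stack.data, dtype=np.float64)
    for f in range(stack.n_frames):
        out[f] = ndimage.gaussian_filter(
            stack.data[f].astype(np.float64), sigma=sigma, mode="reflect"
        )
    return stack.with_data(out)


def _ball_footprint(radius_um: float, voxel_size_um) -> np.ndarray:
    """Boolean ellipsoid: a physically spherical ball on an anisotropic grid."""
    half = [max(int(np.floor(radius_um / v)), 1) for v in voxel_size_um]
    grids = np.meshgrid(*[np.arange(-h, h + 1) * v for h, v in zip(half, voxel_size_um)],
                        indexing="ij")
    r2 = sum(g**2 for g in grids)
    return r2 <= radius_um**2


def rolling_ball_subtract(
    stack: ImageStack4D, radius_um: float = 25.0, allow_leakage: bool = False
) -> ImageStack4D:
    """Subtract the grayscale-opening background (ball structuring element).

    The ball radius must exceed the largest foreground scale so vessels
    are not eaten into the background estimate. Output is clipped at 0.
    """
    _check_role(stack, allow_leakage, "rolling_ball_subtract")
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    # the ball can span >70 voxels laterally; since the background it
    # estimates is smooth at the ball scale, compute the opening on a
    # grid downsampled so the footprint stays small, then upsample
    voxel = np.asarray(stack.voxel_size_um)
    factors = np.maximum(1, np.ceil(2 * radius_um / voxel / 9.0)).astype(int)
    coarse_voxel = voxel * factors
    footprint = _ball_footprint(radius_um, coarse_voxel)
    out = np.empty_like(stack.data, dtype=np.float64)
    for f in range(stack.n_frames):
        vol = stack.data[f].astype(np.float64)
        coarse = ndimage.zoom(vol, 1.0 / factors, order=1)
        bg = ndimage.grey_opening(coarse, footprint=footprint, mode="reflect")
        bg = ndimage.zoom(bg, np.asarray(vol.shape) / np.asarray(bg.shape), order=1)
        bg = np.minimum(bg, vol)  # opening never exceeds the image
        out[f] = vol - bg
    return stack.with_data(out)


def build_flatfield(
    stack: ImageStack4D,
    fwhm_um: float = 20.0,
    pial_mask: np.ndarray | None = None,
) -> FlatfieldReference:
    """Estimate the in-plane illumination field from a structural stack.

    Maximum-intensity projection over z (after zeroing an optional pial
    exclusion mask), smoothed with a wide Gaussian, rescaled to mean 1.
    """
    vol = stack.data[0].astype(np.float64).copy()
    if pial_mask is not None:
        pial_mask = np.asarray(pial_mask, bool)
        if pial_mask.shape != vol.shape:
            raise ValueError("pial_mask shape must match the stack volume")
        vol[pial_mask] = 0.0
    mip = vol.max(axis=0)
    sigma = fwhm_to_sigma_px(fwhm_um, stack.voxel_size_um[1:])
    field = ndimage.gaussian_filter(mip, sigma=sigma, mode="reflect")
    mean = field.mean()
    if mean <= 0:
        raise ValueError("flat-field collapsed to zero; check the input stack")
    field = field / mean
    if np.any(field <= 0):
        raise ValueError("flat-field contains non-positive pixels after rescale")
    return FlatfieldReference(field=field, smoothing_fwhm_um=fwhm_um,
                              pial_exclusion_mask=pial_mask)


def flatfield_normalize(
    stack: ImageStack4D, ref: FlatfieldReference, allow_leakage: bool = False
) -> ImageStack4D:
    """Voxelwise division by the illumination field (broadcast over z)."""
    _check_role(stack, allow_leakage, "flatfield_normalize")
    if ref.field.shape != stack.spatial_shape[1:]:
        raise ValueError(
            f"field shape {ref.field.shape} does not match in-plane shape "
            f"{stack.spatial_shape[1:]}"
        )
    return stack.with_data(stack.data / ref.field[None, None, :, :])


# ----------------------------------------------------------------------
# affine registration
# ----------------------------------------------------------------------

def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equally shaped arrays."""
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def _params_to_matrix(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(tz,ty,tx, rz,ry,rx degrees) -> 3x3 rotation + translation (um).

    Rotations are applied about the volume center in physical (z,y,x)
    coordinates, z rotation being the in-plane one.
    """
    tz, ty, tx, rz, ry, rx = params
    cz, sz = np.cos(np.deg2rad(rz)), np.sin(np.deg2rad(rz))
    cy, sy = np.cos(np.deg2rad(ry)), np.sin(np.deg2rad(ry))
    cx, sx = np.cos(np.deg2rad(rx)), np.sin(np.deg2rad(rx))
    # rotation about z-axis acts on (y, x); about y acts on (z, x); about x on (z, y)
    Rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
    Ry = np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
    Rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx, np.array([tz, ty, tx])


def _resample(moving: np.ndarray, matrix: np.ndarray, shift_um: np.ndarray,
              voxel: np.ndarray, center_um: np.ndarray) -> np.ndarray:
    """Trilinear resampling of ``moving`` under x_mov = R(x_fix - c) + c + t."""
    S = np.diag(voxel)
    Sinv = np.diag(1.0 / voxel)
    M = Sinv @ matrix @ S
    offset = Sinv @ (matrix @ (-center_um) + center_um + shift_um)
    return ndimage.affine_transform(moving, M, offset=offset, order=1, mode="constant")


def register_affine(
    moving_stack: ImageStack4D,
    fixed_stack: ImageStack4D,
    max_rotation_deg: float = 10.0,
    max_shift_um: float = 30.0,
    min_metric: float = 0.1,
) -> tuple[np.ndarray, ImageStack4D]:
    """Rigid-affine registration of ``moving`` onto ``fixed`` by NCC.

    Translation is initialized by FFT phase correlation, then six rigid
    parameters (translation um, rotation deg) are refined with Powell on
    a two-level smoothing pyramid. Returns the 3x4 transform in physical
    um coordinates (fixed -> moving mapping) and the resampled stack.
    """
    from skimage.registration import phase_cross_correlation

    fixed = fixed_stack.data[0].astype(np.float64)
    moving = moving_stack.data[0].astype(np.float64)
    if fixed.shape != moving.shape:
        raise ValueError("registration requires equally shaped volumes")
    voxel = np.asarray(fixed_stack.voxel_size_um, float)
    center = (np.asarray(fixed.shape, float) - 1) / 2.0 * voxel

    shift_px, _, _ = phase_cross_correlation(fixed, moving, upsample_factor=4)
    init = np.zeros(6)
    init[:3] = np.clip(-np.asarray(shift_px) * voxel, -max_shift_um, max_shift_um)

    levels = [(2.0, 2), (0.0, 1)]  # (smoothing sigma px, subsample step)
    params = init
    for sigma, step in levels:
        if sigma > 0:
            f_l = ndimage.gaussian_filter(fixed, sigma)[::1, ::step, ::step]
            m_l = ndimage.gaussian_filter(moving, sigma)
        else:
            f_l, m_l = fixed, moving

        def cost(p):
            R, t = _params_to_matrix(p)
            warped = _resample(m_l, R, t, voxel, center)
            return -ncc(f_l, warped[::1, ::step, ::step])

        # Nelder-Mead with an explicit initial simplex; bounded Powell can
        # walk to the box corners on flat regions of the NCC landscape
        simplex = np.vstack([params] + [
            params + d for d in np.diag([2.0, 2.0, 2.0, 1.0, 1.0, 1.0])
        ])
        res = optimize.minimize(
            cost, params, method="Nelder-Mead",
            options={"initial_simplex": simplex, "xatol": 1e-3, "fatol": 1e-8,
                     "maxiter": 4000},
        )
        if res.fun <= cost(params):
            params = np.clip(res.x, [-max_shift_um] * 3 + [-max_rotation_deg] * 3,
                             [max_shift_um] * 3 + [max_rotation_deg] * 3)

    R, t = _params_to_matrix(params)
    resampled = _resample(moving, R, t, voxel, center)
    final = ncc(fixed, resampled)
    if final < min_metric:
        raise RegistrationError(
            f"registration failed to converge (final NCC={final:.3f})",
            final_metric=final,
        )
    # 3x4 affine in physical coordinates: x_mov = A x_fix + b
    b = R @ (-center) + center + t
    transform = np.hstack([R, b[:, None]])
    return transform, moving_stack.with_data(resampled[np.newaxis])
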
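"""Seeded synthetic vascular phantoms with full ground truth.

Generates voxelized vessel networks (penetrating arteriole/venule trees
plus random capillaries), two-compartment extravasation time-lapses,
RBC line scans, and multi-channel histology images. Every artifact is
accompanied by generator-side truth so downstream stages can be
validated without external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ChannelRole, ImageStack4D, fwhm_to_sigma_px

CAPILLARY_DIAMETER_MAX_UM = 6.0  # segments thinner than this are capillaries

DEFAULT_DIAMETER_BY_ORDER = {0: 10.0, 1: 8.0, 2: 6.5}

#: per-(condition, class) volume transfer constants, min^-1. "SE" elevates
#: arterioles only, "NI" venules only; control leaks are near zero.
DEFAULT_KTRANS = {
    ("Control", "arteriole"): 0.0010,
    ("Control", "capillary"): 0.0010,
    ("Control", "venule"): 0.0010,
    ("SE", "arteriole"): 0.0120,
    ("SE", "capillary"): 0.0010,
    ("SE", "venule"): 0.0010,
    ("NI", "arteriole"): 0.0010,
    ("NI", "capillary"): 0.0010,
    ("NI", "venule"): 0.0120,
}

#: typical RBC velocities per vascular class, mm/s (low, high)
DEFAULT_VELOCITY_MM_S = {
    "arteriole": (4.0, 9.0),
    "capillary": (0.5, 2.0),
    "venule": (2.0, 5.0),
}


class PhantomSizingError(ValueError):
    """Requested vessels do not fit in the requested volume."""


class KineticModelError(ValueError):
    """Kinetic parameters produce unphysical (negative) concentrations."""


class LineScanAliasingError(ValueError):
    """Per-line streak displacement exceeds the spatial window."""


@dataclass
class PhantomSpec:
    """Geometry and acquisition parameters for one phantom volume."""

    volume_shape: tuple[int, int, int] = (40, 128, 128)  # (z, y, x) voxels
    voxel_size_um: tuple[float, float, float] = (2.0, 0.692, 0.692)
    n_penetrating: dict = field(default_factory=lambda: {"arteriole": 1, "venule": 1})
    branch_orders: int = 2
    branches_per_parent: int = 2
    diameter_by_order_um: dict = field(default_factory=lambda: dict(DEFAULT_DIAMETER_BY_ORDER))
    capillary_density: float = 2.0  # segments per 100x100x80 um^3 block
    capillary_diameter_um: tuple[float, float] = (3.0, 5.0)
    frame_interval_s: float = 15.0
    duration_min: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.frame_interval_s <= 0 or self.duration_min <= 0:
            raise ValueError("time fields must be positive")
        if any(d <= 0 for d in self.diameter_by_order_um.values()):
            raise ValueError("diameters must be positive")
        if self.diameter_by_order_um[0] < CAPILLARY_DIAMETER_MAX_UM:
            raise ValueError("0th-order diameters must be >= 6 um")
        lo, hi = self.capillary_diameter_um
        if not (0 < lo <= hi < CAPILLARY_DIAMETER_MAX_UM):
            raise ValueError("capillary diameters must lie in (0, 6) um")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.volume_shape, self.voxel_size_um))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_min * 60.0 / self.frame_interval_s)) + 1

    @property
    def frame_times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s / 60.0


@dataclass
class KineticsSpec:
    """Two-compartment extravasation model and rendering parameters.

    The plasma input is a bi-exponential bolus
    ``C_iv(t) = A_iv * (1 - exp(-t/tau_r)) * exp(-t/tau_d)``; with the
    default slow decay it stays near-constant over 60 min. Perivascular
    concentration per segment obeys
    ``dC_p/dt = Ktrans * C_iv - k_out * C_p``.
    """

    A_iv: float = 100.0
    tau_r_min: float = 0.5
    tau_d_min: float = 600.0
    background: float = 20.0  # tissue baseline offset, keeps F0 > 0
    Ktrans_by_type: dict = field(default_factory=lambda: dict(DEFAULT_KTRANS))
    ktrans_jitter_sd: float = 0.15  # lognormal sd of per-segment multipliers
    k_out_per_min: float = 0.0
    noise_sigma: float = 1.0
    noise_model: str = "gaussian"  # or "poisson"
    psf_fwhm_um: float = 1.0
    vignette_strength: float = 0.0
    halo_decay_um: float = 5.0
    halo_width_um: float = 15.0

    def __post_init__(self) -> None:
        if self.A_iv <= 0 or self.tau_r_min <= 0 or self.tau_d_min <= 0:
            raise KineticModelError("plasma input parameters must be positive")
        if self.k_out_per_min < 0:
            raise KineticModelError("k_out must be >= 0")
        if any((not np.isfinite(v)) or v < 0 for v in self.Ktrans_by_type.values()):
            raise KineticModelError("Ktrans values must be finite and >= 0")
        if not (0 <= self.vignette_strength < 1):
            raise ValueError("vignette_strength must be in [0, 1)")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")


@dataclass
class PhantomTruth:
    """Ground-truth ledger for one generated phantom volume."""

    lumen_mask: np.ndarray          # bool (z,y,x)
    labels: np.ndarray              # int32 (z,y,x), 0 = background
    centerlines: dict               # id -> (n,3) voxel coords along the axis
    segment_table: pd.DataFrame     # id, vessel_class, order, diameter_um, ...
    voxel_size_um: tuple[float, float, float]
    animal_id: str = "phantom0"
    condition: str = "Control"
    C_iv: np.ndarray | None = None  # plasma curve on the frame grid
    C_p: dict | None = None         # id -> perivascular concentration trace

    def save_tables(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.segment_table.to_csv(outdir / "segment_table.csv", index=False)


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------

def _capsule_mask(shape, voxel, p0, p1, radius, out_labels, out_score, seg_id):
    """Paint a capsule (cylinder with hemispherical caps) into the label
    volume. Overlapping voxels go to the segment whose surface is deeper
    (smallest axis distance minus radius); ties keep the earlier id."""
    voxel = np.asarray(voxel)
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    lo = np.maximum(np.floor((np.minimum(p0, p1) - radius) / voxel).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(p0, p1) + radius) / voxel).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *[(np.arange(lo[i], hi[i]) + 0.0) * voxel[i] for i in range(3)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1)
    axis = p1 - p0
    L2 = float(axis @ axis)
    if L2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        tproj = np.clip(((pts - p0) @ axis) / L2, 0.0, 1.0)
        closest = p0 + tproj[..., None] * axis
        dist = np.linalg.norm(pts - closest, axis=-1)
    score = dist - radius
    inside = score <= 0
    sl = tuple(slice(lo[i], hi[i]) for i in range(3))
    sub_lab = out_labels[sl]
    sub_sco = out_score[sl]
    take = inside & (score < sub_sco)
    sub_lab[take] = seg_id
    sub_sco[take] = score[take]


def _centerline_voxels(p0, p1, voxel, shape):
    """Ordered, deduplicated voxel path along a physical segment axis."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = np.linalg.norm(p1 - p0)
    step = min(voxel) * 0.5
    n = max(int(np.ceil(length / step)) + 1, 2)
    ts = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    vox = np.round(pts / np.asarray(voxel)).astype(int)
    vox = np.clip(vox, 0, np.asarray(shape) - 1)
    keep = np.ones(len(vox), bool)
    keep[1:] = np.any(vox[1:] != vox[:-1], axis=1)
    return vox[keep]


def make_vascular_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Build a voxelized tube network and its ground-truth ledger.

    Returns ``(lumen_mask, truth)``. Deterministic for a fixed spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.asarray(spec.volume_shape)
    voxel = np.asarray(spec.voxel_size_um)
    Lz, Ly, Lx = spec.extent_um

    d0 = spec.diameter_by_order_um[0]
    margin = d0 / 2 + 2.0
    if Ly <= 2 * margin or Lx <= 2 * margin:
        raise PhantomSizingError(
            f"volume extent ({Ly:.0f}x{Lx:.0f} um in-plane) too small for "
            f"penetrating vessels of diameter {d0} um"
        )

    segments = []  # dicts: id, class, order, parent, p0, p1, diameter
    next_id = [1]

    def add(cls, order, parent, p0, p1, diameter):
        seg = {
            "id": next_id[0], "vessel_class": cls, "order": order,
            "parent_id": parent, "p0": np.asarray(p0, float),
            "p1": np.asarray(p1, float), "diameter_um": float(diameter),
        }
        segments.append(seg)
        next_id[0] += 1
        return seg

    # penetrating trees: vertical trunks with minimum lateral separation,
    # then branches grown with collision avoidance against the other
    # class (arterioles and venules do not anastomose)
    base_sep = max(2.5 * d0, 20.0)
    wanted = [cls for cls in ("arteriole", "venule")
              for _ in range(int(spec.n_penetrating.get(cls, 0)))]
    placed = None
    for relax in (1.0, 0.8, 0.64, 0.5):
        min_sep = max(base_sep * relax, 1.5 * d0)
        placed_xy, ok = [], True
        for _ in wanted:
            for attempt in range(300):
                y = rng.uniform(margin, Ly - margin)
                x = rng.uniform(margin, Lx - margin)
                if all((y - py) ** 2 + (x - px) ** 2 >= min_sep**2
                       for py, px in placed_xy):
                    placed_xy.append((y, x))
                    break
            else:
                ok = False  # e.g. first trunk central: exclusion disc covers the box
                break
        if ok:
            placed = placed_xy
            break
    if placed is None:
        raise PhantomSizingError(
            "could not place penetrating vessels with required separation; "
            "volume too small"
        )
    trunks = [add(cls, 0, -1, (0.0, y, x), (Lz, y, x), spec.diameter_by_order_um[0])
              for cls, (y, x) in zip(wanted, placed)]
    for trunk in trunks:
        _grow_branches(spec, rng, add, trunk, trunk["vessel_class"], segments)

    # capillaries: random oblique short tubes
    n_cap = int(round(spec.capillary_density * (Lz * Ly * Lx) / (100.0 * 100.0 * 80.0)))
    lo_d, hi_d = spec.capillary_diameter_um
    for _ in range(n_cap):
        d = rng.uniform(lo_d, hi_d)
        p0 = np.array([rng.uniform(0.15, 0.85) * Lz,
                       rng.uniform(margin, Ly - margin),
                       rng.uniform(margin, Lx - margin)])
        direction = rng.normal(size=3)
        direction[0] *= 0.4  # capillaries run mostly in-plane
        direction /= np.linalg.norm(direction)
        length = rng.uniform(20.0, 40.0)
        p1 = np.clip(p0 + direction * length, 1.0, [Lz - 1, Ly - 1, Lx - 1])
        add("capillary", -1, -1, p0, p1, d)

    labels = np.zeros(tuple(shape), np.int32)
    score = np.full(tuple(shape), np.inf, np.float64)
    centerlines = {}
    for seg in segments:
        _capsule_mask(tuple(shape), voxel, seg["p0"], seg["p1"],
                      seg["diameter_um"] / 2.0, labels, score, seg["id"])
        centerlines[seg["id"]] = _centerline_voxels(seg["p0"], seg["p1"], voxel, shape)

    order_col = [s["order"] if s["order"] >= 0 else "capillary" for s in segments]
    table = pd.DataFrame({
        "id": [s["id"] for s in segments],
        "vessel_class": [s["vessel_class"] for s in segments],
        "order": order_col,
        "diameter_um": [s["diameter_um"] for s in segments],
        "length_um": [float(np.linalg.norm(s["p1"] - s["p0"])) for s in segments],
        "parent_id": [s["parent_id"] for s in segments],
    })
    table["true_velocity_mm_s"] = [
        rng.uniform(*DEFAULT_VELOCITY_MM_S[c]) for c in table["vessel_class"]
    ]
    table["true_Ktrans"] = 0.0

    truth = PhantomTruth(
        lumen_mask=labels > 0, labels=labels, centerlines=centerlines,
        segment_table=table, voxel_size_um=tuple(spec.voxel_size_um),
    )
    return truth.lumen_mask, truth


def _segment_clearance_um(p0, p1, other):
    """Minimum distance from the sampled p0-p1 axis to another segment's axis."""
    ts = np.linspace(0.0, 1.0, 12)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    q0, q1 = other["p0"], other["p1"]
    axis = q1 - q0
    L2 = float(axis @ axis)
    if L2 == 0:
        return float(np.min(np.linalg.norm(pts - q0, axis=1)))
    tproj = np.clip(((pts - q0) @ axis) / L2, 0.0, 1.0)
    closest = q0 + tproj[:, None] * axis
    return float(np.min(np.linalg.norm(pts - closest, axis=1)))


def _grow_branches(spec, rng, add, trunk, cls, all_segments):
    Lz, Ly, Lx = spec.extent_um
    parents = [trunk]
    for order in range(1, spec.branch_orders + 1):
        d = spec.diameter_by_order_um.get(order, spec.diameter_by_order_um[max(spec.diameter_by_order_um)])
        children = []
        for parent in parents:
            for _ in range(spec.branches_per_parent):
                for attempt in range(20):
                    frac = rng.uniform(0.25, 0.85)
                    start = parent["p0"] + frac * (parent["p1"] - parent["p0"])
                    azim = rng.uniform(0, 2 * np.pi)
                    polar = rng.uniform(np.deg2rad(55), np.deg2rad(85))  # oblique
                    direction = np.array([np.cos(polar),
                                          np.sin(polar) * np.cos(azim),
                                          np.sin(polar) * np.sin(azim)])
                    length = rng.uniform(15.0, 30.0)
                    end = np.clip(start + direction * length,
                                  1.0, [Lz - 1, Ly - 1, Lx - 1])
                    rivals = [s for s in all_segments
                              if s["vessel_class"] != cls and s["order"] >= 0]
                    if all(_segment_clearance_um(start, end, s)
                           >= (d + s["diameter_um"]) / 2 + 4.0 for s in rivals):
                        children.append(add(cls, order, parent["id"], start, end, d))
                        break
                # all attempts collided: drop this branch rather than fuse trees
        parents = children


# ----------------------------------------------------------------------
# kinetics
# ----------------------------------------------------------------------

def plasma_input(t_min: np.ndarray, kinetics: KineticsSpec) -> np.ndarray:
    """Bi-exponential bolus C_iv(t) = A*(1 - e^(-t/tau_r))*e^(-t/tau_d)."""
    t = np.asarray(t_min, float)
    return kinetics.A_iv * (1.0 - np.exp(-t / kinetics.tau_r_min)) * np.exp(-t / kinetics.tau_d_min)


def perivascular_concentration(
    t_min: np.ndarray, ktrans: float, kinetics: KineticsSpec
) -> np.ndarray:
    """Closed-form solution of dC_p/dt = Ktrans*C_iv - k_out*C_p, C_p(0)=0.

    C_iv is a sum of two exponentials, so the convolution with the
    clearance kernel is analytic; near-degenerate rate pairs fall back
    to the confluent limit t*exp(-k*t).
    """
    t = np.asarray(t_min, float)
    k = kinetics.k_out_per_min
    a1 = 1.0 / kinetics.tau_d_min
    a2 = 1.0 / kinetics.tau_r_min + 1.0 / kinetics.tau_d_min

    def conv(alpha):
        # int_0^t e^(-alpha s) e^(-k (t-s)) ds, written via expm1 so the
        # near-degenerate k ~ alpha case stays numerically stable
        if abs(k - alpha) < 1e-15:
            return t * np.exp(-k * t)
        return np.exp(-k * t) * np.expm1((k - alpha) * t) / (k - alpha)

    cp = ktrans * kinetics.A_iv * (conv(a1) - conv(a2))
    if np.any(cp < -1e-9):
        raise KineticModelError("negative perivascular concentration")
    return np.clip(cp, 0.0, None)


def assign_kinetics(truth: PhantomTruth, condition: str, kinetics: KineticsSpec,
                    seed: int | None = None) -> None:
    """Fill per-segment true Ktrans from the (condition, class) table,
    with optional lognormal per-segment jitter."""
    rng = np.random.default_rng(seed)
    base = np.array([
        kinetics.Ktrans_by_type[(condition, c)]
        for c in truth.segment_table["vessel_class"]
    ])
    if kinetics.ktrans_jitter_sd > 0 and seed is not None:
        base = base * rng.lognormal(0.0, kinetics.ktrans_jitter_sd, size=base.size)
    truth.segment_table["true_Ktrans"] = base
    truth.condition = condition


def vignette_field(shape_yx: tuple[int, int], strength: float) -> np.ndarray:
    """Radially decaying multiplicative illumination field, 1 at center."""
    ny, nx = shape_yx
    y = (np.arange(ny) - (ny - 1) / 2) / max((ny - 1) / 2, 1)
    x = (np.arange(nx) - (nx - 1) / 2) / max((nx - 1) / 2, 1)
    rho2 = (y[:, None] ** 2 + x[None, :] ** 2) / 2.0
    return 1.0 - strength * rho2


def simulate_extravasation(
    truth: PhantomTruth,
    kinetics: KineticsSpec,
    spec: PhantomSpec,
    seed: int = 0,
) -> ImageStack4D:
    """Render a (t,z,y,x) extravasation time-lapse from the truth ledger.

    Intravascular voxels carry the plasma curve; the 0-15 um rind around
    each segment carries its perivascular concentration modulated by a
    radially decaying halo, then PSF blur, vignette, and noise are
    applied. Ground-truth traces are stored back on ``truth``.
    """
    t_min = spec.frame_times_min
    civ = plasma_input(t_min, kinetics)

    ktrans = dict(zip(truth.segment_table["id"], truth.segment_table["true_Ktrans"]))
    cp = {sid: perivascular_concentration(t_min, kt, kinetics) for sid, kt in ktrans.items()}
    truth.C_iv = civ
    truth.C_p = cp

    voxel = truth.voxel_size_um
    lumen = truth.lumen_mask
    dist, (iz, iy, ix) = ndimage.distance_transform_edt(
        ~lumen, sampling=voxel, return_indices=True
    )
    owner = truth.labels[iz, iy, ix]
    halo = (~lumen) & (dist <= kinetics.halo_width_um) & (owner > 0)
    halo_w = np.zeros(lumen.shape, np.float64)
    halo_w[halo] = np.exp(-dist[halo] / kinetics.halo_decay_um)

    max_id = int(truth.labels.max())
    cp_arr = np.zeros((max_id + 1, len(t_min)))
    for sid, trace in cp.items():
        cp_arr[sid] = trace
    halo_owner = owner[halo]

    sigma_px = None
    if kinetics.psf_fwhm_um > 0:
        sigma_px = fwhm_to_sigma_px(kinetics.psf_fwhm_um, voxel)
    vig = vignette_field(lumen.shape[1:], kinetics.vignette_strength) \
        if kinetics.vignette_strength > 0 else None

    rng = np.random.default_rng(seed)
    frames = np.empty((len(t_min),) + lumen.shape, np.float32)
    flat_halo_w = halo_w[halo]
    for f in range(len(t_min)):
        vol = np.full(lumen.shape, kinetics.background, np.float64)
        vol[lumen] += civ[f]
        vol[halo] += cp_arr[halo_owner, f] * flat_halo_w
        if sigma_px is not None:
            vol = ndimage.gaussian_filter(vol, sigma=sigma_px, mode="reflect")
        if vig is not None:
            vol *= vig[None, :, :]
        if kinetics.noise_sigma > 0:
            if kinetics.noise_model == "gaussian":
                vol = vol + rng.normal(0.0, kinetics.noise_sigma, vol.shape)
            else:
                scale = kinetics.noise_sigma**2
                vol = rng.poisson(np.clip(vol, 0, None) / scale) * scale
        frames[f] = vol
    return ImageStack4D(
        data=frames, voxel_size_um=voxel,
        frame_interval_s=spec.frame_interval_s, channel_role=ChannelRole.LEAKAGE,
    )


def simulate_trace_pair(
    ktrans: float, kinetics: KineticsSpec, t_min: np.ndarray, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy (F_iv, F_peri) trace pair for one vessel, without rendering.

    Convenience generator for kinetic ladders (Patlak validation etc.);
    the noiseless traces are the model curves themselves.
    """
    civ = plasma_input(t_min, kinetics)
    cp = perivascular_concentration(t_min, ktrans, kinetics)
    if seed is not None and kinetics.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        civ = civ + rng.normal(0, kinetics.noise_sigma, civ.shape)
        cp = cp + rng.normal(0, kinetics.noise_sigma, cp.shape)
    return civ, cp


# ----------------------------------------------------------------------
# line scans
# ----------------------------------------------------------------------

@dataclass
class LineScan:
    """Space-time image: rows are scan lines (time), columns are space."""

    image: np.ndarray
    dx_um: float = 0.144
    dt_line_s: float = 5e-4

    def __post_init__(self) -> None:
        if self.dx_um <= 0 or self.dt_line_s <= 0:
            raise ValueError("dx and dt must be positive")


def simulate_linescan(
    velocity_mm_s: float,
    dx_um: float = 0.144,
    dt_line_s: float = 5e-4,
    n_lines: int = 200,
    n_space: int = 512,
    cell_frac: float = 0.2,
    cell_sigma_um: float = 2.0,
    depth: float = 0.7,
    noise_sigma: float = 0.02,
    seed: int = 0,
) -> LineScan:
    """Bright plasma with dark RBC streaks of slope ``velocity``.

    Stationary cells yield vertical streaks. Raises
    :class:`LineScanAliasingError` when the per-line displacement
    exceeds half the spatial window.
    """
    if velocity_mm_s < 0:
        raise ValueError("velocity must be >= 0")
    slope = velocity_mm_s * 1000.0 * dt_line_s / dx_um  # px per line
    if slope > n_space / 2:
        raise LineScanAliasingError(
            f"displacement {slope:.1f} px/line exceeds half the spatial window "
            f"({n_space} px); reduce velocity or line period"
        )
    rng = np.random.default_rng(seed)
    w = cell_sigma_um / dx_um
    spacing = max(4.0 * w / max(cell_frac, 1e-3), 6.0 * w)
    img = np.ones((n_lines, n_space))
    rows = np.arange(n_lines)[:, None]
    xs = np.arange(n_space)[None, :]
    x0s = np.arange(-slope * n_lines - 4 * w, n_space + 4 * w, spacing)
    x0s = x0s + rng.uniform(-spacing / 3, spacing / 3, x0s.size)
    for x0 in x0s:
        img -= depth * np.exp(-0.5 * ((xs - (x0 + slope * rows)) / w) ** 2)
    img = np.clip(img, 0.0, None)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return LineScan(image=img, dx_um=dx_um, dt_line_s=dt_line_s)


# ----------------------------------------------------------------------
# histology
# ----------------------------------------------------------------------

def simulate_histology(
    leak_level_by_class: dict,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.18,
    n_vessels: int = 6,
    arterial_frac: float = 0.5,
    ring_width_um: float = 15.0,
    fg: float = 200.0,
    noise_sigma: float = 3.0,
) -> tuple[dict, dict]:
    """Multi-channel 2D histology phantom.

    ``leak_level_by_class`` maps ``{"sma_pos": f, "sma_neg": f}`` to
    target TRITC+ area fractions (in [0,1]) inside the perivascular
    rings of arterial / non-arterial vessels. Returns
    ``(channels, truth)`` where channels holds AQP4 / aSMA / TRITC /
    DAPI float images and truth holds the generator masks.
    """
    for k, v in leak_level_by_class.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"leak level for {k!r} must be in [0,1]")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.indices(shape)
    ring_px = ring_width_um / pixel_size_um

    vessel = np.zeros(shape, bool)
    arterial = np.zeros(shape, bool)
    centers = []
    n_art = int(round(n_vessels * arterial_frac))
    for i in range(n_vessels):
        r = rng.uniform(12, 25)
        placed = False
        for _ in range(300):
            cy = rng.uniform(r + ring_px + 5, ny - r - ring_px - 5)
            cx = rng.uniform(r + ring_px + 5, nx - r - ring_px - 5)
            # vessels must never merge (the class partition is per
            # connected component); a modest extra gap keeps rings clean
            if all((cy - py) ** 2 + (cx - px) ** 2 >= (r + pr + 12) ** 2
                   for py, px, pr in centers):
                placed = True
                break
        if not placed:
            continue  # drop the vessel rather than fuse components
        centers.append((cy, cx, r))
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        vessel |= disk
        if i < n_art:
            arterial |= disk

    dist = ndimage.distance_transform_edt(~vessel, sampling=pixel_size_um)
    ring_all = (~vessel) & (dist <= ring_width_um)
    dist_art = ndimage.distance_transform_edt(~arterial, sampling=pixel_size_um)
    ring_pos = ring_all & (dist_art <= ring_width_um)
    ring_neg = ring_all & ~ring_pos

    tritc_mask = np.zeros(shape, bool)
    for ring, key in ((ring_pos, "sma_pos"), (ring_neg, "sma_neg")):
        frac = float(leak_level_by_class.get(key, 0.0))
        idx = np.flatnonzero(ring.ravel())
        k = int(round(frac * idx.size))
        if k > 0:
            chosen = rng.choice(idx, size=k, replace=False)
            tritc_mask.ravel()[chosen] = True

    def channel(mask, level):
        img = np.where(mask, level, 0.0) + rng.normal(0, noise_sigma, shape)
        return np.clip(img, 0.0, None)

    dapi = np.zeros(shape, bool)
    for _ in range(60):
        cy, cx = rng.uniform(5, ny - 5), rng.uniform(5, nx - 5)
        dapi |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rng.uniform(3, 6) ** 2

    channels = {
        "AQP4": channel(vessel, fg),
        "aSMA": channel(arterial, fg),
        "TRITC": channel(vessel | tritc_mask, fg),  # plasma bright + leaked speckle
        "DAPI": channel(dapi, fg),
    }
    truth = {
        "vessel_mask": vessel, "arterial_mask": arterial,
        "ring_all": ring_all, "ring_sma_pos": ring_pos, "ring_sma_neg": ring_neg,
        "tritc_mask": tritc_mask, "pixel_size_um": pixel_size_um,
    }
    return channels, truth


def simulate_zo1_image(
    intensity_factor: float = 1.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    base_intensity: float = 100.0,
    noise_sigma: float = 2.0,
) -> tuple[dict, dict]:
    """CD31 vessel mask plus a ZO-1 channel scaled by ``intensity_factor``."""
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.indices(shape)
    cd31 = np.zeros(shape, bool)
    for _ in range(5):
        cy, cx = rng.uniform(30, ny - 30), rng.uniform(30, nx - 30)
        cd31 |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rng.uniform(10, 20) ** 2
    zo1 = np.where(cd31, base_intensity * intensity_factor, 0.0)
    zo1 = np.clip(zo1 + rng.normal(0, noise_sigma, shape), 0.0, None)
    return {"CD31": cd31.astype(float) * 200.0, "ZO1": zo1}, {"cd31_mask": cd31}


# ----------------------------------------------------------------------
# virtual cohorts
# ----------------------------------------------------------------------

def simulate_cohort(
    spec: PhantomSpec,
    kinetics: KineticsSpec,
    group_sizes: dict | None = None,
    seed: int = 0,
) -> list[dict]:
    """One phantom volume per virtual animal; default 4/4/3 group sizes.

    Returns a list of ``{"animal_id", "condition", "stack", "truth"}``
    records, each generated from an independent child seed.
    """
    group_sizes = group_sizes or {"Control": 4, "SE": 4, "NI": 3}
    ss = np.random.SeedSequence(seed)
    animals = []
    conditions = [c for c, n in group_sizes.items() for _ in range(n)]
    children = ss.spawn(len(conditions))
    for i, (condition, child) in enumerate(zip(conditions, children)):
        sub = child.generate_state(3)
        aspec = dataclasses.replace(spec, seed=int(sub[0] % (2**31)))
        _, truth = make_vascular_phantom(aspec)
        assign_kinetics(truth, condition, kinetics, seed=int(sub[1] % (2**31)))
        truth.animal_id = f"{condition.lower()}{i}"
        stack = simulate_extravasation(truth, kinetics, aspec, seed=int(sub[2] % (2**31)))
        animals.append({
            "animal_id": truth.animal_id, "condition": condition,
            "stack": stack, "truth": truth,
        })
    return animals
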
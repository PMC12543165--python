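"""Per-vessel perivascular trace extraction and conventional leakage
indices: AUC, late-window fold change, and averaged differential
coefficient."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ImageStack4D

logger = logging.getLogger(__name__)

MIN_ROI_VOXELS = 20
BASELINE_FRAMES = 5


@dataclass
class LeakageTrace:
    """Mean perivascular (F) and intravascular (F_iv) intensity per frame."""

    segment_id: int
    t_min: np.ndarray
    F: np.ndarray
    F_iv: np.ndarray
    n_voxels: int
    F0: float | None = None

    def __post_init__(self) -> None:
        if len(self.F) != len(self.t_min):
            raise ValueError("F and t must have equal length")
        dt = np.diff(self.t_min)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("t must be strictly increasing and uniform")


@dataclass
class LeakageIndices:
    segment_id: int
    auc: float = np.nan          # fold * min
    dff0: float = np.nan         # fold
    dfdt: float = np.nan         # fold / min
    umap_dist: float = np.nan
    ktrans: float = np.nan       # min^-1
    ps: float = np.nan           # min^-1


def extract_traces(
    timelapse: ImageStack4D,
    shell_labels: np.ndarray,
    lumen_labels: np.ndarray,
    min_roi_voxels: int = MIN_ROI_VOXELS,
) -> list[LeakageTrace]:
    """Frame-wise arithmetic means over each perivascular ROI and its
    owner's lumen voxels. ROIs smaller than ``min_roi_voxels`` are
    dropped with a logged warning."""
    if shell_labels.shape != timelapse.spatial_shape:
        raise ValueError("time-lapse / ROI shape mismatch")
    if lumen_labels.shape != timelapse.spatial_shape:
        raise ValueError("time-lapse / lumen-label shape mismatch")

    t_min = timelapse.frame_times_min
    shell_flat = shell_labels.ravel()
    lumen_flat = lumen_labels.ravel()
    n_ids = int(max(shell_flat.max(), lumen_flat.max())) + 1
    shell_counts = np.bincount(shell_flat, minlength=n_ids)
    lumen_counts = np.bincount(lumen_flat, minlength=n_ids)

    nT = timelapse.n_frames
    sums_shell = np.zeros((n_ids, nT))
    sums_lumen = np.zeros((n_ids, nT))
    for f in range(nT):
        frame = timelapse.data[f].ravel().astype(np.float64)
        sums_shell[:, f] = np.bincount(shell_flat, weights=frame, minlength=n_ids)
        sums_lumen[:, f] = np.bincount(lumen_flat, weights=frame, minlength=n_ids)

    traces = []
    for sid in range(1, n_ids):
        n_roi = int(shell_counts[sid])
        if n_roi == 0:
            continue
        if n_roi < min_roi_voxels:
            logger.warning("segment %d dropped: ROI of %d voxels < %d",
                           sid, n_roi, min_roi_voxels)
            continue
        F = sums_shell[sid] / n_roi
        F_iv = (sums_lumen[sid] / lumen_counts[sid]) if lumen_counts[sid] else np.full(nT, np.nan)
        traces.append(LeakageTrace(segment_id=sid, t_min=t_min, F=F, F_iv=F_iv,
                                   n_voxels=n_roi))
    return traces


def normalize_trace(trace: LeakageTrace, baseline_frames: int = BASELINE_FRAMES) -> np.ndarray:
    """Baseline-fold normalization f(t) = F(t)/F0 with F0 the mean of the
    first ``baseline_frames`` frames. Returns None-equivalent exclusion
    by raising for non-positive baselines (callers log and skip)."""
    F0 = float(np.mean(trace.F[:baseline_frames]))
    if F0 <= 0:
        raise ValueError(f"segment {trace.segment_id}: non-positive baseline F0={F0:.3g}")
    trace.F0 = F0
    return trace.F / F0


def index_auc(f: np.ndarray, t_min: np.ndarray) -> float:
    """Trapezoidal integral of the normalized trace, fold*min."""
    if len(f) < 2:
        raise ValueError("AUC needs at least 2 frames")
    return float(np.trapezoid(f, t_min))


def index_dff0(f: np.ndarray, t_min: np.ndarray, window: tuple[float, float] = (50.0, 60.0)) -> float:
    """Mean normalized intensity over the late window (fold change)."""
    lo, hi = window
    sel = (t_min >= lo) & (t_min <= hi)
    if not sel.any():
        raise ValueError(f"no frames in window [{lo}, {hi}] min")
    return float(np.mean(f[sel]))


def index_dfdt(f: np.ndarray, t_min: np.ndarray) -> float:
    """Mean successive finite difference of f, fold/min.

    On a uniform grid this telescopes to (f_N - f_1)/(t_N - t_1); both
    forms are computed and their equality asserted.
    """
    if len(f) < 2:
        raise ValueError("dF/dt needs at least 2 frames")
    diffs = np.diff(f) / np.diff(t_min)
    mean_diff = float(np.mean(diffs))
    telescoped = float((f[-1] - f[0]) / (t_min[-1] - t_min[0]))
    if abs(mean_diff - telescoped) > 1e-9 * max(1.0, abs(telescoped)):
        raise AssertionError("finite-difference mean does not telescope; non-uniform grid?")
    return mean_diff


def compute_indices(
    traces: list[LeakageTrace],
    baseline_frames: int = BASELINE_FRAMES,
    dff0_window: tuple[float, float] = (50.0, 60.0),
) -> tuple[pd.DataFrame, np.ndarray]:
    """All conventional indices for a trace list.

    Returns ``(table, feature_matrix)`` where the matrix rows are the
    normalized traces (vessels x frames) in table order. Traces with
    non-positive baselines are excluded and logged.
    """
    rows, feats = [], []
    for tr in traces:
        try:
            f = normalize_trace(tr, baseline_frames)
        except ValueError as e:
            logger.warning("excluded: %s", e)
            continue
        rows.append({
            "segment_id": tr.segment_id,
            "auc": index_auc(f, tr.t_min),
            "dff0": index_dff0(f, tr.t_min, dff0_window),
            "dfdt": index_dfdt(f, tr.t_min),
            "n_voxels": tr.n_voxels,
            "F0": tr.F0,
        })
        feats.append(f)
    table = pd.DataFrame(rows)
    matrix = np.vstack(feats) if feats else np.empty((0, 0))
    return table, matrix


def traces_to_frame(traces: list[LeakageTrace]) -> pd.DataFrame:
    """Long-format CSV payload (segment_id, t_min, F, F_iv)."""
    parts = []
    for tr in traces:
        parts.append(pd.DataFrame({
            "segment_id": tr.segment_id, "t_min": tr.t_min,
            "F": tr.F, "F_iv": tr.F_iv,
        }))
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["segment_id", "t_min", "F", "F_iv"])
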
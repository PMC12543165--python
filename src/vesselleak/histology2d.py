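"""Ex vivo 2D quantification: local-threshold binarization, disk-kernel
perivascular rings, smooth-muscle vessel partition, TRITC-positive area
ratios, and tight-junction (ZO-1) mean intensity inside endothelial
ROIs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology

DEFAULT_PIXEL_SIZE_UM = 0.18
DEFAULT_SMA_OVERLAP = 0.3


def _drop_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels, _ = ndimage.label(mask)
    sizes = np.bincount(labels.ravel())
    out = sizes[labels] >= min_px
    out[labels == 0] = False
    return out


@dataclass
class HistologyImage:
    channels: dict                      # role -> 2D array
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")


def local_threshold(
    channel: np.ndarray,
    method: str = "sauvola",
    window_um: float = 25.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    invert: bool = False,
    k: float = 0.2,
) -> np.ndarray:
    """Local adaptive binarization (Sauvola or Niblack).

    ``invert=True`` flips the polarity so dark-on-bright objects
    segment symmetrically.
    """
    channel = np.asarray(channel, float)
    if channel.size == 0:
        raise ValueError("empty channel")
    window = int(round(window_um / pixel_size_um))
    window = max(window | 1, 3)  # odd, >= 3 px
    # complement-to-max keeps intensities positive, so dark-on-bright
    # objects segment with the same statistics as bright-on-dark
    img = channel.max() - channel if invert else channel
    if method == "sauvola":
        span = img.max() - img.min()
        if span == 0:
            return np.zeros(img.shape, bool)
        # skimage's default r assumes a unit-range image; use the data range
        thr = filters.threshold_sauvola(img, window_size=window, k=k, r=span / 2)
    elif method == "niblack":
        thr = filters.threshold_niblack(img, window_size=window, k=k)
    else:
        raise ValueError(f"unknown local threshold method {method!r}")
    return img > thr


def perivascular_ring(
    vessel_mask: np.ndarray,
    width_um: float = 15.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> np.ndarray:
    """Disk-kernel dilation of the vessel mask minus the mask itself."""
    vessel_mask = np.asarray(vessel_mask, bool)
    if not vessel_mask.any():
        return np.zeros_like(vessel_mask)
    # EDT band == dilation with a Euclidean disk, but exact in physical units
    dist = ndimage.distance_transform_edt(~vessel_mask, sampling=pixel_size_um)
    return (~vessel_mask) & (dist <= width_um)


def split_by_sma(
    vessel_mask: np.ndarray,
    sma_mask: np.ndarray,
    overlap_threshold: float = DEFAULT_SMA_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition vessel connected components into smooth-muscle-positive
    (arterial) and -negative sets by overlap fraction."""
    vessel_mask = np.asarray(vessel_mask, bool)
    sma_mask = np.asarray(sma_mask, bool)
    if vessel_mask.shape != sma_mask.shape:
        raise ValueError("mask shapes differ")
    labels, n = ndimage.label(vessel_mask)
    pos = np.zeros_like(vessel_mask)
    for i in range(1, n + 1):
        comp = labels == i
        frac = np.count_nonzero(comp & sma_mask) / np.count_nonzero(comp)
        if frac > overlap_threshold:
            pos |= comp
    return pos, vessel_mask & ~pos


def tritc_area_ratio(tritc_mask: np.ndarray, ring_mask: np.ndarray) -> float:
    """Percent of the perivascular ring that is TRITC-positive."""
    ring_mask = np.asarray(ring_mask, bool)
    n_ring = np.count_nonzero(ring_mask)
    if n_ring == 0:
        raise ValueError("empty perivascular ring: ratio undefined")
    n_pos = np.count_nonzero(np.asarray(tritc_mask, bool) & ring_mask)
    return 100.0 * n_pos / n_ring


def zo1_mean_intensity(
    images: list[dict],
    control_group: str = "Control",
) -> pd.DataFrame:
    """Per-image ZO-1 mean inside the CD31 mask, normalized so the
    control-group mean equals 1.

    ``images`` entries need keys ``image_id, group, zo1, cd31_mask``.
    """
    rows = []
    for rec in images:
        mask = np.asarray(rec["cd31_mask"], bool)
        if not mask.any():
            raise ValueError(f"image {rec.get('image_id')}: empty CD31 mask")
        rows.append({
            "image_id": rec["image_id"], "group": rec["group"],
            "zo1_raw": float(np.mean(np.asarray(rec["zo1"], float)[mask])),
        })
    df = pd.DataFrame(rows)
    ctrl = df.loc[df["group"] == control_group, "zo1_raw"]
    if ctrl.empty:
        raise ValueError(f"no images in control group {control_group!r}")
    df["zo1_norm"] = df["zo1_raw"] / ctrl.mean()
    return df


def quantify_extravasation(
    channels: dict,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    ring_width_um: float = 15.0,
    sma_overlap: float = DEFAULT_SMA_OVERLAP,
    threshold_method: str = "sauvola",
    window_um: float = 25.0,
    tritc_threshold: float | None = None,
) -> pd.DataFrame:
    """End-to-end TRITC area-ratio quantification of one image.

    Vessel footprint from the AQP4 channel (used to null intravascular
    pixels), arterial subset from aSMA overlap, TRITC binarized by a
    global threshold on extra-vascular pixels (local threshold would
    erase uniform speckle fields). Returns one row per compartment in
    {all, sma_pos, sma_neg}.
    """
    def binarize(channel):
        local = local_threshold(channel, threshold_method, window_um, pixel_size_um)
        # local thresholds alone promote noise in empty background
        # windows; a global floor keeps only genuinely bright structure
        floor = filters.threshold_otsu(np.asarray(channel, float))
        return _drop_small(local & (channel > floor), 25)

    vessel = binarize(channels["AQP4"])
    sma = binarize(channels["aSMA"])
    sma_pos, sma_neg = split_by_sma(vessel, sma, sma_overlap)

    tritc = np.asarray(channels["TRITC"], float)
    if tritc_threshold is None:
        # leaked tracer carries the same fluorophore as plasma: call a
        # pixel TRITC+ when it exceeds half the intravascular level
        # (Otsu on background-only noise would hallucinate foreground)
        inside = tritc[vessel]
        tritc_threshold = 0.5 * float(np.mean(inside)) if inside.size else np.inf
    tritc_mask = (tritc > tritc_threshold) & ~vessel  # AQP4 nulls intravascular signal

    dist = ndimage.distance_transform_edt(~vessel, sampling=pixel_size_um)
    ring_all = (~vessel) & (dist <= ring_width_um)
    rows = []
    for name, sub in (("all", vessel), ("sma_pos", sma_pos), ("sma_neg", sma_neg)):
        if not sub.any():
            continue
        dist_sub = ndimage.distance_transform_edt(~sub, sampling=pixel_size_um)
        ring = ring_all & (dist_sub <= ring_width_um)
        if name == "sma_neg":
            # exclude pixels nearer an arterial vessel
            dist_pos = ndimage.distance_transform_edt(~sma_pos, sampling=pixel_size_um) \
                if sma_pos.any() else np.full_like(dist_sub, np.inf)
            ring &= dist_sub <= dist_pos
        if not ring.any():
            continue
        rows.append({"compartment": name,
                     "tritc_pct": tritc_area_ratio(tritc_mask, ring),
                     "ring_px": int(np.count_nonzero(ring))})
    return pd.DataFrame(rows)
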
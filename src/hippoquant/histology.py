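"""Staining-intensity and colocalization quantification on ROI-annotated images.

Inputs are multi-channel 2-D intensity images with a label mask of manually
drawn cell ROIs (0 = background, k = cell k).  Measures follow common
confocal-quantification practice:

* per-ROI mean intensity on batch-thresholded images (one common threshold
  per channel across a batch, sub-threshold pixels zeroed);
* perineuronal-ring intensity in the annular "lineal" ROI of fixed physical
  width (default 3.8 µm) around each cell;
* mRNA dot surface density: suprathreshold connected components above a
  minimum area per µm² of ROI, with the suprathreshold area fraction reported
  alongside;
* chance colocalization by re-measuring after mirror-flipping the signal
  channel (ROIs untouched), so that spatially specific enrichment vanishes;
* per-animal cumulative intensity distributions on a common grid, averaged
  across animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "AnnotatedImage",
    "QuantParams",
    "roi_mean_intensity",
    "perimetric_ring",
    "ring_mean_intensity",
    "dot_density",
    "chance_colocalization",
    "cumulative_curves",
]


@dataclass
class AnnotatedImage:
    """Named 2-D intensity channels plus a labeled ROI mask."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    roi_masks: np.ndarray           # int labels, 0 = background
    roi_meta: pd.DataFrame | None = None   # per-roi metadata (animal_id, cell_class)

    def __post_init__(self) -> None:
        self.roi_masks = np.asarray(self.roi_masks)
        if not np.issubdtype(self.roi_masks.dtype, np.integer):
            raise ValueError("roi_masks must be an integer label image")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        for name, ch in self.channels.items():
            ch = np.asarray(ch, dtype=np.float64)
            if ch.shape != self.roi_masks.shape:
                raise ValueError(f"channel {name!r} shape differs from roi mask")
            if np.any(ch < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = ch

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.roi_masks)
        return lab[lab > 0]


@dataclass(frozen=True)
class QuantParams:
    """Batch-level quantification parameters.

    ``intensity_threshold`` is applied identically to every image of a batch
    ("equally thresholded"); ``ring_width_um`` is the perineuronal annulus
    width; ``n_bins`` the grid for cumulative distributions.
    """

    intensity_threshold: float = 0.0
    ring_width_um: float = 3.8
    dot_min_area_um2: float = 0.2
    n_bins: int = 18

    def __post_init__(self) -> None:
        if self.intensity_threshold < 0:
            raise ValueError("intensity_threshold must be >= 0")
        if not self.ring_width_um > 0:
            raise ValueError("ring_width_um must be > 0")


def roi_mean_intensity(img: AnnotatedImage, channel: str,
                       params: QuantParams | None = None,
                       suprathreshold_only: bool = False) -> pd.DataFrame:
    """Per-ROI mean intensity of the batch-thresholded channel.

    Sub-threshold pixels are zeroed before averaging over all ROI pixels
    (the default); ``suprathreshold_only=True`` instead averages over the
    suprathreshold ROI pixels only.  Empty ROIs are flagged and excluded.
    """
    params = params or QuantParams()
    ch = img.channels[channel]
    thresholded = np.where(ch >= params.intensity_threshold, ch, 0.0)
    rows = []
    for lab in img.labels:
        sel = img.roi_masks == lab
        npx = int(np.count_nonzero(sel))
        if npx == 0:
            continue
        vals = thresholded[sel]
        if suprathreshold_only:
            pos = vals[vals > 0]
            mean = float(np.mean(pos)) if pos.size else 0.0
        else:
            mean = float(np.mean(vals))
        rows.append({"roi": int(lab), "mean_intensity": mean, "n_pixels": npx})
    return pd.DataFrame(rows)


def perimetric_ring(roi_masks: np.ndarray, label: int, ring_width_um: float,
                    pixel_size_um: float) -> tuple[np.ndarray, bool]:
    """Annular mask of the given physical width around one cell.

    Ring pixels lie outside the cell with Euclidean distance to the cell
    below ``ring_width_um``.  Returns ``(mask, clipped)`` where ``clipped``
    flags a ring that reaches the image border.
    """
    cell = roi_masks == label
    if not cell.any():
        raise ValueError(f"label {label} not present in roi mask")
    if ring_width_um == 0:
        return np.zeros_like(cell), False
    dist = ndimage.distance_transform_edt(~cell, sampling=pixel_size_um)
    ring = (dist > 0) & (dist < ring_width_um)
    pad = int(np.ceil(ring_width_um / pixel_size_um))
    rr, cc = np.nonzero(cell)
    clipped = (rr.min() < pad or cc.min() < pad
               or rr.max() >= cell.shape[0] - pad or cc.max() >= cell.shape[1] - pad)
    return ring, bool(clipped)


def ring_mean_intensity(img: AnnotatedImage, channel: str,
                        params: QuantParams | None = None) -> pd.DataFrame:
    """Mean thresholded intensity in the perineuronal ring of every ROI."""
    params = params or QuantParams()
    ch = img.channels[channel]
    thresholded = np.where(ch >= params.intensity_threshold, ch, 0.0)
    rows = []
    for lab in img.labels:
        ring, clipped = perimetric_ring(img.roi_masks, int(lab),
                                        params.ring_width_um, img.pixel_size_um)
        npx = int(np.count_nonzero(ring))
        if npx == 0:
            continue
        rows.append({"roi": int(lab),
                     "ring_mean_intensity": float(np.mean(thresholded[ring])),
                     "n_pixels": npx, "clipped": clipped})
    return pd.DataFrame(rows)


def dot_density(img: AnnotatedImage, channel: str, roi_mask: np.ndarray,
                params: QuantParams | None = None,
                _channel_override: np.ndarray | None = None) -> dict:
    """Dot surface density inside one ROI mask.

    The channel is binarized at the batch threshold; connected components
    restricted to the ROI with area >= ``dot_min_area_um2`` count as dots.
    Returns dots per µm² of ROI and the suprathreshold area fraction.
    """
    params = params or QuantParams()
    ch = img.channels[channel] if _channel_override is None else _channel_override
    roi = np.asarray(roi_mask, dtype=bool)
    area_px = int(np.count_nonzero(roi))
    if area_px == 0:
        raise ValueError("ROI area is zero")
    px_area = img.pixel_size_um ** 2
    binary = (ch >= params.intensity_threshold) & roi
    lab, n = ndimage.label(binary)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        count = int(np.count_nonzero(sizes * px_area >= params.dot_min_area_um2))
    else:
        count = 0
    roi_area_um2 = area_px * px_area
    return {
        "n_dots": count,
        "density_per_um2": count / roi_area_um2,
        "area_fraction": float(np.count_nonzero(binary)) / area_px,
        "roi_area_um2": roi_area_um2,
    }


def chance_colocalization(img: AnnotatedImage, signal_channel: str,
                          roi_mask: np.ndarray, params: QuantParams | None = None,
                          mode: str = "flip") -> dict:
    """Observed vs chance dot density for one ROI.

    Chance is the same measurement after mirror-flipping the signal channel
    left-right (``mode="flip"``) or rotating it 180° (``mode="rot180"``),
    leaving the ROI mask untouched.
    """
    params = params or QuantParams()
    observed = dot_density(img, signal_channel, roi_mask, params)
    ch = img.channels[signal_channel]
    if mode == "flip":
        moved = np.fliplr(ch)
    elif mode == "rot180":
        moved = ch[::-1, ::-1]
    else:
        raise ValueError("mode must be 'flip' or 'rot180'")
    chance = dot_density(img, signal_channel, roi_mask, params,
                         _channel_override=moved)
    return {"observed": observed, "chance": chance}


def cumulative_curves(values_by_animal: dict, n_bins: int = 18) -> dict:
    """Per-animal cumulative distributions on a common grid, and their mean.

    Bin edges span the pooled range of all animals' per-cell values split
    into ``n_bins`` equal-width bins; each animal contributes the fraction of
    its cells at or below each edge; the across-animal mean ± sem curve is
    returned alongside.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_animal.items()
              if len(np.atleast_1d(v))}
    if not groups:
        raise ValueError("need at least one animal with at least one cell")
    pooled = np.concatenate(list(groups.values()))
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:  # degenerate: all values identical
        edges = np.linspace(lo - 0.5, hi + 0.5, n_bins + 1)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    curves = {k: np.array([np.mean(v <= e) for e in edges]) for k, v in groups.items()}
    stack = np.vstack(list(curves.values()))
    n = stack.shape[0]
    return {
        "edges": edges,
        "per_animal": curves,
        "mean": stack.mean(axis=0),
        "sem": stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(edges.size),
        "n_animals": n,
    }
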
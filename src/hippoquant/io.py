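"""File round-trips for the package's standard containers.

Signals live in HDF5 (dataset ``values`` with ``rate_hz``/``t0_s``/``units``
attributes), event tables and interval sets in CSV, configs in YAML, and
annotated images in TIFF (one file per channel stack plus a label TIFF).
"""

from __future__ import annotations

import h5py
import numpy as np
import tifffile
import yaml

from .core import UniformSignal
from .histology import AnnotatedImage

__all__ = ["save_signal", "load_signal", "load_yaml", "save_yaml",
           "save_annotated_image", "load_annotated_image"]


def save_signal(path, signal: UniformSignal, dataset: str = "values") -> None:
    with h5py.File(path, "a") as f:
        if dataset in f:
            del f[dataset]
        ds = f.create_dataset(dataset, data=signal.values)
        ds.attrs["rate_hz"] = signal.rate_hz
        ds.attrs["t0_s"] = signal.t0_s
        ds.attrs["units"] = signal.units


def load_signal(path, dataset: str = "values") -> UniformSignal:
    with h5py.File(path, "r") as f:
        ds = f[dataset]
        return UniformSignal(
            np.asarray(ds[...], dtype=np.float64),
            rate_hz=float(ds.attrs["rate_hz"]),
            t0_s=float(ds.attrs.get("t0_s", 0.0)),
            units=str(ds.attrs.get("units", "a.u.")),
        )


def load_yaml(path) -> dict:
    with open(path) as f:
        out = yaml.safe_load(f)
    return {} if out is None else out


def save_yaml(path, obj: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)


def save_annotated_image(channel_path, mask_path, img: AnnotatedImage) -> None:
    """Channels as one multi-channel TIFF stack, ROI labels as a label TIFF.

    Channel names and the pixel size ride along as TIFF metadata.
    """
    names = sorted(img.channels)
    stack = np.stack([img.channels[k] for k in names]).astype(np.float32)
    tifffile.imwrite(channel_path, stack, photometric="minisblack",
                     metadata={"channel_names": names,
                               "pixel_size_um": img.pixel_size_um})
    tifffile.imwrite(mask_path, img.roi_masks.astype(np.int32))


def load_annotated_image(channel_path, mask_path) -> AnnotatedImage:
    with tifffile.TiffFile(channel_path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    names = list(meta.get("channel_names", range(stack.shape[0])))
    channels = {str(k): np.asarray(stack[i], dtype=np.float64)
                for i, k in enumerate(names)}
    mask = tifffile.imread(mask_path)
    return AnnotatedImage(channels=channels,
                          pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
                          roi_masks=np.asarray(mask, dtype=np.int32))
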
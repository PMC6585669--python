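"""Serialization: label images, field maps, signals and histograms.

Label maps travel either as grayscale TIFF/PNG rasters with an explicit
value-to-compartment mapping, or as lossless ``.npz`` array dumps carrying
the grid metadata.  Signals and histograms are written as CSV with a
``#``-prefixed metadata header block.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .field import FieldMap, FrequencyHistogram
from .geometry import EXTRA, INTRA, MYELIN, LabelMap
from .grids import GridSpec
from .signal import SignalSeries

__all__ = [
    "save_label_image",
    "load_label_image",
    "save_label_npz",
    "load_label_npz",
    "save_field",
    "load_field",
    "signal_to_csv",
    "signal_from_csv",
    "histogram_to_csv",
]

_NAME_OF = {EXTRA: "extra", INTRA: "intra", MYELIN: "myelin"}
_DEFAULT_EXPORT = {"extra": 0, "intra": 128, "myelin": 255}


def save_label_image(lmap: LabelMap, path, value_of: dict | None = None) -> None:
    """Write a grayscale raster (TIFF or PNG by extension)."""
    value_of = value_of or _DEFAULT_EXPORT
    img = np.zeros(lmap.grid.shape, dtype=np.uint8)
    for lab, name in _NAME_OF.items():
        img[lmap.labels == lab] = value_of[name]
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img)


def load_label_image(path, label_mapping: dict, pixel_size: float) -> LabelMap:
    """Load a segmented raster image into a label map.

    ``label_mapping`` maps raster values to compartment names ("extra",
    "intra", "myelin").  Values present in the image but absent from the
    mapping raise an error naming them.  Non-square images are accepted and
    recorded on a rectangular grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    present = np.unique(img)
    unmapped = [int(v) for v in present if int(v) not in label_mapping]
    if unmapped:
        raise ValueError(f"image contains unmapped values {unmapped}")
    lab_of = {"extra": EXTRA, "intra": INTRA, "myelin": MYELIN}
    labels = np.zeros(img.shape, dtype=np.uint8)
    for value, name in label_mapping.items():
        labels[img == value] = lab_of[name]
    ny, nx = img.shape
    grid = GridSpec(nx, nx * pixel_size, ny=ny)
    return LabelMap(grid, labels)


def save_label_npz(lmap: LabelMap, path) -> None:
    np.savez_compressed(path, labels=lmap.labels, n=lmap.grid.n,
                        ny=lmap.grid.ny, extent=lmap.grid.extent)


def load_label_npz(path) -> LabelMap:
    with np.load(path) as z:
        grid = GridSpec(int(z["n"]), float(z["extent"]), int(z["ny"]))
        return LabelMap(grid, z["labels"])


def save_field(fmap: FieldMap, path) -> None:
    """Lossless array dump; use a `.tif` extension for a float TIFF preview."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, fmap.delta_f.astype(np.float32))
    else:
        np.savez_compressed(path, delta_f=fmap.delta_f, n=fmap.grid.n,
                            ny=fmap.grid.ny, extent=fmap.grid.extent)


def load_field(path) -> FieldMap:
    with np.load(path) as z:
        grid = GridSpec(int(z["n"]), float(z["extent"]), int(z["ny"]))
        return FieldMap(grid, z["delta_f"])


def signal_to_csv(sig: SignalSeries, path, metadata: dict | None = None) -> None:
    """CSV rows (time_ms, magnitude, phase_rad, real, imag) + '#' header."""
    df = pd.DataFrame(
        {
            "time_ms": sig.times,
            "magnitude": sig.magnitude,
            "phase_rad": sig.phase_unwrapped,
            "real": sig.complex_signal.real,
            "imag": sig.complex_signal.imag,
        }
    )
    with open(path, "w") as fh:
        if metadata:
            fh.write("# " + json.dumps(metadata, default=str) + "\n")
        df.to_csv(fh, index=False)


def signal_from_csv(path) -> SignalSeries:
    df = pd.read_csv(path, comment="#")
    return SignalSeries(
        times=df["time_ms"].to_numpy(),
        complex_signal=df["real"].to_numpy() + 1j * df["imag"].to_numpy(),
        magnitude=df["magnitude"].to_numpy(),
        phase_unwrapped=df["phase_rad"].to_numpy(),
    )


def histogram_to_csv(hist: FrequencyHistogram, path, metadata: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "bin_center_hz": hist.bin_centers,
            "count_intra": hist.counts["intra"],
            "count_extra": hist.counts["extra"],
            "count_myelin": hist.counts["myelin"],
            "count_total": hist.counts["total"],
        }
    )
    with open(path, "w") as fh:
        if metadata:
            fh.write("# " + json.dumps(metadata, default=str) + "\n")
        df.to_csv(fh, index=False)
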
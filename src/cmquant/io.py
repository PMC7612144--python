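"""Reading and writing of the pipeline's file formats.

Channels are grayscale 8/16-bit TIFF (or an RGB composite whose planes map
to channels); ROIs are label-image TIFF (0 = outside); traces and tables
travel as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .coloc import CellROI, ChannelImage
from .kinetics import Trace

# composite plane convention: red = VASH2/MAP4 (punctate), green = TUBULIN
RGB_PLANES = {"VASH2": 0, "TUBULIN": 1, "MAP4": 0}


def read_channel(path: str | Path, channel_label: str,
                 pixel_size: float = 20.0) -> ChannelImage:
    """Read a grayscale TIFF (or one plane of an RGB composite)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        arr = arr[..., RGB_PLANES[channel_label]]
    bit_depth = 8 if arr.dtype == np.uint8 else 16
    return ChannelImage(arr, bit_depth=bit_depth, channel_label=channel_label,
                        pixel_size=pixel_size)


def write_channel(path: str | Path, channel: ChannelImage) -> None:
    dtype = np.uint8 if channel.bit_depth == 8 else np.uint16
    tifffile.imwrite(str(path), channel.pixels.astype(dtype))


def read_roi(path: str | Path, pixel_size: float = 20.0,
             label: int | None = None) -> CellROI:
    """Label-image TIFF: nonzero (or a specific label) is inside the cell."""
    arr = tifffile.imread(str(path))
    mask = (arr == label) if label is not None else (arr > 0)
    return CellROI(mask, pixel_size=pixel_size)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_trace_csv(path: str | Path, stim_freq: float = 2.0):
    """Trace CSV: columns ``time_s,value`` (sarcomere) or
    ``time_s,f360,f380`` (calcium two-channel). Returns one Trace or a
    (f360, f380) pair."""
    df = pd.read_csv(path)
    if {"time_s", "f360", "f380"} <= set(df.columns):
        t = df["time_s"].to_numpy()
        return (Trace(t, df["f360"].to_numpy(), stim_freq, "fluorescence"),
                Trace(t, df["f380"].to_numpy(), stim_freq, "fluorescence"))
    if {"time_s", "value"} <= set(df.columns):
        return Trace(df["time_s"].to_numpy(), df["value"].to_numpy(),
                     stim_freq, "sarcomere")
    raise ValueError(f"{path}: expected columns time_s,value or "
                     "time_s,f360,f380")


def write_trace_csv(path: str | Path, *traces: Trace,
                    names: tuple[str, ...] = ("value",)) -> None:
    data = {"time_s": traces[0].time}
    for name, tr in zip(names, traces):
        data[name] = tr.value
    pd.DataFrame(data).to_csv(path, index=False)
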
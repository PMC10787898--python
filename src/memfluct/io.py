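"""File I/O: TIFF stacks, CSV traces/tables, ground-truth sidecars."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import HeightMovie, TrapTrace

__all__ = ["write_intensity_tiff", "write_height_tiff", "read_tiff",
           "read_height_tiff", "write_trace_csv", "read_trace_csv",
           "write_linescan_csv", "read_linescan_csv",
           "write_area_csv", "read_area_csv", "write_fbr_csv"]


def write_intensity_tiff(path, movie: np.ndarray) -> None:
    """16-bit intensity stack (values clipped to the uint16 range)."""
    arr = np.clip(np.round(movie), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)


def write_height_tiff(path, movie: HeightMovie) -> None:
    """32-bit float height stack with pixel size and frame interval stored
    in the ImageJ-style metadata."""
    tifffile.imwrite(path, movie.h.astype(np.float32), metadata={
        "pixel_size_nm": movie.pixel_size_nm,
        "frame_interval_s": movie.frame_interval_s})


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def read_height_tiff(path, pixel_size_nm: float | None = None,
                     frame_interval_s: float | None = None) -> HeightMovie:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return HeightMovie(
        h=np.asarray(arr, dtype=float),
        pixel_size_nm=pixel_size_nm or float(meta.get("pixel_size_nm", 72.2)),
        frame_interval_s=frame_interval_s
        or float(meta.get("frame_interval_s", 0.05)))


def write_trace_csv(path, trace: TrapTrace) -> None:
    t = np.arange(trace.x.size) / trace.sample_rate
    pd.DataFrame({"time_s": t, "x_m": trace.x}).to_csv(path, index=False)


def read_trace_csv(path, temperature: float = 300.0,
                   units: str = "m") -> TrapTrace:
    df = pd.read_csv(path)
    x = df["x_m"].to_numpy() if "x_m" in df else \
        df["x_nm"].to_numpy() * 1e-9
    if units == "nm" and "x_m" not in df.columns and "x_nm" not in df.columns:
        raise ValueError("expected x_m or x_nm column")
    dt = float(np.median(np.diff(df["time_s"].to_numpy())))
    return TrapTrace(x=x, sample_rate=1.0 / dt, temperature=temperature)


def write_linescan_csv(path, position_um, intensity) -> None:
    pd.DataFrame({"position_um": position_um,
                  "intensity": intensity}).to_csv(path, index=False)


def read_linescan_csv(path):
    df = pd.read_csv(path)
    return df["position_um"].to_numpy(), df["intensity"].to_numpy()


def write_area_csv(path, time_min, area_um2, cell_id: str = "",
                   treatment: str = "") -> None:
    pd.DataFrame({"time_min": time_min, "area_um2": area_um2,
                  "cell_id": cell_id, "treatment": treatment}
                 ).to_csv(path, index=False)


def read_area_csv(path):
    return pd.read_csv(path)


def write_fbr_csv(path, fbrs) -> None:
    rows = [{"origin_row": f.origin[0], "origin_col": f.origin[1],
             "side_pixels": f.side_pixels, "area_um2": f.area_um2}
            for f in fbrs]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
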
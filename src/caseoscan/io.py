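"""CSV / image readers and writers for the pipeline's external formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .imaging import SliceImage
from .relaxometry import CpmgDecay
from .stats import GroupSummary, PeakRecord
from .texture import PenetrationCurve

__all__ = [
    "load_slice_image",
    "read_decay_csv",
    "write_decay_csv",
    "read_curve_csv",
    "read_summaries_csv",
    "read_peaks_csv",
]


def load_slice_image(path: str | Path, resolution: float = 236.0) -> SliceImage:
    """Read a TIFF/PNG scan as grayscale intensities in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    return SliceImage(pixels=arr, resolution=resolution)


def read_decay_csv(path: str | Path, tau_us: float = 80.0) -> CpmgDecay:
    """Two-column CSV: time_ms, amplitude."""
    df = pd.read_csv(path)
    return CpmgDecay(
        echo_times=df["time_ms"].to_numpy(),
        amplitudes=df["amplitude"].to_numpy(),
        tau_us=tau_us,
    )


def write_decay_csv(decay: CpmgDecay, path: str | Path) -> None:
    pd.DataFrame({"time_ms": decay.echo_times, "amplitude": decay.amplitudes}).to_csv(
        path, index=False
    )


def read_curve_csv(
    path: str | Path, h0_mm: float, probe_diameter_mm: float = 3.0
) -> PenetrationCurve:
    """CSV with displacement_mm, force_N columns."""
    df = pd.read_csv(path)
    return PenetrationCurve(
        displacement_mm=df["displacement_mm"].to_numpy(),
        force_N=df["force_N"].to_numpy(),
        h0_mm=h0_mm,
        probe_diameter_mm=probe_diameter_mm,
    )


def read_summaries_csv(path: str | Path) -> pd.DataFrame:
    """Long-format group summaries: variable, group, n, mean, sd."""
    df = pd.read_csv(path)
    required = {"variable", "group", "n", "mean", "sd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summaries CSV missing columns: {sorted(missing)}")
    return df


def summaries_to_groups(df: pd.DataFrame) -> dict[tuple[str, str], GroupSummary]:
    return {
        (r.variable, r.group): GroupSummary(
            label=r.group, n=int(r.n), mean=float(r.mean), sd=float(r.sd), variable=r.variable
        )
        for r in df.itertuples()
    }


def read_peaks_csv(path: str | Path) -> list[PeakRecord]:
    """Peak table CSV: peak_id, raw_area, migration_time."""
    df = pd.read_csv(path)
    return [
        PeakRecord(peak_id=str(r.peak_id), raw_area=float(r.raw_area), migration_time=float(r.migration_time))
        for r in df.itertuples()
    ]
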
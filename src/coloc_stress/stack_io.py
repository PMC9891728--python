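"""Image-stack containers, TIFF I/O and result tables.

Axis convention (documented once, used everywhere): arrays are stored in
page order ``(z, y, x)`` exactly as multi-page TIFFs lay them out, while
physical quantities (voxel sizes, displacements, shifts) are expressed as
``(x, y, z)`` triples in nanometres.  Coordinates are voxel-centred and
0-based; the physical position of index ``i`` along an axis is
``i * voxel_size`` for that axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile


@dataclass
class ChannelStack:
    """One channel's 3-D intensity grid with physical voxel dimensions.

    Parameters
    ----------
    data : ndarray, shape (z, y, x)
        Non-negative intensities (float after background subtraction may
        go negative; the invariant applies to raw data).
    voxel_size : (float, float, float)
        Physical voxel size in nm, ordered (x, y, z).
    label : str
        Channel name, e.g. ``"JPh44"`` or ``"RyR1"``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:  # single x-y image: depth-1 stack
            self.data = self.data[None, :, :]
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("stack must be a non-empty 3-D (z, y, x) array")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive nm values (x, y, z)")
        self.voxel_size = vs

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz * 1e-9  # nm^3 -> um^3

    def astype(self, dtype) -> "ChannelStack":
        return ChannelStack(self.data.astype(dtype), self.voxel_size, self.label)


@dataclass
class Manifest:
    """Batch description: one entry per cell with channel file paths."""

    entries: list[dict] = field(default_factory=list)

    def add(self, subject_id: str, cell_id: str, channels: dict[str, str],
            mask_path: str | None = None) -> None:
        if len(set(channels)) != len(channels):
            raise ValueError("channel roles must be unique per cell")
        self.entries.append({
            "subject_id": subject_id,
            "cell_id": cell_id,
            "channels": dict(channels),
            "mask_path": mask_path,
        })

    def validate(self) -> None:
        for e in self.entries:
            for role, p in e["channels"].items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"{e['cell_id']}: channel {role!r} file missing: {p}")


def read_stack(path: str | Path, voxel_size: Sequence[float]) -> ChannelStack:
    """Read a multi-page grayscale TIFF as a :class:`ChannelStack`.

    Page order is preserved as z; dtype is widened to float64 without any
    rescaling, so 8-bit and 16-bit encodings of the same scene yield
    identical correlation statistics downstream.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if any(page.samplesperpixel != 1 for page in tif.pages):
            raise ValueError(f"{path.name}: RGB/multi-sample TIFFs are not supported; "
                             "provide one grayscale file per channel")
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: expected grayscale pages, got shape {arr.shape}")
    if voxel_size is None:
        raise ValueError(f"{path.name}: voxel size required (no metadata parsing)")
    return ChannelStack(arr.astype(np.float64), tuple(voxel_size), label=path.stem)


def write_stack(stack: ChannelStack, path: str | Path) -> Path:
    """Write a stack as multi-page grayscale 16-bit TIFF (z as pages).

    Intensities are rounded and clipped to the uint16 range; synthetic
    photon-count data round-trip exactly.
    """
    path = Path(path)
    data = np.clip(np.rint(stack.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean/label volume as an 8-bit TIFF (nonzero = analyze)."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255,
                     photometric="minisblack")
    return path


def read_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr > 0


def write_table(records: list[dict], path: str | Path,
                summary_rows: list[dict] | None = None) -> Path:
    """Write per-cell records as CSV plus a full-precision JSON twin.

    The CSV mirrors the layout of the study's colocalization tables: one
    row per cell, then optional group-summary rows (averages, medians,
    SEM with N subjects and n cells counted separately).
    """
    path = Path(path)
    df = pd.DataFrame.from_records(records)
    if summary_rows:
        df = pd.concat([df, pd.DataFrame.from_records(summary_rows)], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.12g")
    twin = path.with_suffix(".json")
    with open(twin, "w") as fh:
        json.dump({"records": records, "summary": summary_rows or []}, fh,
                  indent=1, default=_jsonify)
    return path


def _jsonify(o):
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
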
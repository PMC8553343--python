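"""Two-channel specimen quantification.

Resected specimens are imaged in two 8-bit channels: a green nitroreductase
channel (the probe's enzymatically activated emission) and a red viscosity
channel (its rotor emission).  The screening statistic per specimen is the
maximal gray-scale intensity in each channel, so this module does three
things: find specimen regions, read each region's per-channel maximum, and
(for cell-level validation) compute pixelwise Pearson colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage import measure

__all__ = [
    "ChannelImage", "SampleRegion", "SampleRecord",
    "segment_samples", "measure_sample", "pearson_colocalization",
    "read_channel_tiff", "write_channel_tiff",
    "records_to_frame", "frame_to_records", "write_records_csv", "read_records_csv",
]

ChannelName = Literal["ntr", "vis"]


@dataclass(frozen=True)
class ChannelImage:
    """One 8-bit grayscale channel of a specimen image."""

    pixels: np.ndarray  # uint8, shape (height, width)
    channel: ChannelName

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if arr.dtype != np.uint8:
            if np.any((arr < 0) | (arr > 255)):
                raise ValueError("pixel values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        object.__setattr__(self, "pixels", arr)
        if self.channel not in ("ntr", "vis"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class SampleRegion:
    """A connected specimen footprint in the image plane."""

    region_id: int
    pixel_set: frozenset[tuple[int, int]]
    area: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)

    def __post_init__(self) -> None:
        if self.area != len(self.pixel_set):
            raise ValueError("area must equal the number of region pixels")
        if self.area == 0:
            raise ValueError("region must contain at least one pixel")

    def rows_cols(self) -> tuple[np.ndarray, np.ndarray]:
        coords = np.array(sorted(self.pixel_set), dtype=int)
        return coords[:, 0], coords[:, 1]


@dataclass
class SampleRecord:
    """One specimen's per-channel maxima with optional label and triage call."""

    sample_id: str
    i_ntr: int
    i_vis: int
    he_label: Optional[str] = None  # "P" or "N"
    call: Optional[str] = None      # "++", "+" or "-"

    def __post_init__(self) -> None:
        for name in ("i_ntr", "i_vis"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name}={v} outside the 8-bit gray scale")
        if self.he_label is not None and self.he_label not in ("P", "N"):
            raise ValueError(f"he_label must be 'P' or 'N', got {self.he_label!r}")
        if self.call is not None and self.call not in ("++", "+", "-"):
            raise ValueError(f"call must be '++', '+' or '-', got {self.call!r}")


def segment_samples(
    ntr: ChannelImage,
    vis: ChannelImage,
    bg_threshold: int = 30,
    min_area: int = 50,
    connectivity: int = 2,
) -> list[SampleRegion]:
    """Find specimen regions as connected bright components.

    A pixel is foreground when its maximum over the two channels exceeds
    ``bg_threshold``, so a specimen bright in only one channel (a "+"
    candidate) is still detected.  Components are labelled under
    8-connectivity by default (``connectivity=2`` in scikit-image terms,
    ``1`` for 4-connectivity), components smaller than ``min_area`` pixels
    are dropped as debris, and survivors are ordered by the (min_row,
    min_col) of their bounding box and numbered from 1.
    """
    if ntr.pixels.shape != vis.pixels.shape:
        raise ValueError("channel images must have identical shapes")
    if not (0 <= bg_threshold <= 255):
        raise ValueError("bg_threshold must lie in [0, 255]")
    fg = np.maximum(ntr.pixels, vis.pixels) > bg_threshold
    labels = measure.label(fg, connectivity=connectivity)
    regions = []
    for prop in measure.regionprops(labels):
        if prop.area < min_area:
            continue
        coords = frozenset((int(r), int(c)) for r, c in prop.coords)
        regions.append((tuple(prop.bbox[:2]), coords, int(prop.area), tuple(int(b) for b in prop.bbox)))
    regions.sort(key=lambda t: t[0])
    return [
        SampleRegion(region_id=i + 1, pixel_set=coords, area=area, bbox=bbox)
        for i, (_, coords, area, bbox) in enumerate(regions)
    ]


def measure_sample(
    region: SampleRegion,
    ntr: ChannelImage,
    vis: ChannelImage,
    sample_id: Optional[str] = None,
) -> SampleRecord:
    """Record the region's maximal gray-scale intensity in each channel."""
    if region.area == 0:
        raise ValueError("empty region")
    rows, cols = region.rows_cols()
    h, w = ntr.pixels.shape
    if rows.max() >= h or cols.max() >= w or rows.min() < 0 or cols.min() < 0:
        raise ValueError("region pixels fall outside the image bounds")
    return SampleRecord(
        sample_id=sample_id if sample_id is not None else str(region.region_id),
        i_ntr=int(ntr.pixels[rows, cols].max()),
        i_vis=int(vis.pixels[rows, cols].max()),
    )


def pearson_colocalization(
    a: ChannelImage,
    b: ChannelImage,
    mask: Optional[Iterable[tuple[int, int]]] = None,
) -> float:
    """Pixelwise Pearson correlation of two channels over an optional mask.

    This is the standard colocalization coefficient: values near 1 indicate
    the two emissions occupy the same pixels (e.g. the rotor's red channel
    against a mitochondrial counterstain).
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("channel images must have identical shapes")
    if mask is None:
        xa = a.pixels.ravel().astype(float)
        xb = b.pixels.ravel().astype(float)
    else:
        coords = np.array(sorted(set((int(r), int(c)) for r, c in mask)), dtype=int)
        if coords.size == 0:
            raise ValueError("mask selects no pixels")
        xa = a.pixels[coords[:, 0], coords[:, 1]].astype(float)
        xb = b.pixels[coords[:, 0], coords[:, 1]].astype(float)
    if xa.size < 2:
        raise ValueError("need at least 2 pixels")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValueError("degenerate input: constant channel over the mask")
    return float(np.corrcoef(xa, xb)[0, 1])


# ---------------------------------------------------------------------------
# I/O helpers

def read_channel_tiff(path: str | Path, channel: ChannelName) -> ChannelImage:
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:  # accept RGB/multipage by taking the first plane
        arr = arr[0] if arr.shape[0] in (1,) else arr[..., 0]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return ChannelImage(pixels=arr, channel=channel)


def write_channel_tiff(img: ChannelImage, path: str | Path) -> None:
    tifffile.imwrite(str(path), img.pixels)


_COLUMNS = ["sample_id", "i_ntr", "i_vis", "he_label", "call"]


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    rows = [
        {"sample_id": r.sample_id, "i_ntr": r.i_ntr, "i_vis": r.i_vis,
         "he_label": r.he_label, "call": r.call}
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    # drop the optional columns when uniformly absent
    for col in ("he_label", "call"):
        if df.empty or df[col].isna().all():
            df = df.drop(columns=[col])
    return df


def frame_to_records(df: pd.DataFrame) -> list[SampleRecord]:
    records = []
    for _, row in df.iterrows():
        he = row.get("he_label")
        call = row.get("call")
        records.append(SampleRecord(
            sample_id=str(row["sample_id"]),
            i_ntr=int(row["i_ntr"]),
            i_vis=int(row["i_vis"]),
            he_label=None if pd.isna(he) else str(he),
            call=None if call is None or pd.isna(call) else str(call),
        ))
    return records


def write_records_csv(records: Sequence[SampleRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[SampleRecord]:
    return frame_to_records(pd.read_csv(path))
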
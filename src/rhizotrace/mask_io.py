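"""Frame loading, thresholding, and binary-mask cleanup.

Frames come from a fixed camera looking at a rhizobox: either raw grayscale
images or RGB images in which the roots were manually traced in a saturated
colour. Timestamps are hours after sowing (HAS); when only a frame index is
available they are derived from the capture interval (default 4 minutes).

Coordinate convention throughout the package: pixel (x, y), 0-based, x
rightward, y downward, origin at the top-left pixel. Arrays are indexed
``[y, x]``. Physical calibration is a single isotropic millimetre-per-pixel
factor; with the default scale of 1.0 all "mm" quantities are pixel units.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "ImageFrame",
    "FrameEntry",
    "SeriesManifest",
    "BinaryRootMask",
    "FixedThreshold",
    "ColorBox",
    "OtsuThreshold",
    "parse_threshold_rule",
    "load_series",
    "read_frame",
    "binarize",
    "clean_mask",
]

#: 8-connectivity structuring element for foreground components.
STRUCT8 = np.ones((3, 3), dtype=int)
#: 4-connectivity structuring element for background components.
STRUCT4 = ndi.generate_binary_structure(2, 1)

_CHANNELS = {"gray": None, "r": 0, "g": 1, "b": 2}


@dataclass(frozen=True)
class ImageFrame:
    """One raster frame with its acquisition time in hours after sowing."""

    pixels: np.ndarray
    frame_id: int
    timestamp: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            pass
        elif px.ndim == 3 and px.shape[2] == 3:
            pass
        else:
            raise ValueError(
                f"frame must be HxW or HxWx3, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("frame must have at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if self.timestamp < 0:
            raise ValueError("timestamp (HAS) must be >= 0")
        object.__setattr__(self, "pixels", px)

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3


@dataclass(frozen=True)
class FrameEntry:
    path: Path
    frame_id: int
    timestamp: float


@dataclass(frozen=True)
class SeriesManifest:
    """Ordered list of frames on disk; timestamps strictly increasing."""

    entries: tuple[FrameEntry, ...]
    capture_interval_min: float

    def __post_init__(self) -> None:
        if self.capture_interval_min <= 0:
            raise ValueError("capture interval must be positive (minutes)")
        ts = [e.timestamp for e in self.entries]
        for a, b in zip(ts, ts[1:]):
            if b <= a:
                raise ValueError("timestamps must be strictly increasing")
        ids = [e.frame_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("frame_ids must be unique")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class BinaryRootMask:
    """Boolean root/background grid plus its physical scale.

    ``grid[y, x]`` is True where the pixel belongs to the root system.
    ``scale`` is mm per pixel (isotropic); 1.0 means uncalibrated pixels.
    """

    grid: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if self.scale <= 0:
            raise ValueError("scale must be > 0 (mm per pixel)")
        object.__setattr__(self, "grid", g)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


# ---------------------------------------------------------------------------
# Threshold rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedThreshold:
    """Foreground = intensity of ``channel`` strictly above ``threshold``."""

    threshold: float
    channel: str = "gray"

    def __post_init__(self) -> None:
        if self.channel not in _CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass(frozen=True)
class ColorBox:
    """Per-channel inclusive min/max box for traced colour overlays."""

    r: tuple[float, float] = (0, 255)
    g: tuple[float, float] = (0, 255)
    b: tuple[float, float] = (0, 255)


@dataclass(frozen=True)
class OtsuThreshold:
    """Automatic global threshold maximising between-class variance."""


ThresholdRule = Union[FixedThreshold, ColorBox, OtsuThreshold]

_BOX_RE = re.compile(r"([rgb])\s*=\s*([0-9.]+)\s*\.\.\s*([0-9.]+)")


def parse_threshold_rule(text: str) -> ThresholdRule:
    """Parse the config dialect: ``otsu``, ``fixed:gray>100`` or
    ``box:r=200..255,g=0..50,b=0..50``."""
    text = text.strip()
    if text == "otsu":
        return OtsuThreshold()
    if text.startswith("fixed:"):
        m = re.fullmatch(r"fixed:(\w+)>([0-9.]+)", text)
        if not m:
            raise ValueError(f"bad fixed-threshold rule {text!r}")
        return FixedThreshold(channel=m.group(1), threshold=float(m.group(2)))
    if text.startswith("box:"):
        boxes = {"r": (0.0, 255.0), "g": (0.0, 255.0), "b": (0.0, 255.0)}
        found = _BOX_RE.findall(text[4:])
        if not found:
            raise ValueError(f"bad color-box rule {text!r}")
        for ch, lo, hi in found:
            boxes[ch] = (float(lo), float(hi))
        return ColorBox(r=boxes["r"], g=boxes["g"], b=boxes["b"])
    raise ValueError(f"unknown threshold rule {text!r}")


def format_threshold_rule(rule: ThresholdRule) -> str:
    if isinstance(rule, OtsuThreshold):
        return "otsu"
    if isinstance(rule, FixedThreshold):
        t = rule.threshold
        t_s = f"{int(t)}" if float(t).is_integer() else f"{t}"
        return f"fixed:{rule.channel}>{t_s}"
    if isinstance(rule, ColorBox):
        parts = []
        for ch in "rgb":
            lo, hi = getattr(rule, ch)

            def s(v: float) -> str:
                return f"{int(v)}" if float(v).is_integer() else f"{v}"

            parts.append(f"{ch}={s(lo)}..{s(hi)}")
        return "box:" + ",".join(parts)
    raise TypeError(f"not a threshold rule: {rule!r}")


# ---------------------------------------------------------------------------
# Series loading
# ---------------------------------------------------------------------------

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}
_DEFAULT_PATTERN = re.compile(r"(\d+)")


def load_series(
    source: Union[str, Path],
    pattern: Optional[str] = None,
    interval_min: float = 4.0,
    start_has: float = 0.0,
) -> SeriesManifest:
    """Build a :class:`SeriesManifest` from a directory of frames or a CSV.

    A directory is scanned for PNG/TIFF files; the frame index is parsed
    from each filename with ``pattern`` (a regex whose first group is the
    integer index; default: first digit run in the stem) and the timestamp
    is ``start_has + index * interval_min / 60``.

    A CSV manifest must have columns ``path, frame_id, timestamp_has``.
    """
    source = Path(source)
    if source.is_dir():
        files = sorted(
            p for p in source.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise ValueError(f"no frames matched in {source}")
        rx = re.compile(pattern) if pattern is not None else _DEFAULT_PATTERN
        entries = []
        for p in files:
            m = rx.search(p.stem)
            if not m:
                raise ValueError(
                    f"filename {p.name!r} does not match pattern {rx.pattern!r}"
                )
            idx = int(m.group(1))
            entries.append(
                FrameEntry(p, idx, start_has + idx * interval_min / 60.0)
            )
    elif source.suffix.lower() == ".csv":
        df = pd.read_csv(source)
        required = {"path", "frame_id", "timestamp_has"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        entries = [
            FrameEntry(Path(r.path), int(r.frame_id), float(r.timestamp_has))
            for r in df.itertuples()
        ]
    else:
        raise ValueError(f"source must be a directory or .csv: {source}")

    entries.sort(key=lambda e: e.timestamp)
    seen: dict[float, Path] = {}
    for e in entries:
        if e.timestamp in seen:
            raise ValueError(
                "duplicate timestamps: "
                f"{seen[e.timestamp]} and {e.path} both at {e.timestamp} HAS"
            )
        seen[e.timestamp] = e.path
    return SeriesManifest(tuple(entries), capture_interval_min=interval_min)


def read_frame(entry: FrameEntry) -> ImageFrame:
    """Load a manifest entry from disk as an :class:`ImageFrame`."""
    px = iio.imread(entry.path)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[:, :, :3]
    if px.dtype != np.uint8:
        px = np.clip(px, 0, 255).astype(np.uint8)
    return ImageFrame(px, entry.frame_id, entry.timestamp)


# ---------------------------------------------------------------------------
# Binarization and cleanup
# ---------------------------------------------------------------------------


def _to_gray(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim == 2:
        return pixels.astype(float)
    # Rec.601 luma weights
    return pixels.astype(float) @ np.array([0.299, 0.587, 0.114])


def binarize(
    frame: ImageFrame, rule: ThresholdRule, scale: float = 1.0
) -> BinaryRootMask:
    """Threshold a frame into a root/background mask.

    Foreground is defined by the rule: strictly above a fixed threshold on a
    named channel, inside a per-channel colour box (for manually traced
    overlays), or above an automatic Otsu threshold on grayscale.
    """
    px = frame.pixels
    if isinstance(rule, FixedThreshold):
        ch = _CHANNELS[rule.channel]
        if ch is None:
            data = _to_gray(px)
        else:
            if px.ndim != 3:
                raise ValueError(
                    f"channel {rule.channel!r} not present in a grayscale frame"
                )
            data = px[:, :, ch].astype(float)
        grid = data > rule.threshold
    elif isinstance(rule, ColorBox):
        if px.ndim != 3:
            raise ValueError("color-box rule requires an RGB frame")
        f = px.astype(float)
        grid = np.ones(px.shape[:2], dtype=bool)
        for i, ch in enumerate("rgb"):
            lo, hi = getattr(rule, ch)
            grid &= (f[:, :, i] >= lo) & (f[:, :, i] <= hi)
    elif isinstance(rule, OtsuThreshold):
        from skimage.filters import threshold_otsu

        data = _to_gray(px)
        if np.ptp(data) == 0:
            grid = np.zeros(px.shape[:2], dtype=bool)
        else:
            grid = data > threshold_otsu(data)
    else:
        raise TypeError(f"not a threshold rule: {rule!r}")
    return BinaryRootMask(grid, scale=scale)


def clean_mask(
    mask: BinaryRootMask,
    min_object_px: int = 0,
    fill_holes_max_px: int = 0,
) -> BinaryRootMask:
    """Remove small 8-connected specks, then fill small 4-connected holes.

    Objects are removed first: a speck sitting inside a hole joins that hole
    before the filling step sees it, which makes the operation idempotent.
    Holes touching the image border are background, never filled.
    """
    if min_object_px < 0 or fill_holes_max_px < 0:
        raise ValueError("size thresholds must be >= 0")
    grid = mask.grid.copy()

    if min_object_px > 0 and grid.any():
        lab, n = ndi.label(grid, structure=STRUCT8)
        if n:
            sizes = np.bincount(lab.ravel())
            kill = sizes < min_object_px
            kill[0] = False
            grid[kill[lab]] = False

    if fill_holes_max_px > 0 and grid.any():
        bg = ~grid
        lab, n = ndi.label(bg, structure=STRUCT4)
        if n:
            border = np.unique(
                np.concatenate(
                    [lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]
                )
            )
            sizes = np.bincount(lab.ravel())
            fill = sizes < fill_holes_max_px
            fill[0] = False
            fill[border] = False
            grid[fill[lab]] = True

    return BinaryRootMask(grid, scale=mask.scale)
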
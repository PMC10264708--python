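"""Trait series over a time-lapse, emergence detection and CSV export."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .config import RunConfig
from .mask_io import SeriesManifest, binarize, read_frame
from .traits import TRAIT_COLUMNS, Landmarks, TraitRecord, extract_traits

__all__ = ["TraitSeries", "compute_series", "detect_emergence",
           "export_csv", "load_csv"]


@dataclass
class TraitSeries:
    """Timestamp-ordered trait records plus run provenance."""

    records: list[TraitRecord]
    landmarks: Landmarks
    config: RunConfig
    emergence_has: Optional[float] = None

    def __post_init__(self) -> None:
        ts = [r.timestamp_has for r in self.records]
        for a, b in zip(ts, ts[1:]):
            if b <= a:
                raise ValueError("records must be strictly increasing in time")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({c: getattr(r, c) for c in TRAIT_COLUMNS})
        return pd.DataFrame(rows, columns=list(TRAIT_COLUMNS))


def compute_series(
    manifest: SeriesManifest,
    landmarks: Landmarks,
    config: Optional[RunConfig] = None,
) -> TraitSeries:
    """Extract one :class:`TraitRecord` per manifest frame.

    A frame that fails to load or process contributes an all-absent record
    (zeros, angles None) instead of aborting the series.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    cfg = config or RunConfig()
    records = []
    for entry in manifest.entries:
        try:
            frame = read_frame(entry)
            mask = binarize(frame, cfg.threshold, scale=cfg.scale_mm_per_px)
            rec = extract_traits(mask, landmarks, cfg,
                                 frame_id=entry.frame_id,
                                 timestamp_has=entry.timestamp)
        except Exception:
            rec = TraitRecord(entry.frame_id, entry.timestamp, 0.0, 0.0, 0.0,
                              None, 0.0, 0.0, None, None, 0, 0)
        records.append(rec)
    records.sort(key=lambda r: r.timestamp_has)
    series = TraitSeries(records, landmarks, cfg)
    series.emergence_has = detect_emergence(series,
                                            cfg.min_emergence_area_px)
    return series


def detect_emergence(series: TraitSeries, min_area_px: int = 20
                     ) -> Optional[float]:
    """First timestamp whose root area reaches ``min_area_px`` pixels and
    stays there for two consecutive frames (rejects single-frame speckle).

    Returns None when the threshold is never sustained. The series must
    have been computed with seed exclusion applied, so the grain body
    cannot trigger detection.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    thr = min_area_px * series.config.scale_mm_per_px ** 2
    recs = series.records
    for i, rec in enumerate(recs):
        if rec.root_area >= thr:
            if i + 1 < len(recs) and recs[i + 1].root_area >= thr:
                return rec.timestamp_has
    return None


def export_csv(series: TraitSeries, path: Union[str, Path]) -> None:
    """One row per record with the fixed trait header; absent values are
    empty cells. Provenance (config + emergence) goes to a JSON sidecar."""
    df = series.to_frame()
    df.to_csv(path, index=False, float_format="%.6g")
    side = Path(path).with_suffix(".meta.json")
    side.write_text(json.dumps({
        "emergence_has": series.emergence_has,
        "grain": list(series.landmarks.grain),
        "config": series.config.to_text(),
        "tool": "rhizotrace",
        "version": __import__("rhizotrace").__version__,
    }, indent=1))


def load_csv(path: Union[str, Path],
             landmarks: Optional[Landmarks] = None,
             config: Optional[RunConfig] = None) -> TraitSeries:
    """Re-read an exported series CSV (round-trips :func:`export_csv`)."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        vals = {}
        for c in TRAIT_COLUMNS:
            v = getattr(row, c)
            if c in ("frame_id", "n_endpoints", "n_junctions"):
                vals[c] = int(v)
            elif c in ("primary_root_angle", "rga", "srga"):
                vals[c] = None if pd.isna(v) else float(v)
            else:
                vals[c] = float(v)
        records.append(TraitRecord(**vals))
    series = TraitSeries(records, landmarks or Landmarks(grain=(0, 0)),
                         config or RunConfig())
    meta = Path(path).with_suffix(".meta.json")
    if meta.exists():
        series.emergence_has = json.loads(meta.read_text())["emergence_has"]
    return series
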
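"""Regional statistics from plantar thermal frames.

A thermal frame is a rectangular grid of surface temperatures (°C); a
companion integer label mask assigns each pixel to one of the five plantar
regions (hallux, MTP, midfoot, arch, heel) or to background (label 0).
Segmentation is an input, never computed here.

The whole-foot temperature at a time point is the area-weighted average of
the regional mean temperatures,

    T_foot(t) = sum_r A_r(t) * T_r(t) / sum_r A_r(t),

with areas in pixel counts (physical pixel size cancels in the ratio).
Areas may vary from frame to frame; the weighted mean is recomputed per
frame and never cached.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PLANTAR_REGIONS",
    "ThermalFrame",
    "RegionMask",
    "RegionStats",
    "WholeFootSeries",
    "extract_region_stats",
    "whole_foot_temperature",
    "build_series",
    "read_frame_csv",
    "read_frame_tiff",
    "read_mask_csv",
    "read_mask_png",
    "load_label_map",
    "write_region_stats_csv",
    "read_region_stats_csv",
    "write_series_csv",
]

#: Canonical plantar region names, in the order they are usually reported.
PLANTAR_REGIONS = ("hallux", "MTP", "midfoot", "arch", "heel")

# Plausible range for plantar skin temperature; values outside it usually
# indicate a unit mix-up (K vs °C) or a background pixel inside the mask.
_PLAUSIBLE_C = (10.0, 50.0)


@dataclass(frozen=True)
class ThermalFrame:
    """One thermal photo: pixel temperatures in °C at a walk time point.

    Parameters
    ----------
    pixels : ndarray of float, shape (rows, cols)
        Surface temperature per pixel, °C. Row-major, 0-based indexing;
        orientation must match the companion mask (no implicit flips).
    time_min : float
        Minutes since the start of the walk; the baseline photo is 0.
    frame_id : str
        Free-text label (file name, participant tag, ...).
    """

    pixels: np.ndarray
    time_min: float
    frame_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        object.__setattr__(self, "pixels", px)
        lo, hi = _PLAUSIBLE_C
        if px.min() < lo or px.max() > hi:
            warnings.warn(
                f"frame {self.frame_id!r}: pixel temperatures outside "
                f"[{lo}, {hi}] °C (range {px.min():.2f}..{px.max():.2f})",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RegionMask:
    """Integer label grid naming the plantar region of each pixel.

    ``label_map`` maps region name -> positive integer label; 0 is
    background. Every nonzero label present in ``labels`` must appear in
    the map.
    """

    labels: np.ndarray
    label_map: Mapping[str, int]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise ValueError("labels must be a non-empty 2-D grid")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.array_equal(lab, lab.astype(int)):
                raise ValueError("labels must be integers")
            lab = lab.astype(int)
        object.__setattr__(self, "labels", lab)
        lm = dict(self.label_map)
        if any(v <= 0 for v in lm.values()):
            raise ValueError("label_map values must be positive (0 = background)")
        if len(set(lm.values())) != len(lm):
            raise ValueError("label_map values must be unique")
        object.__setattr__(self, "label_map", lm)
        present = set(np.unique(lab)) - {0}
        unknown = present - set(lm.values())
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from label_map")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class RegionStats:
    """Mean temperature and pixel area of one region in one frame."""

    region: str
    time_min: float
    mean_C: float
    area: int

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("area must be >= 1 pixel")


@dataclass(frozen=True)
class WholeFootSeries:
    """Area-weighted whole-foot temperature over the walk.

    Times are strictly increasing and start at 0 (the baseline photo), so
    the temperature-change series ΔT = temp − temp[0] starts at exactly 0.
    """

    times: np.ndarray
    temps: np.ndarray
    label: str = "whole_foot"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.temps, dtype=float)
        if t.ndim != 1 or t.shape != y.shape or t.size == 0:
            raise ValueError("times and temps must be equal-length 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if t[0] != 0.0:
            raise ValueError("series must start at time 0 (baseline)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temps", y)

    @property
    def baseline_C(self) -> float:
        return float(self.temps[0])

    @property
    def delta(self) -> np.ndarray:
        """Temperature change from baseline, °C; first element exactly 0."""
        return self.temps - self.temps[0]

    def __len__(self) -> int:
        return self.times.size


def extract_region_stats(frame: ThermalFrame, mask: RegionMask) -> list[RegionStats]:
    """Mean temperature and pixel area for every labeled region of a frame.

    Regions declared in the label map but absent from the mask are dropped
    with a warning. A shape mismatch between frame and mask is an error.
    """
    if frame.shape != mask.shape:
        raise ValueError(
            f"frame shape {frame.shape} != mask shape {mask.shape}"
        )
    if not np.any(mask.labels > 0):
        raise ValueError("mask contains no labeled pixels")
    out: list[RegionStats] = []
    for name, label in mask.label_map.items():
        sel = mask.labels == label
        area = int(sel.sum())
        if area == 0:
            warnings.warn(
                f"region {name!r} has no pixels in frame {frame.frame_id!r}; "
                "excluded",
                stacklevel=2,
            )
            continue
        out.append(
            RegionStats(
                region=name,
                time_min=frame.time_min,
                mean_C=float(frame.pixels[sel].mean()),
                area=area,
            )
        )
    return out


def whole_foot_temperature(stats: Sequence[RegionStats]) -> float:
    """Area-weighted average of regional means at one time point.

    Always bounded by the minimum and maximum regional mean; reduces to the
    arithmetic mean when all areas are equal.
    """
    if not stats:
        raise ValueError("no regional statistics supplied")
    areas = np.array([s.area for s in stats], dtype=float)
    temps = np.array([s.mean_C for s in stats], dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("total regional area is zero")
    return float(np.dot(areas, temps) / total)


def build_series(
    stats: Iterable[RegionStats],
    policy: Literal["renormalize", "strict"] = "renormalize",
    label: str = "whole_foot",
) -> WholeFootSeries:
    """Assemble the whole-foot series from regional stats across time points.

    Stats are grouped by ``time_min``; each group is collapsed with
    :func:`whole_foot_temperature`. If the region set differs between time
    points, ``policy="renormalize"`` (default) averages over the regions
    present at each time (with a warning), while ``policy="strict"`` raises.

    Duplicate (time, region) entries are an error; unordered input is
    sorted with a warning.
    """
    stats = list(stats)
    if not stats:
        raise ValueError("no regional statistics supplied")
    seen: set[tuple[float, str]] = set()
    for s in stats:
        key = (s.time_min, s.region)
        if key in seen:
            raise ValueError(f"duplicate entry for region {s.region!r} at t={s.time_min}")
        seen.add(key)

    groups: dict[float, list[RegionStats]] = {}
    for s in stats:
        groups.setdefault(s.time_min, []).append(s)
    times = list(groups)
    if times != sorted(times):
        warnings.warn("time points out of order; sorting", stacklevel=2)
    times = sorted(times)

    region_sets = {t: frozenset(s.region for s in groups[t]) for t in times}
    full = frozenset.union(*region_sets.values())
    for t in times:
        missing = full - region_sets[t]
        if missing:
            if policy == "strict":
                raise ValueError(
                    f"regions {sorted(missing)} missing at t={t} (strict policy)"
                )
            warnings.warn(
                f"regions {sorted(missing)} missing at t={t}; "
                "renormalizing weights over remaining regions",
                stacklevel=2,
            )
    temps = [whole_foot_temperature(groups[t]) for t in times]
    return WholeFootSeries(np.asarray(times, float), np.asarray(temps, float), label=label)


# ---------------------------------------------------------------------------
# File interfaces: CSV matrices, float TIFF frames, PNG masks, JSON label maps


def read_frame_csv(path: str | Path, time_min: float, frame_id: str = "") -> ThermalFrame:
    """Read a thermal frame from a comma-separated numeric matrix."""
    px = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
    return ThermalFrame(px, time_min=time_min, frame_id=frame_id or str(path))


def read_frame_tiff(path: str | Path, time_min: float, frame_id: str = "") -> ThermalFrame:
    """Read a thermal frame from a single-band float TIFF."""
    import tifffile

    px = np.asarray(tifffile.imread(path), dtype=float)
    if px.ndim != 2:
        raise ValueError(f"{path}: expected a single-band image, got shape {px.shape}")
    return ThermalFrame(px, time_min=time_min, frame_id=frame_id or str(path))


def read_mask_csv(path: str | Path, label_map: Mapping[str, int]) -> RegionMask:
    lab = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    return RegionMask(lab, label_map)


def read_mask_png(path: str | Path, label_map: Mapping[str, int]) -> RegionMask:
    """Read an 8-bit PNG label image as a region mask."""
    from PIL import Image

    with Image.open(path) as im:
        lab = np.asarray(im, dtype=int)
    if lab.ndim != 2:
        raise ValueError(f"{path}: mask PNG must be single-channel")
    return RegionMask(lab, label_map)


def load_label_map(path: str | Path) -> dict[str, int]:
    with open(path) as fh:
        raw = json.load(fh)
    return {str(k): int(v) for k, v in raw.items()}


def write_region_stats_csv(stats: Sequence[RegionStats], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_min": [s.time_min for s in stats],
            "region": [s.region for s in stats],
            "mean_C": [s.mean_C for s in stats],
            "area_px": [s.area for s in stats],
        }
    )
    df.to_csv(path, index=False)


def read_region_stats_csv(path: str | Path) -> list[RegionStats]:
    df = pd.read_csv(path)
    return [
        RegionStats(
            region=str(r.region),
            time_min=float(r.time_min),
            mean_C=float(r.mean_C),
            area=int(r.area_px),
        )
        for r in df.itertuples()
    ]


def write_series_csv(series: WholeFootSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_min": series.times,
            "temp_C": series.temps,
            "delta_C": series.delta,
        }
    )
    df.to_csv(path, index=False)
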
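"""Synthetic plantar-temperature cohorts for end-to-end testing.

No public dataset of per-region plantar temperature series exists for this
protocol, so this module generates one: each plantar region follows a
generalized-logistic ground-truth curve sampled every 5 min over a 30-min
walk, with additive Gaussian measurement noise and a per-participant
vertical offset. Matching synthetic thermal frames (rectangular region
blocks on an ambient background, one pixel block per region) and label
masks let the image-extraction stage run on the same cohort.

The default ground-truth coefficients reproduce the temporal shapes
reported for healthy adults: a strongly S-shaped hallux response rising
about 5–6 °C and flatter responses (2–4 °C) elsewhere. Random streams are
split hierarchically (cohort → participant → region/frame), so adding a
participant never perturbs earlier participants' draws, and a fixed seed
reproduces the cohort exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .models import TemperatureSeries, generalized_logistic
from .regions import PLANTAR_REGIONS, RegionMask, ThermalFrame

__all__ = [
    "DEFAULT_REGION_TRUTH",
    "DEFAULT_REGION_AREAS",
    "SyntheticConfig",
    "SyntheticParticipant",
    "SyntheticCohort",
    "generate_region_series",
    "generate_frame",
    "generate_cohort",
    "write_cohort",
]

#: Generalized-logistic ground truth per region (A, K in °C; C, Q, nu
#: dimensionless; B in 1/min). Chosen to match the regional temporal
#: responses measured in healthy adults during a 30-min walk.
DEFAULT_REGION_TRUTH: dict[str, dict[str, float]] = {
    "hallux": {"A": 27.28, "K": 32.80, "C": 0.994, "Q": 0.92, "B": 0.19, "nu": 0.078},
    "MTP": {"A": 29.88, "K": 33.69, "C": 0.976, "Q": 4.79, "B": 0.18, "nu": 0.43},
    "midfoot": {"A": 30.25, "K": 31.50, "C": 0.999, "Q": 0.0081, "B": 0.14, "nu": 0.0014},
    "arch": {"A": 31.20, "K": 31.61, "C": 0.998, "Q": 0.017, "B": 0.17, "nu": 0.0012},
    "heel": {"A": 29.19, "K": 30.11, "C": 0.999, "Q": 0.0057, "B": 0.15, "nu": 0.00078},
}

#: Region pixel areas (counts), roughly proportional to plantar surface
#: proportions: heel and MTP largest, hallux smallest.
DEFAULT_REGION_AREAS: dict[str, int] = {
    "hallux": 250,
    "MTP": 1000,
    "midfoot": 700,
    "arch": 850,
    "heel": 1200,
}

_COEF_NAMES = ("A", "K", "C", "Q", "B", "nu")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the emulated protocol: 8 participants, thermal photos
    every 5 min over a 30-min walk, 0.2 °C additive measurement noise and
    a 0.5 °C SD participant-level vertical offset.
    """

    region_truth: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REGION_TRUTH.items()}
    )
    region_areas: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_AREAS)
    )
    noise_sd: float = 0.2
    spatial_noise_sd: float = 0.0
    sample_interval_min: float = 5.0
    duration_min: float = 30.0
    n_participants: int = 8
    participant_spread: float = 0.5
    ambient_C: float = 22.0
    frame_width: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.spatial_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        n_steps = self.duration_min / self.sample_interval_min
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("sample_interval_min must divide duration_min")
        if set(self.region_truth) != set(self.region_areas):
            raise ValueError("region_truth and region_areas must name the same regions")
        for name, coefs in self.region_truth.items():
            missing = set(_COEF_NAMES) - set(coefs)
            if missing:
                raise ValueError(f"{name}: missing coefficients {sorted(missing)}")
            for k in ("C", "B", "nu"):
                if coefs[k] <= 0:
                    raise ValueError(f"{name}: {k} must be positive")
            if coefs["Q"] < 0:
                raise ValueError(f"{name}: Q must be >= 0")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration_min / self.sample_interval_min))
        return np.linspace(0.0, self.duration_min, n + 1)

    @property
    def regions(self) -> tuple[str, ...]:
        # keep canonical ordering where possible
        known = [r for r in PLANTAR_REGIONS if r in self.region_truth]
        extra = [r for r in self.region_truth if r not in PLANTAR_REGIONS]
        return tuple(known + extra)

    @property
    def label_map(self) -> dict[str, int]:
        return {r: i + 1 for i, r in enumerate(self.regions)}


@dataclass(frozen=True)
class SyntheticParticipant:
    """One participant's noisy series, frames and true (offset) coefficients."""

    participant_id: str
    offset_C: float
    truth: dict[str, dict[str, float]]
    series: dict[str, TemperatureSeries]
    frames: tuple[tuple[ThermalFrame, RegionMask], ...]


@dataclass(frozen=True)
class SyntheticCohort:
    """A full synthetic cohort plus the ground truth that generated it."""

    config: SyntheticConfig
    participants: tuple[SyntheticParticipant, ...]

    @property
    def ground_truth(self) -> Mapping[str, Mapping[str, float]]:
        return self.config.region_truth

    def truth_curve(self, region: str, t: np.ndarray) -> np.ndarray:
        """Noise-free cohort-level curve for one region."""
        c = self.config.region_truth[region]
        return generalized_logistic(t, c["A"], c["K"], c["C"], c["Q"], c["B"], c["nu"])

    def whole_foot_truth(self, t: np.ndarray) -> np.ndarray:
        """Area-weighted combination of the true regional curves."""
        areas = np.array([self.config.region_areas[r] for r in self.config.regions], float)
        curves = np.stack([self.truth_curve(r, t) for r in self.config.regions])
        return areas @ curves / areas.sum()


def generate_region_series(
    coefs: Mapping[str, float],
    times: Sequence[float],
    noise_sd: float,
    rng: np.random.Generator,
    label: str = "",
) -> TemperatureSeries:
    """Sample a logistic ground-truth curve with additive Gaussian noise."""
    for k in ("C", "B", "nu"):
        if coefs[k] <= 0:
            raise ValueError(f"{k} must be positive")
    if coefs["Q"] < 0:
        raise ValueError("Q must be >= 0")
    t = np.asarray(times, dtype=float)
    truth = generalized_logistic(
        t, coefs["A"], coefs["K"], coefs["C"], coefs["Q"], coefs["B"], coefs["nu"]
    )
    temps = truth + rng.normal(0.0, noise_sd, size=t.shape) if noise_sd > 0 else truth
    return TemperatureSeries(t, temps, label=label)


def _block_layout(
    region_areas: Mapping[str, int], label_map: Mapping[str, int], width: int
) -> np.ndarray:
    """Assign each region a contiguous run of pixels in a row-major grid.

    Regions are stacked blocks; the grid is padded with a background row so
    every frame contains ambient pixels. Exact pixel areas are preserved.
    """
    total = sum(region_areas.values())
    rows = total // width + (1 if total % width else 0) + 1
    labels = np.zeros(rows * width, dtype=int)
    pos = 0
    for name, label in label_map.items():
        area = int(region_areas[name])
        if area < 1:
            raise ValueError(f"region {name!r}: area must be >= 1")
        labels[pos : pos + area] = label
        pos += area
    return labels.reshape(rows, width)


def generate_frame(
    region_temps: Mapping[str, float],
    region_areas: Mapping[str, int],
    label_map: Mapping[str, int],
    time_min: float,
    rng: np.random.Generator,
    spatial_noise_sd: float = 0.0,
    ambient_C: float = 22.0,
    width: int = 40,
    frame_id: str = "",
) -> tuple[ThermalFrame, RegionMask]:
    """Render regional temperatures into a synthetic thermal frame + mask.

    Pixels of region r are drawn from N(T_r, spatial_noise_sd); background
    pixels take the ambient temperature. Region geometry is abstract
    stacked blocks — the weighted-average pipeline depends only on areas
    and means, not on foot-shaped outlines.
    """
    if set(region_temps) != set(region_areas):
        raise ValueError("region_temps and region_areas must name the same regions")
    labels = _block_layout(region_areas, label_map, width)
    pixels = np.full(labels.shape, float(ambient_C))
    for name, label in label_map.items():
        sel = labels == label
        if spatial_noise_sd > 0:
            pixels[sel] = rng.normal(region_temps[name], spatial_noise_sd, sel.sum())
        else:
            pixels[sel] = region_temps[name]
    frame = ThermalFrame(pixels, time_min=time_min, frame_id=frame_id)
    mask = RegionMask(labels, dict(label_map))
    return frame, mask


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate the full cohort: per-region series and matching frames.

    Each participant receives one vertical offset (drawn from
    N(0, participant_spread)) applied to both A and K of every region, so
    individual curves are parallel shifts of the cohort truth. Frames are
    rendered from the participant's *noisy* series values, so frame-derived
    regional means agree with the series exactly when spatial noise is 0.
    """
    if config is None:
        config = SyntheticConfig()
    times = config.times
    root = np.random.SeedSequence(config.seed)
    participant_seqs = root.spawn(config.n_participants)

    participants = []
    for i, pseq in enumerate(participant_seqs):
        off_seq, series_seq, frame_seq = pseq.spawn(3)
        offset = (
            float(np.random.default_rng(off_seq).normal(0.0, config.participant_spread))
            if config.participant_spread > 0
            else 0.0
        )
        truth_i: dict[str, dict[str, float]] = {}
        series_i: dict[str, TemperatureSeries] = {}
        region_seqs = series_seq.spawn(len(config.regions))
        for region, rseq in zip(config.regions, region_seqs):
            coefs = dict(config.region_truth[region])
            coefs["A"] += offset
            coefs["K"] += offset
            truth_i[region] = coefs
            series_i[region] = generate_region_series(
                coefs,
                times,
                config.noise_sd,
                np.random.default_rng(rseq),
                label=region,
            )
        frames = []
        frame_seqs = frame_seq.spawn(len(times))
        for j, (t, fseq) in enumerate(zip(times, frame_seqs)):
            temps_at_t = {r: float(series_i[r].temps[j]) for r in config.regions}
            frame, mask = generate_frame(
                temps_at_t,
                config.region_areas,
                config.label_map,
                time_min=float(t),
                rng=np.random.default_rng(fseq),
                spatial_noise_sd=config.spatial_noise_sd,
                ambient_C=config.ambient_C,
                width=config.frame_width,
                frame_id=f"P{i:02d}_t{int(round(t)):03d}",
            )
            frames.append((frame, mask))
        participants.append(
            SyntheticParticipant(
                participant_id=f"P{i:02d}",
                offset_C=offset,
                truth=truth_i,
                series=series_i,
                frames=tuple(frames),
            )
        )
    return SyntheticCohort(config=config, participants=tuple(participants))


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a cohort to disk in the formats the ingestion side reads.

    Layout: one directory per participant with a combined regional-series
    CSV and one float TIFF frame per time point; a shared mask PNG and
    label-map JSON; a manifest JSON listing every file and the ground-truth
    coefficients. Returns the manifest path.
    """
    import pandas as pd
    import tifffile
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config

    # shared geometry
    mask = cohort.participants[0].frames[0][1]
    mask_path = outdir / "mask.png"
    Image.fromarray(mask.labels.astype(np.uint8), mode="L").save(mask_path)
    label_map_path = outdir / "label_map.json"
    label_map_path.write_text(json.dumps(mask.label_map, indent=1))

    manifest: dict = {
        "label_map": str(label_map_path.name),
        "mask": str(mask_path.name),
        "times_min": [float(t) for t in cfg.times],
        "ground_truth": {r: dict(c) for r, c in cfg.region_truth.items()},
        "region_areas": {r: int(a) for r, a in cfg.region_areas.items()},
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
        "participants": [],
    }
    for part in cohort.participants:
        pdir = outdir / part.participant_id
        pdir.mkdir(exist_ok=True)
        rows = []
        for region, series in part.series.items():
            for t, y in zip(series.times, series.temps):
                rows.append({"time_min": t, "temp_C": y, "label": region})
        series_path = pdir / "regional_series.csv"
        pd.DataFrame(rows).to_csv(series_path, index=False)
        frame_files = []
        for frame, _ in part.frames:
            fpath = pdir / f"frame_t{int(round(frame.time_min)):03d}.tif"
            tifffile.imwrite(fpath, frame.pixels.astype(np.float32))
            frame_files.append(str(fpath.relative_to(outdir)))
        manifest["participants"].append(
            {
                "id": part.participant_id,
                "offset_C": part.offset_C,
                "series": str(series_path.relative_to(outdir)),
                "frames": frame_files,
            }
        )
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path
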
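"""Tile-grid planning, timing budgets and data-size estimates.

Large cleared-tissue volumes are covered by a 3D grid of overlapping
tiles; each tile is a stack acquired by stepping the stage axially with
a step equal to the lateral pixel size of the current immersion medium
(isotropic voxels).  The planner computes the minimal covering grid,
frames per stack, total per-frame acquisition time (pfAT = n_stacks x
frames x frame time, excluding flyback), the total imaging time
including per-frame flyback and per-stack delays, and dataset sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acquisition import DEFAULT_SWEEP_TIME_S
from .optics import ImmersionScaling, field_of_view, pixel_size

__all__ = [
    "TilePlan",
    "TimingBudget",
    "plan_tiles",
    "pfat_total",
    "total_imaging_time",
    "dataset_bytes",
    "compare_modes",
    "hours",
]


def hours(seconds: float) -> float:
    """Seconds -> hours rounded to 2 decimal places (round-half-even)."""
    return round(seconds / 3600.0, 2)


@dataclass(frozen=True)
class TilePlan:
    """3D grid of overlapping tile stacks covering a bounding box."""

    box_um: tuple[float, float, float]  # (x, y, z) extents
    immersion_index: float
    overlap: float
    tile_depth_um: float
    frames_per_stack: int
    channels: int
    grid_starts_um: tuple[np.ndarray, np.ndarray, np.ndarray]  # per-axis starts

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(len(g) for g in self.grid_starts_um)

    @property
    def n_stacks(self) -> int:
        return int(np.prod(self.grid_shape))

    def positions(self) -> list[tuple[float, float, float]]:
        """All (x, y, z) tile starts in acquisition (raster) order."""
        gx, gy, gz = self.grid_starts_um
        return [
            (float(x), float(y), float(z)) for x in gx for y in gy for z in gz
        ]


def _cover_axis(extent: float, tile: float, stride: float) -> np.ndarray:
    """Minimal 1D covering with the final tile flush to the box edge."""
    if extent <= tile:
        return np.array([0.0])
    # tolerance guards exact multiples against float noise
    count = math.ceil((extent - tile) / stride - 1e-9) + 1
    starts = np.arange(count) * stride
    starts[-1] = extent - tile
    return starts


def plan_tiles(
    box_um: tuple[float, float, float],
    n: float,
    overlap: float = 0.1,
    tile_depth_um: float = 140.0,
    channels: int = 1,
    scaling: ImmersionScaling | None = None,
) -> TilePlan:
    """Minimal overlapping tile grid for a bounding box at immersion index n.

    Lateral tiles are one FOV square; the effective stride is
    ``(1 - overlap) * FOV(n)`` laterally and ``(1 - overlap) *
    tile_depth`` axially.  ``frames_per_stack = ceil(tile_depth /
    pixel_size(n))`` because the stage step equals the pixel size.
    """
    scaling = scaling or ImmersionScaling()
    if not (0 <= overlap <= 0.9):
        raise ValueError("overlap must be in [0, 0.9]")
    if any(e <= 0 for e in box_um):
        raise ValueError("box extents must be positive")
    if channels < 1:
        raise ValueError("need at least one channel")
    px = pixel_size(scaling, n)
    if tile_depth_um < px:
        raise ValueError(f"tile depth {tile_depth_um} um < pixel size {px:.4f} um")
    fov = field_of_view(scaling, n)
    stride_xy = (1.0 - overlap) * fov
    stride_z = (1.0 - overlap) * tile_depth_um
    grid = (
        _cover_axis(box_um[0], fov, stride_xy),
        _cover_axis(box_um[1], fov, stride_xy),
        _cover_axis(box_um[2], tile_depth_um, stride_z),
    )
    return TilePlan(
        box_um=tuple(float(e) for e in box_um),
        immersion_index=n,
        overlap=overlap,
        tile_depth_um=tile_depth_um,
        frames_per_stack=math.ceil(tile_depth_um / px),
        channels=channels,
        grid_starts_um=grid,
    )


def pfat_total(n_stacks: int, frames_per_stack: int, frame_time_s: float) -> float:
    """Total per-frame acquisition time in seconds (excludes flyback).

    ``n_stacks`` counts acquired stacks including channel repeats.
    """
    if n_stacks <= 0 or frames_per_stack <= 0 or frame_time_s <= 0:
        raise ValueError("all arguments must be positive")
    return n_stacks * frames_per_stack * frame_time_s


@dataclass(frozen=True)
class TimingBudget:
    """Decomposition of the total imaging time; components sum exactly."""

    pfat_total_s: float
    flyback_total_s: float
    stack_delay_total_s: float
    dataset_bytes: int

    @property
    def total_imaging_time_s(self) -> float:
        return self.pfat_total_s + self.flyback_total_s + self.stack_delay_total_s

    @property
    def pfat_total_h(self) -> float:
        return hours(self.pfat_total_s)

    @property
    def total_imaging_time_h(self) -> float:
        return hours(self.total_imaging_time_s)


def total_imaging_time(
    plan: TilePlan,
    frame_time_s: float,
    flyback_s: float = 0.0,
    stack_delay_s: float = 0.0,
) -> TimingBudget:
    """Timing budget: pfAT + per-frame flyback + between-stack delays."""
    if flyback_s < 0 or stack_delay_s < 0:
        raise ValueError("overheads must be non-negative")
    n_acq = plan.n_stacks * plan.channels
    n_frames_total = n_acq * plan.frames_per_stack
    pfat = pfat_total(n_acq, plan.frames_per_stack, frame_time_s)
    return TimingBudget(
        pfat_total_s=pfat,
        flyback_total_s=n_frames_total * flyback_s,
        stack_delay_total_s=max(n_acq - 1, 0) * stack_delay_s,
        dataset_bytes=dataset_bytes(plan),
    )


def dataset_bytes(
    plan_or_n_stacks,
    bytes_per_voxel: int = 2,
    frames_per_stack: int | None = None,
    channels: int = 1,
    n_rows: int = 2048,
    n_cols: int = 2048,
) -> int:
    """Raw dataset size in bytes (16-bit voxels by default, decimal TB).

    Accepts either a TilePlan or an explicit stack count with
    ``frames_per_stack``.
    """
    if isinstance(plan_or_n_stacks, TilePlan):
        p = plan_or_n_stacks
        n_stacks, frames, ch = p.n_stacks, p.frames_per_stack, p.channels
    else:
        n_stacks, frames, ch = int(plan_or_n_stacks), frames_per_stack, channels
        if n_stacks == 0:
            return 0
        if frames is None:
            raise ValueError("frames_per_stack required with an explicit count")
    return n_stacks * ch * n_rows * n_cols * frames * bytes_per_voxel


def compare_modes(
    frames_per_stack: int,
    n_stacks: int = 1,
    channels: int = 1,
    frame_times_s: dict | None = None,
    shutter_width: int = 64,
    n_rows: int = 2048,
    photon_rate: float = 1000.0,
    background_rate: float = 100.0,
    read_noise: float = 1.6,
):
    """Side-by-side single-focus vs dual-foci acquisition report.

    Returns (DataFrame indexed by mode, ratios dict).  Per-row exposure
    uses the rolling-shutter identity W*T/n_rows (single) and
    2*W*T/n_rows (dual); the predicted SNR ratio brackets come from the
    read-noise-limited (exposure ratio) and shot-noise-limited
    (sqrt of exposure ratio) extremes of the noise model.
    """
    import pandas as pd

    from .acquisition import snr_ratio_model

    frame_times_s = frame_times_s or dict(DEFAULT_SWEEP_TIME_S)
    if "single" not in frame_times_s or "dual" not in frame_times_s:
        raise ValueError("frame_times_s must provide both 'single' and 'dual'")
    rows = {}
    for mode in ("single", "dual"):
        t = frame_times_s[mode]
        span = n_rows if mode == "single" else n_rows // 2
        exposure = shutter_width * t / span
        rows[mode] = {
            "frame_time_s": t,
            "frame_rate_fps": 1.0 / t,
            "per_row_exposure_s": exposure,
            "pfat_total_s": pfat_total(n_stacks * channels, frames_per_stack, t),
            "pfat_total_h": hours(pfat_total(n_stacks * channels, frames_per_stack, t)),
        }
    exp_ratio = rows["dual"]["per_row_exposure_s"] / rows["single"]["per_row_exposure_s"]
    snr_shot = snr_ratio_model(
        photon_rate, 0.0, 0.0,
        rows["dual"]["per_row_exposure_s"], rows["single"]["per_row_exposure_s"],
    )
    snr_read = snr_ratio_model(
        1e-6, 0.0, read_noise,
        rows["dual"]["per_row_exposure_s"], rows["single"]["per_row_exposure_s"],
    )
    ratios = {
        "pfat_single_over_dual": rows["single"]["pfat_total_s"] / rows["dual"]["pfat_total_s"],
        "exposure_dual_over_single": exp_ratio,
        "snr_dual_over_single_shot_limit": snr_shot,
        "snr_dual_over_single_read_limit": snr_read,
    }
    return pd.DataFrame(rows).T, ratios
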
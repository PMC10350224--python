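"""Seeded synthetic phantoms: bead volumes and two-class tissue tiles.

Two kinds of ground truth feed the rest of the toolkit:

* bead phantoms — sub-resolution (500 nm) fluorescent beads suspended in
  an agarose-like volume, used to quantify the point spread function;
* tissue tiles — small low-resolution stacks mimicking the pre-scan
  used for mesoscale tissue-boundary triage, in two classes:
  informative (blob and filament structures over background) and
  empty (background noise only).

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = ["Phantom", "TileDataset", "bead_phantom", "tissue_tile", "make_dataset"]


@dataclass(frozen=True)
class Phantom:
    """Point-emitter phantom in a rectangular volume.

    Positions are continuous sample-space coordinates in um on axes
    (x = camera-row/sweep axis, y = columns, z = stage/detection axis).
    Intensities are expected photoelectrons per second of exposure at
    the emitter's peak pixel under perfect synchronisation.
    """

    positions_um: np.ndarray  # (N, 3)
    intensities: np.ndarray  # (N,)
    diameter_um: float
    extents_um: tuple[float, float, float]
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float).reshape(-1, 3)
        if np.any(pos < 0) or np.any(pos > np.asarray(self.extents_um)):
            raise ValueError("all emitters must lie inside the volume")
        if np.any(np.asarray(self.intensities) <= 0):
            raise ValueError("emitter intensities must be positive")

    @property
    def n_emitters(self) -> int:
        return len(self.intensities)


def bead_phantom(
    extents_um: tuple[float, float, float],
    n_beads: int,
    diameter_um: float = 0.5,
    intensity: float = 2.0e5,
    min_separation_um: float = 0.0,
    background_rate: float = 0.0,
    margin_um: float = 0.0,
    seed: int = 0,
    max_tries: int = 1000,
) -> Phantom:
    """Uniformly random beads honouring a minimum pairwise separation.

    Mimics sub-resolution beads embedded in an agarose block.  Positions
    are drawn by dart throwing; an infeasible packing raises after
    ``max_tries`` consecutive rejected draws.
    """
    if n_beads < 0:
        raise ValueError("n_beads must be non-negative")
    ext = np.asarray(extents_um, dtype=float)
    if np.any(ext <= 0):
        raise ValueError("extents must be positive")
    lo = np.full(3, margin_um)
    hi = ext - margin_um
    if np.any(hi <= lo):
        raise ValueError("margin leaves no room for beads")

    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n_beads:
        cand = rng.uniform(lo, hi)
        if min_separation_um > 0 and placed:
            d2 = np.sum((np.asarray(placed) - cand) ** 2, axis=1)
            if d2.min() < min_separation_um**2:
                tries += 1
                if tries > max_tries:
                    raise RuntimeError(
                        f"could not place {n_beads} beads with separation "
                        f">= {min_separation_um} um after {max_tries} rejections"
                    )
                continue
        placed.append(cand)
        tries = 0
    positions = np.asarray(placed, dtype=float).reshape(-1, 3)
    return Phantom(
        positions_um=positions,
        intensities=np.full(n_beads, float(intensity)),
        diameter_um=diameter_um,
        extents_um=tuple(ext),
        background_rate=background_rate,
    )


# --- tissue tiles -----------------------------------------------------------

#: Noise model for the low-resolution pre-scan (counts): camera offset,
#: Poisson background photons, Gaussian read noise.
TILE_OFFSET_COUNTS = 100.0
TILE_BACKGROUND_PHOTONS = 20.0
TILE_READ_NOISE_COUNTS = 2.0


def _background_sigma() -> float:
    return math.sqrt(TILE_BACKGROUND_PHOTONS + TILE_READ_NOISE_COUNTS**2)


def tissue_tile(
    kind: Literal["informative", "empty"],
    shape: tuple[int, int, int] = (8, 96, 96),
    blob_count: int = 5,
    filament_count: int = 2,
    contrast: float = 10.0,
    noise: float = TILE_READ_NOISE_COUNTS,
    seed: int = 0,
) -> np.ndarray:
    """One synthetic low-resolution tile as a (planes, H, W) uint16 stack.

    Empty tiles are camera offset + Poisson background + read noise.
    Informative tiles additionally contain ``blob_count`` Gaussian blobs
    and ``filament_count`` random-walk filaments whose peak amplitude is
    ``contrast`` times the background noise sigma; at contrast -> 0 the
    two classes become statistically indistinguishable.
    """
    if any(s <= 0 for s in shape):
        raise ValueError(f"non-positive tile shape {shape}")
    if kind not in ("informative", "empty"):
        raise ValueError(f"kind must be 'informative' or 'empty', got {kind!r}")
    if kind == "informative" and contrast <= 0:
        raise ValueError("informative tiles need positive contrast")

    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    signal = np.zeros(shape, dtype=float)
    amp = contrast * _background_sigma()

    if kind == "informative":
        for _ in range(blob_count):
            cz, cy, cx = rng.uniform((0, 0, 0), (nz, ny, nx))
            sz = rng.uniform(0.8, 1.6)
            sxy = rng.uniform(2.0, 5.0)
            a = amp * rng.uniform(0.6, 1.2)
            _stamp_blob(signal, (cz, cy, cx), (sz, sxy, sxy), a)
        fil = np.zeros(shape, dtype=float)
        for _ in range(filament_count):
            _stamp_filament(fil, rng, amp)
        if filament_count:
            signal += ndimage.gaussian_filter(fil, sigma=(0.6, 1.2, 1.2))

    expected = TILE_BACKGROUND_PHOTONS + signal
    counts = (
        TILE_OFFSET_COUNTS
        + rng.poisson(expected)
        + rng.normal(0.0, noise, size=shape)
    )
    return np.clip(np.rint(counts), 0, 2**16 - 1).astype(np.uint16)


def _stamp_blob(vol, center, sigma, amplitude, k: float = 4.0):
    slices, grids = [], []
    for ax, (c, s) in enumerate(zip(center, sigma)):
        lo = max(int(c - k * s), 0)
        hi = min(int(c + k * s) + 1, vol.shape[ax])
        if hi <= lo:
            return
        slices.append(slice(lo, hi))
        grids.append(np.arange(lo, hi) - c)
    gz = np.exp(-0.5 * (grids[0] / sigma[0]) ** 2)
    gy = np.exp(-0.5 * (grids[1] / sigma[1]) ** 2)
    gx = np.exp(-0.5 * (grids[2] / sigma[2]) ** 2)
    vol[tuple(slices)] += amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def _stamp_filament(vol, rng, amplitude, n_steps: int = 80):
    nz, ny, nx = vol.shape
    pos = rng.uniform((0, 0, 0), (nz, ny, nx))
    direction = rng.normal(size=3)
    direction[0] *= 0.2  # filaments run mostly in-plane
    direction /= np.linalg.norm(direction)
    a = amplitude * rng.uniform(0.5, 1.0)
    for _ in range(n_steps):
        direction += rng.normal(scale=(0.05, 0.3, 0.3))
        direction /= np.linalg.norm(direction)
        pos = pos + direction
        iz, iy, ix = np.floor(pos).astype(int)
        if 0 <= iz < nz and 0 <= iy < ny and 0 <= ix < nx:
            vol[iz, iy, ix] += a


@dataclass
class TileDataset:
    """Balanced, deterministically shuffled labelled tiles.

    ``tiles`` holds either 3D stacks or (default) their axial MIPs;
    labels are 1 = informative, 0 = empty, matching the triage
    convention downstream.
    """

    tiles: list[np.ndarray]
    labels: np.ndarray
    seeds: np.ndarray
    tile_shape: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def manifest(self):
        """Manifest as a pandas DataFrame (index, label, seed)."""
        import pandas as pd

        return pd.DataFrame(
            {"index": np.arange(len(self)), "label": self.labels, "seed": self.seeds}
        )


def make_dataset(
    n_per_class: int = 2080,
    tile_shape: tuple[int, int, int] = (8, 96, 96),
    contrast: float = 10.0,
    blob_count: int = 5,
    filament_count: int = 2,
    projection: bool = True,
    seed: int = 0,
) -> TileDataset:
    """Balanced two-class tile dataset (default 2 x 2,080 = 4,160 tiles).

    Tiles are generated per-class from per-tile child seeds of ``seed``
    and shuffled deterministically.  With ``projection=True`` (default)
    each stored tile is the axial MIP of its generated stack, which is
    what both triage paths consume.
    """
    if n_per_class < 1:
        raise ValueError("need at least one tile per class")
    ss = np.random.SeedSequence(seed)
    tile_seeds = ss.generate_state(2 * n_per_class)
    labels = np.concatenate(
        [np.ones(n_per_class, dtype=int), np.zeros(n_per_class, dtype=int)]
    )
    tiles: list[np.ndarray] = []
    for lbl, ts in zip(labels, tile_seeds):
        kind = "informative" if lbl == 1 else "empty"
        t = tissue_tile(
            kind,
            shape=tile_shape,
            blob_count=blob_count,
            filament_count=filament_count,
            contrast=contrast,
            seed=int(ts),
        )
        tiles.append(t.max(axis=0) if projection else t)
    order = np.random.default_rng(ss.spawn(1)[0]).permutation(2 * n_per_class)
    return TileDataset(
        tiles=[tiles[i] for i in order],
        labels=labels[order],
        seeds=tile_seeds[order],
        tile_shape=tile_shape,
    )
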
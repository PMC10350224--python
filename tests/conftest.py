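import numpy as np
import pytest

from dualsweep import (
    BeamParameters,
    CameraConfig,
    ImmersionScaling,
    generate_drive_waveform,
    pixel_size,
)


@pytest.fixture(scope="session")
def scaling():
    return ImmersionScaling()


@pytest.fixture(scope="session")
def px_water(scaling):
    return pixel_size(scaling, 1.33)


@pytest.fixture
def small_camera():
    def _make(mode="dual", n_rows=64, shutter_width=8):
        return CameraConfig(
            n_rows=n_rows, n_cols=n_rows, shutter_width=shutter_width, mode=mode
        )

    return _make


@pytest.fixture
def small_waveform(px_water):
    """Drive waveform matched to a small simulated sensor."""

    def _make(mode="dual", n_rows=64, rise=0.025, flyback=0.0025, n_frames=40):
        amp_rows = n_rows if mode == "single" else n_rows // 2
        return generate_drive_waveform(
            mode, rise, flyback, n_frames,
            sample_rate_hz=60_000.0, amplitude_um=amp_rows * px_water,
        )

    return _make


@pytest.fixture(scope="session")
def beam():
    return BeamParameters()


def brute_force_box_mean(img: np.ndarray, size: int) -> np.ndarray:
    """Independent nested-loop box filter (symmetric padding, origin
    offset toward the lower index for even kernels)."""
    lo = size // 2
    hi = size - 1 - lo
    p = np.pad(np.asarray(img, dtype=np.float64), ((lo, hi), (lo, hi)),
               mode="symmetric")
    out = np.empty(img.shape, dtype=np.float64)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = p[i : i + size, j : j + size].sum() / (size * size)
    return out
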
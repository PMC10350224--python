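"""Rolling-shutter acquisition timing, actuator tracking and image formation.

The instrument sweeps the waist of one (single mode) or two (dual mode)
light sheets along the camera row axis, synchronised with the sCMOS
rolling shutter.  In dual mode the two active shutter bands are always
separated by half the frame (1024 rows on a 2048-row chip) and each
sheet covers only half of the field of view, so at equal frame time the
per-row exposure doubles — the signal advantage of the dual-foci scheme
— or, equivalently, the frame time can be shortened four-fold at equal
per-row exposure because the actuator travel is also halved.

The axial sweep is commanded by a sawtooth waveform: a linear rise over
the per-frame acquisition time (pfAT) T followed by a flyback of
duration F during which the laser is gated off.  The linear focus
actuator (LFA) carrying the remote-focusing mirror is modelled as a
second-order low-pass system; its tracking error translates directly
into a sheet-waist/shutter synchronisation offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal as _signal

from .optics import BeamParameters, ImmersionScaling, beam_radius, pixel_size

__all__ = [
    "CameraConfig",
    "ShutterSchedule",
    "DriveWaveform",
    "IdealActuator",
    "LagActuator",
    "LfaModel",
    "SimulatedStack",
    "shutter_schedule",
    "generate_drive_waveform",
    "lfa_track",
    "synchronization_map",
    "simulate_stack",
    "snr_ratio_model",
]

Mode = Literal["single", "dual"]

#: Validated per-mode minimum full-FOV sweep times for the default
#: instrument: 100 ms over the full range in single mode, 25 ms over the
#: half range in dual mode (configuration facts, not derived here).
DEFAULT_SWEEP_TIME_S = {"single": 0.100, "dual": 0.025}


@dataclass(frozen=True)
class CameraConfig:
    """sCMOS geometry, shutter mode and noise model.

    ``shutter_width`` W is the number of simultaneously active rows per
    shutter band.  The readout direction is fixed (unidirectional chip),
    which is what forces the flyback in the drive waveform.
    """

    n_rows: int = 2048
    n_cols: int = 2048
    shutter_width: int = 64
    mode: Mode = "dual"
    offset_counts: float = 100.0
    read_noise_counts: float = 1.6
    conversion_gain: float = 0.5  # counts per photoelectron
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.mode not in ("single", "dual"):
            raise ValueError(f"mode must be 'single' or 'dual', got {self.mode!r}")
        if self.mode == "dual" and self.n_rows % 2 != 0:
            raise ValueError("dual mode requires an even number of rows")
        wmax = self.n_rows if self.mode == "single" else self.n_rows // 2
        if not (1 <= self.shutter_width <= wmax):
            raise ValueError(
                f"shutter width {self.shutter_width} out of range [1, {wmax}] "
                f"for {self.mode} mode"
            )
        if self.offset_counts < 0 or self.read_noise_counts < 0:
            raise ValueError("offset and read noise must be non-negative")
        if self.conversion_gain <= 0:
            raise ValueError("conversion gain must be positive")

    @property
    def rows_per_shutter(self) -> int:
        return self.n_rows if self.mode == "single" else self.n_rows // 2

    @property
    def saturation_counts(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class ShutterSchedule:
    """Per-row activation window [t_on, t_off) within one frame, seconds."""

    t_on: np.ndarray
    t_off: np.ndarray
    mode: Mode
    frame_time_s: float

    @property
    def per_row_exposure_s(self) -> float:
        exp = self.t_off - self.t_on
        if not np.allclose(exp, exp[0]):
            raise AssertionError("per-row exposure is not constant")
        return float(exp[0])

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.t_on + self.t_off)


def shutter_schedule(cam: CameraConfig, frame_time_s: float) -> ShutterSchedule:
    """Rolling-shutter activation windows for one frame of duration T.

    Single mode: row r is active on ``[r*tau, r*tau + W*tau)`` with
    ``tau = T / n_rows``.  Dual mode: the two shutter bands start at
    rows 0 and n_rows/2 and sweep concurrently, so rows r and
    r + n_rows/2 share ``[r*tau_d, r*tau_d + W*tau_d)`` with
    ``tau_d = T / (n_rows/2)``.  Per-row exposure is hence W*T/n_rows
    (single) and 2*W*T/n_rows (dual): exposure doubles at equal T and W.
    """
    if frame_time_s <= 0:
        raise ValueError("frame time must be positive")
    span = cam.rows_per_shutter
    tau = frame_time_s / span
    r = np.arange(cam.n_rows)
    phase = r % span  # identical for rows r and r + span in dual mode
    t_on = phase * tau
    t_off = t_on + cam.shutter_width * tau
    return ShutterSchedule(t_on=t_on, t_off=t_off, mode=cam.mode,
                           frame_time_s=frame_time_s)


@dataclass(frozen=True)
class DriveWaveform:
    """Sampled sawtooth command for the LFA plus camera/laser gating.

    ``command_um`` rises linearly 0 -> amplitude over the rise (pfAT)
    portion of each period and returns to 0 over the flyback; the laser
    gate is low during flyback; one camera TTL trigger marks each
    period start.
    """

    mode: Mode
    rise_time_s: float
    flyback_time_s: float
    amplitude_um: float
    n_frames: int
    sample_rate_hz: float
    time_s: np.ndarray
    command_um: np.ndarray
    laser_gate: np.ndarray
    trigger_times_s: np.ndarray

    @property
    def period_s(self) -> float:
        return self.rise_time_s + self.flyback_time_s

    def to_frame(self):
        """Waveform as a pandas DataFrame (time, command, trigger, laser gate)."""
        import pandas as pd

        trigger = np.zeros_like(self.time_s)
        idx = np.searchsorted(self.time_s, self.trigger_times_s)
        trigger[np.clip(idx, 0, len(trigger) - 1)] = 1.0
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "command_um": self.command_um,
                "camera_trigger": trigger,
                "laser_gate": self.laser_gate.astype(float),
            }
        )


def generate_drive_waveform(
    mode: Mode,
    rise_time_s: float,
    flyback_time_s: float,
    n_frames: int,
    sample_rate_hz: float,
    amplitude_um: float,
) -> DriveWaveform:
    """Sawtooth drive with flyback, camera triggers and laser gating.

    The amplitude is the sample-space sweep range: the full FOV in
    single mode, half the FOV in dual mode (each sheet covers half the
    frame).  The default flyback is 10% of the rise time when the caller
    does not specify one.
    """
    if rise_time_s <= 0 or flyback_time_s < 0:
        raise ValueError("rise time must be positive, flyback non-negative")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if sample_rate_hz <= 0:
        raise ValueError("sample rate must be positive")
    shortest = min(rise_time_s, flyback_time_s) if flyback_time_s > 0 else rise_time_s
    if sample_rate_hz < 10.0 / shortest:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz too low to resolve the waveform "
            f"(need >= {10.0 / shortest:.1f} Hz)"
        )
    period = rise_time_s + flyback_time_s
    t = np.arange(math.ceil(n_frames * period * sample_rate_hz)) / sample_rate_hz
    phase = t % period
    in_rise = phase < rise_time_s
    command = np.where(
        in_rise,
        amplitude_um * phase / rise_time_s,
        amplitude_um * (1.0 - (phase - rise_time_s) / max(flyback_time_s, 1e-300)),
    )
    # beyond the requested frames the command is irrelevant; clip to range
    command = np.clip(command, 0.0, amplitude_um)
    triggers = np.arange(n_frames) * period
    return DriveWaveform(
        mode=mode,
        rise_time_s=rise_time_s,
        flyback_time_s=flyback_time_s,
        amplitude_um=amplitude_um,
        n_frames=n_frames,
        sample_rate_hz=sample_rate_hz,
        time_s=t,
        command_um=command,
        laser_gate=in_rise,
        trigger_times_s=triggers,
    )


class IdealActuator:
    """Actuator that follows the command exactly (zero response time)."""

    def track(self, wave: DriveWaveform) -> tuple[np.ndarray, np.ndarray]:
        return wave.command_um.copy(), np.zeros_like(wave.command_um)


@dataclass(frozen=True)
class LagActuator:
    """Pure transport delay: position(t) = command(t - lag)."""

    lag_s: float

    def track(self, wave: DriveWaveform) -> tuple[np.ndarray, np.ndarray]:
        if self.lag_s < 0:
            raise ValueError("lag must be non-negative")
        shift = self.lag_s * wave.sample_rate_hz
        n = int(round(shift))
        pos = np.empty_like(wave.command_um)
        if n == 0:
            pos[:] = wave.command_um
        else:
            pos[:n] = wave.command_um[0]
            pos[n:] = wave.command_um[:-n] if n < len(pos) else wave.command_um[0]
        return pos, pos - wave.command_um


@dataclass(frozen=True)
class LfaModel:
    """Voice-coil linear focus actuator as a second-order low-pass system.

    Catalogue figures for the default actuator: 10 mm travel, 50 nm
    repeatability, 3 ms response (settle) time at maximum travel.  The
    natural frequency defaults to the value for which the 2% settling
    time ``~ 4 / (zeta * wn)`` of the unit step equals the response
    time.  Tracking error of the LTI model scales linearly with the
    commanded amplitude and vanishes as the sweep slows down.
    """

    travel_range_mm: float = 10.0
    repeatability_nm: float = 50.0
    response_time_s: float = 0.003
    damping: float = 0.8
    natural_frequency_rad_s: float | None = None

    def __post_init__(self) -> None:
        if self.response_time_s < 0:
            raise ValueError("response time must be non-negative")
        if self.response_time_s > 0 and self.damping <= 0:
            raise ValueError("unstable parameterization: damping must be > 0")

    @property
    def wn(self) -> float:
        if self.natural_frequency_rad_s is not None:
            return self.natural_frequency_rad_s
        return 4.0 / (self.damping * self.response_time_s)

    @property
    def is_ideal(self) -> bool:
        return self.response_time_s == 0

    def track(self, wave: DriveWaveform) -> tuple[np.ndarray, np.ndarray]:
        if self.is_ideal:
            return IdealActuator().track(wave)
        wn = self.wn
        if wn <= 0:
            raise ValueError("unstable parameterization: natural frequency <= 0")
        sys = _signal.lti([wn**2], [1.0, 2.0 * self.damping * wn, wn**2])
        # the sawtooth starts at zero, so a zero initial state is the
        # resting actuator
        _, pos, _ = _signal.lsim(sys, wave.command_um, wave.time_s)
        return pos, pos - wave.command_um


def lfa_track(wave: DriveWaveform, lfa) -> tuple[np.ndarray, np.ndarray]:
    """Actuator position trace and tracking error (actual - commanded)."""
    return lfa.track(wave)


def synchronization_map(
    wave: DriveWaveform,
    lfa,
    cam: CameraConfig,
    extra_offset_um: float = 0.0,
) -> np.ndarray:
    """Per-row sheet-waist offset (um) at each row's exposure midpoint.

    Row r's object plane is the position the ideal sweep reaches at the
    midpoint of r's activation window, so an ideal actuator gives zero
    offset everywhere; with a real actuator the offset is its tracking
    error sampled at the midpoint.  In dual mode rows r and r + 1024
    share a window and therefore have identical offsets by construction.
    ``extra_offset_um`` imposes a constant defocus on top (used to study
    how synchronisation error degrades the axial PSF).
    """
    if wave.mode != cam.mode:
        raise ValueError(f"waveform mode {wave.mode!r} != camera mode {cam.mode!r}")
    sched = shutter_schedule(cam, wave.rise_time_s)
    mid = sched.midpoints()
    pos, err = lfa.track(wave)
    # sample the tracking error of the first full period at the midpoints
    offsets = np.interp(mid, wave.time_s, err)
    return offsets + extra_offset_um


@dataclass
class SimulatedStack:
    """Acquired 3D stack: (frames, rows, cols) 16-bit counts + metadata."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]  # (z, row, col)
    metadata: dict

    def __post_init__(self) -> None:
        if self.data.dtype != np.uint16:
            raise ValueError("stack data must be uint16")


def _expected_bead_image(
    phantom,
    beam: BeamParameters,
    cam: CameraConfig,
    wave: DriveWaveform,
    offsets_um: np.ndarray,
    px: float,
    exposure_s: float,
    detection_fwhm_um: float,
    n_frames: int,
) -> np.ndarray:
    """Expected photoelectrons per voxel for point-ish emitters.

    Axes: x (camera rows) = sweep/propagation axis, y (cols), z (stage /
    detection axis).  The sheet is thin in z; its thickness at row r is
    the beam radius evaluated at that row's synchronisation offset.
    Widths combine in quadrature: emitters are Gaussian blobs of
    FWHM = diameter, detection blur is isotropic.
    """
    fw2sig = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sig_det = detection_fwhm_um * fw2sig
    sig_bead = phantom.diameter_um * fw2sig
    sig_lat2 = sig_det**2 + sig_bead**2

    expected = np.zeros((n_frames, cam.n_rows, cam.n_cols))
    x_rows = np.arange(cam.n_rows) * px
    y_cols = np.arange(cam.n_cols) * px
    z_frames = np.arange(n_frames) * px

    for (x_e, y_e, z_e), inten in zip(phantom.positions_um, phantom.intensities):
        r_e = int(np.clip(round(x_e / px), 0, cam.n_rows - 1))
        # sheet intensity cross-section sigma = w/2 at this row's offset
        w_here = beam_radius(beam, float(offsets_um[r_e]))
        sig_z2 = (w_here / 2.0) ** 2 + sig_det**2 + sig_bead**2
        sig_lat = math.sqrt(sig_lat2)
        sig_z = math.sqrt(sig_z2)

        rx = _gauss_window(x_rows, x_e, sig_lat)
        ry = _gauss_window(y_cols, y_e, sig_lat)
        rz = _gauss_window(z_frames, z_e, sig_z)
        gx = np.exp(-0.5 * ((x_rows[rx] - x_e) / sig_lat) ** 2)
        gy = np.exp(-0.5 * ((y_cols[ry] - y_e) / sig_lat) ** 2)
        gz = np.exp(-0.5 * ((z_frames[rz] - z_e) / sig_z) ** 2)
        expected[np.ix_(rz, rx, ry)] += (
            inten * exposure_s * gz[:, None, None] * gx[None, :, None] * gy[None, None, :]
        )
    return expected


def _gauss_window(coords: np.ndarray, center: float, sigma: float, k: float = 6.0):
    lo = np.searchsorted(coords, center - k * sigma)
    hi = np.searchsorted(coords, center + k * sigma)
    return np.arange(max(lo, 0), min(hi + 1, len(coords)))


def simulate_stack(
    phantom,
    beam: BeamParameters,
    scaling: ImmersionScaling,
    cam: CameraConfig,
    wave: DriveWaveform,
    lfa=None,
    seed: int = 0,
    n: float = 1.33,
    detection_fwhm_um: float = 0.83,
    extra_sync_offset_um: float = 0.0,
) -> SimulatedStack:
    """Image a phantom through the swept-sheet + rolling-shutter model.

    Expected signal at a voxel is emitter brightness x per-row exposure
    x sheet cross-section (Gaussian of width w evaluated at the row's
    synchronisation offset) x isotropic detection blur.  Counts are then
    ``offset + gain * Poisson(photoelectrons) + N(0, read_noise)``
    clipped to the bit depth.  The stage steps one lateral pixel per
    frame (isotropic voxels) and ``wave.n_frames`` planes are acquired.
    Fully reproducible for a fixed seed.
    """
    sched = shutter_schedule(cam, wave.rise_time_s)
    exposure = sched.per_row_exposure_s
    if exposure <= 0:
        raise ValueError("empty active window")
    lfa = lfa if lfa is not None else IdealActuator()
    offsets = synchronization_map(wave, lfa, cam, extra_offset_um=extra_sync_offset_um)
    px = pixel_size(scaling, n)

    expected = _expected_bead_image(
        phantom, beam, cam, wave, offsets, px, exposure,
        detection_fwhm_um, wave.n_frames,
    )
    expected += phantom.background_rate * exposure

    rng = np.random.default_rng(seed)
    electrons = rng.poisson(expected).astype(np.float64)
    counts = (
        cam.offset_counts
        + cam.conversion_gain * electrons
        + rng.normal(0.0, cam.read_noise_counts, size=expected.shape)
    )
    saturated = counts > cam.saturation_counts
    if saturated.any():
        import warnings

        warnings.warn(
            f"{int(saturated.sum())} voxels saturated at {cam.saturation_counts}",
            stacklevel=2,
        )
    counts = np.clip(np.rint(counts), 0, cam.saturation_counts).astype(np.uint16)
    return SimulatedStack(
        data=counts,
        voxel_size_um=(px, px, px),
        metadata={
            "mode": cam.mode,
            "rise_time_s": wave.rise_time_s,
            "flyback_time_s": wave.flyback_time_s,
            "per_row_exposure_s": exposure,
            "immersion_index": n,
            "detection_fwhm_um": detection_fwhm_um,
            "seed": seed,
        },
    )


def snr_ratio_model(
    photon_rate: float,
    background_rate: float,
    read_noise: float,
    exposure_a: float,
    exposure_b: float,
) -> float:
    """Predicted SNR ratio between two exposures under a sCMOS noise model.

    SNR(e) = S e / sqrt(S e + B e + sigma_r^2) with signal rate S,
    background rate B (photoelectrons per second) and read noise
    sigma_r (electrons rms).  In the shot-noise limit the ratio tends
    to sqrt(e_a/e_b); in the read-noise limit it tends to e_a/e_b.
    """
    if photon_rate < 0 or background_rate < 0 or read_noise < 0:
        raise ValueError("rates and read noise must be non-negative")
    if exposure_a <= 0 or exposure_b <= 0:
        raise ValueError("exposures must be positive")

    def _snr(e: float) -> float:
        var = photon_rate * e + background_rate * e + read_noise**2
        if var == 0:
            raise ZeroDivisionError("zero noise variance: SNR undefined")
        return photon_rate * e / math.sqrt(var)

    denom = _snr(exposure_b)
    if denom == 0:
        raise ZeroDivisionError("zero SNR in denominator")
    return _snr(exposure_a) / denom
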
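"""Stack I/O, plain-text configuration and run provenance.

Stacks are multi-page 16-bit TIFFs with a JSON metadata sidecar
(``<stack>.tif.json``) holding voxel size, acquisition metadata and the
hash of the configuration that produced them.  Configuration files use
one documented plain-text dialect::

    # comment
    camera.mode = dual
    modes.dual_sweep_time_s = 0.025

Unknown keys and out-of-range values are reported as a single itemized
error; every key not present in the file takes its documented default
(logged at debug level with provenance).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .acquisition import CameraConfig
from .cnn import ClassifierConfig
from .optics import BeamParameters, ImmersionScaling, RemoteFocusGeometry
from .triage import TriageParams

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "load_config",
    "save_config",
    "config_hash",
]

log = logging.getLogger("dualsweep")


def write_stack(stack, path, config_hash_value: str | None = None) -> None:
    """Write a SimulatedStack (or uint16 array) as multi-page TIFF + sidecar."""
    path = Path(path)
    data = stack.data if hasattr(stack, "data") else np.asarray(stack)
    if data.dtype != np.uint16:
        raise ValueError(f"stacks are stored as uint16, got {data.dtype}")
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = dict(getattr(stack, "metadata", {}))
    meta["voxel_size_um"] = list(getattr(stack, "voxel_size_um", (1.0, 1.0, 1.0)))
    if config_hash_value is not None:
        meta["config_hash"] = config_hash_value
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_stack(path):
    """Read a multi-page 16-bit TIFF and its metadata sidecar.

    Returns (data, metadata).  Non-16-bit files raise instead of being
    silently promoted.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # corrupt / truncated file
        raise OSError(f"unreadable TIFF {path}: {exc}") from exc
    if data.dtype != np.uint16:
        raise ValueError(
            f"{path}: expected 16-bit stack, got {data.dtype}; convert explicitly"
        )
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return data, meta


# --- configuration ----------------------------------------------------------

def _positive(x):
    return x > 0


def _non_negative(x):
    return x >= 0


#: key -> (type, default, validator, description)
CONFIG_SCHEMA: dict[str, tuple] = {
    "camera.n_rows": (int, 2048, _positive, "sensor rows"),
    "camera.n_cols": (int, 2048, _positive, "sensor columns"),
    "camera.shutter_width": (int, 64, _positive, "active rows per shutter"),
    "camera.mode": (str, "dual", lambda v: v in ("single", "dual"), "shutter mode"),
    "camera.offset_counts": (float, 100.0, _non_negative, "camera offset"),
    "camera.read_noise_counts": (float, 1.6, _non_negative, "read noise rms"),
    "camera.conversion_gain": (float, 0.5, _positive, "counts per electron"),
    "camera.bit_depth": (int, 16, _positive, "ADC bit depth"),
    "optics.reference_magnification": (float, 15.28, _positive, "M at n_ref"),
    "optics.reference_index": (float, 1.33, lambda v: v >= 1, "calibration RI"),
    "optics.sensor_pitch_um": (float, 6.5, _positive, "physical pixel pitch"),
    "optics.wavelength_um": (float, 0.488, _positive, "excitation wavelength"),
    "optics.waist_radius_um": (float, 0.4, _positive, "sheet waist w0"),
    "optics.immersion_index": (float, 1.33, lambda v: v >= 1, "immersion RI"),
    "optics.axial_gain": (float, 1.0, _positive, "sample um per mirror um"),
    "optics.separation_rows": (int, 1024, _positive, "dual foci separation"),
    "optics.detection_fwhm_um": (float, 0.83, _positive, "detection blur FWHM"),
    "modes.single_sweep_time_s": (float, 0.100, _positive, "single-mode pfAT"),
    "modes.dual_sweep_time_s": (float, 0.025, _positive, "dual-mode pfAT"),
    "modes.flyback_fraction": (float, 0.1, _non_negative, "flyback / rise time"),
    "phantom.n_beads": (int, 50, _non_negative, "beads per volume"),
    "phantom.bead_diameter_um": (float, 0.5, _positive, "bead diameter"),
    "phantom.bead_intensity": (float, 2.0e5, _positive, "photoelectrons/s"),
    "phantom.min_separation_um": (float, 5.0, _non_negative, "bead spacing"),
    "tiles.n_per_class": (int, 2080, _positive, "tiles per class"),
    "tiles.planes": (int, 8, _positive, "tile planes"),
    "tiles.height": (int, 96, _positive, "tile height px"),
    "tiles.width": (int, 96, _positive, "tile width px"),
    "tiles.contrast": (float, 10.0, _non_negative, "signal / noise sigma"),
    "tiles.blob_count": (int, 5, _non_negative, "blobs per tile"),
    "tiles.filament_count": (int, 2, _non_negative, "filaments per tile"),
    "triage.kernel_small": (int, 20, _positive, "small box kernel"),
    "triage.kernel_large": (int, 40, _positive, "large box kernel"),
    "triage.intensity_threshold": (float, 2.5, _positive, "difference cutoff"),
    "triage.informative_cutoff": (float, 0.1, lambda v: 0 < v < 100, "score %"),
    "triage.probability_threshold": (float, 0.5, lambda v: 0 <= v <= 1, "CNN cut"),
    "planner.overlap": (float, 0.1, lambda v: 0 <= v <= 0.9, "tile overlap"),
    "planner.tile_depth_um": (float, 140.0, _positive, "tile axial depth"),
    "planner.channels": (int, 1, _positive, "colour channels"),
    "planner.stack_delay_s": (float, 0.0, _non_negative, "between-stack delay"),
    "run.seed": (int, 0, _non_negative, "global seed"),
    "run.output_dir": (str, ".", lambda v: True, "output directory"),
    "run.verbosity": (str, "info", lambda v: v in ("quiet", "info", "debug"),
                      "logging level"),
}


@dataclass
class RunConfig:
    """Validated flat key-value configuration plus typed accessors."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, key: str):
        return self.values[key]

    def camera(self) -> CameraConfig:
        v = self.values
        return CameraConfig(
            n_rows=v["camera.n_rows"],
            n_cols=v["camera.n_cols"],
            shutter_width=v["camera.shutter_width"],
            mode=v["camera.mode"],
            offset_counts=v["camera.offset_counts"],
            read_noise_counts=v["camera.read_noise_counts"],
            conversion_gain=v["camera.conversion_gain"],
            bit_depth=v["camera.bit_depth"],
        )

    def scaling(self) -> ImmersionScaling:
        v = self.values
        return ImmersionScaling(
            reference_magnification=v["optics.reference_magnification"],
            reference_index=v["optics.reference_index"],
            sensor_pitch_um=v["optics.sensor_pitch_um"],
            n_rows=v["camera.n_rows"],
            n_cols=v["camera.n_cols"],
        )

    def beam(self) -> BeamParameters:
        v = self.values
        return BeamParameters(
            wavelength_um=v["optics.wavelength_um"],
            refractive_index=v["optics.immersion_index"],
            waist_radius_um=v["optics.waist_radius_um"],
        )

    def geometry(self) -> RemoteFocusGeometry:
        v = self.values
        return RemoteFocusGeometry.calibrated(
            self.scaling(),
            n=v["optics.immersion_index"],
            separation_rows=v["optics.separation_rows"],
            axial_gain=v["optics.axial_gain"],
        )

    def triage_params(self) -> TriageParams:
        v = self.values
        return TriageParams(
            kernel_small=v["triage.kernel_small"],
            kernel_large=v["triage.kernel_large"],
            intensity_threshold=v["triage.intensity_threshold"],
            informative_cutoff=v["triage.informative_cutoff"],
        )

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig()

    def sweep_time_s(self, mode: str | None = None) -> float:
        mode = mode or self.values["camera.mode"]
        key = "modes.single_sweep_time_s" if mode == "single" else "modes.dual_sweep_time_s"
        return self.values[key]

    def flyback_s(self, mode: str | None = None) -> float:
        return self.sweep_time_s(mode) * self.values["modes.flyback_fraction"]

    @property
    def hash(self) -> str:
        return config_hash(self)


def config_hash(cfg: RunConfig) -> str:
    payload = "\n".join(f"{k}={cfg.values[k]!r}" for k in sorted(cfg.values))
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def load_config(path=None) -> RunConfig:
    """Parse and validate a config file; missing file/keys take defaults.

    All problems (unknown keys, unparsable or out-of-range values) are
    collected and raised together as one itemized ValueError.
    """
    raw: dict[str, str] = {}
    if path is not None and Path(path).exists():
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value', got {line!r}")
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()

    problems: list[str] = []
    values: dict = {}
    for key, sval in raw.items():
        if key not in CONFIG_SCHEMA:
            problems.append(f"unknown key {key!r}")
            continue
        typ, _default, check, desc = CONFIG_SCHEMA[key]
        try:
            val = typ(sval)
        except ValueError:
            problems.append(f"{key}: cannot parse {sval!r} as {typ.__name__}")
            continue
        if not check(val):
            problems.append(f"{key}: value {val!r} out of range ({desc})")
            continue
        values[key] = val
    for key, (typ, default, _check, _desc) in CONFIG_SCHEMA.items():
        if key not in values:
            values[key] = default
            log.debug("config %s = %r (default)", key, default)

    cfg = RunConfig(values=values)
    # cross-field invariants are enforced by the domain objects
    try:
        cfg.camera()
    except ValueError as exc:
        problems.append(f"camera: {exc}")
    if problems:
        raise ValueError(
            "invalid configuration:\n  " + "\n  ".join(problems)
        )
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    lines = [f"{k} = {cfg.values[k]}" for k in sorted(cfg.values)]
    Path(path).write_text("\n".join(lines) + "\n")
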
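"""Configuration schema for the middle-ear / transducer pipeline.

One flat document (YAML or JSON) with sections ``middle_ear``, ``transducer``,
``signal_chain``, ``noise``, ``control``, ``experiment`` and ``fitting``
describes a complete run.  Every section validates its own invariants on
construction; unknown keys are rejected so that typos fail loudly.

The shipped defaults (``earloop/data/default.yaml``) describe a synthetic
human middle ear: a four-mass ossicular chain (eardrum, malleus–incus block,
stapes, cochlear fluid load) with a main transfer-function resonance near
1 kHz, and a 35 mg free-floating two-plate piezo transducer for the
incudostapedial joint gap.  The electromechanical couplings and the noise
floor in that file are produced by the scripted calibration procedure in
:mod:`earloop.calibrate`, not chosen by hand.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "MiddleEarConfig",
    "TransducerConfig",
    "SignalChainConfig",
    "NoiseModel",
    "ForwardPathConfig",
    "ControlConfig",
    "ExperimentConfig",
    "FittingConfig",
    "RunConfig",
    "load_config",
    "dump_config",
    "default_config",
]

#: Valid middle-ear topology states.
STATES = ("intact", "transducer_idle", "transducer_active",
          "transducer_fixed_frame")


class ConfigError(ValueError):
    """Configuration parse or validation failure (names section and field)."""


def _coerce_floats(obj: Any) -> None:
    """Coerce declared-float fields (YAML 1.1 reads ``1e4`` as a string)."""
    for f in fields(obj):
        if f.type in ("float", float):
            val = getattr(obj, f.name)
            try:
                setattr(obj, f.name, float(val))
            except (TypeError, ValueError) as exc:
                raise ConfigError(
                    f"{type(obj).__name__}.{f.name}: not a number: "
                    f"{val!r}") from exc


def _require_positive(section: str, obj: Any, names: list[str],
                      allow_zero: tuple[str, ...] = ()) -> None:
    for name in names:
        val = getattr(obj, name)
        if name in allow_zero:
            if val < 0:
                raise ConfigError(f"{section}.{name} must be >= 0, got {val}")
        elif val <= 0:
            raise ConfigError(f"{section}.{name} must be > 0, got {val}")


@dataclass
class MiddleEarConfig:
    """Lumped parameters of the ossicular chain (SI units).

    The chain is eardrum -> malleus–incus block -> (incudostapedial joint or
    transducer) -> stapes -> annular ligament + cochlear fluid load.  The
    cochlea is a simplified spring–mass–damper hung on the stapes; it is the
    dominant energy sink of the network.
    """

    eardrum_area: float = 6.0e-5          # m^2, converts Pa -> N
    eardrum_mass: float = 1.0e-5          # kg
    eardrum_stiffness: float = 3560.0      # N/m, drum suspension to ground
    eardrum_damping: float = 0.15         # N s/m
    malleus_coupling_stiffness: float = 1890.0   # N/m, manubrium link
    malleus_coupling_damping: float = 0.08
    malleus_incus_mass: float = 5.5e-5    # kg
    ligament_stiffness: float = 70.0     # N/m, ossicular suspension
    ligament_damping: float = 0.05
    isj_stiffness: float = 12000.0          # N/m, incudostapedial joint
    isj_damping: float = 0.1
    stapes_mass: float = 3.5e-6           # kg
    annular_stiffness: float = 2160.0     # N/m
    annular_damping: float = 0.15
    cochlea_mass: float = 1.0e-5          # kg, entrained fluid
    cochlea_stiffness: float = 650.0     # N/m
    cochlea_damping: float = 0.8         # N s/m, main dissipation
    loss_factor: float = 0.0              # optional structural damping
    contact_diameter_mm: float = 1.0      # stapes-head contact (informational)
    state: str = "intact"

    def __post_init__(self) -> None:
        _coerce_floats(self)
        if self.state not in STATES:
            raise ConfigError(
                f"middle_ear.state must be one of {STATES}, got {self.state!r}")
        _require_positive(
            "middle_ear", self,
            [f.name for f in fields(self)
             if f.name not in ("state", "loss_factor")],
            allow_zero=("eardrum_damping", "malleus_coupling_damping",
                        "ligament_damping", "isj_damping", "annular_damping"))
        if self.loss_factor < 0:
            raise ConfigError("middle_ear.loss_factor must be >= 0")

    def with_state(self, state: str) -> "MiddleEarConfig":
        return dataclasses.replace(self, state=state)


@dataclass
class TransducerConfig:
    """Free-floating two-plate piezo device in the joint gap.

    Sensor and actuator plates are ideal linear electromechanical couplings
    (V per N and N per V) in parallel with passive plate stiffness/damping;
    both plates share one titanium frame whose 35 mg inertial mass is the
    only support of the device.
    """

    frame_mass: float = 35.0e-6           # kg, whole-device inertial mass
    sensor_coupling: float = 81.534706052  # V per N of sensor-plate force
    actuator_coupling: float = 4.2292024467e-4  # N per V of drive
    sensor_plate_stiffness: float = 5.0e4  # N/m
    sensor_plate_damping: float = 0.3
    actuator_plate_stiffness: float = 5.0e4
    actuator_plate_damping: float = 0.3
    max_drive_voltage: float = 1.0        # V, hard clip of the DAC output
    length_mm: float = 4.0                # informational footprint
    width_mm: float = 2.5
    thickness_mm: float = 1.0

    def __post_init__(self) -> None:
        _coerce_floats(self)
        _require_positive(
            "transducer", self, [f.name for f in fields(self)],
            allow_zero=("sensor_plate_damping", "actuator_plate_damping"))


@dataclass
class SignalChainConfig:
    """Analogue/digital signal chain around the controller."""

    preamp_gain: float = 1000.0           # sensor preamplifier
    adc_bits: int = 16
    adc_range: float = 10.0               # V, symmetric +-range
    antialias_order: int = 4              # Butterworth, analogue
    antialias_cutoff: float = 4000.0      # Hz
    sample_rate: float = 10000.0          # Hz

    def __post_init__(self) -> None:
        _coerce_floats(self)
        self.adc_bits = int(self.adc_bits)
        if self.adc_bits < 1:
            raise ConfigError("signal_chain.adc_bits must be >= 1")
        _require_positive("signal_chain", self,
                          ["preamp_gain", "adc_range", "antialias_order",
                           "antialias_cutoff", "sample_rate"])
        if self.antialias_cutoff >= self.sample_rate / 2:
            raise ConfigError("signal_chain.antialias_cutoff must be < fs/2")

    @property
    def delta_u(self) -> float:
        """ADC voltage resolution: full range divided by 2**bits."""
        return 2.0 * self.adc_range / (2 ** self.adc_bits)

    @property
    def sample_period(self) -> float:
        return 1.0 / self.sample_rate


@dataclass
class NoiseModel:
    """Sensor noise referred to the sensor output (before the preamp)."""

    rms_volts: float = 2.7287164880e-7
    shape: str = "white"                  # "white" or "pink"

    def __post_init__(self) -> None:
        _coerce_floats(self)
        if self.rms_volts < 0:
            raise ConfigError("noise.rms_volts must be >= 0")
        if self.shape not in ("white", "pink"):
            raise ConfigError("noise.shape must be 'white' or 'pink'")


@dataclass
class ForwardPathConfig:
    """Digital forward path: scalar gain, low-pass filter, processing delay."""

    gain_db: float = 0.0
    lowpass_order: int = 4                # Butterworth
    lowpass_cutoff: float = 4000.0        # Hz
    delay_samples: int = 1                # >= 1: sampled operation

    def __post_init__(self) -> None:
        _coerce_floats(self)
        if self.delay_samples < 1:
            raise ConfigError("control.forward.delay_samples must be >= 1")
        _require_positive("control.forward", self,
                          ["lowpass_order", "lowpass_cutoff"])


@dataclass
class ControlConfig:
    """Adaptive feedback canceller and stability-analysis settings."""

    forward: ForwardPathConfig = field(default_factory=ForwardPathConfig)
    lms_taps: int = 100
    lms_step: float = 0.05
    lms_eps: float = 1.0e-8
    lms_leakage: float = 0.0
    normalized: bool = True
    msg_ceiling_db: float = 60.0
    seed: int = 20140807

    def __post_init__(self) -> None:
        if isinstance(self.forward, dict):
            self.forward = ForwardPathConfig(**self.forward)
        _coerce_floats(self)
        if self.lms_taps < 1:
            raise ConfigError("control.lms_taps must be >= 1")
        if not (0.0 < self.lms_step < 2.0):
            raise ConfigError("control.lms_step must be in (0, 2)")
        if self.lms_eps <= 0 or self.lms_leakage < 0:
            raise ConfigError("control.lms_eps > 0 and lms_leakage >= 0 required")


@dataclass
class ExperimentConfig:
    """Protocol / measurement settings."""

    multisine_points: int = 2048
    stimulus_f_min: float = 100.0         # Hz, lowest multisine component
    stimulus_f_max: float = 2500.0        # Hz, highest multisine component
    stimulus_spl: float = 50.0            # dB SPL at the eardrum (stage 5)
    calibrated_band: tuple[float, float] = (250.0, 2500.0)
    grid_points: int = 128
    grid_f_min: float = 100.0
    grid_f_max: float = 5000.0
    sweep_step_db: float = 0.5
    sweep_start_db: float = -20.0
    mic_gain_pa_per_mm_s: float = 50.0    # inner-ear microphone emulation
    mic_corner_hz: float = 150.0

    def __post_init__(self) -> None:
        _coerce_floats(self)
        if isinstance(self.calibrated_band, list):
            self.calibrated_band = tuple(self.calibrated_band)
        _require_positive("experiment", self,
                          ["multisine_points", "stimulus_f_min",
                           "stimulus_f_max", "grid_points", "grid_f_min",
                           "grid_f_max", "mic_gain_pa_per_mm_s",
                           "mic_corner_hz"])
        if not (0.5 <= self.sweep_step_db <= 3.0):
            raise ConfigError("experiment.sweep_step_db must be in [0.5, 3] dB")


@dataclass
class FittingConfig:
    """Audiogram fitting settings (Berger-style half-gain rule by default)."""

    berger_coefficients: dict[float, float] = field(default_factory=dict)
    default_coefficient: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.default_coefficient <= 1.0):
            raise ConfigError("fitting.default_coefficient must be in (0, 1]")
        self.berger_coefficients = {
            float(k): float(v) for k, v in self.berger_coefficients.items()}


_SECTION_TYPES: dict[str, type] = {
    "middle_ear": MiddleEarConfig,
    "transducer": TransducerConfig,
    "signal_chain": SignalChainConfig,
    "noise": NoiseModel,
    "control": ControlConfig,
    "experiment": ExperimentConfig,
    "fitting": FittingConfig,
}


@dataclass
class RunConfig:
    """Complete validated run description."""

    middle_ear: MiddleEarConfig = field(default_factory=MiddleEarConfig)
    transducer: TransducerConfig = field(default_factory=TransducerConfig)
    signal_chain: SignalChainConfig = field(default_factory=SignalChainConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    control: ControlConfig = field(default_factory=ControlConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    seed: int = 20140807
    output_dir: str = "results"

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["experiment"]["calibrated_band"] = list(
            self.experiment.calibrated_band)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("config document must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for name, typ in _SECTION_TYPES.items():
            if name in data:
                section = data[name]
                if not isinstance(section, dict):
                    raise ConfigError(f"section {name!r} must be a mapping")
                legal = {f.name for f in fields(typ)}
                bad = set(section) - legal
                if bad:
                    raise ConfigError(
                        f"section {name!r}: unknown keys {sorted(bad)}")
                try:
                    kwargs[name] = typ(**section)
                except ConfigError:
                    raise
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"section {name!r}: {exc}") from exc
        for scalar in ("seed", "output_dir"):
            if scalar in data:
                kwargs[scalar] = data[scalar]
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Stable content hash used in output provenance blocks."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        from earloop import __version__
        return {"config_hash": self.config_hash(), "seed": self.seed,
                "version": __version__}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" (line {mark.line + 1})" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{where}: {exc}") from exc
    return RunConfig.from_dict(data or {})


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def default_config() -> RunConfig:
    """The shipped, calibrated default configuration."""
    ref = resources.files("earloop").joinpath("data/default.yaml")
    with resources.as_file(ref) as path:
        return load_config(path)
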
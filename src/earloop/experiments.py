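"""Measurement-protocol pipeline stages on the synthetic middle ear.

Reproduces the bench procedure as five stages:

1. intact ossicular chain — reference transfer function;
2. transducer inserted idle — mass-loaded transfer function and the sensor's
   pressure sensitivity;
3. noise — sensor hearing-threshold curve from the noise floor;
4. actuator performance — stapes output per volt and the frame feedback path;
5. functional gain — stapes velocity at 50 dB SPL eardrum input, transducer
   idle versus aided at the maximum stable gain.

Also provides the inner-ear microphone calibration (multisine drive of the
separated stapes side, cross-spectral transfer estimation) and the opened
incudostapedial-joint impedance comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import RunConfig
from .control import (ForwardPath, LMSFilter, StabilityReport,
                      msg_time_domain, simulate_closed_loop)
from .middle_ear import (OSSICLES, STAPES, HarmonicExcitation,
                         build_middle_ear, build_opened_joint,
                         harmonic_response, joint_point_response, metf)
from .network import FrequencyGrid, FrequencyResponse
from .transducer import (DiscretePlant, FeedbackPath, actuator_response,
                         coupled_plant, equivalent_spl,
                         internal_feedback_path, pressure_from_spl,
                         sensor_sensitivity, sensor_threshold_spl,
                         spl_from_pressure)

__all__ = [
    "MultisineStimulus",
    "make_multisine",
    "CalibrationDataset",
    "calibrate_inner_ear",
    "ProtocolResult",
    "run_protocol",
    "DynamicRangeCurve",
    "dynamic_range",
    "impedance_study",
]


# ---------------------------------------------------------------------------
# multisine stimulus
# ---------------------------------------------------------------------------

@dataclass
class MultisineStimulus:
    """Periodic broadband multisine: flat component amplitudes, seeded phases.

    Components sit on exact FFT bins of an ``n_points`` record at ``fs``, so
    a one-period FFT recovers the amplitudes without leakage.  ``rms``
    rescales the finished signal; phases follow the given seed ("schroeder"
    as seed selects deterministic Schroeder phases instead).
    """

    n_points: int = 2048
    fs: float = 10000.0
    f_min: float = 100.0
    f_max: float = 2500.0
    rms: float = 1.0
    seed: int | str = 20140807

    def __post_init__(self) -> None:
        if self.f_max > self.fs / 2:
            raise ValueError("multisine component above Nyquist")
        if self.f_min <= 0 or self.f_min > self.f_max:
            raise ValueError("need 0 < f_min <= f_max")

    @property
    def bin_spacing(self) -> float:
        return self.fs / self.n_points

    @property
    def bins(self) -> np.ndarray:
        k0 = int(np.ceil(self.f_min / self.bin_spacing))
        k1 = int(np.floor(self.f_max / self.bin_spacing))
        return np.arange(k0, k1 + 1)

    @property
    def frequencies(self) -> np.ndarray:
        return self.bins * self.bin_spacing


def make_multisine(spec: MultisineStimulus) -> tuple[np.ndarray, float]:
    """Synthesise one period; returns ``(signal, crest_factor)``."""
    k = spec.bins
    if k.size == 0:
        raise ValueError("no multisine components in the requested band")
    if spec.seed == "schroeder":
        phases = -np.pi * np.arange(len(k)) * (np.arange(len(k)) + 1) / len(k)
    else:
        rng = np.random.default_rng(int(spec.seed))
        phases = rng.uniform(0.0, 2.0 * np.pi, len(k))
    n = spec.n_points
    t = np.arange(n) / n
    x = np.sum(np.cos(2.0 * np.pi * np.outer(k, t)
                      + phases[:, None]), axis=0)
    rms = float(np.sqrt(np.mean(x ** 2)))
    x *= spec.rms / rms
    crest = float(np.max(np.abs(x)) / spec.rms)
    return x, crest


def _bin_spectrum(x: np.ndarray, n_points: int, bins: np.ndarray,
                  discard: int = 1) -> np.ndarray:
    """Mean one-period complex spectrum at the multisine bins.

    Uses whole periods, discarding the first ``discard`` periods as settling
    time; exact at bin frequencies for periodic stimuli.
    """
    n_periods = len(x) // n_points
    if n_periods <= discard:
        discard = max(0, n_periods - 1)
    segs = x[discard * n_points:(n_periods) * n_points]
    segs = segs.reshape(-1, n_points)
    spec = np.fft.rfft(segs, axis=1) / n_points
    return np.mean(spec, axis=0)[bins]


# ---------------------------------------------------------------------------
# inner-ear microphone calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationDataset:
    """Simultaneous inner-ear pressure / stapes velocity records.

    ``transfer`` is the estimated pressure-to-velocity response at the
    stimulus bins (mm/s per Pa); ``coherence`` the magnitude-squared
    coherence of the estimate per bin.
    """

    pressure: np.ndarray
    velocity: np.ndarray
    frequencies: np.ndarray
    transfer: np.ndarray
    coherence: np.ndarray
    fs: float


def calibrate_inner_ear(cfg: RunConfig, force_amp: float = 1e-4,
                        seed: int | None = None,
                        n_periods: int = 8) -> CalibrationDataset:
    """Estimate the inner-ear microphone transfer from simulated records.

    The model is separated at the incudostapedial joint; a floating-mass
    style force drive (multisine) shakes the stapes head.  The inner-ear
    microphone is emulated as a first-order high-pass conversion from stapes
    velocity to cavity pressure, so the estimation recovers a genuinely
    frequency-dependent transfer.  The velocity-per-pressure transfer is the
    cross-spectrum ratio ``S_pv / S_pp`` averaged over whole periods.
    """
    if force_amp <= 0:
        raise ValueError("excitation force must be > 0")
    exp = cfg.experiment
    seed = cfg.seed if seed is None else seed
    _, stapes_side = build_opened_joint(cfg.middle_ear)
    ss = stapes_side.state_space(inputs=[{STAPES: 1.0}],
                                 outputs=[("velocity", STAPES)])
    fs = cfg.signal_chain.sample_rate
    spec = MultisineStimulus(exp.multisine_points, fs, exp.stimulus_f_min,
                             exp.stimulus_f_max, rms=force_amp, seed=seed)
    period, _ = make_multisine(spec)
    drive = np.tile(period, n_periods)
    ssd = ss.to_discrete(1.0 / fs, method="zoh")
    _, y, _ = sps.dlsim(ssd, drive[:, None])
    vel_mm_s = y[:, 0] * 1e3
    # microphone emulation: velocity -> pressure through a one-pole high-pass
    wc = 2.0 * np.pi * exp.mic_corner_hz
    mic = sps.cont2discrete(([exp.mic_gain_pa_per_mm_s, 0.0], [1.0, wc]),
                            1.0 / fs, method="bilinear")
    pressure = sps.lfilter(mic[0].ravel(), mic[1].ravel(), vel_mm_s)
    if np.allclose(pressure, 0.0):
        raise ValueError("zero pressure record; cannot calibrate")
    bins = spec.bins
    P = _bin_spectrum(pressure, spec.n_points, bins)
    V = _bin_spectrum(vel_mm_s, spec.n_points, bins)
    transfer = (np.conj(P) * V) / (np.conj(P) * P)
    coherence = np.ones(len(bins))  # noiseless synthetic records
    return CalibrationDataset(pressure, vel_mm_s, spec.frequencies,
                              transfer, coherence, fs)


# ---------------------------------------------------------------------------
# five-stage protocol
# ---------------------------------------------------------------------------

@dataclass
class ProtocolResult:
    """Outputs of the five measurement stages on one shared grid."""

    grid: FrequencyGrid
    metf_intact: FrequencyResponse
    metf_idle: FrequencyResponse
    sensitivity: FrequencyResponse          # mV/Pa
    threshold_spl: np.ndarray               # dB SPL per grid frequency
    actuator: FrequencyResponse             # mm/s per V
    actuator_spl: np.ndarray                # equivalent dB SPL at max drive
    feedback: FeedbackPath
    msg_report: StabilityReport
    fg_frequencies: np.ndarray              # multisine bins, Hz
    functional_gain_db: np.ndarray          # aided - idle, dB
    insertion_loss_db: np.ndarray           # idle - intact on the grid, dB
    runs: dict = field(default_factory=dict)


def _stage5_runs(cfg: RunConfig, plant: DiscretePlant,
                 msg_report: StabilityReport
                 ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Aided / idle stapes-velocity spectra at the stage-5 stimulus level."""
    exp = cfg.experiment
    chain = cfg.signal_chain
    p_rms = pressure_from_spl(exp.stimulus_spl)
    spec = MultisineStimulus(exp.multisine_points, chain.sample_rate,
                             exp.stimulus_f_min, exp.stimulus_f_max,
                             rms=p_rms, seed=cfg.seed)
    period, _ = make_multisine(spec)
    n_eval = 6
    stim = np.tile(period, n_eval)

    # idle: actuator never driven; plain open-loop filtering of the stimulus
    y = plant.simulate_open(stim, np.zeros_like(stim))
    v_idle = _bin_spectrum(y[:, 1], spec.n_points, spec.bins)

    forward = ForwardPath.from_config(cfg.control.forward, chain)
    forward = forward.with_gain_db(msg_report.msg_db)
    weights = np.asarray(msg_report.details.get("weights", []), dtype=float)
    lms = LMSFilter(cfg.control.lms_taps, cfg.control.lms_step,
                    cfg.control.lms_eps, cfg.control.lms_leakage,
                    cfg.control.normalized,
                    weights if weights.size else None)
    # weights stay frozen: adapting against a periodic stimulus would bias
    # the canceller toward predicting the stimulus itself
    run = simulate_closed_loop(plant, forward, lms, stim, chain,
                               noise_rms=cfg.noise.rms_volts,
                               rng=np.random.default_rng(cfg.seed + 1),
                               adapt=False,
                               max_drive=cfg.transducer.max_drive_voltage)
    v_aided = _bin_spectrum(run.stapes_velocity, spec.n_points, spec.bins)
    return v_idle, v_aided, {"aided": run, "stimulus_bins": spec.frequencies}


def run_protocol(cfg: RunConfig, grid: FrequencyGrid | None = None,
                 msg_report: StabilityReport | None = None,
                 keep_runs: bool = False) -> ProtocolResult:
    """Execute the five measurement stages and collect all curves.

    Stage 5 drives the eardrum at the configured stimulus level (50 dB SPL
    by default) with the forward gain set to the time-domain maximum stable
    gain (recomputed here unless a report is passed in).
    """
    exp = cfg.experiment
    if grid is None:
        grid = FrequencyGrid.default(exp.grid_points, exp.grid_f_min,
                                     exp.grid_f_max)
    me, td, chain = cfg.middle_ear, cfg.transducer, cfg.signal_chain
    stage = "intact ossicular chain"
    try:
        metf_intact = metf(me.with_state("intact"), grid)
        stage = "insertion of transducer"
        metf_idle = metf(me.with_state("transducer_idle"), grid, td)
        sens = sensor_sensitivity(me, td, grid)
        stage = "noise"
        thresh = sensor_threshold_spl(sens, cfg.noise)
        stage = "actuator performance"
        act = actuator_response(me, td, td.max_drive_voltage, grid)
        act_spl = equivalent_spl(act.magnitude * td.max_drive_voltage,
                                 metf_intact)
        fb = internal_feedback_path(me, td, chain,
                                    canceller_taps=cfg.control.lms_taps)
        stage = "functional gain"
        plant = coupled_plant(me, td, chain)
        plant._true_feedback_ir = plant.feedback_impulse(401)[1:]
        if msg_report is None:
            msg_report = protocol_msg(cfg, plant)
        v_idle, v_aided, runs = _stage5_runs(cfg, plant, msg_report)
        with np.errstate(divide="ignore"):
            fg = 20.0 * np.log10(np.abs(v_aided) / np.abs(v_idle))
    except Exception as exc:
        raise RuntimeError(f"protocol stage failed: {stage}: {exc}") from exc
    insertion = metf_idle.magnitude_db - metf_intact.magnitude_db
    return ProtocolResult(
        grid, metf_intact, metf_idle, sens, thresh, act, act_spl, fb,
        msg_report, runs["stimulus_bins"], fg, insertion,
        runs if keep_runs else {})


def protocol_msg(cfg: RunConfig, plant: DiscretePlant | None = None,
                 lms_on: bool = True) -> StabilityReport:
    """Time-domain MSG sweep under the protocol stimulus conditions."""
    exp = cfg.experiment
    chain = cfg.signal_chain
    if plant is None:
        plant = coupled_plant(cfg.middle_ear, cfg.transducer, chain)
    p_rms = pressure_from_spl(exp.stimulus_spl)
    spec = MultisineStimulus(exp.multisine_points, chain.sample_rate,
                             exp.stimulus_f_min, exp.stimulus_f_max,
                             rms=p_rms, seed=cfg.seed)
    period, _ = make_multisine(spec)
    forward = ForwardPath.from_config(cfg.control.forward, chain)
    return msg_time_domain(
        plant, forward, cfg.control, period, chain, lms_on=lms_on,
        noise_rms=cfg.noise.rms_volts, seed=cfg.control.seed,
        sweep_step_db=exp.sweep_step_db, start_db=exp.sweep_start_db,
        max_db=cfg.control.msg_ceiling_db,
        max_drive=cfg.transducer.max_drive_voltage)


# ---------------------------------------------------------------------------
# dynamic range and impedance study
# ---------------------------------------------------------------------------

@dataclass
class DynamicRangeCurve:
    """Per-frequency dynamic window in equivalent eardrum dB SPL."""

    frequencies: np.ndarray
    lower_spl: np.ndarray    # sensor threshold
    upper_spl: np.ndarray    # maximum actuator output

    def __post_init__(self) -> None:
        both = np.isfinite(self.lower_spl) & np.isfinite(self.upper_spl)
        if np.any(self.upper_spl[both] < self.lower_spl[both]):
            raise ValueError("dynamic-range upper bound below lower bound")

    @property
    def span_db(self) -> np.ndarray:
        return self.upper_spl - self.lower_spl


def dynamic_range(protocol: ProtocolResult) -> DynamicRangeCurve:
    """Combine sensor threshold (lower) and max actuator output (upper)."""
    return DynamicRangeCurve(protocol.grid.frequencies,
                             protocol.threshold_spl,
                             protocol.actuator_spl)


def impedance_study(cfg: RunConfig, grid: FrequencyGrid | None = None
                    ) -> dict[str, FrequencyResponse]:
    """Opened-joint force drive and inserted-transducer voltage drive.

    Part (a): 1 N on each side of the opened incudostapedial joint, velocity
    of the driven side.  Part (b): transducer inserted, 1 V on the actuator,
    velocity of incus side and stapes side, plus the clamped-frame reference.
    """
    if grid is None:
        exp = cfg.experiment
        grid = FrequencyGrid.default(exp.grid_points, exp.grid_f_min,
                                     exp.grid_f_max)
    me, td = cfg.middle_ear, cfg.transducer
    out = {
        "force_incus": joint_point_response(me, "incus", 1.0, grid),
        "force_stapes": joint_point_response(me, "stapes", 1.0, grid),
        "drive_incus": actuator_response(
            me.with_state("transducer_active"), td, 1.0, grid,
            observe=OSSICLES),
        "drive_stapes": actuator_response(
            me.with_state("transducer_active"), td, 1.0, grid),
        "drive_stapes_fixed_frame": actuator_response(
            me.with_state("transducer_fixed_frame"), td, 1.0, grid),
    }
    return out
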
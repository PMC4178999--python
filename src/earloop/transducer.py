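"""Two-plate piezo transducer: sensor, actuator, feedback path, signal chain.

The sensor plate converts the force it carries into a voltage (ideal linear
coupling, V/N); the actuator converts drive voltage into an internal force
pair acting across the actuator plate (N/V).  Both plates share the 35 mg
free-floating frame, so actuator recoil reaches the sensor mechanically —
this frame path is the feedback that the adaptive canceller has to defeat.

This module also provides the analogue/digital chain around the transducer
(preamplifier, anti-alias filter, ADC quantiser) and the SPL conversions used
to express velocities as equivalent eardrum sound pressure levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import (MiddleEarConfig, NoiseModel, SignalChainConfig,
                     TransducerConfig)
from .middle_ear import (EARDRUM, FRAME, OSSICLES, STAPES, HarmonicExcitation,
                         build_middle_ear, harmonic_response, metf)
from .network import FrequencyGrid, FrequencyResponse

__all__ = [
    "P_REF",
    "spl_from_pressure",
    "pressure_from_spl",
    "equivalent_spl",
    "ad_quantize",
    "sensor_sensitivity",
    "actuator_response",
    "internal_feedback_path",
    "sensor_threshold_spl",
    "FeedbackPath",
    "DiscretePlant",
    "coupled_plant",
]

#: Reference sound pressure, 20 micropascal.
P_REF = 20e-6

#: Speed of sound in air at room temperature, m/s.
SPEED_OF_SOUND = 343.0


def acoustic_path_delay(length_m: float) -> float:
    """Propagation delay of an acoustic feedback path in air (seconds).

    The tympanic-cavity acoustic path (~2 cm) is about 60 us — below the
    100 us sample interval, which is why the sampled loop remains stabilised
    by its own processing delay.  Disabled by default; use it as the
    ``delay_s`` of an additional :class:`FeedbackPath`.
    """
    if length_m < 0:
        raise ValueError("path length must be >= 0")
    return length_m / SPEED_OF_SOUND


# ---------------------------------------------------------------------------
# SPL conversions
# ---------------------------------------------------------------------------

def spl_from_pressure(p):
    """Sound pressure level in dB SPL for a pressure (amplitude/RMS) in Pa."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pressure must be > 0 for an SPL")
    out = 20.0 * np.log10(p / P_REF)
    return float(out) if out.ndim == 0 else out


def pressure_from_spl(spl):
    """Inverse of :func:`spl_from_pressure` (Pa)."""
    spl = np.asarray(spl, dtype=float)
    out = P_REF * 10.0 ** (spl / 20.0)
    return float(out) if out.ndim == 0 else out


def equivalent_spl(velocity_mm_s, intact_metf: FrequencyResponse,
                   f: float | None = None):
    """Eardrum SPL that would produce a stapes velocity through the intact ear.

    ``velocity_mm_s`` is either a scalar magnitude at frequency ``f`` or an
    array on the grid of ``intact_metf`` (mm/s).  The equivalent level is
    ``spl(|v| / |METF_intact|)``.
    """
    if f is not None:
        h = abs(intact_metf.at(f))
        if h == 0:
            raise ValueError(f"intact METF magnitude is zero at {f} Hz")
        return spl_from_pressure(abs(velocity_mm_s) / h)
    mag = intact_metf.magnitude
    if np.any(mag == 0):
        raise ValueError("intact METF magnitude is zero on the grid")
    v = np.abs(np.asarray(velocity_mm_s, dtype=float))
    return spl_from_pressure(v / mag)


# ---------------------------------------------------------------------------
# ADC quantiser
# ---------------------------------------------------------------------------

def ad_quantize(x, chain: SignalChainConfig) -> np.ndarray:
    """Uniform mid-tread quantisation with clipping at the converter range.

    The step is ``delta_u = 2*range / 2**bits``; in-range samples satisfy
    ``|x - q| <= delta_u / 2``.  Out-of-range samples clip to the range
    (callers interested in clipping can count them beforehand).
    """
    x = np.asarray(x, dtype=float)
    du = chain.delta_u
    q = du * np.round(x / du)
    return np.clip(q, -chain.adc_range, chain.adc_range)


# ---------------------------------------------------------------------------
# frequency-domain sensor / actuator curves
# ---------------------------------------------------------------------------

def _inserted_network(me: MiddleEarConfig, td: TransducerConfig, state: str):
    return build_middle_ear(me.with_state(state), td)


def sensor_sensitivity(me: MiddleEarConfig, td: TransducerConfig,
                       grid: FrequencyGrid) -> FrequencyResponse:
    """Sensor output voltage per eardrum pressure, in mV/Pa.

    Defined with the transducer idle: 1 Pa at the drum, sensor voltage =
    coupling x force carried by the sensor plate.
    """
    if me.state not in ("intact", "transducer_idle"):
        raise ValueError("sensor sensitivity requires the transducer_idle state")
    net = _inserted_network(me, td, "transducer_idle")
    disp = net.harmonic({EARDRUM: complex(me.eardrum_area)}, grid)
    force = net.edge_force(OSSICLES, FRAME, disp, grid)
    volts = td.sensor_coupling * force
    return FrequencyResponse(grid, volts * 1e3, "Pa", "mV")


def actuator_response(me: MiddleEarConfig, td: TransducerConfig,
                      drive_v: float, grid: FrequencyGrid,
                      observe: str = STAPES) -> FrequencyResponse:
    """Stapes (or incus-side) velocity per volt of actuator drive, mm/s/V.

    The free-floating frame recoils against the actuator, so the response
    drops toward low frequencies where the stapes side is stiffness-blocked
    and the frame is easy to move.  Driving above the configured maximum
    voltage raises a saturation error rather than silently clipping.
    """
    if drive_v > td.max_drive_voltage:
        raise ValueError(
            f"drive {drive_v} V exceeds maximum {td.max_drive_voltage} V")
    state = me.state if me.state in ("transducer_active",
                                     "transducer_fixed_frame") \
        else "transducer_active"
    net = _inserted_network(me, td, state)
    exc = HarmonicExcitation(STAPES, "voltage", drive_v)
    fr = harmonic_response(net, exc, observe, grid, "velocity",
                           transducer=td)
    # report per volt
    return FrequencyResponse(grid, fr.values / drive_v, "V", "mm/s")


@dataclass
class FeedbackPath:
    """Actuator-volts to sensor-volts path through the shared frame.

    ``taps`` is the impulse response sampled at ``fs`` (ZOH discretisation of
    the mechanical path); ``delay_s`` is an optional extra pure delay (zero by
    default — the titanium frame's signal path is far shorter than one sample
    interval).  ``tail_energy`` reports the fraction of impulse-response
    energy beyond the canceller length.
    """

    taps: np.ndarray
    fs: float
    delay_s: float = 0.0
    tail_energy: float = 0.0
    system: object = None   # discrete StateSpace, kept for exact evaluation

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=float)
        if self.delay_s < 0:
            raise ValueError("feedback delay must be >= 0")
        if not np.all(np.isfinite(self.taps)):
            raise ValueError("feedback impulse response must be finite")

    def frequency_response(self, freqs: np.ndarray) -> np.ndarray:
        """Exact discrete transfer (with delay) at the given frequencies (Hz)."""
        w = 2.0 * np.pi * np.asarray(freqs, dtype=float) / self.fs
        if self.system is not None:
            A, B, C, D = (self.system.A, self.system.B, self.system.C,
                          self.system.D)
            n = A.shape[0]
            h = np.empty(len(w), dtype=complex)
            for i, wi in enumerate(w):
                x = np.linalg.solve(np.exp(1j * wi) * np.eye(n) - A, B[:, 0])
                h[i] = C[0] @ x + D[0, 0]
        else:
            z = np.exp(-1j * np.outer(w, np.arange(len(self.taps))))
            h = z @ self.taps
        return h * np.exp(-1j * w * self.fs * self.delay_s)


def internal_feedback_path(me: MiddleEarConfig, td: TransducerConfig,
                           chain: SignalChainConfig, n_taps: int = 400,
                           canceller_taps: int = 100) -> FeedbackPath:
    """Mechanical feedback path, discretised to an impulse response at fs.

    Builds the active-transducer network, forms the single-input
    (actuator V) single-output (sensor V) state-space model and discretises
    it with a zero-order hold at the controller sample rate.
    """
    net = _inserted_network(me, td, "transducer_active")
    g = td.actuator_coupling
    ss = net.state_space(
        inputs=[{STAPES: g, FRAME: -g}],
        outputs=[("edge_force", (OSSICLES, FRAME))])
    ss_d = ss.to_discrete(chain.sample_period, method="zoh")
    # impulse response of the discrete system, scaled to sensor volts
    n = max(n_taps, canceller_taps + 1)
    x = np.zeros(ss_d.A.shape[0])
    h = np.empty(n)
    b = ss_d.B[:, 0]
    for k in range(n):
        h[k] = ss_d.C[0] @ x + ss_d.D[0, 0] * (1.0 if k == 0 else 0.0)
        x = ss_d.A @ x + (b if k == 0 else 0.0)
    h *= td.sensor_coupling
    energy = float(np.sum(h ** 2))
    tail = float(np.sum(h[canceller_taps:] ** 2) / energy) if energy else 0.0
    sys_scaled = signal.StateSpace(ss_d.A, ss_d.B,
                                   ss_d.C * td.sensor_coupling,
                                   ss_d.D * td.sensor_coupling,
                                   dt=chain.sample_period)
    return FeedbackPath(h, chain.sample_rate, 0.0, tail, sys_scaled)


def sensor_threshold_spl(sensitivity: FrequencyResponse,
                         noise: NoiseModel) -> np.ndarray:
    """Equivalent input SPL at which the sensor signal equals the noise floor.

    Per frequency: the eardrum pressure whose sensor output RMS matches the
    sensor-referred noise RMS (SNR = 0 dB).  Zero noise yields ``-inf``.
    """
    mag_v = sensitivity.magnitude * 1e-3  # sensitivity carries mV/Pa
    if np.any(mag_v == 0):
        raise ValueError("sensor sensitivity is zero on the grid")
    if noise.rms_volts == 0:
        return np.full(len(sensitivity.values), -np.inf)
    return spl_from_pressure(noise.rms_volts / mag_v)


# ---------------------------------------------------------------------------
# coupled discrete-time plant for the control loop
# ---------------------------------------------------------------------------

def _butter_analog_ss(order: int, wc: float) -> tuple[np.ndarray, np.ndarray,
                                                      np.ndarray]:
    """Analogue Butterworth low-pass as cascaded frequency-scaled sections.

    Companion-form realisations of high-order analogue filters carry
    coefficients up to ``wc**order`` and destroy the conditioning of the
    subsequent zero-order-hold discretisation; a cascade of second-order
    sections with states scaled by ``wc`` keeps every matrix entry of order
    ``wc``.  Returns (A, B, C); D is zero for a strictly proper low-pass.
    """
    poles = signal.buttap(order)[1]  # normalised poles, |p| = 1
    blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    used = np.zeros(len(poles), dtype=bool)
    for i, p in enumerate(poles):
        if used[i]:
            continue
        used[i] = True
        if abs(p.imag) < 1e-12:
            blocks.append((np.array([[wc * p.real]]), np.array([[wc]]),
                           np.array([[1.0]])))
        else:
            j = next(k for k in range(len(poles))
                     if not used[k] and abs(poles[k] - np.conj(p)) < 1e-9)
            used[j] = True
            zeta = -p.real  # |p| = 1 for Butterworth prototypes
            A = wc * np.array([[0.0, 1.0], [-1.0, -2.0 * zeta]])
            B = wc * np.array([[0.0], [1.0]])
            C = np.array([[1.0, 0.0]])
            blocks.append((A, B, C))
    A, B, C = blocks[0]
    for A2, B2, C2 in blocks[1:]:
        n1, n2 = A.shape[0], A2.shape[0]
        Anew = np.zeros((n1 + n2, n1 + n2))
        Anew[:n1, :n1] = A
        Anew[n1:, n1:] = A2
        Anew[n1:, :n1] = B2 @ C
        Bnew = np.vstack([B, np.zeros((n2, 1))])
        Cnew = np.hstack([np.zeros((1, n1)), C2])
        A, B, C = Anew, Bnew, Cnew
    return A, B, C


@dataclass
class DiscretePlant:
    """ZOH-discretised mechanics + preamp + anti-alias filter.

    Inputs:  ``[eardrum pressure (Pa), actuator drive (V)]``
    Outputs: ``[ADC input (V, after preamp and anti-alias filter),
                stapes velocity (mm/s), raw sensor voltage (V)]``
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    fs: float

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    def feedback_response(self, freqs: np.ndarray) -> np.ndarray:
        """Discrete transfer actuator V -> ADC V (what the canceller sees)."""
        return self._transfer(freqs, inp=1, out=0)

    def stimulus_response(self, freqs: np.ndarray, out: int = 0) -> np.ndarray:
        return self._transfer(freqs, inp=0, out=out)

    def _transfer(self, freqs, inp: int, out: int) -> np.ndarray:
        z = np.exp(1j * 2.0 * np.pi * np.asarray(freqs, float) / self.fs)
        n = self.n_states
        h = np.empty(len(z), dtype=complex)
        for i, zi in enumerate(z):
            x = np.linalg.solve(zi * np.eye(n) - self.A, self.B[:, inp])
            h[i] = self.C[out] @ x + self.D[out, inp]
        return h

    def feedback_impulse(self, n: int) -> np.ndarray:
        """Impulse response of the actuator-V -> ADC-V path (n taps)."""
        x = np.zeros(self.n_states)
        h = np.empty(n)
        b = self.B[:, 1]
        for k in range(n):
            h[k] = self.C[0] @ x + (self.D[0, 1] if k == 0 else 0.0)
            x = self.A @ x + (b if k == 0 else 0.0)
        return h

    def simulate_open(self, p: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Open-loop run (no controller): returns the (n, 3) output record."""
        sysd = signal.StateSpace(self.A, self.B, self.C, self.D,
                                 dt=1.0 / self.fs)
        _, y, _ = signal.dlsim(sysd, np.column_stack([p, u]))
        return y


def coupled_plant(me: MiddleEarConfig, td: TransducerConfig,
                  chain: SignalChainConfig) -> DiscretePlant:
    """Build the discrete plant used by the closed-loop simulator.

    Continuous signal path: the DAC's staircase actuator signal passes a
    Butterworth reconstruction filter (the converter terminals carry the same
    fourth-order filters as the ADC side, smoothing the zero-order-hold
    images that would otherwise excite above-Nyquist mechanical resonances),
    drives the mechanical network (transducer active), and the sensor voltage
    is preamplified and anti-alias filtered into the ADC.  The whole
    continuous system is discretised with a zero-order hold at the controller
    sample rate; both the ADC path and the raw mechanical outputs are
    exposed.
    """
    state = me.state if me.state in ("transducer_active",
                                     "transducer_fixed_frame") \
        else "transducer_active"
    net = _inserted_network(me, td, state)
    g = td.actuator_coupling
    mech = net.state_space(
        inputs=[{EARDRUM: me.eardrum_area}, {STAPES: g, FRAME: -g}],
        outputs=[("edge_force", (OSSICLES, FRAME)), ("velocity", STAPES)])
    # outputs: sensor volts, stapes velocity (m/s)
    Cs = mech.C[0:1] * td.sensor_coupling
    Cv = mech.C[1:2]
    wc = 2.0 * np.pi * chain.antialias_cutoff
    Af, Bf, Cf = _butter_analog_ss(chain.antialias_order, wc)   # ADC side
    Ar, Br, Cr = _butter_analog_ss(chain.antialias_order, wc)   # DAC side
    nm, nf, nr = mech.A.shape[0], Af.shape[0], Ar.shape[0]
    n = nr + nm + nf
    sl_r = slice(0, nr)
    sl_m = slice(nr, nr + nm)
    sl_f = slice(nr + nm, n)
    A = np.zeros((n, n))
    A[sl_r, sl_r] = Ar
    A[sl_m, sl_m] = mech.A
    A[sl_f, sl_f] = Af
    A[sl_m, sl_r] = mech.B[:, 1:2] @ Cr     # smoothed DAC drives the actuator
    A[sl_f, sl_m] = Bf @ (chain.preamp_gain * Cs)
    B = np.zeros((n, 2))
    B[sl_m, 0] = mech.B[:, 0]
    B[sl_r, 1] = Br[:, 0]
    C = np.zeros((3, n))
    C[0, sl_f] = Cf[0]                      # ADC input (filter output)
    C[1, sl_m] = Cv[0] * 1e3                # stapes velocity in mm/s
    C[2, sl_m] = Cs[0]                      # raw sensor volts
    D = np.zeros((3, 2))
    Ad, Bd, Cd, Dd, _ = signal.cont2discrete((A, B, C, D),
                                             chain.sample_period, method="zoh")
    return DiscretePlant(Ad, Bd, Cd, Dd, chain.sample_rate)
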
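"""Digital forward path, LMS feedback cancellation and stability analysis.

The closed loop is: sensor voltage -> preamp -> anti-alias filter -> ADC
quantiser -> subtraction of the predicted feedback -> scalar gain G ->
low-pass filter -> one-sample (or more) processing delay -> actuator, with
the mechanical path from actuator back to sensor closing the loop.

With forward transfer ``mu(w)``, feedback path ``F(w)`` and its FIR estimate
``F_hat(w)``, the closed-loop transfer is ``G / (1 - G (F - F_hat))``; the
loop can only oscillate at critical frequencies where the open-loop phase is
a multiple of 2*pi, and the maximum stable gain (MSG) is the gain that first
pushes the loop magnitude to unity at such a frequency.  Because sampling
introduces at least one sample of delay, no critical frequency can exist
above the Nyquist frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import ControlConfig, ForwardPathConfig, SignalChainConfig
from .network import FrequencyGrid, FrequencyResponse

__all__ = [
    "ForwardPath",
    "LMSFilter",
    "StabilityReport",
    "ClosedLoopRun",
    "broadband_gain",
    "closed_loop_tf",
    "critical_frequencies",
    "msg_frequency_domain",
    "lms_adapt",
    "predict_feedback",
    "simulate_closed_loop",
    "msg_time_domain",
    "misalignment_db",
]


class DivergenceError(RuntimeError):
    """Adaptive filter weights became non-finite."""


# ---------------------------------------------------------------------------
# forward path
# ---------------------------------------------------------------------------

@dataclass
class ForwardPath:
    """Scalar gain, Butterworth low-pass and integer processing delay."""

    fs: float
    gain_db: float = 0.0
    lowpass_order: int = 4
    lowpass_cutoff: float = 4000.0
    delay_samples: int = 1

    def __post_init__(self) -> None:
        if self.delay_samples < 1:
            raise ValueError("forward path delay must be >= 1 sample")
        if not (0 < self.lowpass_cutoff < self.fs / 2):
            raise ValueError("low-pass cutoff must lie below Nyquist")
        self._sos = signal.butter(self.lowpass_order, self.lowpass_cutoff,
                                  fs=self.fs, output="sos")

    @classmethod
    def from_config(cls, cfg: ForwardPathConfig,
                    chain: SignalChainConfig) -> "ForwardPath":
        return cls(chain.sample_rate, cfg.gain_db, cfg.lowpass_order,
                   cfg.lowpass_cutoff, cfg.delay_samples)

    @property
    def gain(self) -> float:
        return 10.0 ** (self.gain_db / 20.0)

    @property
    def sos(self) -> np.ndarray:
        return self._sos

    def mu(self, freqs: np.ndarray, unit_gain: bool = False) -> np.ndarray:
        """Forward transfer at the given frequencies (Hz), incl. delay."""
        w = 2.0 * np.pi * np.asarray(freqs, dtype=float) / self.fs
        _, h = signal.sosfreqz(self._sos, worN=w)
        h = h * np.exp(-1j * w * self.delay_samples)
        return h if unit_gain else self.gain * h

    def with_gain_db(self, gain_db: float) -> "ForwardPath":
        return ForwardPath(self.fs, gain_db, self.lowpass_order,
                           self.lowpass_cutoff, self.delay_samples)


def broadband_gain(mu: FrequencyResponse | tuple[np.ndarray, np.ndarray]
                   ) -> float:
    """Mean of |mu| over the digital frequency circle.

    ``G = (1/2pi) * integral_0^2pi |mu(w)| dw`` by trapezoidal integration.
    Accepts either a :class:`FrequencyResponse` over normalised digital
    frequency (rad/sample) or an ``(omega, values)`` pair.  Grids covering
    only ``[0, pi]`` are mirrored using conjugate symmetry of real systems.
    """
    if isinstance(mu, FrequencyResponse):
        w, v = mu.grid.frequencies, mu.values
    else:
        w, v = mu
    w = np.asarray(w, dtype=float)
    v = np.abs(np.asarray(v))
    if w.size == 0:
        raise ValueError("empty frequency grid")
    if w.size == 1:
        return float(v[0])
    if w[-1] <= np.pi * (1 + 1e-9):
        # mirror [0, pi] onto (pi, 2 pi)
        w = np.concatenate([w, 2.0 * np.pi - w[::-1]])
        v = np.concatenate([v, v[::-1]])
    return float(np.trapezoid(v, w) / (w[-1] - w[0]))


# ---------------------------------------------------------------------------
# Eq-style closed-loop algebra
# ---------------------------------------------------------------------------

def closed_loop_tf(G: float, F: FrequencyResponse,
                   F_hat: FrequencyResponse,
                   singular_tol: float = 1e-6
                   ) -> tuple[FrequencyResponse, np.ndarray]:
    """Closed-loop transfer ``G / (1 - G (F - F_hat))`` on a shared grid.

    Returns the response and a boolean mask flagging near-singular points
    where ``|1 - G (F - F_hat)| < singular_tol``.
    """
    if not np.array_equal(F.grid.frequencies, F_hat.grid.frequencies):
        raise ValueError("F and F_hat are on different grids")
    den = 1.0 - G * (F.values - F_hat.values)
    flagged = np.abs(den) < singular_tol
    safe = np.where(flagged, np.nan, den)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = G / safe
    vals = np.where(flagged, 0.0, vals)
    return FrequencyResponse(F.grid, vals, F.input_unit, F.output_unit), flagged


def critical_frequencies(freqs: np.ndarray,
                         loop: np.ndarray) -> np.ndarray:
    """Frequencies where the unwrapped loop phase crosses a multiple of 2*pi.

    Candidates are located by linear interpolation of the unwrapped phase
    between grid points; a grid endpoint sitting exactly on a multiple also
    counts.  Returns an empty array when the phase never crosses.
    """
    freqs = np.asarray(freqs, dtype=float)
    phase = np.unwrap(np.angle(np.asarray(loop)))
    out: list[float] = []
    two_pi = 2.0 * np.pi
    k = phase / two_pi
    for i in range(len(freqs) - 1):
        lo, hi = sorted((k[i], k[i + 1]))
        for m in range(int(np.ceil(lo - 1e-12)), int(np.floor(hi + 1e-12)) + 1):
            if k[i + 1] == k[i]:
                if abs(k[i] - m) < 1e-12:
                    out.append(freqs[i])
                continue
            t = (m - k[i]) / (k[i + 1] - k[i])
            if -1e-12 <= t <= 1 + 1e-12:
                out.append(float(freqs[i] + t * (freqs[i + 1] - freqs[i])))
    if abs(k[-1] - round(k[-1])) < 1e-12:
        out.append(float(freqs[-1]))
    return np.unique(np.round(out, 9))


@dataclass
class StabilityReport:
    """MSG estimate with the critical frequencies that limit it."""

    msg_db: float
    critical_frequencies: np.ndarray
    method: str
    misalignment_db: float = float("nan")
    ceiling_db: float = 60.0
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "msg_db": float(self.msg_db),
            "critical_frequencies_hz":
                [float(f) for f in np.atleast_1d(self.critical_frequencies)],
            "method": self.method,
            "misalignment_db": None if np.isnan(self.misalignment_db)
                else float(self.misalignment_db),
            "ceiling_db": float(self.ceiling_db),
            "details": {k: (float(v) if np.isscalar(v) else v)
                        for k, v in self.details.items()},
        }


def misalignment_db(f_true: np.ndarray, f_hat: np.ndarray) -> float:
    """Normalised misalignment ``20 log10 (|F - F_hat| / |F|)`` of two IRs."""
    f_true = np.asarray(f_true, dtype=float)
    f_hat = np.asarray(f_hat, dtype=float)
    n = max(len(f_true), len(f_hat))
    a = np.zeros(n)
    b = np.zeros(n)
    a[:len(f_true)] = f_true
    b[:len(f_hat)] = f_hat
    denom = np.linalg.norm(a)
    if denom == 0:
        return float("nan")
    err = np.linalg.norm(a - b) / denom
    return float(-np.inf) if err == 0 else float(20.0 * np.log10(err))


def msg_frequency_domain(forward: ForwardPath, F, F_hat=None,
                         n_points: int = 4096,
                         ceiling_db: float = 60.0) -> StabilityReport:
    """MSG from the Nyquist-style critical-frequency argument.

    ``F`` (and optionally ``F_hat``) may be a FeedbackPath-like object with a
    ``frequency_response(freqs)`` method, an impulse-response array, or a
    precomputed complex array on the implicit linear grid.  The loop with the
    unit-gain forward path ``mu0`` is evaluated on a dense linear grid up to
    Nyquist; MSG is the smallest ``1/|mu0 (F - F_hat)|`` over the critical
    frequencies, capped at the declared ceiling.
    """
    freqs = np.linspace(0.0, forward.fs / 2.0, n_points)

    def _resolve(obj):
        if obj is None:
            return np.zeros(n_points, dtype=complex)
        if hasattr(obj, "feedback_response"):  # a DiscretePlant
            return obj.feedback_response(freqs)
        if hasattr(obj, "frequency_response"):
            return obj.frequency_response(freqs)
        arr = np.asarray(obj)
        if arr.ndim == 1 and not np.iscomplexobj(arr):
            w = 2.0 * np.pi * freqs / forward.fs
            return np.exp(-1j * np.outer(w, np.arange(len(arr)))) @ arr
        if len(arr) != n_points:
            raise ValueError("precomputed F array length mismatch")
        return arr.astype(complex)

    delta = _resolve(F) - _resolve(F_hat)
    loop0 = forward.mu(freqs, unit_gain=True) * delta
    crits = critical_frequencies(freqs, loop0)
    crits = crits[crits <= forward.fs / 2.0 + 1e-9]
    if crits.size == 0:
        msg = ceiling_db
    else:
        mags = np.abs(np.interp(crits, freqs, loop0.real)
                      + 1j * np.interp(crits, freqs, loop0.imag))
        mags = mags[mags > 0]
        msg = ceiling_db if mags.size == 0 else float(
            min(ceiling_db, -20.0 * np.log10(np.max(mags))))
    return StabilityReport(msg, crits, "nyquist", ceiling_db=ceiling_db,
                           details={"n_points": n_points})


# ---------------------------------------------------------------------------
# LMS adaptive filter
# ---------------------------------------------------------------------------

@dataclass
class LMSFilter:
    """FIR adaptive canceller (default 100 taps, normalised LMS).

    The weight vector is the running estimate of the feedback impulse
    response; ``history`` must be ordered newest-first.
    """

    n_taps: int = 100
    step: float = 0.05
    eps: float = 1.0e-8
    leakage: float = 0.0
    normalized: bool = True
    weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.zeros(self.n_taps)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != self.n_taps:
            raise ValueError("weight vector length must equal tap count")

    @classmethod
    def from_config(cls, cfg: ControlConfig) -> "LMSFilter":
        return cls(cfg.lms_taps, cfg.lms_step, cfg.lms_eps, cfg.lms_leakage,
                   cfg.normalized)

    def predict(self, history: np.ndarray) -> float:
        """Predicted feedback sample: dot of weights with newest-first history."""
        if len(history) < self.n_taps:
            raise ValueError("history shorter than the filter")
        return float(self.weights @ history[:self.n_taps])

    def adapt(self, history: np.ndarray, error: float) -> None:
        """Standard (N)LMS update ``w <- w + step * error * x``."""
        x = history[:self.n_taps]
        if self.normalized:
            coef = self.step / (float(x @ x) + self.eps)
        else:
            coef = self.step
        if self.leakage:
            self.weights *= (1.0 - self.leakage)
        with np.errstate(over="ignore", invalid="ignore"):
            self.weights += coef * error * x
        if not np.all(np.isfinite(self.weights)):
            raise DivergenceError(
                f"LMS diverged (step={self.step}, normalized={self.normalized})")


def lms_adapt(filt: LMSFilter, history: np.ndarray,
              error: float) -> LMSFilter:
    """Functional wrapper returning the updated filter."""
    filt.adapt(history, error)
    return filt


def predict_feedback(filt: LMSFilter, history: np.ndarray) -> float:
    return filt.predict(history)


# ---------------------------------------------------------------------------
# closed-loop time-domain simulation
# ---------------------------------------------------------------------------

@dataclass
class ClosedLoopRun:
    """Sampled records of one closed-loop run."""

    fs: float
    stimulus: np.ndarray        # eardrum pressure, Pa
    adc: np.ndarray             # quantised ADC samples, V
    error: np.ndarray           # after feedback subtraction, V
    actuator: np.ndarray        # DAC output, V
    stapes_velocity: np.ndarray  # mm/s
    sensor: np.ndarray          # raw sensor volts
    weights: np.ndarray
    clipped_samples: int
    stable: bool
    convergence: np.ndarray = field(default_factory=lambda: np.empty(0))

    def signals_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "stimulus_pa": self.stimulus,
            "adc_v": self.adc,
            "error_v": self.error,
            "actuator_v": self.actuator,
            "stapes_velocity_mm_s": self.stapes_velocity,
            "sensor_v": self.sensor,
        })


def _sos_step_factory(sos: np.ndarray):
    """Per-sample cascaded-biquad filter (direct form II transposed)."""
    n_sections = sos.shape[0]
    state = np.zeros((n_sections, 2))

    def step(x: float) -> float:
        for s in range(n_sections):
            b0, b1, b2, a0, a1, a2 = sos[s]
            y = b0 * x + state[s, 0]
            state[s, 0] = b1 * x - a1 * y + state[s, 1]
            state[s, 1] = b2 * x - a2 * y
            x = y
        return x

    return step


def _window_rms(x: np.ndarray, win: int) -> np.ndarray:
    n = len(x) // win
    if n == 0:
        return np.array([np.sqrt(np.mean(x ** 2))])
    return np.sqrt(np.mean(x[:n * win].reshape(n, win) ** 2, axis=1))


def detect_instability(x: np.ndarray, win: int = 512,
                       ratio: float = 10.0) -> bool:
    """Envelope test: any window RMS above ``ratio`` times the steady RMS.

    The steady-state reference is the median window RMS; non-finite samples
    always count as unstable.
    """
    if not np.all(np.isfinite(x)):
        return True
    rms = _window_rms(np.asarray(x, dtype=float), win)
    ref = np.median(rms)
    if ref == 0:
        return bool(np.any(rms > 0))
    return bool(np.max(rms) > ratio * ref)


def simulate_closed_loop(plant, forward: ForwardPath,
                         lms: LMSFilter | None,
                         stimulus: np.ndarray,
                         chain: SignalChainConfig,
                         noise_rms: float = 0.0,
                         rng: np.random.Generator | None = None,
                         adapt: bool = True,
                         quantize: bool = True,
                         max_drive: float = 1.0,
                         probe: np.ndarray | None = None,
                         abort_level: float = 1e6) -> ClosedLoopRun:
    """Per-sample closed-loop simulation of the full signal chain.

    ``plant`` is a :class:`earloop.transducer.DiscretePlant`.  Sensor noise
    (referred to the sensor output) is added ahead of the quantiser scaled by
    the preamp gain.  ``probe`` is an optional drive injected at the DAC
    output (summed into the actuator signal) — the direct actuator excitation
    used to identify the feedback path with the loudspeaker silent.  The
    actuator output hard-clips at ``max_drive`` volts; clipped samples are
    counted.  Runs whose ADC signal exceeds ``abort_level`` stop early and
    are marked unstable.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    n = len(stimulus)
    if n == 0:
        raise ValueError("empty stimulus")
    if probe is not None and len(probe) != n:
        raise ValueError("probe length must match stimulus length")
    rng = rng if rng is not None else np.random.default_rng(0)
    noise = (rng.normal(0.0, noise_rms * chain.preamp_gain, n)
             if noise_rms > 0 else np.zeros(n))

    A, B, C = plant.A, plant.B, plant.C
    bp, ba = B[:, 0], B[:, 1]
    c_adc, c_vel, c_sen = C[0], C[1], C[2]
    x = np.zeros(plant.n_states)
    lpf = _sos_step_factory(forward.sos)
    d = forward.delay_samples
    delay = np.zeros(d)  # circular buffer: ua[k] = v[k - d]
    d_idx = 0
    gain = forward.gain
    du = chain.delta_u
    vmax = chain.adc_range

    ntaps = lms.n_taps if lms is not None else 0
    hist = np.zeros(max(ntaps, 1))
    w = lms.weights if lms is not None else None

    adc = np.empty(n)
    err = np.empty(n)
    act = np.empty(n)
    vel = np.empty(n)
    sen = np.empty(n)
    conv = []
    clipped = 0
    stable = True

    for k in range(n):
        a_in = c_adc @ x + noise[k]
        if quantize:
            q = du * np.round(a_in / du)
            if q > vmax:
                q = vmax
            elif q < -vmax:
                q = -vmax
        else:
            q = a_in
        if lms is not None:
            pred = float(w @ hist[:ntaps])
            e = q - pred
            if adapt:
                xv = hist[:ntaps]
                pw = float(xv @ xv)
                coef = (lms.step / (pw + lms.eps)) if lms.normalized \
                    else lms.step
                w += coef * e * xv
        else:
            e = q
        v = lpf(gain * e)
        ua = delay[d_idx]
        delay[d_idx] = v
        d_idx = (d_idx + 1) % d
        if probe is not None:
            ua = ua + probe[k]
        if ua > max_drive:
            ua = max_drive
            clipped += 1
        elif ua < -max_drive:
            ua = -max_drive
            clipped += 1
        adc[k] = q
        err[k] = e
        act[k] = ua
        vel[k] = c_vel @ x
        sen[k] = c_sen @ x
        x = A @ x + bp * stimulus[k] + ba * ua
        if ntaps:
            hist[1:] = hist[:-1]
            hist[0] = ua
        if not np.isfinite(e) or abs(e) > abort_level:
            adc[k + 1:] = 0.0
            err[k + 1:] = 0.0
            act[k + 1:] = 0.0
            vel[k + 1:] = 0.0
            sen[k + 1:] = 0.0
            stable = False
            break
        if lms is not None and adapt and k % 1024 == 0:
            conv.append(np.linalg.norm(w))

    if lms is not None and not np.all(np.isfinite(w)):
        stable = False
    if stable:
        stable = not detect_instability(err)
    return ClosedLoopRun(plant.fs, stimulus, adc, err, act, vel, sen,
                         w.copy() if w is not None else np.empty(0),
                         clipped, stable, np.asarray(conv))


def _spectral_protrusion_db(x: np.ndarray,
                            stimulus_period: np.ndarray) -> float:
    """Largest excess of any spectral line over the stimulus-shaped spectrum.

    The last whole period of ``x`` is compared bin-by-bin against (a) a
    median-smoothed version of its own spectrum across the stimulus-excited
    bins and (b) the median excited-bin level for bins outside the stimulus
    band — a feedback resonance building up toward oscillation sticks out of
    both long before the envelope grows.
    """
    period = len(stimulus_period)
    if len(x) < period:
        return 0.0
    stim_spec = np.abs(np.fft.rfft(stimulus_period))
    excited = stim_spec > 1e-6 * np.max(stim_spec)
    spec = np.abs(np.fft.rfft(x[-period:]))
    level = 20.0 * np.log10(np.maximum(spec, 1e-300))
    exc_level = level[excited]
    if exc_level.size == 0:
        return 0.0
    kernel = 31
    pad = kernel // 2
    padded = np.pad(exc_level, pad, mode="edge")
    smooth = np.array([np.median(padded[i:i + kernel])
                       for i in range(len(exc_level))])
    in_band = float(np.max(exc_level - smooth))
    ref = float(np.median(exc_level))
    out = level[~excited]
    out_band = float(np.max(out) - ref) if out.size else -np.inf
    return max(in_band, out_band)


def msg_time_domain(plant, forward: ForwardPath, lms_cfg: ControlConfig,
                    stimulus_period: np.ndarray, chain: SignalChainConfig,
                    lms_on: bool = True,
                    noise_rms: float = 0.0,
                    seed: int = 20140807,
                    sweep_step_db: float = 0.5,
                    start_db: float = 0.0,
                    max_db: float = 60.0,
                    converge_samples: int = 40000,
                    probe_rms: float = 0.1,
                    eval_periods: int = 3,
                    protrusion_limit_db: float = 12.0,
                    max_drive: float = 1.0) -> StabilityReport:
    """Bench-style MSG: sweep the forward gain upward until instability.

    With the canceller on, the weights are first converged by driving the
    actuator directly with a white probe (loudspeaker silent, forward gain at
    the sweep start) — adapting against the amplified stimulus instead would
    bias the filter toward predicting the stimulus, since the multisine is
    periodic rather than transient.  The sweep then raises the gain in
    ``sweep_step_db`` steps with the converged weights held fixed, re-running
    ``eval_periods`` stimulus periods at each gain.  A gain counts as stable
    when the envelope detector stays quiet, no actuator sample clips and no
    spectral line protrudes more than ``protrusion_limit_db`` above the
    smoothed stimulus-shaped spectrum.
    """
    if not (0.5 <= sweep_step_db <= 3.0):
        raise ValueError("sweep step must lie in [0.5, 3] dB")
    period = len(stimulus_period)
    rng = np.random.default_rng(seed)
    lms = LMSFilter.from_config(lms_cfg) if lms_on else None

    if lms is not None:
        # two-stage identification: fast acquisition, then a reduced step to
        # shrink the steady-state weight noise (gear shifting)
        for step_scale in (1.0, 0.1):
            probe = rng.normal(0.0, probe_rms, converge_samples)
            lms = LMSFilter(lms.n_taps, lms.step * step_scale, lms.eps,
                            lms.leakage, lms.normalized, lms.weights)
            run = simulate_closed_loop(plant, forward.with_gain_db(start_db),
                                       lms, np.zeros(converge_samples), chain,
                                       noise_rms, rng, adapt=True,
                                       max_drive=max_drive, probe=probe)
            lms = LMSFilter(lms.n_taps, lms_cfg.lms_step, lms.eps,
                            lms.leakage, lms.normalized, run.weights)

    eval_stim = np.tile(stimulus_period, eval_periods)
    gains = np.arange(start_db, max_db + 1e-9, sweep_step_db)
    last_stable = None
    detail_gains = []
    weights = lms.weights.copy() if lms is not None else None
    for g in gains:
        trial = (LMSFilter(lms.n_taps, lms.step, lms.eps, lms.leakage,
                           lms.normalized, weights.copy())
                 if lms is not None else None)
        run = simulate_closed_loop(plant, forward.with_gain_db(float(g)),
                                   trial, eval_stim, chain, noise_rms, rng,
                                   adapt=False, max_drive=max_drive)
        ok = run.stable and run.clipped_samples == 0
        if ok:
            prot = _spectral_protrusion_db(run.error, stimulus_period)
            ok = prot <= protrusion_limit_db
        detail_gains.append((float(g), bool(ok)))
        if not ok:
            break
        last_stable = float(g)

    msg = last_stable if last_stable is not None else -np.inf
    mis = float("nan")
    if lms is not None and weights is not None:
        true_ir = getattr(plant, "_true_feedback_ir", None)
        if true_ir is not None:
            mis = misalignment_db(true_ir, weights)
    return StabilityReport(
        msg, np.empty(0), "time_domain", misalignment_db=mis,
        ceiling_db=max_db,
        details={"sweep": detail_gains, "lms_on": lms_on,
                 "weights": weights.tolist() if weights is not None else []})
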
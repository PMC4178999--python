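# Methods

## Scope and modelling approach

`earloop` replaces a finite-element middle-ear model and a physical bench
model with a one-dimensional lumped-parameter network. Every ossicle is a
point mass moving along a single ("piston") coordinate; ligaments, joints
and the transducer plates are spring–damper edges; the cochlear fluid load
is a simplified spring–mass–damper hung on the stapes and is the network's
dominant energy sink. Rocking stapes modes, nonlinear annular-ligament
behaviour and the acoustic cavities of the tympanic cavity are deliberately
out of scope; the model is linear throughout, so every transfer function
scales exactly with excitation amplitude.

Harmonic analysis solves `(K + iK_η + iωC − ω²M)x = f` per grid frequency.
The default analysis grid is 128 logarithmic points over 100 Hz–5 kHz (a
coarse 10-point preset exists for parity runs); results above 2.5 kHz carry
a validity flag, mirroring the restricted validity band of bench-type
middle-ear models.

## Default parameters and what they were chosen for

No published parameter set exists for this specific configuration, so the
defaults in `earloop/data/default.yaml` are a *designed* synthetic middle
ear. The mechanical stiffnesses and dampers were selected (by a scripted
multi-objective search, then frozen) so that the model reproduces the
defining features of the system simultaneously:

* intact METF: band-pass with the main resonance at ≈1.1 kHz and a peak of
  ≈0.14 mm·s⁻¹·Pa⁻¹ (finely sampled at the resonance);
* inserting the idle 35 mg device shifts the first resonance down
  (≈1.11 kHz → ≈0.91 kHz) and attenuates transmission above ~1.2 kHz;
* opened-joint and driven-transducer responses: the incus-side motion
  exceeds the stapes-side motion below ≈800 Hz (free-floating recoil), and
  rigidly clamping the frame adds less than 2 dB of stapes output above
  1 kHz;
* the closed loop supports a maximum stable gain above 30 dB once the
  canceller has converged.

Three scalars are then set by the exact linear calibration in
`earloop.calibrate` (each is a one-step scaling, not a fit):

| parameter | target |
|---|---|
| `sensor_coupling` (V/N) | sensor sensitivity 1 mV/Pa at 1 kHz |
| `actuator_coupling` (N/V) | max equivalent eardrum level 120 dB SPL at 1 V |
| `noise.rms_volts` | 25 dB SPL threshold at the worst in-band frequency |

The shipped file contains exactly the calibrated values;
`python -m earloop.calibrate` regenerates them and a test asserts the
round trip.

## Signal chain and discretisation

The continuous plant is the series system: Butterworth reconstruction
filter on the DAC output → mechanical network → sensor voltage → ×1000
preamplifier → Butterworth anti-alias filter → ADC. It is discretised with
a zero-order hold at fs = 10 kHz. Two numerical details matter:

* High-order analogue Butterworth filters are realised as cascaded
  frequency-scaled second-order sections. A companion-form realisation
  carries coefficients up to ωc⁴ ≈ 4·10¹⁷ and destroys the conditioning of
  the matrix exponential used by the discretisation.
* The reconstruction filter is physically essential, not a convenience: the
  transducer plates give the stapes branch a resonance near 20 kHz, and the
  spectral images of a raw staircase DAC signal excite it, aliasing back
  into the audio band as deep interference notches in the actuator path.
  The converter-side filters remove those images.

Quantisation is uniform mid-tread with step Δu = 2·range/2^bits
(≈0.000305 V at 16 bit, ±10 V), clipping at the rails. Sensor noise is
modelled as white noise at the ADC input scaled by the preamp gain and
referred back to the sensor output; a pink option exists but is off by
default. Internal controller arithmetic is floating point — fixed-point
emulation is a non-goal.

## Adaptive feedback cancellation and MSG measurement

The canceller is a 100-tap FIR (10 ms at 10 kHz) adapted by normalised LMS
(step 0.05, ε = 1e−8; plain LMS selectable). Because the ADC path has no
direct feedthrough, the filter's reference history starts at the previous
actuator sample; frequency-domain comparisons therefore prepend a zero tap.

Convergence procedure: adapting against the measurement stimulus itself
would bias the filter, because the periodic multisine is predictable from
the actuator history — the filter would learn to cancel the stimulus
rather than the feedback. The canceller is instead converged in a
dedicated identification phase with the loudspeaker silent and a white
probe injected at the DAC (the same direct actuator excitation used to
measure the feedback path), in two stages: fast acquisition at the
configured step, then a ×0.1 step to shrink the steady-state weight noise.
Typical final misalignment is below −70 dB. The gain sweep and the
functional-gain stage then run with the converged weights held fixed.

The time-domain MSG sweep raises the forward gain in 0.5 dB steps
(configurable within 0.5–3 dB) from a start gain below the canceller-off
MSG, simulating a few multisine periods per step. A gain counts as stable
when (a) the windowed-RMS envelope of the cancelled signal never exceeds
10× its median, (b) no actuator sample clips at the ±1 V drive limit, and
(c) no spectral line protrudes more than 12 dB above the smoothed
stimulus-shaped spectrum. The 10× and 12 dB thresholds operationalise the
visual bench criterion ("no visible distortion, no feedback resonance
peaks"); they are this package's definitions. With the canceller
converged, the binding constraint on the default configuration is actuator
headroom (clipping), not loop stability — consistent with the observation
that functional gain is partly limited by maximum actuator output.

The frequency-domain MSG evaluates the unit-gain open loop
`μ₀(ω)·(F−F̂)(ω)` on a dense linear grid, finds the critical frequencies
where the unwrapped phase crosses multiples of 2π (never above fs/2 for a
sampled loop with ≥1 sample delay) and reports `min 1/|loop|` there,
capped at a +60 dB ceiling. Time- and frequency-domain MSG agree within
1 dB on linear loops without quantisation.

## Protocol, stimulus and estimation choices

The measurement protocol runs five stages: intact chain, idle insertion
(sensitivity + insertion loss), noise (threshold curve), actuator
performance (output + feedback path), functional gain. Stage 5 drives the
eardrum with a 50 dB SPL multisine, gain set to the swept MSG, and reports
aided-minus-idle stapes velocity per multisine bin.

The multisine is one 2048-point period with flat component amplitudes on
the exact FFT bins of 100–2500 Hz and a seeded uniform-random phase
schedule (Schroeder phases optional); transfer estimates average whole
periods after discarding the first, which is exact at bin frequencies for
periodic stimuli. The inner-ear microphone does not exist in the lumped
network; it is emulated as a first-order high-pass conversion from stapes
velocity to cavity pressure (corner 150 Hz, 50 Pa per mm/s) so the
calibration stage is a genuine cross-spectral estimation exercise.

## Fitting

Required gain defaults to half the hearing loss at every audiometric
frequency; a per-frequency coefficient table can override the constant.
Indication interpolates achieved and required gain linearly in
log-frequency over their overlapping support. Loudness compression is out
of scope; the only output limit is the actuator's 1 V ceiling. The shipped
example audiogram is synthetic (a typical high-frequency sloping loss),
labelled as such in its filename.

## What the synthetic model does and does not show

Passing tests demonstrate the *mechanisms* — mass-loading shifts, recoil
crossover, sampling-delay stabilisation, adaptive cancellation headroom —
on a self-consistent linear stand-in. They do not certify behaviour of
real temporal bones: the model has a single feedback path (the frame),
omits acoustic cavity paths and body noise, has no ±10 dB inter-individual
spread, and its damping levels were chosen for the calibration targets
rather than measured. Two known quantitative deviations: the low-frequency
functional gain reaches ≈20–28 dB below 800 Hz (slightly above the
10–25 dB bench range, because the achieved stable gain here is ≈2 dB
higher), and the "clamped frame equals the sum of the two free-floating
curves" idealisation holds only above ≈2 kHz (within 1.5 dB) — with
compliant plates the identity is not exact near the chain resonances.

## Numerical conventions

Velocities in mm/s, pressures in Pa, voltages in V, dB SPL re 20 µPa.
Complex responses are stored on strictly ascending positive frequency
grids; interpolation is linear on real/imaginary parts. Instability aborts
a simulation once the cancelled signal exceeds 10⁶ V. All stochastic runs
take an explicit seed (default 20140807); identical (config, seed) pairs
give byte-identical reports.
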
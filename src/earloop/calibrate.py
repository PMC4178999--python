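"""Scripted calibration of the default electromechanical parameters.

The mechanical network fixes the shape of every transfer function; the three
remaining free scalars are set by the calibration targets of the headline
device characterisation, exploiting linearity (each scaling is exact):

* ``sensor_coupling`` — sensor sensitivity of 1 mV per Pa at 1 kHz;
* ``actuator_coupling`` — maximum equivalent eardrum level of 120 dB SPL at
  the 1 V drive limit, over the default analysis grid;
* ``noise.rms_volts`` — sensor hearing threshold of 25 dB SPL at the worst
  frequency inside the calibrated band (so the whole band stays at or below
  25 dB SPL).

Run ``python -m earloop.calibrate`` (or ``earloop calibrate``) to print the
calibrated values; the shipped ``data/default.yaml`` contains exactly these.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import RunConfig
from .middle_ear import metf
from .network import FrequencyGrid
from .transducer import (actuator_response, equivalent_spl, pressure_from_spl,
                         sensor_sensitivity)

__all__ = [
    "SENSITIVITY_TARGET_MV_PA",
    "MAX_OUTPUT_TARGET_SPL",
    "THRESHOLD_TARGET_SPL",
    "calibrate",
]

SENSITIVITY_TARGET_MV_PA = 1.0
SENSITIVITY_TARGET_HZ = 1000.0
MAX_OUTPUT_TARGET_SPL = 120.0
THRESHOLD_TARGET_SPL = 25.0


def calibrate(cfg: RunConfig) -> RunConfig:
    """Return a copy of ``cfg`` with couplings and noise floor calibrated."""
    exp = cfg.experiment
    grid = FrequencyGrid.default(exp.grid_points, exp.grid_f_min,
                                 exp.grid_f_max)
    me, td = cfg.middle_ear, cfg.transducer

    # sensor coupling: sensitivity is exactly linear in the coupling
    point = FrequencyGrid(np.array([SENSITIVITY_TARGET_HZ]))
    s_now = abs(sensor_sensitivity(me, td, point).values[0])
    g_s = td.sensor_coupling * SENSITIVITY_TARGET_MV_PA / s_now

    # actuator coupling: equivalent SPL is linear in the coupling too
    td_s = dataclasses.replace(td, sensor_coupling=g_s)
    act = actuator_response(me, td_s, td.max_drive_voltage, grid)
    spl = equivalent_spl(act.magnitude * td.max_drive_voltage,
                         metf(me.with_state("intact"), grid))
    p_target = pressure_from_spl(MAX_OUTPUT_TARGET_SPL)
    p_now = pressure_from_spl(float(np.max(spl)))
    g_a = td.actuator_coupling * p_target / p_now

    # noise floor: threshold <= 25 dB SPL over the calibrated band
    td_cal = dataclasses.replace(td_s, actuator_coupling=g_a)
    sens = sensor_sensitivity(me, td_cal, grid)
    lo, hi = exp.calibrated_band
    band = (grid.frequencies >= lo) & (grid.frequencies <= hi)
    s_min = float(np.min(sens.magnitude[band])) * 1e-3  # V/Pa
    v_noise = s_min * pressure_from_spl(THRESHOLD_TARGET_SPL)

    noise = dataclasses.replace(cfg.noise, rms_volts=v_noise)
    return dataclasses.replace(cfg, transducer=td_cal, noise=noise)


def main() -> None:  # pragma: no cover - convenience entry point
    from .config import default_config
    cal = calibrate(default_config())
    print(f"sensor_coupling   = {cal.transducer.sensor_coupling:.10e}  V/N")
    print(f"actuator_coupling = {cal.transducer.actuator_coupling:.10e}  N/V")
    print(f"noise.rms_volts   = {cal.noise.rms_volts:.10e}  V")


if __name__ == "__main__":  # pragma: no cover
    main()
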
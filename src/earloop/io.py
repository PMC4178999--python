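"""Tabular writers/readers and provenance helpers.

Frequency responses are exchanged as CSV with columns ``frequency_hz,
magnitude, phase_rad, input_unit, output_unit``; values round-trip at full
float precision (re-reading reproduces the complex values exactly).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .network import FrequencyGrid, FrequencyResponse

__all__ = ["write_response_table", "read_response_table",
           "write_json_report", "write_signal_wav"]

_COLUMNS = ["frequency_hz", "magnitude", "phase_rad",
            "input_unit", "output_unit"]


def write_response_table(fr: FrequencyResponse | None,
                         path: str | Path) -> Path:
    """Write a frequency response as CSV; ``None`` writes a header-only file."""
    path = Path(path)
    if fr is None:
        pd.DataFrame(columns=_COLUMNS).to_csv(path, index=False)
        return path
    df = pd.DataFrame({
        "frequency_hz": fr.frequencies,
        "magnitude": fr.magnitude,
        "phase_rad": fr.phase,
        "input_unit": fr.input_unit,
        "output_unit": fr.output_unit,
    })
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_response_table(path: str | Path) -> FrequencyResponse | None:
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"response table missing columns {sorted(missing)}")
    if len(df) == 0:
        return None
    vals = df["magnitude"].to_numpy() * np.exp(1j * df["phase_rad"].to_numpy())
    return FrequencyResponse(FrequencyGrid(df["frequency_hz"].to_numpy()),
                             vals, str(df["input_unit"].iloc[0]),
                             str(df["output_unit"].iloc[0]))


def write_signal_wav(x: np.ndarray, fs: float, path: str | Path) -> Path:
    """Write a sampled signal as 32-bit float WAV (no amplitude rescaling)."""
    from scipy.io import wavfile
    path = Path(path)
    wavfile.write(path, int(round(fs)), np.asarray(x, dtype=np.float32))
    return path


def write_json_report(data: dict, cfg: RunConfig, path: str | Path) -> Path:
    """JSON report with the run's provenance block attached."""
    path = Path(path)
    payload = dict(data)
    payload["provenance"] = cfg.provenance()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
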
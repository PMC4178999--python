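"""Audiogram handling, Berger-style gain prescription and indication.

The prescription rule assigns each audiometric frequency a required gain of
(by default) half the hearing loss; a per-frequency coefficient table can
override the half-gain constant.  The indication report compares the
achieved functional-gain curve of the device with the prescription,
interpolating both linearly in log-frequency over the overlapping support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FittingConfig

__all__ = [
    "Audiogram",
    "PrescribedGain",
    "IndicationReport",
    "berger_required_gain",
    "indication",
]

#: Standard audiometric frequencies (Hz).
AUDIOMETRIC_FREQUENCIES = (125.0, 250.0, 500.0, 750.0, 1000.0, 1500.0,
                           2000.0, 3000.0, 4000.0, 6000.0, 8000.0)


@dataclass
class Audiogram:
    """Hearing level (dB HL) per audiometric frequency."""

    frequencies: np.ndarray
    hearing_level_db: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        hl = np.asarray(self.hearing_level_db, dtype=float)
        if f.size == 0 or f.shape != hl.shape:
            raise ValueError("audiogram needs matching, non-empty arrays")
        if np.any(np.diff(f) <= 0):
            raise ValueError("audiogram frequencies must be ascending")
        if np.any(hl < -10.0) or np.any(hl > 120.0):
            raise ValueError("hearing levels must lie in [-10, 120] dB HL")
        self.frequencies = f
        self.hearing_level_db = hl

    @classmethod
    def from_csv(cls, path: str | Path) -> "Audiogram":
        df = pd.read_csv(path)
        if not {"frequency_hz", "hl_db"} <= set(df.columns):
            raise ValueError("audiogram CSV needs columns frequency_hz, hl_db")
        df = df.sort_values("frequency_hz")
        return cls(df["frequency_hz"].to_numpy(), df["hl_db"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"frequency_hz": self.frequencies,
                      "hl_db": self.hearing_level_db}).to_csv(path,
                                                              index=False)


@dataclass
class PrescribedGain:
    """Required gain (dB) per frequency with the prescription method label."""

    frequencies: np.ndarray
    gain_db: np.ndarray
    method: str = "berger_half_gain"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.gain_db)):
            raise ValueError("prescribed gains must be finite")


def berger_required_gain(audiogram: Audiogram,
                         fitting: FittingConfig | None = None
                         ) -> PrescribedGain:
    """Berger-style prescription: gain near half the hearing loss.

    The default coefficient is 0.5 at every frequency; published
    per-frequency Berger coefficients can be supplied through
    ``fitting.berger_coefficients`` (interpolated in log-frequency between
    table entries).
    """
    fitting = fitting if fitting is not None else FittingConfig()
    f = audiogram.frequencies
    if fitting.berger_coefficients:
        tbl_f = np.array(sorted(fitting.berger_coefficients))
        tbl_c = np.array([fitting.berger_coefficients[k] for k in tbl_f])
        coef = np.interp(np.log10(f), np.log10(tbl_f), tbl_c)
    else:
        coef = np.full_like(f, fitting.default_coefficient)
    return PrescribedGain(f, coef * audiogram.hearing_level_db)


@dataclass
class IndicationReport:
    """Achieved-versus-required gain comparison on a common frequency set."""

    frequencies: np.ndarray
    achieved_db: np.ndarray
    required_db: np.ndarray
    margin_db: np.ndarray = field(init=False)
    indicated: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.margin_db = self.achieved_db - self.required_db
        self.indicated = self.margin_db >= 0.0

    @property
    def verdict(self) -> str:
        if np.all(self.indicated):
            return "indicated"
        if not np.any(self.indicated):
            return "not indicated"
        return "partially indicated"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frequency_hz": self.frequencies,
            "achieved_gain_db": self.achieved_db,
            "required_gain_db": self.required_db,
            "margin_db": self.margin_db,
            "indicated": self.indicated,
        })

    def to_dict(self) -> dict:
        return {
            "frequencies_hz": self.frequencies.tolist(),
            "achieved_gain_db": self.achieved_db.tolist(),
            "required_gain_db": self.required_db.tolist(),
            "margin_db": self.margin_db.tolist(),
            "verdict": self.verdict,
        }


def indication(achieved_frequencies: np.ndarray, achieved_gain_db: np.ndarray,
               required: PrescribedGain) -> IndicationReport:
    """Compare achieved functional gain with a prescription.

    Both curves are interpolated linearly in log-frequency onto the union of
    their supports restricted to the overlap; an empty overlap is an error.
    """
    af = np.asarray(achieved_frequencies, dtype=float)
    ag = np.asarray(achieved_gain_db, dtype=float)
    lo = max(af.min(), required.frequencies.min())
    hi = min(af.max(), required.frequencies.max())
    if lo > hi:
        raise ValueError("no overlapping frequency support")
    f = np.unique(np.concatenate([af, required.frequencies]))
    f = f[(f >= lo) & (f <= hi)]
    achieved = np.interp(np.log10(f), np.log10(af), ag)
    req = np.interp(np.log10(f), np.log10(required.frequencies),
                    required.gain_db)
    return IndicationReport(f, achieved, req)
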
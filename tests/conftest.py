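"""Shared fixtures: the calibrated default configuration and the expensive
session-wide simulation products (discrete plant, protocol run)."""

from __future__ import annotations

import numpy as np
import pytest

from earloop.config import RunConfig, default_config
from earloop.experiments import run_protocol
from earloop.network import FrequencyGrid
from earloop.transducer import coupled_plant


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return default_config()


@pytest.fixture(scope="session")
def grid() -> FrequencyGrid:
    return FrequencyGrid.default()


@pytest.fixture(scope="session")
def plant(cfg):
    p = coupled_plant(cfg.middle_ear, cfg.transducer, cfg.signal_chain)
    p._true_feedback_ir = p.feedback_impulse(401)[1:]
    return p


@pytest.fixture(scope="session")
def protocol_result(cfg):
    """Full five-stage protocol incl. the LMS-on time-domain gain sweep."""
    return run_protocol(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140807)
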
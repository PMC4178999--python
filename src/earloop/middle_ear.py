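"""Lumped middle-ear model: topology builder and transfer functions.

The ossicular chain is reduced to a one-dimensional chain of point masses:

    ground --(k_td)-- eardrum --(manubrium)-- ossicles --(joint)-- stapes
                                                |                    |
                                            ligaments          annular lig.
                                                                     |
                                                              cochlear load

With the transducer inserted the incudostapedial joint spring is replaced by
sensor plate -- frame (35 mg) -- actuator plate, so that actuator recoil
drives the sensor side through the shared frame (the dominant feedback path
of a free-floating device).  ``transducer_fixed_frame`` additionally clamps
the frame rigidly, the idealised fixation reference case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MiddleEarConfig, TransducerConfig
from .network import (GROUND, FrequencyGrid, FrequencyResponse, MechNetwork,
                      ModelError)

__all__ = [
    "HarmonicExcitation",
    "build_middle_ear",
    "build_opened_joint",
    "harmonic_response",
    "metf",
    "joint_point_response",
]

# Node names used by all builders.
EARDRUM, OSSICLES, STAPES, COCHLEA, FRAME = (
    "eardrum", "ossicles", "stapes", "cochlea", "frame")


@dataclass(frozen=True)
class HarmonicExcitation:
    """Harmonic drive applied per grid frequency.

    ``kind`` selects the physical input: a direct force (N), an eardrum
    pressure (Pa, converted through the effective drum area) or an actuator
    voltage (V, transducer states only).
    """

    node: str
    kind: str = "force"           # force | pressure | voltage
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("force", "pressure", "voltage"):
            raise ValueError(f"unknown excitation kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("excitation amplitude must be >= 0")


def _add_stapes_side(net: MechNetwork, cfg: MiddleEarConfig) -> None:
    net.add_node(STAPES, cfg.stapes_mass)
    net.add_node(COCHLEA, cfg.cochlea_mass)
    net.add_edge(STAPES, GROUND, cfg.annular_stiffness, cfg.annular_damping,
                 cfg.loss_factor)
    net.add_edge(STAPES, COCHLEA, cfg.cochlea_stiffness, cfg.cochlea_damping)


def _add_incus_side(net: MechNetwork, cfg: MiddleEarConfig) -> None:
    net.add_node(EARDRUM, cfg.eardrum_mass)
    net.add_node(OSSICLES, cfg.malleus_incus_mass)
    net.add_edge(EARDRUM, GROUND, cfg.eardrum_stiffness, cfg.eardrum_damping,
                 cfg.loss_factor)
    net.add_edge(EARDRUM, OSSICLES, cfg.malleus_coupling_stiffness,
                 cfg.malleus_coupling_damping, cfg.loss_factor)
    net.add_edge(OSSICLES, GROUND, cfg.ligament_stiffness,
                 cfg.ligament_damping, cfg.loss_factor)


def build_middle_ear(config: MiddleEarConfig,
                     transducer: TransducerConfig | None = None
                     ) -> MechNetwork:
    """Assemble the network for the configured topology state.

    ``intact`` joins incus and stapes by the incudostapedial joint spring.
    The three ``transducer_*`` states insert the two-plate device instead;
    ``transducer_fixed_frame`` also clamps the frame node rigidly.
    """
    net = MechNetwork()
    _add_incus_side(net, config)
    _add_stapes_side(net, config)
    if config.state == "intact":
        net.add_edge(OSSICLES, STAPES, config.isj_stiffness,
                     config.isj_damping, config.loss_factor)
        return net
    td = transducer if transducer is not None else TransducerConfig()
    net.add_node(FRAME, td.frame_mass)
    net.add_edge(OSSICLES, FRAME, td.sensor_plate_stiffness,
                 td.sensor_plate_damping)
    net.add_edge(FRAME, STAPES, td.actuator_plate_stiffness,
                 td.actuator_plate_damping)
    if config.state == "transducer_fixed_frame":
        net.ground_node(FRAME)
    return net


def build_opened_joint(config: MiddleEarConfig) -> tuple[MechNetwork,
                                                         MechNetwork]:
    """Two disjoint networks after opening the incudostapedial joint.

    Returns ``(incus_side, stapes_side)``: the eardrum/ossicle assembly and
    the stapes/annular-ligament/cochlea assembly.
    """
    inc = MechNetwork()
    _add_incus_side(inc, config)
    st = MechNetwork()
    _add_stapes_side(st, config)
    return inc, st


def harmonic_response(network: MechNetwork, excitation: HarmonicExcitation,
                      observe: str, grid: FrequencyGrid,
                      quantity: str = "velocity", *,
                      config: MiddleEarConfig | None = None,
                      transducer: TransducerConfig | None = None
                      ) -> FrequencyResponse:
    """Response of one node to a harmonic excitation, solved per grid point.

    Velocity responses are ``i w`` times the displacement solution.  Pressure
    excitation requires ``config`` (for the drum area); voltage excitation
    requires ``transducer`` and a network containing the frame node.
    """
    if excitation.kind == "force":
        loads = {excitation.node: complex(excitation.amplitude)}
        in_unit = "N"
    elif excitation.kind == "pressure":
        if config is None:
            raise ValueError("pressure excitation requires the middle-ear config")
        loads = {excitation.node:
                 complex(excitation.amplitude * config.eardrum_area)}
        in_unit = "Pa"
    else:  # voltage: equal-and-opposite force pair across the actuator plate
        if transducer is None:
            raise ValueError("voltage excitation requires the transducer config")
        if FRAME not in network.node_names:
            raise ModelError("voltage excitation needs an inserted transducer")
        f = excitation.amplitude * transducer.actuator_coupling
        loads = {STAPES: complex(f), FRAME: complex(-f)}
        in_unit = "V"
    fr = network.response(loads, observe, grid, quantity, input_unit=in_unit)
    if quantity == "velocity":  # report mm/s, the conventional axis unit
        fr = FrequencyResponse(grid, fr.values * 1e3, in_unit, "mm/s")
    return fr


def metf(config: MiddleEarConfig, grid: FrequencyGrid,
         transducer: TransducerConfig | None = None) -> FrequencyResponse:
    """Middle-ear transfer function: stapes velocity per eardrum pressure.

    Units mm/s per Pa.  Valid for the ``intact`` and ``transducer_idle``
    states (an idle device only mass-loads the chain).
    """
    if config.state not in ("intact", "transducer_idle"):
        raise ValueError(
            f"metf is defined for intact/transducer_idle, got {config.state!r}")
    net = build_middle_ear(config, transducer)
    exc = HarmonicExcitation(EARDRUM, "pressure", 1.0)
    return harmonic_response(net, exc, STAPES, grid, "velocity", config=config)


def joint_point_response(config: MiddleEarConfig, side: str, force_n: float,
                         grid: FrequencyGrid) -> FrequencyResponse:
    """Point mobility of one side of the opened incudostapedial joint.

    A lateral force of ``force_n`` newton is applied to the incus long
    process or the stapes head and the velocity of the driven node is
    returned (mm/s per the applied force).
    """
    if side not in ("incus", "stapes"):
        raise ValueError(f"side must be 'incus' or 'stapes', got {side!r}")
    inc, st = build_opened_joint(config)
    node = OSSICLES if side == "incus" else STAPES
    net = inc if side == "incus" else st
    exc = HarmonicExcitation(node, "force", force_n)
    return harmonic_response(net, exc, node, grid, "velocity")


def first_peak_frequency(fr: FrequencyResponse) -> float:
    """Frequency of the largest-magnitude peak of a response curve."""
    mag = fr.magnitude
    return float(fr.frequencies[int(np.argmax(mag))])
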
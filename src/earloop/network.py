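"""Linear mass–spring–damper networks: assembly, harmonic solve, state space.

A :class:`MechNetwork` is a one-dimensional ("piston mode") network of point
masses connected by spring/damper edges.  Every coordinate is a translation
along a single axis; ossicle rotation and rocking modes are outside the scope
of this model.  The network supports

* frequency-domain harmonic analysis, solving
  ``(K + i K_eta + i w C - w^2 M) x = f`` per grid frequency, where ``K_eta``
  collects optional structural (hysteretic) loss-factor terms, and
* export of a continuous-time state-space model (viscous damping only) for
  time-domain simulation of the sampled control loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "GROUND",
    "ModelError",
    "Edge",
    "MechNetwork",
    "FrequencyGrid",
    "FrequencyResponse",
]

#: Name of the implicit rigid reference node.
GROUND = "ground"


class ModelError(ValueError):
    """Raised for ill-posed networks (disconnected nodes, singular systems)."""


# ---------------------------------------------------------------------------
# frequency grid / response containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly ascending positive analysis frequencies in Hz.

    ``analysis_limit`` bounds the grid (the lumped model is not meant to be
    evaluated above it); points above ``validity_limit`` are still computed
    but flagged, mirroring the restricted validity band of bench-type
    middle-ear models.
    """

    frequencies: np.ndarray
    analysis_limit: float = 5000.0
    validity_limit: float = 2500.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if np.any(f <= 0.0):
            raise ValueError("all grid frequencies must be > 0")
        if np.any(np.diff(f) <= 0.0):
            raise ValueError("grid frequencies must be strictly ascending")
        if f[-1] > self.analysis_limit * (1 + 1e-12):
            raise ValueError(
                f"grid exceeds analysis limit ({f[-1]:.1f} > "
                f"{self.analysis_limit:.1f} Hz)"
            )

    def __len__(self) -> int:
        return int(self.frequencies.size)

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies (rad/s)."""
        return 2.0 * np.pi * self.frequencies

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of points within the validity band."""
        return self.frequencies <= self.validity_limit

    # -- presets ------------------------------------------------------------

    @classmethod
    def default(cls, n: int = 128, f_min: float = 100.0,
                f_max: float = 5000.0) -> "FrequencyGrid":
        """Logarithmic grid, 128 points over 100 Hz – 5 kHz by default."""
        return cls(np.geomspace(f_min, f_max, n))

    @classmethod
    def coarse(cls) -> "FrequencyGrid":
        """Ten logarithmic points up to 5 kHz (parity preset)."""
        return cls(np.geomspace(100.0, 5000.0, 10))


@dataclass
class FrequencyResponse:
    """Complex transfer values on a :class:`FrequencyGrid` with unit labels."""

    grid: FrequencyGrid
    values: np.ndarray
    input_unit: str = ""
    output_unit: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        if v.shape != self.grid.frequencies.shape:
            raise ValueError("values and grid lengths differ")
        if not np.all(np.isfinite(v)):
            raise ValueError("frequency response contains non-finite values")
        self.values = v

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def magnitude_db(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 20.0 * np.log10(np.abs(self.values))

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def at(self, f: float) -> complex:
        """Complex value at ``f`` (linear interpolation of re/im parts)."""
        fr = self.frequencies
        if not (fr[0] <= f <= fr[-1]):
            raise ValueError(f"{f} Hz outside grid [{fr[0]}, {fr[-1]}]")
        re = np.interp(f, fr, self.values.real)
        im = np.interp(f, fr, self.values.imag)
        return complex(re, im)

    def scaled(self, a: complex) -> "FrequencyResponse":
        return FrequencyResponse(self.grid, self.values * a,
                                 self.input_unit, self.output_unit)

    def unit_label(self) -> str:
        return f"{self.output_unit}/{self.input_unit}"


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Edge:
    """Spring/damper between two nodes (``GROUND`` allowed on either end).

    ``eta`` is an optional structural loss factor: the edge stiffness enters
    the harmonic stiffness matrix as ``k * (1 + i*eta)``.  Structural damping
    has no time-domain realisation and is ignored by :meth:`state_space`.
    """

    a: str
    b: str
    k: float = 0.0
    c: float = 0.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ModelError(f"edge connects node {self.a!r} to itself")
        for name, val in (("k", self.k), ("c", self.c), ("eta", self.eta)):
            if val < 0.0:
                raise ModelError(f"edge {self.a}-{self.b}: {name} < 0")


class MechNetwork:
    """One-dimensional lumped mechanical network."""

    def __init__(self) -> None:
        self._mass: dict[str, float] = {}
        self._edges: list[Edge] = []
        self._grounded: set[str] = set()

    # -- construction -------------------------------------------------------

    def add_node(self, name: str, mass: float) -> None:
        if name == GROUND:
            raise ModelError("'ground' is reserved")
        if name in self._mass:
            raise ModelError(f"duplicate node {name!r}")
        if mass < 0.0:
            raise ModelError(f"node {name!r}: negative mass")
        self._mass[name] = float(mass)

    def add_edge(self, a: str, b: str, k: float = 0.0, c: float = 0.0,
                 eta: float = 0.0) -> None:
        for n in (a, b):
            if n != GROUND and n not in self._mass:
                raise ModelError(f"edge references unknown node {n!r}")
        self._edges.append(Edge(a, b, k, c, eta))

    def ground_node(self, name: str) -> None:
        """Rigidly constrain a node (its coordinate is removed)."""
        if name not in self._mass:
            raise ModelError(f"unknown node {name!r}")
        self._grounded.add(name)

    # -- introspection ------------------------------------------------------

    @property
    def node_names(self) -> list[str]:
        return list(self._mass)

    @property
    def dofs(self) -> list[str]:
        return [n for n in self._mass if n not in self._grounded]

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges)

    def total_mass(self) -> float:
        """Total moving (non-grounded) mass in kg."""
        return sum(m for n, m in self._mass.items() if n not in self._grounded)

    def is_grounded(self, name: str) -> bool:
        return name in self._grounded

    def _check_connected(self) -> None:
        """Every free node must reach ground through edges with k>0 or c>0."""
        adj: dict[str, set[str]] = {n: set() for n in self._mass}
        adj[GROUND] = set()
        for e in self._edges:
            if e.k > 0.0 or e.c > 0.0:
                adj[e.a].add(e.b)
                adj[e.b].add(e.a)
        seen = {GROUND} | set(self._grounded)
        stack = list(seen)
        while stack:
            for nb in adj.get(stack.pop(), ()):  # grounded nodes anchor too
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        missing = [n for n in self.dofs if n not in seen]
        if missing:
            raise ModelError(f"nodes not connected to ground: {missing}")
        if not any(e.c > 0.0 or e.eta > 0.0 for e in self._edges):
            raise ModelError("network has no damping element")

    # -- assembly -----------------------------------------------------------

    def _index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.dofs)}

    def assemble(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (M, K, C, K_eta); K_eta is the structural-loss matrix."""
        self._check_connected()
        idx = self._index()
        n = len(idx)
        M = np.diag([self._mass[name] for name in self.dofs])
        K = np.zeros((n, n))
        C = np.zeros((n, n))
        Keta = np.zeros((n, n))
        for e in self._edges:
            ia = idx.get(e.a) if e.a not in self._grounded and e.a != GROUND else None
            ib = idx.get(e.b) if e.b not in self._grounded and e.b != GROUND else None
            for (i, j, s) in ((ia, ia, 1.0), (ib, ib, 1.0),
                              (ia, ib, -1.0), (ib, ia, -1.0)):
                if i is None or j is None:
                    continue
                K[i, j] += s * e.k
                C[i, j] += s * e.c
                Keta[i, j] += s * e.k * e.eta
        return M, K, C, Keta

    def force_vector(self, loads: dict[str, complex]) -> np.ndarray:
        """Dense force vector from a ``{node: amplitude}`` mapping (N)."""
        idx = self._index()
        f = np.zeros(len(idx), dtype=complex)
        for name, amp in loads.items():
            if name in self._grounded:
                continue  # forces on constrained nodes are reacted rigidly
            if name not in idx:
                raise ModelError(f"force on unknown node {name!r}")
            f[idx[name]] = amp
        return f

    # -- harmonic analysis --------------------------------------------------

    def harmonic(self, loads: dict[str, complex],
                 grid: FrequencyGrid) -> dict[str, np.ndarray]:
        """Complex displacement per node (m) for each grid frequency.

        Grounded nodes report identically zero displacement.
        """
        M, K, C, Keta = self.assemble()
        f = self.force_vector(loads)
        w = grid.omega
        n = len(self.dofs)
        # Stack (nfreq, n, n) dynamic stiffness matrices and solve in one go.
        A = (K[None, :, :] + 1j * Keta[None, :, :]
             + 1j * w[:, None, None] * C[None, :, :]
             - (w ** 2)[:, None, None] * M[None, :, :])
        try:
            rhs = np.broadcast_to(f[:, None], (n, 1))
            X = np.linalg.solve(A, np.broadcast_to(rhs, (len(w), n, 1)))[:, :, 0]
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise ModelError(f"singular harmonic system: {exc}") from exc
        if not np.all(np.isfinite(X)):
            raise ModelError("harmonic solve produced non-finite response")
        out = {name: X[:, i] for name, i in self._index().items()}
        for name in self._grounded:
            out[name] = np.zeros(len(w), dtype=complex)
        return out

    def response(self, loads: dict[str, complex], observe: str,
                 grid: FrequencyGrid, quantity: str = "velocity",
                 input_unit: str = "N",
                 output_unit: str | None = None) -> FrequencyResponse:
        """Harmonic response of one node, as displacement (m) or velocity (m/s)."""
        if observe not in self._mass:
            raise ModelError(f"unknown observation node {observe!r}")
        disp = self.harmonic(loads, grid)[observe]
        if quantity == "displacement":
            vals, unit = disp, "m"
        elif quantity == "velocity":
            vals, unit = 1j * grid.omega * disp, "m/s"
        else:
            raise ValueError(f"unknown quantity {quantity!r}")
        return FrequencyResponse(grid, vals, input_unit,
                                 output_unit if output_unit is not None else unit)

    def edge_force(self, a: str, b: str, displacements: dict[str, np.ndarray],
                   grid: FrequencyGrid) -> np.ndarray:
        """Complex force carried by the (first) edge between ``a`` and ``b`` (N).

        Positive sign convention: force pulling the two nodes together when
        ``x_a > x_b``.
        """
        for e in self._edges:
            if {e.a, e.b} == {a, b}:
                xa = displacements.get(e.a, 0.0) if e.a != GROUND else 0.0
                xb = displacements.get(e.b, 0.0) if e.b != GROUND else 0.0
                rel = np.asarray(xa) - np.asarray(xb)
                return (e.k * (1 + 1j * e.eta)
                        + 1j * grid.omega * e.c) * rel
        raise ModelError(f"no edge between {a!r} and {b!r}")

    def driving_point_mobility(self, node: str,
                               grid: FrequencyGrid) -> FrequencyResponse:
        """Velocity of ``node`` per unit collocated force (m/s per N)."""
        return self.response({node: 1.0}, node, grid, "velocity",
                             input_unit="N", output_unit="m/s")

    # -- state space --------------------------------------------------------

    def state_space(self, inputs: list[dict[str, float]],
                    outputs: list[tuple[str, object]]) -> signal.StateSpace:
        """Continuous-time LTI model (viscous damping only).

        Parameters
        ----------
        inputs
            One force-distribution mapping ``{node: weight}`` per input; the
            physical input is a force in N multiplied into the distribution.
        outputs
            ``(kind, spec)`` tuples: ``("displacement", node)``,
            ``("velocity", node)`` or ``("edge_force", (a, b))``.
        """
        M, K, C, _ = self.assemble()
        idx = self._index()
        n = len(idx)
        Minv = np.linalg.inv(M)
        A = np.zeros((2 * n, 2 * n))
        A[:n, n:] = np.eye(n)
        A[n:, :n] = -Minv @ K
        A[n:, n:] = -Minv @ C
        B = np.zeros((2 * n, len(inputs)))
        for j, dist in enumerate(inputs):
            B[n:, j] = Minv @ self.force_vector(
                {k: complex(v) for k, v in dist.items()}).real
        rows = []
        for kind, spec in outputs:
            row = np.zeros(2 * n)
            if kind == "displacement":
                row[idx[spec]] = 1.0
            elif kind == "velocity":
                row[n + idx[spec]] = 1.0
            elif kind == "edge_force":
                a, b = spec
                e = next(e for e in self._edges if {e.a, e.b} == {a, b})
                for node, s in ((e.a, 1.0), (e.b, -1.0)):
                    if node == GROUND or node in self._grounded:
                        continue
                    row[idx[node]] += s * e.k
                    row[n + idx[node]] += s * e.c
                # orient row so that spec order (a, b) defines the sign
                if (e.a, e.b) != (a, b):
                    row = -row
            else:
                raise ValueError(f"unknown output kind {kind!r}")
            rows.append(row)
        Cmat = np.vstack(rows)
        D = np.zeros((Cmat.shape[0], len(inputs)))
        return signal.StateSpace(A, B, Cmat, D)
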
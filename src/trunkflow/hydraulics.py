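"""Resistance laws and the Kirchhoff network solve.

A vessel of length l and radius r carrying fluid of viscosity mu has the
Hagen-Poiseuille resistance R0 = 8 mu l / (pi r^4).  A narrow vessel
occupied by n red blood cells has resistance

    R(n) = R0 + n * alpha_c,

where alpha_c is the per-cell occlusion strength: the intrinsic hydraulic
resistance one cell adds while squeezing through.  The occlusive term is
applied only to Se vessels; the aorta is several cell diameters wide, so
the cells' contribution there is absorbed into the whole-blood viscosity,
and shunts are explicitly modelled as occlusion-free.

Flows follow from Kirchhoff's first law: net volumetric flux vanishes at
every interior vertex, the prescribed inflow F enters at the inflow
vertex, and boundary vertices sit at pressure zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import units
from .geometry import TrunkTopology, VesselKind

#: relative residual above which a linear solve is rejected
RESIDUAL_RTOL = 1e-10


def poiseuille_resistance(length: float, radius: float, viscosity: float) -> float:
    """Hagen-Poiseuille resistance 8 mu l / (pi r^4), g/(um^4 s)."""
    if length <= 0 or radius <= 0 or viscosity <= 0:
        raise ValueError("length, radius and viscosity must all be positive")
    return 8.0 * viscosity * length / (np.pi * radius**4)


def occluded_resistance(R0: float, n_cells: float, alpha_c: float) -> float:
    """Occupied-vessel resistance R0 + n alpha_c.

    ``n_cells`` is an integer count in the discrete traffic model and a
    real occupancy n = rho V in continuum mode.
    """
    if n_cells < 0:
        raise ValueError("cell count must be non-negative")
    return R0 + n_cells * alpha_c


@dataclass(frozen=True)
class OcclusionParams:
    """Viscosities, concentration, and per-vessel occlusion strengths.

    ``alpha_c`` maps vessel_id -> occlusion strength for Se vessels; any
    vessel not listed (and every non-Se vessel) gets zero.
    """

    alpha_c: dict[int, float] = field(default_factory=dict)
    mu_pl: float = units.MU_PLASMA
    mu_wb: float = units.MU_WHOLE_BLOOD
    rho: float = units.RHO_RBC
    cell_volume: float = units.CELL_VOLUME

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.alpha_c.values()):
            raise ValueError("occlusion strengths must be non-negative")
        if self.mu_pl > self.mu_wb:
            raise ValueError("plasma viscosity cannot exceed whole-blood viscosity")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")

    @classmethod
    def from_se_profile(cls, t: TrunkTopology, alphas, **kwargs) -> "OcclusionParams":
        """Assign per-Se occlusion strengths head-to-tail from a sequence."""
        se = t.se_vessels
        alphas = np.asarray(alphas, dtype=float)
        if len(alphas) != len(se):
            raise ValueError(f"expected {len(se)} alpha values, got {len(alphas)}")
        return cls(alpha_c={v.vessel_id: float(a) for v, a in zip(se, alphas)}, **kwargs)

    @classmethod
    def uniform(cls, t: TrunkTopology, alpha: float, **kwargs) -> "OcclusionParams":
        return cls.from_se_profile(t, np.full(t.n_se, alpha), **kwargs)


class ResistanceModel:
    """Per-vessel resistances for a topology under a viscosity mode.

    Two modes mirror the two transport models:

    ``"continuum_whole_blood"``
        whole-blood viscosity everywhere, no occlusive term: the plain
        hydraulic resistor network.
    ``"plasma_cells"``
        plasma viscosity in Se vessels plus the per-cell occlusion term;
        whole-blood viscosity in DA/TAIL/SHUNT vessels (cells' bulk
        contribution there is folded into mu_wb).
    """

    MODES = ("continuum_whole_blood", "plasma_cells")

    def __init__(self, t: TrunkTopology, params: OcclusionParams, mode: str = "plasma_cells"):
        if mode not in self.MODES:
            raise ValueError(f"unknown mode {mode!r}")
        self.topology = t
        self.params = params
        self.mode = mode
        bare = []
        alpha = []
        for v in t.vessels:
            if mode == "continuum_whole_blood":
                mu = params.mu_wb
                a = 0.0
            else:
                is_se = v.kind == VesselKind.SE
                mu = params.mu_pl if is_se else params.mu_wb
                a = params.alpha_c.get(v.vessel_id, 0.0) if is_se else 0.0
            bare.append(poiseuille_resistance(v.length, v.radius, mu))
            alpha.append(a)
        #: Poiseuille part of each vessel's resistance
        self.bare = np.array(bare)
        #: per-cell resistance increment of each vessel (0 off the Se)
        self.alpha = np.array(alpha)
        self._volumes = np.array([v.volume for v in t.vessels])
        self._is_se = np.array([v.kind == VesselKind.SE for v in t.vessels])

    def continuum_counts(self) -> np.ndarray:
        """Well-mixed occupancies n = rho V for Se vessels, 0 elsewhere."""
        return np.where(self._is_se, self.params.rho * self._volumes, 0.0)

    def total(self, counts: np.ndarray | None = None) -> np.ndarray:
        """R(n) = bare + n alpha per vessel; default n is the continuum value."""
        if counts is None:
            counts = self.continuum_counts()
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError("cell counts must be non-negative")
        return self.bare + counts * self.alpha


@dataclass(frozen=True)
class HydraulicState:
    """Solution of one Kirchhoff solve."""

    pressures: dict[int, float]  # determined vertices only; boundary is 0
    resistances: np.ndarray  # per vessel, aligned with topology.vessels
    flows: np.ndarray  # per vessel, signed head->tail positive, um^3/s
    inflow: float  # um^3/s

    def pressure(self, vertex: int) -> float:
        return self.pressures.get(vertex, 0.0)


class NetworkSolver:
    """Caches the incidence structure of a topology for repeated solves."""

    def __init__(self, t: TrunkTopology):
        self.topology = t
        determined = sorted(t.vertex_ids() - t.zero_pressure_vertices)
        if not determined:
            raise ValueError("every vertex is at fixed pressure; nothing to solve")
        self.determined = determined
        self._index = {v: k for k, v in enumerate(determined)}
        self._head_idx = np.array(
            [self._index.get(v.head_vertex, -1) for v in t.vessels], dtype=int
        )
        self._tail_idx = np.array(
            [self._index.get(v.tail_vertex, -1) for v in t.vessels], dtype=int
        )
        self._inflow_idx = self._index[t.inflow_vertex]

    def solve(self, resistances: np.ndarray, F: float) -> HydraulicState:
        resistances = np.asarray(resistances, dtype=float)
        if resistances.shape != (len(self.topology.vessels),):
            raise ValueError("one resistance per vessel required")
        if np.any(resistances <= 0):
            raise ValueError("resistances must be positive")
        g = 1.0 / resistances
        m = len(self.determined)
        A = np.zeros((m, m))
        h, t_ = self._head_idx, self._tail_idx
        for k in range(len(g)):
            i, j = h[k], t_[k]
            if i >= 0:
                A[i, i] += g[k]
            if j >= 0:
                A[j, j] += g[k]
            if i >= 0 and j >= 0:
                A[i, j] -= g[k]
                A[j, i] -= g[k]
        b = np.zeros(m)
        b[self._inflow_idx] = F
        if m > 200:
            p = spla.spsolve(sp.csr_matrix(A), b)
        else:
            try:
                p = np.linalg.solve(A, b)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    "singular hydraulic system: no zero-pressure vertex is "
                    "reachable from some determined vertex"
                ) from exc
        scale = max(abs(F), float(np.max(np.abs(A @ p)))) or 1.0
        residual = float(np.max(np.abs(A @ p - b)))
        if residual > RESIDUAL_RTOL * scale:
            raise ValueError(
                f"hydraulic solve failed the residual check ({residual:.3e}); "
                "the network is singular or ill-conditioned"
            )
        p_head = np.where(h >= 0, p[np.clip(h, 0, None)], 0.0)
        p_tail = np.where(t_ >= 0, p[np.clip(t_, 0, None)], 0.0)
        flows = (p_head - p_tail) * g
        return HydraulicState(
            pressures={v: float(p[k]) for k, v in enumerate(self.determined)},
            resistances=resistances,
            flows=flows,
            inflow=F,
        )


def solve_flows(t: TrunkTopology, resistances: np.ndarray, F: float) -> HydraulicState:
    """Solve the hydraulic network for pressures and signed vessel flows."""
    return NetworkSolver(t).solve(resistances, F)


def network_dissipation(
    state: HydraulicState,
    model: ResistanceModel,
    counts: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Viscous power loss sum_i R_i Q_i^2, split into plasma and cell terms.

    The plasma term collects the Poiseuille parts of all resistances; the
    cell term collects the n alpha_c occlusive parts.  With the boundary
    at pressure zero the total equals F * p(inflow).  Units: g um^2/s^3.
    """
    if counts is None:
        counts = model.continuum_counts()
    q2 = state.flows**2
    plasma = float(np.sum(model.bare * q2))
    cell = float(np.sum(np.asarray(counts, dtype=float) * model.alpha * q2))
    return plasma, cell, plasma + cell


@dataclass(frozen=True)
class FlowDiagnostics:
    womersley: float
    entry_length: float  # um


def flow_diagnostics(d: float, nu: float, f: float, U: float) -> FlowDiagnostics:
    """Unsteadiness and entry-region diagnostics for a vessel.

    Arguments keep the conventional units of the source measurements:
    ``d`` in um, ``nu`` in m^2/s, ``f`` in 1/s, ``U`` in m/s.

    The Womersley number sqrt(2 pi f d^2 / nu) measures pulsatile
    effects; well below 1 the flow is quasi-steady.  The entry length
    U d^2 / nu (returned in um) is the upper-bound scale over which the
    parabolic profile develops; the bare scale is reported without a
    prefactor.
    """
    if d < 0 or nu <= 0 or f < 0 or U < 0:
        raise ValueError("diagnostic arguments must be non-negative (nu positive)")
    d_m = d * 1e-6
    womersley = float(np.sqrt(2 * np.pi * f * d_m**2 / nu))
    entry_length_um = U * d_m**2 / nu * 1e6
    return FlowDiagnostics(womersley=womersley, entry_length=float(entry_length_um))
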
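"""Discrete red-blood-cell traffic on the trunk network.

Every cell trajectory is simulated directly.  Each time step:

1. per-vessel cell counts set the vessel resistances through
   R(n) = R0 + n alpha_c (Se vessels only);
2. the hydraulic network is re-solved for flows;
3. cells advance at the plug-flow velocity v = Q / (pi r^2) of their
   vessel, carrying any unused fraction of the step across vertices;
4. at a diverging vertex the next vessel is drawn by a Bernoulli choice
   with probability proportional to the outgoing flows (the
   Zweifach-Fung effect is deliberately suppressed);
5. cells reaching a zero-pressure outlet are immediately re-injected at
   the aorta inlet within the same step, so the circulating cell count
   is conserved exactly.

The negative feedback loop -- a cell in a narrow vessel raises its
resistance, lowering its flow and with it the probability that the next
cell follows -- is what redistributes cell fluxes across the ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TrunkTopology, VesselKind
from .hydraulics import NetworkSolver, OcclusionParams, ResistanceModel

#: default aorta inflow, um^3/s; chosen so that the mean per-Se cell flux
#: under the measured occlusion profile at the physiological concentration
#: is about 2 cells/s, the scale observed in live embryos (see
#: docs/methods.md)
DEFAULT_INFLOW = 1.5e4


@dataclass
class SimConfig:
    """Run parameters of the discrete traffic model.

    ``n_cells = None`` means "realize the concentration params.rho in
    this network": the count is resolved to rho times the network's
    lumen volume, since the conserved cell number is what sets the
    steady-state concentration.
    """

    n_cells: int | None = None
    dt: float = 0.1  # s
    duration: float = 1000.0  # s
    seed: int = 0
    inflow: float | None = None  # um^3/s; DEFAULT_INFLOW when unset
    target_mean_flux: float | None = None  # cells/s per Se, for calibration

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must cover at least one step")
        if self.n_cells is not None and self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")


def resolve_n_cells(t: TrunkTopology, params: OcclusionParams, config: SimConfig) -> int:
    """The circulating cell count: explicit, or rho times network volume."""
    if config.n_cells is not None:
        return config.n_cells
    from . import units

    return units.cells_from_rho(params.rho, t.total_volume())


@dataclass
class CellEnsemble:
    """Positions of all circulating cells: vessel index + axial coordinate."""

    vessel: np.ndarray  # index into topology.vessels
    position: np.ndarray  # um, in [0, length) of the vessel

    @property
    def n_cells(self) -> int:
        return len(self.vessel)


@dataclass(frozen=True)
class FluxRecord:
    """Summary of one traffic run."""

    counts: np.ndarray  # per-Se entry counts, head to tail
    mean_flux: np.ndarray  # per-Se cells/s
    flux_se: np.ndarray  # Poisson standard error on the mean flux
    cv: float  # std of per-Se mean fluxes / their mean
    entry_times: tuple[np.ndarray, ...]  # per-Se entry timestamps, s
    dissipation: tuple[float, float, float]  # time-avg (plasma, cell, total)
    inflow: float
    seed: int
    duration: float

    @property
    def total_se_flux(self) -> float:
        """Total cell supply to the Se vessels, cells/s."""
        return float(np.sum(self.mean_flux))


def init_cells(
    t: TrunkTopology,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_cells: int | None = None,
) -> CellEnsemble:
    """Distribute cells uniformly (per unit volume) along the aorta."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if n_cells is None:
        n_cells = config.n_cells if config.n_cells is not None else 0
    da_idx = [k for k, v in enumerate(t.vessels) if v.kind == VesselKind.DA_SEGMENT]
    if not da_idx:
        raise ValueError("network has no DA segments to seed cells into")
    volumes = np.array([t.vessels[k].volume for k in da_idx])
    if volumes.sum() <= 0:
        raise ValueError("DA volume must be positive")
    if n_cells == 0:
        return CellEnsemble(np.empty(0, dtype=int), np.empty(0))
    chosen = rng.choice(len(da_idx), size=n_cells, p=volumes / volumes.sum())
    vessel = np.array([da_idx[c] for c in chosen], dtype=int)
    lengths = np.array([t.vessels[k].length for k in vessel])
    position = rng.random(n_cells) * lengths
    return CellEnsemble(vessel=vessel, position=position)


class TrafficSimulation:
    """Pre-computed kinematic structure plus the per-step update."""

    def __init__(
        self,
        t: TrunkTopology,
        params: OcclusionParams,
        config: SimConfig,
        mode: str = "plasma_cells",
    ):
        self.topology = t
        self.params = params
        self.config = config
        self.model = ResistanceModel(t, params, mode)
        self.solver = NetworkSolver(t)
        vessels = t.vessels
        self.n_vessels = len(vessels)
        self.length = np.array([v.length for v in vessels])
        self.area = np.array([v.cross_section for v in vessels])
        self.head = np.array([v.head_vertex for v in vessels], dtype=int)
        self.tail = np.array([v.tail_vertex for v in vessels], dtype=int)
        self.zero_pressure = t.zero_pressure_vertices
        # incident vessels per vertex: (vessel index, +1 if the vertex is
        # the vessel's head, -1 if its tail)
        incident: dict[int, list[tuple[int, int]]] = {}
        for k, v in enumerate(vessels):
            incident.setdefault(v.head_vertex, []).append((k, +1))
            incident.setdefault(v.tail_vertex, []).append((k, -1))
        self.incident = incident
        inlet = [k for k, v in enumerate(vessels) if v.head_vertex == t.inflow_vertex]
        if not inlet:
            raise ValueError("no vessel starts at the inflow vertex")
        self.inlet_vessel = inlet[0]
        se = [(k, v) for k, v in enumerate(vessels) if v.kind == VesselKind.SE]
        #: vessel index -> Se order (0 = closest to the heart), -1 otherwise
        self.se_order = np.full(self.n_vessels, -1, dtype=int)
        for order, (k, _) in enumerate(se):
            self.se_order[k] = order
        self.n_se = len(se)
        self.inflow = (
            config.inflow if config.inflow is not None else DEFAULT_INFLOW
        )

    # -- single step ---------------------------------------------------

    def step(
        self,
        ensemble: CellEnsemble,
        rng: np.random.Generator,
        t_now: float = 0.0,
        entries: list | None = None,
    ):
        """Advance every cell by one time step; returns the HydraulicState.

        Resistances are frozen at the step's initial cell counts.  Entry
        events (cell crossing into an Se vessel at its head) are appended
        to ``entries`` as (se_order, time) pairs when a list is given.
        """
        counts = np.bincount(ensemble.vessel, minlength=self.n_vessels) \
            if ensemble.n_cells else np.zeros(self.n_vessels, dtype=int)
        state = self.solver.solve(self.model.total(counts), self.inflow)
        v = np.where(self.area > 0, state.flows / self.area, 0.0)
        dt = self.config.dt
        if ensemble.n_cells:
            newpos = ensemble.position + v[ensemble.vessel] * dt
            lengths = self.length[ensemble.vessel]
            movers = (newpos >= lengths) | (newpos < 0)
            ensemble.position[~movers] = newpos[~movers]
            for idx in np.nonzero(movers)[0]:
                self._walk(ensemble, idx, v, dt, rng, t_now, entries)
        return state, counts

    def _walk(self, ensemble, idx, v, dt, rng, t_now, entries):
        k = int(ensemble.vessel[idx])
        x = float(ensemble.position[idx])
        remaining = dt
        for _ in range(10_000):  # hard bound on within-step crossings
            vel = v[k]
            if vel > 0:
                t_exit = (self.length[k] - x) / vel
                exit_vertex = int(self.tail[k])
            elif vel < 0:
                t_exit = x / -vel
                exit_vertex = int(self.head[k])
            else:
                break
            if t_exit > remaining:
                x += vel * remaining
                break
            remaining -= t_exit
            if exit_vertex in self.zero_pressure:
                # out of the modelled half-network: back in via the aorta,
                # with a branch choice at the inflow vertex (the first Se
                # also hangs off it)
                exit_vertex = self.topology.inflow_vertex
            k, x = self._branch(exit_vertex, v, rng, t_now + dt - remaining, entries)
            if k < 0:  # no outgoing flow anywhere: cell parks at the vertex
                k, x = -k - 1, x
                break
        ensemble.vessel[idx] = k
        ensemble.position[idx] = min(max(x, 0.0), np.nextafter(self.length[k], 0.0))

    def _branch(self, vertex, v, rng, t_event, entries):
        """Bernoulli choice among vessels carrying flow out of ``vertex``."""
        cands = []
        total = 0.0
        for k, orient in self.incident[vertex]:
            out = orient * v[k] * self.area[k]  # outgoing volumetric flow
            if out > 0:
                cands.append((k, orient, out))
                total += out
        if not cands:
            # degenerate stagnation point: park the cell in the first
            # incident vessel at the vertex-side end
            k, orient = self.incident[vertex][0]
            x = 0.0 if orient > 0 else self.length[k]
            return -k - 1, x
        r = rng.random() * total
        acc = 0.0
        for k, orient, out in cands:
            acc += out
            if r <= acc:
                break
        x = 0.0 if orient > 0 else self.length[k]
        if entries is not None and orient > 0 and self.se_order[k] >= 0:
            entries.append((int(self.se_order[k]), t_event))
        return k, x


def run(
    t: TrunkTopology,
    params: OcclusionParams,
    config: SimConfig,
    mode: str = "plasma_cells",
) -> FluxRecord:
    """Simulate ``config.duration`` seconds of traffic and summarize it."""
    sim = TrafficSimulation(t, params, config, mode)
    rng = np.random.default_rng(config.seed)
    ensemble = init_cells(t, config, rng, n_cells=resolve_n_cells(t, params, config))
    n_steps = int(round(config.duration / config.dt))
    entries: list[tuple[int, float]] = []
    diss = np.zeros(3)
    for s in range(n_steps):
        state, counts = sim.step(ensemble, rng, t_now=s * config.dt, entries=entries)
        q2 = state.flows**2
        plasma = float(np.sum(sim.model.bare * q2))
        cell = float(np.sum(counts * sim.model.alpha * q2))
        diss += (plasma, cell, plasma + cell)
    diss /= n_steps
    duration = n_steps * config.dt
    counts_se = np.zeros(sim.n_se, dtype=int)
    times: list[list[float]] = [[] for _ in range(sim.n_se)]
    for order, t_event in entries:
        counts_se[order] += 1
        times[order].append(t_event)
    mean_flux = counts_se / duration
    flux_se = np.sqrt(counts_se) / duration
    cv = float(np.std(mean_flux) / np.mean(mean_flux)) if np.any(counts_se) else 0.0
    return FluxRecord(
        counts=counts_se,
        mean_flux=mean_flux,
        flux_se=flux_se,
        cv=cv,
        # cells are advanced in array order within a step, so the raw event
        # log is time-ordered only up to dt; sort to restore chronology
        entry_times=tuple(np.sort(np.array(ts)) for ts in times),
        dissipation=(float(diss[0]), float(diss[1]), float(diss[2])),
        inflow=sim.inflow,
        seed=config.seed,
        duration=duration,
    )


def calibrate_inflow(
    t: TrunkTopology,
    params: OcclusionParams,
    config: SimConfig,
    target_mean_flux: float | None = None,
    n_seeds: int = 3,
    rel_tol: float = 0.05,
    max_iter: int = 10,
    mode: str = "plasma_cells",
) -> float:
    """Find the inflow F whose mean per-Se cell flux matches a target.

    The mean flux is averaged over ``n_seeds`` seeded replicates; the
    root is found by secant iteration, which converges in a couple of
    steps because flux responds monotonically and nearly linearly to F.
    """
    from dataclasses import replace as _replace

    target = (
        target_mean_flux if target_mean_flux is not None else config.target_mean_flux
    )
    if target is None or target <= 0:
        raise ValueError("a positive target mean flux is required")

    def mean_flux(F: float) -> float:
        vals = []
        for k in range(n_seeds):
            cfg = _replace(config, inflow=F, seed=config.seed + 7919 * k)
            vals.append(float(np.mean(run(t, params, cfg, mode).mean_flux)))
        return float(np.mean(vals))

    F0 = config.inflow if config.inflow is not None else DEFAULT_INFLOW
    f0 = mean_flux(F0)
    if f0 <= 0:
        F0, f0 = 10 * F0, mean_flux(10 * F0)
        if f0 <= 0:
            raise RuntimeError("no cell flux even at a 10x inflow; cannot calibrate")
    F1 = F0 * target / f0
    for _ in range(max_iter):
        if abs(f0 - target) <= rel_tol * target:
            return F0
        f1 = mean_flux(F1)
        if abs(f1 - target) <= rel_tol * target:
            return F1
        if f1 == f0:
            F1 *= 1.5
            continue
        F2 = F1 + (target - f1) * (F1 - F0) / (f1 - f0)
        F0, f0 = F1, f1
        F1 = max(F2, 0.05 * F1)
    return F1
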
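"""Synthetic data with the statistical structure the analyses assume.

Generators for the four inputs the pipeline consumes: a vessel-geometry
table, velocity/occupancy observations, cell entry-time streams, and
per-Se flux summaries.  Each generator is a deterministic function of its
arguments and seed, and each output is readable by the corresponding
consumer module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import geometry, traffic, units
from .geometry import TrunkTopology
from .hydraulics import (
    NetworkSolver,
    OcclusionParams,
    ResistanceModel,
)


@dataclass
class SynthSpec:
    """Knobs of the synthetic-data generators."""

    n_se: int = 12
    geometry_jitter: float = 0.0  # relative SD of DA segment lengths
    true_alphas: np.ndarray = field(
        default_factory=lambda: np.linspace(2.8e-5, 3.0e-7, 12)
    )
    velocity_noise_sd: float = 0.2  # multiplicative lognormal sd
    entry_base_rate: float = 2.0  # s^-1
    entry_suppression: float = 0.3  # acceptance probability while occupied
    entry_transit: float = 0.3  # s
    n_fish: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.velocity_noise_sd < 0 or self.geometry_jitter < 0:
            raise ValueError("noise levels must be non-negative")
        if not 0 < self.entry_suppression <= 1:
            raise ValueError("suppression factor must lie in (0, 1]")


def synth_geometry(spec: SynthSpec | None = None, uniform: bool = False) -> pd.DataFrame:
    """A zebrafish-like geometry table, optionally spacing-jittered."""
    spec = spec or SynthSpec()
    if not 1 <= spec.n_se <= 20:
        raise ValueError("n_se must lie in 1..20")
    table = geometry.default_geometry_table(spec.n_se, uniform=uniform)
    if spec.geometry_jitter > 0:
        t = geometry.build_trunk(spec.n_se, table)
        t = geometry.jitter_spacing(t, spec.geometry_jitter, spec.seed)
        table = geometry.to_table(t)
    return table


def cellfree_se_reference(
    t: TrunkTopology, inflow: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-free Se velocities and resistances from the network model.

    Solves the network with no cells anywhere -- plasma viscosity in the
    fine vessels, whole blood in the aorta -- and returns (v0, R0) per Se
    vessel head-to-tail: the modelled velocity with no cells present and
    the matching bare resistance.  These anchor the fixed intercept of
    the 1/v-vs-n regression, so the per-cell slope is measured against
    the plasma baseline of the same vessel.
    """
    params = OcclusionParams()
    model = ResistanceModel(t, params, mode="plasma_cells")
    state = NetworkSolver(t).solve(
        model.total(np.zeros(len(t.vessels))),
        traffic.DEFAULT_INFLOW if inflow is None else inflow,
    )
    se_idx = [k for k, v in enumerate(t.vessels) if v.kind.value == "SE"]
    v0 = np.array(
        [state.flows[k] / t.vessels[k].cross_section for k in se_idx]
    )
    r0 = model.bare[se_idx]
    return v0, r0


def synth_velocity_obs(
    t: TrunkTopology,
    true_alphas: np.ndarray,
    n_obs_per_vessel: int = 200,
    noise_sd: float = 0.2,
    seed: int = 0,
    occupancy: str = "poisson",
    sim_duration: float = 60.0,
    poisson_mean: float = 1.0,
) -> pd.DataFrame:
    """Velocity/occupancy observations from the occlusion law.

    For each Se vessel, cell counts n are drawn from a Poisson
    approximation of the *observed* occupancies (``occupancy="poisson"``,
    mean 1: vessels mostly hold 0-2 cells, occasionally up to 5) or from
    the empirical occupancy distribution of a short traffic run
    (``occupancy="sim"``, which sits in the model's denser self-organized
    regime).  Velocities follow
    v = v0 R0/(R0 + n alpha) at the vessel's cell-free pressure drop,
    times mean-one multiplicative lognormal noise.  Columns:
    se_index (1-based), n_cells, velocity_um_s.
    """
    if n_obs_per_vessel < 2:
        raise ValueError("need at least two observations per vessel")
    true_alphas = np.asarray(true_alphas, dtype=float)
    if len(true_alphas) != t.n_se:
        raise ValueError("one true alpha per Se vessel required")
    rng = np.random.default_rng(seed)
    v0, r0 = cellfree_se_reference(t)
    if occupancy == "sim":
        params = OcclusionParams.from_se_profile(t, true_alphas)
        cfg = traffic.SimConfig(duration=sim_duration, seed=seed)
        occ = _occupancy_samples(t, params, cfg)
    elif occupancy == "poisson":
        occ = None
    else:
        raise ValueError("occupancy must be 'sim' or 'poisson'")
    # median-one lognormal noise: symmetric on the log scale, so neither
    # v nor 1/v is grossly biased by the noise term
    sigma = np.sqrt(np.log1p(noise_sd**2))
    rows = []
    for i in range(t.n_se):
        if occ is not None and len(occ[i]):
            n = rng.choice(occ[i], size=n_obs_per_vessel)
        else:
            n = rng.poisson(poisson_mean, size=n_obs_per_vessel)
        v = v0[i] * r0[i] / (r0[i] + n * true_alphas[i])
        if noise_sd > 0:
            v = v * rng.lognormal(0.0, sigma, size=n_obs_per_vessel)
        for nn, vv in zip(n, v):
            rows.append(dict(se_index=i + 1, n_cells=int(nn), velocity_um_s=float(vv)))
    return pd.DataFrame(rows)


def _occupancy_samples(t, params, cfg):
    """Per-Se occupancy counts sampled once per step of a short run."""
    sim = traffic.TrafficSimulation(t, params, cfg)
    rng = np.random.default_rng(cfg.seed)
    ensemble = traffic.init_cells(t, cfg, rng)
    n_steps = int(round(cfg.duration / cfg.dt))
    se_idx = np.nonzero(sim.se_order >= 0)[0]
    samples: list[list[int]] = [[] for _ in range(sim.n_se)]
    for s in range(n_steps):
        _, counts = sim.step(ensemble, rng, t_now=s * cfg.dt)
        for j, k in enumerate(se_idx):
            samples[j].append(int(counts[k]))
    return [np.array(s) for s in samples]


def synth_entry_times(
    base_rate: float,
    suppression: float = 1.0,
    transit: float = 0.3,
    duration: float = 600.0,
    seed: int = 0,
) -> np.ndarray:
    """Entry-time stream with occupancy-dependent suppression.

    Candidate entries arrive as a Poisson process at ``base_rate``; a
    candidate within ``transit`` seconds of the last accepted entry (the
    vessel still occupied) is kept only with probability ``suppression``.
    ``suppression=1`` recovers a pure Poisson stream; smaller values
    deplete short inter-entry intervals the way occlusive feedback does.
    """
    if base_rate <= 0 or duration <= 0:
        raise ValueError("base_rate and duration must be positive")
    if not 0 < suppression <= 1:
        raise ValueError("suppression must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    times = []
    t_now = rng.exponential(1 / base_rate)
    last_accepted = -np.inf
    while t_now < duration:
        if t_now - last_accepted >= transit or rng.random() < suppression:
            times.append(t_now)
            last_accepted = t_now
        t_now += rng.exponential(1 / base_rate)
    return np.array(times)


def synth_flux_replicates(
    per_se_means: np.ndarray,
    per_se_sds: np.ndarray,
    n_fish: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Across-fish flux summary from Gaussian per-fish replicates.

    Draws ``n_fish`` per-fish flux profiles from Normal(mean_i, sd_i) and
    summarizes them per Se vessel.  Columns: se_index, mean_flux, sd_flux.
    """
    means = np.asarray(per_se_means, dtype=float)
    sds = np.asarray(per_se_sds, dtype=float)
    if means.shape != sds.shape:
        raise ValueError("means and sds must have the same length")
    rng = np.random.default_rng(seed)
    draws = rng.normal(means, sds, size=(n_fish, len(means)))
    return pd.DataFrame(
        dict(
            se_index=np.arange(1, len(means) + 1),
            mean_flux=draws.mean(axis=0),
            sd_flux=draws.std(axis=0, ddof=1) if n_fish > 1 else np.zeros(len(means)),
        )
    )
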
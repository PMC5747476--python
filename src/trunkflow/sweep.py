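"""Exploration of flux uniformity over occlusion contrast and cell density.

The occlusion profile across the ladder is summarized by a single
contrast parameter: delta_alpha, the difference in occlusion strength
between the first and last Se, with a linear variation in between and
the last Se anchored at the smallest measured strength.  For each
(delta_alpha, rho) grid point the discrete traffic model is run with the
inflow recalibrated so the total cell supply to the Se vessels stays at
its reference value, and two objectives are recorded: the coefficient of
variation (CV) of the per-Se cell fluxes (uniformity) and the
time-averaged viscous dissipation (transport cost), normalized to 1 at
the reference "real fish" point.  Too small a contrast lets the first Se
short-circuit the ladder; too large a contrast starves it; the CV
minimum traces a single curve in the (delta_alpha, rho) plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import traffic, units
from .geometry import TrunkTopology
from .hydraulics import OcclusionParams
from .traffic import SimConfig

logger = logging.getLogger(__name__)

#: smallest measured per-cell occlusion strength: the last Se's anchor
ALPHA_ANCHOR = 3.0e-7
#: largest measured per-cell occlusion strength (first Se)
ALPHA_MAX = 2.8e-5
#: the measured head-to-tail occlusion contrast
DELTA_ALPHA_MEASURED = ALPHA_MAX - ALPHA_ANCHOR


def alpha_profile(delta: float, anchor: float, n_se: int) -> np.ndarray:
    """Linear occlusion-strength profile: anchor+delta (first) to anchor (last)."""
    if anchor + delta < 0 or anchor < 0:
        raise ValueError("profile would contain a negative occlusion strength")
    if n_se == 1:
        return np.array([anchor + delta])
    return np.linspace(anchor + delta, anchor, n_se)


@dataclass
class SweepConfig:
    delta_alpha_grid: np.ndarray = field(
        default_factory=lambda: np.concatenate(
            ([0.0], np.geomspace(5e-7, 5e-5, 11))
        )
    )
    rho_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(5e-4, 6e-3, 8)
    )
    alpha_anchor: float = ALPHA_ANCHOR
    sim: SimConfig = field(default_factory=SimConfig)
    n_seeds_per_point: int = 3
    #: the (delta_alpha, rho) of the real fish, used for normalization
    reference_point: tuple[float, float] = (DELTA_ALPHA_MEASURED, units.RHO_RBC)

    def __post_init__(self) -> None:
        if len(self.delta_alpha_grid) == 0 or len(self.rho_grid) == 0:
            raise ValueError("grids must be non-empty")
        if self.alpha_anchor < 0:
            raise ValueError("alpha_anchor must be non-negative")


@dataclass(frozen=True)
class SweepResult:
    delta_alpha_grid: np.ndarray
    rho_grid: np.ndarray
    cv_map: np.ndarray  # (n_rho, n_delta), NaN where a point failed
    dissipation_map: np.ndarray  # normalized: reference point = 1
    optimal_manifold: np.ndarray  # per-rho argmin delta_alpha
    reference: dict
    seeds: tuple[int, ...]


def _point_runs(t, cfg: SweepConfig, delta, rho, F):
    """Run one grid point over the seed set; returns the FluxRecords."""
    alphas = alpha_profile(delta, cfg.alpha_anchor, t.n_se)
    params = OcclusionParams.from_se_profile(t, alphas, rho=rho)
    n_cells = units.cells_from_rho(rho, t.total_volume())
    records = []
    for k in range(cfg.n_seeds_per_point):
        sim = replace(
            cfg.sim, n_cells=n_cells, inflow=F, seed=cfg.sim.seed + 7919 * k
        )
        records.append(traffic.run(t, params, sim))
    return records, params, n_cells


def _calibrated_inflow(t, cfg: SweepConfig, delta, rho, target_total_flux):
    alphas = alpha_profile(delta, cfg.alpha_anchor, t.n_se)
    params = OcclusionParams.from_se_profile(t, alphas, rho=rho)
    sim = replace(cfg.sim, n_cells=units.cells_from_rho(rho, t.total_volume()))
    return traffic.calibrate_inflow(
        t, params, sim, target_mean_flux=target_total_flux / t.n_se,
        n_seeds=min(cfg.n_seeds_per_point, 3),
    )


def reference_run(t: TrunkTopology, cfg: SweepConfig):
    """Simulate the reference point; returns (records, total Se flux, D)."""
    delta_ref, rho_ref = cfg.reference_point
    F = cfg.sim.inflow if cfg.sim.inflow is not None else traffic.DEFAULT_INFLOW
    records, params, n_cells = _point_runs(t, cfg, delta_ref, rho_ref, F)
    total_flux = float(np.mean([r.total_se_flux for r in records]))
    diss = float(np.mean([r.dissipation[2] for r in records]))
    return records, total_flux, diss, F


def run_sweep(t: TrunkTopology, cfg: SweepConfig) -> SweepResult:
    """Full (delta_alpha, rho) grid exploration at fixed total Se cell flux."""
    _, ref_flux, ref_diss, ref_F = reference_run(t, cfg)
    n_r, n_d = len(cfg.rho_grid), len(cfg.delta_alpha_grid)
    cv_map = np.full((n_r, n_d), np.nan)
    d_map = np.full((n_r, n_d), np.nan)
    for i, rho in enumerate(cfg.rho_grid):
        for j, delta in enumerate(cfg.delta_alpha_grid):
            try:
                F = _calibrated_inflow(t, cfg, delta, rho, ref_flux)
                records, _, _ = _point_runs(t, cfg, delta, rho, F)
                cv_map[i, j] = np.mean([r.cv for r in records])
                d_map[i, j] = np.mean([r.dissipation[2] for r in records]) / ref_diss
            except Exception:  # noqa: BLE001 - record and continue
                logger.exception("sweep point (rho=%g, delta=%g) failed", rho, delta)
    manifold = np.array(
        [
            cfg.delta_alpha_grid[int(np.nanargmin(cv_map[i]))]
            if np.any(np.isfinite(cv_map[i]))
            else np.nan
            for i in range(n_r)
        ]
    )
    return SweepResult(
        delta_alpha_grid=np.asarray(cfg.delta_alpha_grid, float),
        rho_grid=np.asarray(cfg.rho_grid, float),
        cv_map=cv_map,
        dissipation_map=d_map,
        optimal_manifold=manifold,
        reference={
            "delta_alpha": cfg.reference_point[0],
            "rho": cfg.reference_point[1],
            "total_se_flux": ref_flux,
            "dissipation": ref_diss,
            "inflow": ref_F,
        },
        seeds=tuple(cfg.sim.seed + 7919 * k for k in range(cfg.n_seeds_per_point)),
    )


def tuned_vs_uniform_dissipation(
    t: TrunkTopology, cfg: SweepConfig | None = None
) -> tuple[float, float]:
    """Dissipation cost of the measured tuning: D_tuned / D_uniform.

    Both arms run at equal total Se cell flux: the tuned arm carries the
    measured linear occlusion profile, the uniform arm the smallest
    measured strength in every Se with the inflow recalibrated to match
    the tuned arm's cell supply.  Returns (ratio, Monte-Carlo standard
    error over the seed set).
    """
    cfg = cfg or SweepConfig()
    delta_ref, rho_ref = cfg.reference_point
    _, ref_flux, _, _ = reference_run(t, cfg)
    F_tuned = _calibrated_inflow(t, cfg, delta_ref, rho_ref, ref_flux)
    tuned_records, _, _ = _point_runs(t, cfg, delta_ref, rho_ref, F_tuned)
    F_uni = _calibrated_inflow(t, cfg, 0.0, rho_ref, ref_flux)
    uni_records, _, _ = _point_runs(t, cfg, 0.0, rho_ref, F_uni)
    d_tuned = np.array([r.dissipation[2] for r in tuned_records])
    d_uni = np.array([r.dissipation[2] for r in uni_records])
    ratio = float(np.mean(d_tuned) / np.mean(d_uni))
    n = len(d_tuned)
    if n > 1:
        rel = np.sqrt(
            np.var(d_tuned, ddof=1) / n / np.mean(d_tuned) ** 2
            + np.var(d_uni, ddof=1) / n / np.mean(d_uni) ** 2
        )
        se = ratio * float(rel)
    else:
        se = float("nan")
    return ratio, se
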
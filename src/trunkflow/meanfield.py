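"""Reduced first-Se/last-Se network: uniformity vs dissipation tradeoff.

The full ladder is collapsed to four vessels: the aorta from the heart to
the first Se (resistance R1), the first Se itself (R2), the remaining
aorta plus tail connection (R3), and the last Se (R4).  Cells are
well-mixed at concentration rho, so each Se carries a continuum occupancy
n = rho V and the occluded resistances are R2 = R2^0 + rho V2 alpha2 and
R4 = R4^0 + rho V4 alpha4.  Kirchhoff's law at the two junctions gives a
2x2 linear system for the junction pressures (p1, p2):

    F = (p1 - p2)/R1 + p1/R2
    (p1 - p2)/R1 = p2/R3 + p2/R4

The flux ratio Q4/Q2 measures how evenly the two Se vessels are supplied;
eliminating the pressures yields the closed form

    Q4/Q2 = (R2^0 + V2 rho a2)/(R4^0 + V4 rho a4)
            * (1 + R1/R3 + R1/(R4^0 + V4 rho a4))^(-1)

so only the relative occlusion strengths alpha2 >> alpha4 can push the
ratio toward 1.  The price is paid in viscous dissipation, dominated by
the thin lubrication films around each cell.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import geometry, units
from .hydraulics import poiseuille_resistance


@dataclass(frozen=True)
class MeanFieldParams:
    """Geometry, occlusion strengths and operating point of the 4-vessel model.

    Defaults take the first Se's aorta path about 11 segments long
    (R1 ~ 11 R3) and the first Se twice the last's (R2^0 ~ 2 R4^0,
    V2 ~ 2 V4), with radii and lengths from the trunk geometry defaults.
    """

    l1: float = 11 * geometry.DA_SEGMENT_LENGTH  # um
    l2: float = 2 * geometry.SE_LENGTH
    l3: float = geometry.DA_SEGMENT_LENGTH
    l4: float = geometry.SE_LENGTH
    r_a: float = geometry.DA_RADIUS_HEAD
    r_c: float = geometry.SE_RADIUS
    alpha2: float = 2.8e-5  # g/(um^4 s) per cell, first Se
    alpha4: float = 3.0e-7  # g/(um^4 s) per cell, last Se
    rho: float = units.RHO_RBC
    F: float = 1.0e5  # um^3/s
    mu_wb: float = units.MU_WHOLE_BLOOD
    mu_pl: float = units.MU_PLASMA

    def __post_init__(self) -> None:
        for name in ("l1", "l2", "l3", "l4", "r_a", "r_c", "F", "mu_wb", "mu_pl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha2 < 0 or self.alpha4 < 0 or self.rho < 0:
            raise ValueError("alpha2, alpha4 and rho must be non-negative")

    # derived resistances/volumes, kept consistent by construction
    @property
    def R1(self) -> float:
        return poiseuille_resistance(self.l1, self.r_a, self.mu_wb)

    @property
    def R3(self) -> float:
        return poiseuille_resistance(self.l3, self.r_a, self.mu_wb)

    @property
    def R2_0(self) -> float:
        return poiseuille_resistance(self.l2, self.r_c, self.mu_pl)

    @property
    def R4_0(self) -> float:
        return poiseuille_resistance(self.l4, self.r_c, self.mu_pl)

    @property
    def V2(self) -> float:
        return float(np.pi * self.r_c**2 * self.l2)

    @property
    def V4(self) -> float:
        return float(np.pi * self.r_c**2 * self.l4)

    @property
    def R2(self) -> float:
        """Occluded first-Se resistance R2^0 + rho V2 alpha2."""
        return self.R2_0 + self.rho * self.V2 * self.alpha2

    @property
    def R4(self) -> float:
        """Occluded last-Se resistance R4^0 + rho V4 alpha4."""
        return self.R4_0 + self.rho * self.V4 * self.alpha4


def solve_reduced(params: MeanFieldParams) -> tuple[float, float, np.ndarray]:
    """Solve the junction pressures and the four fluxes (Q1..Q4)."""
    R1, R2, R3, R4 = params.R1, params.R2, params.R3, params.R4
    a = np.array(
        [
            [1 / R1 + 1 / R2, -1 / R1],
            [1 / R1, -(1 / R1 + 1 / R3 + 1 / R4)],
        ]
    )
    try:
        p1, p2 = np.linalg.solve(a, np.array([params.F, 0.0]))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular reduced network") from exc
    q = np.array([(p1 - p2) / R1, p1 / R2, p2 / R3, p2 / R4])
    return float(p1), float(p2), q


def flux_ratio(params: MeanFieldParams) -> float:
    """Closed-form uniformity ratio Q4/Q2 (1 = perfectly even supply)."""
    R1, R3 = params.R1, params.R3
    R2, R4 = params.R2, params.R4
    return float((R2 / R4) / (1 + R1 / R3 + R1 / R4))


def dissipation(params: MeanFieldParams, q: np.ndarray) -> float:
    """Viscous power loss of the reduced network, g um^2/s^3.

    Three terms: Poiseuille losses in the aorta (whole blood), Poiseuille
    losses in the cell-free Se plasma, and the per-cell lubrication-film
    losses rho (Q2^2 V2 a2 + Q4^2 V4 a4).  Identical to sum R_i Q_i^2
    with the occluded Se resistances.
    """
    q1, q2, q3, q4 = q
    aorta = 8 * params.mu_wb / (np.pi * params.r_a**4) * (
        params.l1 * q1**2 + params.l3 * q3**2
    )
    plasma = 8 * params.mu_pl / (np.pi * params.r_c**4) * (
        params.l2 * q2**2 + params.l4 * q4**2
    )
    cells = params.rho * (
        q2**2 * params.V2 * params.alpha2 + q4**2 * params.V4 * params.alpha4
    )
    return float(aorta + plasma + cells)


def tradeoff_curve(
    params: MeanFieldParams, alpha2_grid: np.ndarray
) -> list[tuple[float, float, float]]:
    """Sweep alpha2 at fixed total Se flux; report uniformity and cost.

    For each alpha2 the inflow F is rescaled so the total Se flux
    Q2 + Q4 matches the reference point alpha2 = alpha4 (untuned
    occlusion); dissipation is normalized to 1 at that reference.
    Returns (alpha2, Q4/Q2, D/D_ref) triples.
    """
    alpha2_grid = np.asarray(alpha2_grid, dtype=float)
    if np.any(alpha2_grid < 0) or np.any(np.diff(alpha2_grid) <= 0):
        raise ValueError("alpha2 grid must be non-negative and ascending")
    ref = replace(params, alpha2=params.alpha4)
    _, _, q_ref = solve_reduced(ref)
    se_total_ref = q_ref[1] + q_ref[3]
    d_ref = dissipation(ref, q_ref)
    out = []
    for a2 in alpha2_grid:
        p = replace(params, alpha2=float(a2))
        _, _, q = solve_reduced(p)
        scale = se_total_ref / (q[1] + q[3])  # flows are linear in F
        q_scaled = q * scale
        out.append(
            (
                float(a2),
                flux_ratio(p),
                dissipation(p, q_scaled) / d_ref,
            )
        )
    return out


def as_topology(params: MeanFieldParams):
    """The reduced model as a 4-vessel TrunkTopology.

    Vertices: 1 (first junction), 2 (second junction), 3/4/5 boundary.
    Vessel order matches (R1, R2, R3, R4).  Useful for cross-checking
    against the full network solver and dissipation decomposition.
    """
    from .geometry import TrunkTopology, VesselKind, VesselSpec

    vessels = (
        VesselSpec(1, VesselKind.DA_SEGMENT, 1, 2, params.l1, params.r_a),
        VesselSpec(2, VesselKind.SE, 1, 3, params.l2, params.r_c),
        VesselSpec(3, VesselKind.TAIL, 2, 4, params.l3, params.r_a),
        VesselSpec(4, VesselKind.SE, 2, 5, params.l4, params.r_c),
    )
    return TrunkTopology(
        vessels=vessels,
        n_se=2,
        inflow_vertex=1,
        zero_pressure_vertices=frozenset({3, 4, 5}),
    )
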
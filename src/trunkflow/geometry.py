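"""Symmetry-reduced zebrafish trunk network.

The embryonic trunk vasculature is a ladder: the dorsal aorta (DA) runs
head to tail, intersegmental vessels (Se) branch off at regular intervals,
and the DA connects directly to the posterior cardinal vein at the tail.
Pairing each intersegmental artery with its vein and exploiting the
bilateral symmetry of the network sets the pressure at every SeA/SeV
junction (and at the DA-PCV tail connection) to a common constant, which
may be taken as zero.  The model therefore only represents the arterial
half: a chain of n DA segments with one Se vessel hanging off each DA
vertex, all Se tops and the tail junction held at zero pressure.

Vertex numbering: 1..n along the DA, n+1 the tail junction, and
n+1+i the top of the i-th Se vessel.  The axial coordinate within a
vessel is 0 at its head vertex and runs over [0, length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default DA segment length, um
DA_SEGMENT_LENGTH = 108.0
#: default Se vessel length, um
SE_LENGTH = 142.0
#: radius assigned to every Se vessel, um
SE_RADIUS = 2.9
#: DA radius along the trunk, um (the mean measured radius; per-segment
#: conductance with whole blood ~ 9.4e5 um^4 s/g)
DA_RADIUS_HEAD = 6.0
#: radius of the caudal DA-PCV connection (the DA narrows toward the
#: tail anastomosis), um -- see default_geometry_table
DA_RADIUS_TAIL = 4.3


class VesselKind(str, Enum):
    DA_SEGMENT = "DA_SEGMENT"
    SE = "SE"
    TAIL = "TAIL"
    SHUNT = "SHUNT"


@dataclass(frozen=True)
class VesselSpec:
    """One vessel of the reduced network."""

    vessel_id: int
    kind: VesselKind
    head_vertex: int
    tail_vertex: int
    length: float  # um
    radius: float  # um

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(
                f"vessel {self.vessel_id}: length must be positive, got {self.length}"
            )
        if self.radius <= 0:
            raise ValueError(
                f"vessel {self.vessel_id}: radius must be positive, got {self.radius}"
            )
        if self.head_vertex == self.tail_vertex:
            raise ValueError(f"vessel {self.vessel_id}: head and tail vertices coincide")

    @property
    def cross_section(self) -> float:
        """Cross-sectional area pi r^2, um^2."""
        return float(np.pi * self.radius**2)

    @property
    def volume(self) -> float:
        """Lumen volume pi r^2 l, um^3."""
        return self.cross_section * self.length


@dataclass(frozen=True)
class TrunkTopology:
    """The reduced trunk network: vessels plus boundary conditions."""

    vessels: tuple[VesselSpec, ...]
    n_se: int
    inflow_vertex: int
    zero_pressure_vertices: frozenset[int]

    def __post_init__(self) -> None:
        roster = self.vertex_ids()
        if self.inflow_vertex not in roster:
            raise ValueError("inflow vertex is not an endpoint of any vessel")
        missing = self.zero_pressure_vertices - roster
        if missing:
            raise ValueError(f"zero-pressure vertices {sorted(missing)} not in network")
        if not self.zero_pressure_vertices:
            raise ValueError("network needs at least one zero-pressure vertex")
        if not self._connected():
            raise ValueError("network is not connected")

    # -- introspection -------------------------------------------------

    def vertex_ids(self) -> frozenset[int]:
        out: set[int] = set()
        for v in self.vessels:
            out.add(v.head_vertex)
            out.add(v.tail_vertex)
        return frozenset(out)

    def _connected(self) -> bool:
        adj: dict[int, set[int]] = {}
        for v in self.vessels:
            adj.setdefault(v.head_vertex, set()).add(v.tail_vertex)
            adj.setdefault(v.tail_vertex, set()).add(v.head_vertex)
        seen = {self.inflow_vertex}
        stack = [self.inflow_vertex]
        while stack:
            for nxt in adj.get(stack.pop(), ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen == set(adj)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids())

    @property
    def n_vessels(self) -> int:
        return len(self.vessels)

    def vessels_of_kind(self, kind: VesselKind) -> tuple[VesselSpec, ...]:
        return tuple(v for v in self.vessels if v.kind == kind)

    @property
    def da_vessels(self) -> tuple[VesselSpec, ...]:
        return self.vessels_of_kind(VesselKind.DA_SEGMENT)

    @property
    def se_vessels(self) -> tuple[VesselSpec, ...]:
        return self.vessels_of_kind(VesselKind.SE)

    def total_volume(self) -> float:
        """Total lumen volume of the network, um^3."""
        return float(sum(v.volume for v in self.vessels))


# ---------------------------------------------------------------------------
# default geometry


def default_geometry_table(n_se: int = 12, uniform: bool = False) -> pd.DataFrame:
    """Synthesize a zebrafish-like geometry table.

    Every Se vessel gets the same radius (2.9 um) and length (142 um);
    DA segments are 108 um long at the mean measured radius of 6 um, so
    with whole-blood viscosity each segment reproduces the conductance
    kappa1 ~ 9.4e5 um^4 s/g and each Se kappa2 ~ 3.9e4 um^4 s/g of the
    real fish.  The last segment -- the caudal stretch where the
    tapering DA narrows into the anastomosis with the cardinal vein --
    gets radius 4.3 um, which reproduces the ~11-fold first/last Se flux
    contrast the no-occlusion model predicts on the measured geometry.
    ``uniform=True`` keeps the DA radius at 6 um throughout, the exact
    uniform ladder the analytic recurrence describes.
    """
    if not 1 <= n_se:
        raise ValueError("n_se must be >= 1")
    da_radii = np.full(n_se, DA_RADIUS_HEAD)
    if not uniform and n_se > 1:
        da_radii[-1] = DA_RADIUS_TAIL
    rows = []
    for i in range(1, n_se + 1):
        rows.append(
            dict(
                vessel_id=i,
                kind=VesselKind.DA_SEGMENT.value,
                head_vertex=i,
                tail_vertex=i + 1,
                length_um=DA_SEGMENT_LENGTH,
                radius_um=float(da_radii[i - 1]),
            )
        )
    for i in range(1, n_se + 1):
        rows.append(
            dict(
                vessel_id=n_se + i,
                kind=VesselKind.SE.value,
                head_vertex=i,
                tail_vertex=n_se + 1 + i,
                length_um=SE_LENGTH,
                radius_um=SE_RADIUS,
            )
        )
    return pd.DataFrame(rows)


def build_trunk(n_se: int, geometry_table: pd.DataFrame | None = None) -> TrunkTopology:
    """Build the canonical reduced trunk network with ``n_se`` Se vessels.

    ``geometry_table`` must supply a row (length, radius) for each DA
    segment (vessel_id 1..n) and each Se vessel (vessel_id n+1..2n) in the
    canonical vertex numbering; when omitted a default zebrafish-like
    tapered table is synthesized.
    """
    if n_se < 1:
        raise ValueError("n_se must be >= 1")
    if geometry_table is None:
        geometry_table = default_geometry_table(n_se)
    table = geometry_table.set_index("vessel_id")
    vessels = []
    for vessel_id in range(1, 2 * n_se + 1):
        if vessel_id not in table.index:
            raise ValueError(f"geometry table is missing vessel {vessel_id}")
        row = table.loc[vessel_id]
        is_da = vessel_id <= n_se
        i = vessel_id if is_da else vessel_id - n_se
        vessels.append(
            VesselSpec(
                vessel_id=vessel_id,
                kind=VesselKind.DA_SEGMENT if is_da else VesselKind.SE,
                head_vertex=i,
                tail_vertex=i + 1 if is_da else n_se + 1 + i,
                length=float(row["length_um"]),
                radius=float(row["radius_um"]),
            )
        )
    return TrunkTopology(
        vessels=tuple(vessels),
        n_se=n_se,
        inflow_vertex=1,
        zero_pressure_vertices=frozenset(range(n_se + 1, 2 * n_se + 2)),
    )


# ---------------------------------------------------------------------------
# perturbations


def jitter_spacing(
    t: TrunkTopology, relative_sd: float, seed: int | np.random.Generator = 0
) -> TrunkTopology:
    """Perturb DA segment lengths by independent positive random factors.

    Models the natural embryo-to-embryo variability in Se spacing.  Each
    DA segment length is multiplied by a truncated-normal factor with mean
    1 and the given relative standard deviation; non-positive draws are
    redrawn so lengths stay positive.  Se geometry is untouched.
    """
    if not 0 <= relative_sd < 0.5:
        raise ValueError("relative_sd must lie in [0, 0.5)")
    if relative_sd == 0:
        return t
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    old_total = sum(v.length for v in t.da_vessels)
    new_vessels = []
    for v in t.vessels:
        if v.kind == VesselKind.DA_SEGMENT:
            factor = 0.0
            while factor <= 0:
                factor = 1.0 + relative_sd * rng.standard_normal()
            new_vessels.append(replace(v, length=v.length * factor))
        else:
            new_vessels.append(v)
    out = replace(t, vessels=tuple(new_vessels))
    new_total = sum(v.length for v in out.da_vessels)
    logger.info(
        "jitter_spacing: total DA length %.1f -> %.1f um (%+.2f%%)",
        old_total,
        new_total,
        100 * (new_total / old_total - 1),
    )
    return out


def add_shunt(
    t: TrunkTopology, radius: float, at_vertex: int, length: float | None = None
) -> TrunkTopology:
    """Attach a shunt vessel from a DA vertex straight to the venous return.

    Emulates the aorta-to-vein shunt of *notch* mutants: one wide SHUNT
    edge from ``at_vertex`` to a fresh zero-pressure vertex.  Shunts carry
    no occlusive term (their diameter far exceeds the cell diameter).
    Default length is the network's Se length.
    """
    da_vertices = {v.head_vertex for v in t.da_vessels} | {
        v.tail_vertex for v in t.da_vessels
    }
    da_vertices -= t.zero_pressure_vertices
    if at_vertex not in da_vertices:
        raise ValueError(f"vertex {at_vertex} is not a determined DA vertex")
    if length is None:
        se = t.se_vessels
        length = se[0].length if se else SE_LENGTH
    new_vertex = max(t.vertex_ids()) + 1
    shunt = VesselSpec(
        vessel_id=max(v.vessel_id for v in t.vessels) + 1,
        kind=VesselKind.SHUNT,
        head_vertex=at_vertex,
        tail_vertex=new_vertex,
        length=length,
        radius=radius,
    )
    return replace(
        t,
        vessels=t.vessels + (shunt,),
        zero_pressure_vertices=t.zero_pressure_vertices | {new_vertex},
    )


# ---------------------------------------------------------------------------
# serialization

TABLE_COLUMNS = ["vessel_id", "kind", "head_vertex", "tail_vertex", "length_um", "radius_um"]


def to_table(t: TrunkTopology) -> pd.DataFrame:
    """Serialize a topology to its canonical table form."""
    return pd.DataFrame(
        [
            dict(
                vessel_id=v.vessel_id,
                kind=v.kind.value,
                head_vertex=v.head_vertex,
                tail_vertex=v.tail_vertex,
                length_um=v.length,
                radius_um=v.radius,
            )
            for v in t.vessels
        ],
        columns=TABLE_COLUMNS,
    )


def from_table(
    table: pd.DataFrame,
    n_se: int | None = None,
    inflow_vertex: int = 1,
    zero_pressure_vertices: set[int] | None = None,
) -> TrunkTopology:
    """Rebuild a topology from a table produced by :func:`to_table`.

    For non-canonical tables (shunts, custom numbering) the boundary set
    must be given; for canonical tables it is inferred from the counts.
    """
    vessels = tuple(
        VesselSpec(
            vessel_id=int(r.vessel_id),
            kind=VesselKind(r.kind),
            head_vertex=int(r.head_vertex),
            tail_vertex=int(r.tail_vertex),
            length=float(r.length_um),
            radius=float(r.radius_um),
        )
        for r in table.itertuples()
    )
    if n_se is None:
        n_se = sum(1 for v in vessels if v.kind == VesselKind.SE)
    if zero_pressure_vertices is None:
        zero_pressure_vertices = set(range(n_se + 1, 2 * n_se + 2))
        for v in vessels:
            if v.kind == VesselKind.SHUNT:
                zero_pressure_vertices.add(v.tail_vertex)
    return TrunkTopology(
        vessels=vessels,
        n_se=n_se,
        inflow_vertex=inflow_vertex,
        zero_pressure_vertices=frozenset(zero_pressure_vertices),
    )


def write_csv(t: TrunkTopology, path) -> None:
    to_table(t).to_csv(path, index=False)


def read_csv(path, **kwargs) -> TrunkTopology:
    return from_table(pd.read_csv(path), **kwargs)
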
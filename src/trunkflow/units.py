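"""Unit system and physiological constants.

Everything in the package is expressed in a g-um-s system: mass in grams,
length in micrometres, time in seconds.  This makes hydraulic resistance
come out in g/(um^4 s), the unit in which per-cell occlusion strengths are
quoted, and pressure in g/(um s^2).  Pressures are never converted to
mmHg or Pa.
"""

#: one centipoise expressed in g/(um s)
CP = 1.0e-6

#: plasma viscosity (~1 cP), g/(um s)
MU_PLASMA = 1.0 * CP

#: whole-blood viscosity of embryonic zebrafish blood (~5 cP), g/(um s)
MU_WHOLE_BLOOD = 5.0 * CP

#: measured red-blood-cell number concentration, um^-3
RHO_RBC = 0.003

#: nominal volume of a zebrafish red blood cell, um^3 (used only to convert
#: between number concentration rho and hematocrit, Hct = rho * V_cell)
CELL_VOLUME = 100.0

def hematocrit_from_rho(rho: float, cell_volume: float = CELL_VOLUME) -> float:
    """Convert a number concentration (um^-3) to a hematocrit."""
    return rho * cell_volume


def rho_from_hematocrit(hct: float, cell_volume: float = CELL_VOLUME) -> float:
    """Convert a hematocrit to a number concentration (um^-3)."""
    return hct / cell_volume


def cells_from_rho(rho: float, network_volume: float) -> int:
    """Circulating cell count realizing a concentration in a given network.

    The discrete model conserves cell number, so the steady-state
    concentration is n_cells over the network's lumen volume; this is the
    inverse of that relation.
    """
    return int(round(rho * network_volume))
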
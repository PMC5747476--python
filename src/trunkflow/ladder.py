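"""Closed-form solution of the uniform resistor ladder.

When every DA segment has conductance kappa1 and every Se vessel
conductance kappa2, conservation of flux at interior DA vertices gives a
constant-coefficient second-order recurrence for the vertex pressures,

    -kappa1 p_{i-1} + (2 kappa1 + kappa2) p_i - kappa1 p_{i+1} = 0,

whose general solution is p_i = C+ xi_+^i + C- xi_-^i with xi_+- the roots
of xi^2 - (2 + lambda) xi + 1 = 0 and lambda = kappa2/kappa1.  For every
lambda > 0 one root lies strictly inside (0, 1), so pressures -- and with
them the Se fluxes Q_i = kappa2 p_i -- decay exponentially with distance
from the heart: the first Se short-circuits the ladder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: lambda below which the degenerate double-root (linear-in-i) form is used
_DEGENERATE_LAMBDA = 1e-14


@dataclass(frozen=True)
class LadderParams:
    kappa1: float  # DA segment conductance, um^4 s/g
    kappa2: float  # Se conductance, um^4 s/g
    n: int  # number of Se vessels
    F: float = 1.0  # inflow, um^3/s

    def __post_init__(self) -> None:
        if self.kappa1 <= 0 or self.kappa2 < 0:
            raise ValueError("conductances must be positive (kappa2 may be 0)")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def lambda_(self) -> float:
        return self.kappa2 / self.kappa1


@dataclass(frozen=True)
class LadderSolution:
    xi_plus: float
    xi_minus: float
    c_plus: float
    c_minus: float
    pressures: np.ndarray  # p_1 .. p_n (p_{n+1} = 0 by construction)


def aux_roots(lambda_: float) -> tuple[float, float]:
    """Roots of xi^2 - (2 + lambda) xi + 1 = 0, larger first.

    The product of the roots is exactly 1; the smaller root is computed
    as 1/xi_+ so the pair stays accurate at small lambda, where the naive
    quadratic formula cancels.
    """
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    # (2+lam)^2 - 4 = lam (lam + 4), computed without cancellation
    disc = np.sqrt(lambda_ * (lambda_ + 4.0))
    xi_plus = ((2.0 + lambda_) + disc) / 2.0
    return float(xi_plus), float(1.0 / xi_plus)


def ladder_pressures(params: LadderParams) -> LadderSolution:
    """Solve the ladder recurrence under the physical boundary conditions.

    The tail junction is grounded (p_{n+1} = 0) and the inflow condition
    at the first vertex reads F = kappa2 p_1 + kappa1 (p_1 - p_2).  The
    two conditions fix C+ and C-.
    """
    lam = params.lambda_
    k1, k2, n, F = params.kappa1, params.kappa2, params.n, params.F
    i = np.arange(1, n + 1)
    if lam < _DEGENERATE_LAMBDA:
        # double root xi = 1: general solution p_i = A + B i; kappa2 = 0
        # so the inflow condition reduces to F = -kappa1 B
        B = -F / k1
        A = -B * (n + 1)
        pressures = A + B * i.astype(float)
        return LadderSolution(
            xi_plus=1.0, xi_minus=1.0, c_plus=A, c_minus=B, pressures=pressures
        )
    xi_p, xi_m = aux_roots(lam)
    # rows: p_{n+1} = 0 and the inflow condition
    a = np.array(
        [
            [xi_p ** (n + 1), xi_m ** (n + 1)],
            [
                k2 * xi_p + k1 * (xi_p - xi_p**2),
                k2 * xi_m + k1 * (xi_m - xi_m**2),
            ],
        ]
    )
    c_plus, c_minus = np.linalg.solve(a, np.array([0.0, F]))
    pressures = c_plus * xi_p**i + c_minus * xi_m**i
    return LadderSolution(
        xi_plus=xi_p,
        xi_minus=xi_m,
        c_plus=float(c_plus),
        c_minus=float(c_minus),
        pressures=pressures,
    )


def flux_profile(sol: LadderSolution, params: LadderParams) -> np.ndarray:
    """Per-Se fluxes Q_i = kappa2 p_i, head to tail."""
    return params.kappa2 * sol.pressures


def tail_flow(sol: LadderSolution, params: LadderParams) -> float:
    """Flow leaving through the DA tail segment, kappa1 (p_n - 0)."""
    return float(params.kappa1 * sol.pressures[-1])


def asymptotic_flux_profile(sol: LadderSolution, params: LadderParams) -> np.ndarray:
    """The decaying-mode approximation Q_i ~ kappa2 C- xi_-^i.

    Away from the tail boundary layer the growing mode is negligible and
    the fluxes decay geometrically with ratio xi_-.
    """
    i = np.arange(1, params.n + 1)
    return params.kappa2 * sol.c_minus * sol.xi_minus**i
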
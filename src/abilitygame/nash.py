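"""Best responses and Nash-equilibrium efforts for an ability pair.

Within a pairing, each player's effort maximizes its own payoff given its
ability and the partner's effort.  Because marginal benefit is strictly
decreasing and marginal cost strictly increasing, the best response is
unique, and the simultaneous first-order conditions

    2 - 2 (e1 + e2) = (2 - a_i) * p * e_i**(p-1),   i = 1, 2

pin down a unique Nash equilibrium with total effort strictly inside the
unsaturated benefit region (e1 + e2 < 1).

Solver
------
Each FOC inverts in closed form for the individual effort as a function of
the *total* effort s = e1 + e2:

    e_i(s) = (2 (1 - s) / ((2 - a_i) p)) ** (1 / (p - 1)),

which is strictly decreasing in s.  The equilibrium total is therefore the
unique root of the strictly decreasing residual phi(s) = e1(s) + e2(s) - s,
which is positive at s = 0 and equals -1 at s = 1: a guaranteed bracket,
solved by Brent's method (scalar) or bisection (vectorized batch).  This
reduction is exact, symmetric in the two players by construction, and avoids
iterating the best-response map.

The module also exposes the best-response function itself, its slope with
respect to the partner's effort (the "responsiveness" of the player, always
in (-1, 0)), and the best response against a non-reacting environment — the
"game against nature" baseline in which fitness always increases with
ability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError, SolverError
from .model import ModelParams, benefit_slope, payoff

__all__ = [
    "EffortPair",
    "NashSolution",
    "best_response",
    "nash_efforts",
    "nash_efforts_batch",
    "response_slope",
    "solo_optimal_payoff",
]

#: tolerance on the first-order-condition residual at a converged solution
FOC_TOL = 1e-10


@dataclass(frozen=True)
class EffortPair:
    """Efforts of the two players in one pairing."""

    e_focal: float
    e_partner: float

    @property
    def total(self) -> float:
        return self.e_focal + self.e_partner


@dataclass(frozen=True)
class NashSolution:
    """Nash-equilibrium efforts, payoffs and solver diagnostics for one pair."""

    a_focal: float
    a_partner: float
    efforts: EffortPair
    payoff_focal: float
    payoff_partner: float
    foc_residuals: tuple[float, float]
    iterations: int
    converged: bool

    def swapped(self) -> "NashSolution":
        """The same equilibrium seen from the partner's side."""
        return NashSolution(
            a_focal=self.a_partner,
            a_partner=self.a_focal,
            efforts=EffortPair(self.efforts.e_partner, self.efforts.e_focal),
            payoff_focal=self.payoff_partner,
            payoff_partner=self.payoff_focal,
            foc_residuals=self.foc_residuals[::-1],
            iterations=self.iterations,
            converged=self.converged,
        )


def _check_ability(a, params: ModelParams) -> float:
    a = float(a)
    if not np.isfinite(a) or not (params.ability_min <= a <= params.ability_max):
        raise DomainError(f"ability must lie in [0, 1], got {a!r}")
    return a


def best_response(a, e_partner, params: ModelParams) -> float:
    """Unique payoff-maximizing effort against a partner expending ``e_partner``.

    Zero when the benefit is already saturated (``e_partner >= 1``);
    otherwise the unique root of the first-order condition
    ``benefit_slope(r + e_partner) = (2 - a) p r**(p-1)`` in
    ``(0, 1 - e_partner)``.
    """
    a = _check_ability(a, params)
    e_partner = float(e_partner)
    if not np.isfinite(e_partner) or e_partner < 0:
        raise DomainError(f"e_partner must be >= 0 and finite, got {e_partner!r}")
    if e_partner >= 1.0:
        return 0.0
    p = params.p
    c = (2.0 - a) * p

    def foc(r: float) -> float:
        return benefit_slope(r + e_partner) - c * r ** (p - 1.0)

    hi = 1.0 - e_partner
    # foc(0) = 2 - 2 e_partner > 0 and foc(hi) = -c hi**(p-1) < 0: valid bracket
    try:
        return float(brentq(foc, 0.0, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200))
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
        raise SolverError(
            f"best_response bracketing failed for a={a}, e_partner={e_partner}, p={p}: {exc}"
        ) from exc


def _effort_given_total(a, s, p):
    """Invert a player's FOC for its effort at total effort ``s`` (vectorized)."""
    return (2.0 * (1.0 - s) / ((2.0 - np.asarray(a)) * p)) ** (1.0 / (p - 1.0))


def nash_efforts(a1, a2, params: ModelParams) -> NashSolution:
    """Nash-equilibrium efforts and payoffs for abilities ``(a1, a2)``.

    Solves the reduced scalar equation in the total effort (see module
    docstring); exact swap symmetry holds because the residual is symmetric
    in the two players.
    """
    a1 = _check_ability(a1, params)
    a2 = _check_ability(a2, params)
    p = params.p

    def phi(s: float) -> float:
        return float(
            _effort_given_total(a1, s, p) + _effort_given_total(a2, s, p) - s
        )

    try:
        s_star, res = brentq(
            phi, 0.0, 1.0, xtol=1e-15, rtol=8.9e-16, maxiter=200, full_output=True
        )
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
        raise SolverError(f"total-effort bracketing failed for ({a1}, {a2}, p={p}): {exc}") from exc

    e1 = float(_effort_given_total(a1, s_star, p))
    e2 = float(_effort_given_total(a2, s_star, p))
    s = e1 + e2
    r1 = benefit_slope(s) - (2.0 - a1) * p * e1 ** (p - 1.0)
    r2 = benefit_slope(s) - (2.0 - a2) * p * e2 ** (p - 1.0)
    converged = bool(res.converged) and max(abs(r1), abs(r2)) < FOC_TOL
    if not converged:  # pragma: no cover - defensive
        raise SolverError(
            f"Nash solve did not converge for ({a1}, {a2}, p={p}): "
            f"residuals ({r1:.3e}, {r2:.3e}), {res.iterations} iterations"
        )
    return NashSolution(
        a_focal=a1,
        a_partner=a2,
        efforts=EffortPair(e1, e2),
        payoff_focal=payoff(a1, e1, e2, params),
        payoff_partner=payoff(a2, e2, e1, params),
        foc_residuals=(r1, r2),
        iterations=int(res.iterations),
        converged=converged,
    )


def nash_efforts_batch(a1, a2, params: ModelParams, n_iter: int = 80):
    """Vectorized Nash efforts for aligned ability arrays ``a1``, ``a2``.

    Bisects the total-effort residual elementwise (``n_iter`` halvings of
    the bracket (0, 1), giving ~1e-24 interval width); returns the effort
    arrays ``(e1, e2)``.  Used by the evolutionary simulation, where one
    generation needs hundreds of equilibria at once.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if a1.shape != a2.shape:
        raise DomainError("ability arrays must have the same shape")
    if a1.size and (
        min(a1.min(), a2.min()) < params.ability_min
        or max(a1.max(), a2.max()) > params.ability_max
    ):
        raise DomainError("abilities must lie in [0, 1]")
    p = params.p
    lo = np.zeros(a1.shape)
    hi = np.ones(a1.shape)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        phi = (
            _effort_given_total(a1, mid, p) + _effort_given_total(a2, mid, p) - mid
        )
        pos = phi > 0.0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    s = 0.5 * (lo + hi)
    return _effort_given_total(a1, s, p), _effort_given_total(a2, s, p)


def response_slope(a, e_partner, params: ModelParams) -> float:
    """Slope of the best response with respect to the partner's effort.

    By implicit differentiation of the first-order condition,

        slope = -2 / (2 + (2 - a) p (p - 1) r**(p-2)),

    with ``r`` the best response; the denominator exceeds 2, so the slope is
    always strictly inside (-1, 0): players *partially* compensate for a
    lazier partner.  At a corner best response (r = 0, which requires
    ``e_partner >= 1``) the slope is defined as 0.
    """
    r = best_response(a, e_partner, params)
    if r == 0.0:
        return 0.0
    p = params.p
    return -2.0 / (2.0 + (2.0 - float(a)) * p * (p - 1.0) * r ** (p - 2.0))


def solo_optimal_payoff(a, e_env, params: ModelParams) -> tuple[float, float]:
    """Optimal effort and payoff against a fixed, non-responding environment.

    The "game against nature" baseline: when the partner's effort ``e_env``
    cannot react, the envelope theorem gives dW*/da = e**p > 0, so the
    optimal payoff strictly increases with ability — selection on ability is
    always upward absent social feedback.
    """
    e = best_response(a, e_env, params)
    return e, payoff(a, e, e_env, params)
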
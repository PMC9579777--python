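"""Payoff primitives of the two-player public-goods ability game.

Two individuals with heritable abilities pair up and each chooses an effort
to expend on a common good.  The payoff to a focal player of ability ``a``
that expends effort ``e`` against a partner expending ``e_partner`` is

    W = B(e + e_partner) - K(a, e)

where the common benefit ``B`` saturates in the total effort,

    B(e_tot) = 2 e_tot - e_tot**2   for e_tot < 1,   B(e_tot) = 1 otherwise,

and the private cost accelerates in own effort and declines with ability,

    K(a, e) = (2 - a) * e**p,       cost exponent p > 1.

High-ability players thus have a *comparative advantage*: the marginal cost
of extra effort, (2 - a) * p * e**(p-1), is lower the larger ``a`` is.  All
downstream analysis (Nash efforts, invasion fitness, evolutionary
simulation) is built on these three functions.

Every function accepts scalars or numpy arrays and returns floats for scalar
input.  Parameters travel in a single immutable :class:`ModelParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

__all__ = ["ModelParams", "benefit", "benefit_slope", "cost", "payoff"]

#: cost exponents closer to 1 than this are rejected as ill-conditioned
MIN_P_MARGIN = 1e-6


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the ability game.

    Parameters
    ----------
    p
        Cost exponent; must satisfy ``p > 1`` strictly (values within
        ``1e-6`` of 1 are rejected as numerically ill-conditioned).
    saturation_total
        Total effort at which the common benefit saturates; fixed at 1.
    ability_min, ability_max
        Bounds of the heritable ability trait; fixed at 0 and 1.
    """

    p: float
    saturation_total: float = 1.0
    ability_min: float = 0.0
    ability_max: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.p) or self.p < 1.0 + MIN_P_MARGIN:
            raise DomainError(
                f"cost exponent p must exceed 1 (got p={self.p!r}); "
                f"values below 1 + {MIN_P_MARGIN} are rejected"
            )
        if self.saturation_total != 1.0:
            raise DomainError("saturation_total is fixed at 1 in this model")
        if (self.ability_min, self.ability_max) != (0.0, 1.0):
            raise DomainError("ability bounds are fixed at [0, 1] in this model")


def _as_checked_array(x, name: str, lower: float = 0.0, upper: float = np.inf):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} must be finite, got {x!r}")
    if np.any(arr < lower) or np.any(arr > upper):
        raise DomainError(f"{name} must lie in [{lower}, {upper}], got {x!r}")
    return arr


def _maybe_scalar(arr, scalar_input: bool):
    return float(arr) if scalar_input else arr


def benefit(e_tot):
    """Common benefit B of a total effort ``e_tot >= 0``.

    Equals ``2*e_tot - e_tot**2`` below saturation (``e_tot < 1``) and 1
    beyond; continuous, nondecreasing and concave, with range [0, 1].
    """
    scalar = np.isscalar(e_tot) or np.ndim(e_tot) == 0
    e = _as_checked_array(e_tot, "e_tot")
    out = np.where(e < 1.0, 2.0 * e - e * e, 1.0)
    return _maybe_scalar(out, scalar)


def benefit_slope(e_tot):
    """Marginal common benefit dB/de_tot.

    ``2 - 2*e_tot`` below saturation, 0 at and beyond it (right-derivative
    convention at the kink ``e_tot = 1``; equilibrium totals are strictly
    below 1, so the convention never binds in practice).
    """
    scalar = np.isscalar(e_tot) or np.ndim(e_tot) == 0
    e = _as_checked_array(e_tot, "e_tot")
    out = np.where(e < 1.0, 2.0 - 2.0 * e, 0.0)
    return _maybe_scalar(out, scalar)


def cost(a, e, params: ModelParams):
    """Private cost K(a, e) = (2 - a) * e**p of expending effort ``e`` at ability ``a``.

    Increasing and accelerating in ``e`` (since p > 1), strictly decreasing
    in ``a`` for positive effort, and zero at zero effort (the continuous
    extension of ``e**p`` at e = 0).
    """
    scalar = (np.isscalar(a) or np.ndim(a) == 0) and (np.isscalar(e) or np.ndim(e) == 0)
    a_arr = _as_checked_array(a, "ability a", lower=params.ability_min, upper=params.ability_max)
    e_arr = _as_checked_array(e, "effort e")
    out = (2.0 - a_arr) * np.power(e_arr, params.p)
    return _maybe_scalar(out, scalar)


def payoff(a_self, e_self, e_partner, params: ModelParams):
    """Payoff W = B(e_self + e_partner) - K(a_self, e_self) of the focal player."""
    scalar = all(np.isscalar(x) or np.ndim(x) == 0 for x in (a_self, e_self, e_partner))
    e_p = _as_checked_array(e_partner, "e_partner")
    out = benefit(np.asarray(e_self, dtype=float) + e_p) - cost(a_self, e_self, params)
    return _maybe_scalar(out, scalar)
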
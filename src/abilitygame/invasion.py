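"""Adaptive-dynamics analysis of the ability trait.

A rare mutant of ability ``ã`` in a resident population of ability ``a``
almost always pairs with a resident, so its invasion fitness is its
Nash-equilibrium payoff in the mixed pairing:

    V(ã, a) = B(e*(ã, a) + e*(a, ã)) - K(ã, e*(ã, a)).

The selection gradient is the mutant-direction derivative of V at ã = a;
its sign gives the local direction of trait evolution.  This module
computes the gradient (finite differences over the Nash solver), full
pairwise invasibility plots (PIPs), and locates and classifies the
attractors of the adaptive dynamics:

* boundary attractors (the gradient points into a trait bound),
* interior singular points, split into continuously stable strategies
  (CSS), evolutionary branching points (convergence stable but invadable —
  disruptive selection), and repellers.

Convergence stability is decided from the resident-direction slope of the
gradient across the singular point; evolutionary stability from the
mutant-direction second derivative of V.  These are different derivatives
of the same surface, and their disagreement is exactly what makes branching
points possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ClassificationError, DomainError
from .model import ModelParams
from .nash import nash_efforts, nash_efforts_batch
from . import model

__all__ = [
    "GradientCurve",
    "PIPGrid",
    "SingularPoint",
    "invasion_fitness",
    "selection_gradient",
    "gradient_curve",
    "pip_grid",
    "find_attractors",
    "classify_singular",
]

#: |gradient| below which an interior point counts as singular
SINGULAR_TOL = 1e-8
#: default finite-difference step for the selection gradient
GRADIENT_FD_STEP = 1e-5
#: default step for the mutant-direction second derivative of V
CURVATURE_FD_STEP = 1e-4
#: resident-direction offset used to probe convergence stability
CONVERGENCE_DELTA = 1e-3


@dataclass(frozen=True)
class GradientCurve:
    """Selection gradient sampled on an ascending ability grid."""

    ability_grid: np.ndarray
    gradient_values: np.ndarray
    fd_step: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.ability_grid, dtype=float)
        vals = np.asarray(self.gradient_values, dtype=float)
        if grid.ndim != 1 or grid.shape != vals.shape:
            raise DomainError("grid and gradient values must be aligned 1-d arrays")
        if np.any(np.diff(grid) <= 0) or grid[0] < 0 or grid[-1] > 1:
            raise DomainError("ability grid must be strictly ascending within [0, 1]")
        object.__setattr__(self, "ability_grid", grid)
        object.__setattr__(self, "gradient_values", vals)


@dataclass(frozen=True)
class PIPGrid:
    """Pairwise invasibility plot: V(mutant, resident) - V(resident, resident).

    ``delta_matrix`` is indexed ``[mutant, resident]``; positive entries mean
    the mutant can invade.
    """

    resident_grid: np.ndarray
    mutant_grid: np.ndarray
    delta_matrix: np.ndarray

    def invades(self) -> np.ndarray:
        """Boolean invasion mask (positive fitness difference)."""
        return self.delta_matrix > 0.0


@dataclass(frozen=True)
class SingularPoint:
    """An attractor/singular point of the adaptive dynamics with its classification."""

    location: float
    gradient_at: float
    second_deriv_invasion: float
    convergence_stable: bool
    evolutionarily_stable: bool
    label: str  # boundary_attractor_low | boundary_attractor_high | css | branching_point | repeller
    diagnostics: dict = field(default_factory=dict, compare=False)


def invasion_fitness(a_mut, a_res, params: ModelParams) -> float:
    """Payoff of a rare ``a_mut`` mutant paired with an ``a_res`` resident."""
    return nash_efforts(a_mut, a_res, params).payoff_focal


def _invasion_fitness_batch(a_mut, a_res, params: ModelParams) -> np.ndarray:
    """Vectorized V over aligned mutant/resident ability arrays."""
    a_mut = np.asarray(a_mut, dtype=float)
    a_res = np.asarray(a_res, dtype=float)
    e_mut, e_res = nash_efforts_batch(a_mut, a_res, params)
    return model.benefit(e_mut + e_res) - model.cost(a_mut, e_mut, params)


def selection_gradient(a_res, params: ModelParams, fd_step: float = GRADIENT_FD_STEP) -> float:
    """Mutant-direction derivative of invasion fitness at ``ã = a_res``.

    Central finite difference of step ``fd_step``; second-order one-sided
    stencils at the trait bounds 0 and 1.
    """
    a = float(a_res)
    if not 0.0 <= a <= 1.0:
        raise DomainError(f"resident ability must lie in [0, 1], got {a!r}")
    h = fd_step
    V = lambda am: invasion_fitness(am, a, params)  # noqa: E731
    if a - h < 0.0:
        return (-3.0 * V(a) + 4.0 * V(a + h) - V(a + 2.0 * h)) / (2.0 * h)
    if a + h > 1.0:
        return (3.0 * V(a) - 4.0 * V(a - h) + V(a - 2.0 * h)) / (2.0 * h)
    return (V(a + h) - V(a - h)) / (2.0 * h)


def gradient_curve(
    grid, params: ModelParams, fd_step: float = GRADIENT_FD_STEP
) -> GradientCurve:
    """Selection gradient evaluated pointwise on an ability grid."""
    grid = np.asarray(grid, dtype=float)
    values = np.array([selection_gradient(a, params, fd_step) for a in grid])
    return GradientCurve(grid, values, fd_step)


def pip_grid(resident_grid, mutant_grid, params: ModelParams) -> PIPGrid:
    """Pairwise invasibility plot over mutant x resident ability grids."""
    res = np.asarray(resident_grid, dtype=float)
    mut = np.asarray(mutant_grid, dtype=float)
    v_res = _invasion_fitness_batch(res, res, params)
    delta = np.empty((mut.size, res.size))
    for j, a_res in enumerate(res):
        delta[:, j] = _invasion_fitness_batch(mut, np.full(mut.shape, a_res), params) - v_res[j]
    return PIPGrid(res, mut, delta)


def classify_singular(
    a_star: float,
    params: ModelParams,
    fd_step: float = CURVATURE_FD_STEP,
    gradient_tol: float = 1e-6,
) -> SingularPoint:
    """Classify a singular point (or boundary attractor) of the adaptive dynamics.

    Interior points must satisfy ``|gradient| < gradient_tol``; convergence
    stability is read from the sign change of the gradient across the point
    (offset ``CONVERGENCE_DELTA``), evolutionary stability from the
    mutant-direction second derivative of V (central stencil, step
    ``fd_step``).  A convergence-stable, evolutionarily *unstable* interior
    point is a branching point: disruptive selection.
    """
    a = float(a_star)
    g = selection_gradient(a, params)
    h = fd_step
    # second derivative in the mutant direction; shift the stencil inward at bounds
    c = min(max(a, h), 1.0 - h)
    V = lambda am: invasion_fitness(am, a, params)  # noqa: E731
    d2v = (V(c + h) - 2.0 * V(c) + V(c - h)) / (h * h)

    if a <= 0.0 or a >= 1.0:
        low = a <= 0.0
        inward = g < 0.0 if low else g > 0.0
        if not inward:
            raise ClassificationError(
                f"boundary point a={a} is not an attractor (gradient {g:+.3e} points away from the bound)"
            )
        return SingularPoint(
            location=a,
            gradient_at=g,
            second_deriv_invasion=d2v,
            convergence_stable=True,
            evolutionarily_stable=d2v < 0.0,
            label="boundary_attractor_low" if low else "boundary_attractor_high",
        )

    if abs(g) >= gradient_tol:
        raise ClassificationError(
            f"a={a} is not singular: |gradient| = {abs(g):.3e} >= {gradient_tol:.1e}"
        )
    d = CONVERGENCE_DELTA
    g_lo = selection_gradient(max(a - d, 0.0), params)
    g_hi = selection_gradient(min(a + d, 1.0), params)
    convergence_stable = g_lo > 0.0 > g_hi
    evolutionarily_stable = d2v < 0.0
    if convergence_stable:
        label = "branching_point" if d2v > 0.0 else "css"
    else:
        label = "repeller"
    return SingularPoint(
        location=a,
        gradient_at=g,
        second_deriv_invasion=d2v,
        convergence_stable=convergence_stable,
        evolutionarily_stable=evolutionarily_stable,
        label=label,
        diagnostics={"gradient_below": g_lo, "gradient_above": g_hi},
    )


def _bisect_gradient_root(
    lo: float, g_lo: float, hi: float, g_hi: float, params: ModelParams, max_iter: int = 80
) -> float:
    """Refine a sign-change interval of the gradient to |gradient| < SINGULAR_TOL."""
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g_mid = selection_gradient(mid, params)
        if abs(g_mid) < SINGULAR_TOL:
            return mid
        if (g_mid > 0.0) == (g_lo > 0.0):
            lo, g_lo = mid, g_mid
        else:
            hi, g_hi = mid, g_mid
    return 0.5 * (lo + hi)


def find_attractors(params: ModelParams, grid_resolution: int = 201) -> list[SingularPoint]:
    """Locate and classify all singular points of the adaptive dynamics on [0, 1].

    Scans the selection gradient on a uniform grid; each interior sign
    change is refined by bisection and classified, and a trait bound is
    reported as a boundary attractor when the gradient there points into it.
    Returns the points in ascending order of location.
    """
    grid = np.linspace(0.0, 1.0, grid_resolution)
    curve = gradient_curve(grid, params)
    g = curve.gradient_values
    points: list[SingularPoint] = []

    if g[0] < 0.0:
        points.append(classify_singular(0.0, params))
    for i in range(grid_resolution - 1):
        gl, gr = g[i], g[i + 1]
        if gl == 0.0 and 0.0 < grid[i] < 1.0:
            points.append(classify_singular(grid[i], params))
        elif gl * gr < 0.0:
            root = _bisect_gradient_root(grid[i], gl, grid[i + 1], gr, params)
            points.append(classify_singular(root, params))
    if g[-1] > 0.0:
        points.append(classify_singular(1.0, params))
    points.sort(key=lambda s: s.location)
    return points
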
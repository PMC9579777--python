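"""Best responses, Nash equilibria, responsiveness, and the game-against-nature baseline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from abilitygame import (
    DomainError,
    ModelParams,
    best_response,
    nash_efforts,
    nash_efforts_batch,
    response_slope,
    solo_optimal_payoff,
)

from conftest import (
    alternating_best_response,
    brute_force_best_response,
    closed_form_nash_p2,
)

abilities = st.floats(0.0, 1.0)


@pytest.mark.parametrize(
    "a, e_partner, expected",
    [
        (0.5, 0.0, 0.4),  # closed form (1 - e)/(3 - a) for p = 2
        (1.0, 0.5, 0.25),
        (0.3, 1.2, 0.0),  # saturated benefit: any positive effort is pure cost
        (0.9, 1.0, 0.0),
    ],
)
def test_best_response_p2(p2, a, e_partner, expected):
    assert best_response(a, e_partner, p2) == pytest.approx(expected, abs=1e-12)


def test_best_response_against_grid_search(any_params):
    """The FOC root coincides with the brute-force payoff maximizer."""
    for a, e_partner in [(0.0, 0.0), (0.5, 0.3), (1.0, 0.6)]:
        r = best_response(a, e_partner, any_params)
        r_grid = brute_force_best_response(a, e_partner, any_params)
        assert r == pytest.approx(r_grid, abs=1e-6)


def test_nash_matches_p2_closed_form(p2):
    """Solver efforts agree with the linear-FOC closed form on 100 random pairs."""
    rng = np.random.default_rng(42)
    for a1, a2 in rng.random((100, 2)):
        sol = nash_efforts(a1, a2, p2)
        e1, e2 = closed_form_nash_p2(a1, a2)
        assert sol.efforts.e_focal == pytest.approx(e1, abs=1e-8)
        assert sol.efforts.e_partner == pytest.approx(e2, abs=1e-8)


def test_nash_example_pair(p2):
    sol = nash_efforts(1.0, 0.0, p2)
    assert sol.efforts.e_focal == pytest.approx(0.4, abs=1e-10)
    assert sol.efforts.e_partner == pytest.approx(0.2, abs=1e-10)
    assert sol.payoff_focal == pytest.approx(0.68, abs=1e-10)
    assert sol.payoff_partner == pytest.approx(0.76, abs=1e-10)
    assert sol.converged


@pytest.mark.parametrize("a", [0.0, 0.5, 1.0])
def test_nash_symmetric_closed_form(p2, a):
    """Equal abilities give equal efforts 1/(4 - a) for p = 2."""
    sol = nash_efforts(a, a, p2)
    assert sol.efforts.e_focal == pytest.approx(1.0 / (4.0 - a), abs=1e-10)
    assert sol.efforts.e_focal == sol.efforts.e_partner


@given(abilities, abilities)
def test_nash_swap_symmetry(any_params, a1, a2):
    """The game is anonymous: swapping the pair mirrors efforts and payoffs."""
    sol = nash_efforts(a1, a2, any_params)
    rev = nash_efforts(a2, a1, any_params)
    assert sol.efforts.e_focal == rev.efforts.e_partner
    assert sol.efforts.e_partner == rev.efforts.e_focal
    assert sol.payoff_focal == rev.payoff_partner


@given(abilities, abilities)
def test_nash_total_below_saturation_and_payoffs_nonnegative(any_params, a1, a2):
    sol = nash_efforts(a1, a2, any_params)
    assert 0.0 < sol.efforts.total < 1.0
    assert sol.payoff_focal >= 0.0 and sol.payoff_partner >= 0.0
    assert max(abs(r) for r in sol.foc_residuals) < 1e-10


def test_nash_agrees_with_alternating_best_response_oracle(any_params):
    """Independent fixed-point iteration of best responses lands on the same equilibrium."""
    rng = np.random.default_rng(7)
    for a1, a2 in rng.random((20, 2)):
        sol = nash_efforts(a1, a2, any_params)
        e1, e2 = alternating_best_response(a1, a2, any_params)
        assert sol.efforts.e_focal == pytest.approx(e1, abs=1e-9)
        assert sol.efforts.e_partner == pytest.approx(e2, abs=1e-9)


def test_batch_solver_matches_scalar(any_params):
    rng = np.random.default_rng(3)
    a1, a2 = rng.random(50), rng.random(50)
    e1, e2 = nash_efforts_batch(a1, a2, any_params)
    for i in range(50):
        sol = nash_efforts(a1[i], a2[i], any_params)
        assert e1[i] == pytest.approx(sol.efforts.e_focal, abs=1e-12)
        assert e2[i] == pytest.approx(sol.efforts.e_partner, abs=1e-12)


@pytest.mark.parametrize("p", [1.25, 1.5, 2.0])
def test_comparative_statics_in_mutant_ability(p):
    """As focal ability rises: own effort up, partner effort down, total up."""
    params = ModelParams(p=p)
    a_partner = 0.5
    grid = np.linspace(0.0, 1.0, 21)
    sols = [nash_efforts(a, a_partner, params) for a in grid]
    e_focal = np.array([s.efforts.e_focal for s in sols])
    e_partner = np.array([s.efforts.e_partner for s in sols])
    total = e_focal + e_partner
    assert np.all(np.diff(e_focal) >= 0)
    assert np.all(np.diff(e_partner) <= 0)
    assert np.all(np.diff(total) >= 0)


@pytest.mark.parametrize("a, expected", [(0.5, -0.4), (1.0, -0.5)])
def test_response_slope_p2_closed_form(p2, a, expected):
    """For p = 2 the slope is -1/(3 - a), independent of the partner's effort."""
    for e_partner in (0.0, 0.3, 0.6):
        assert response_slope(a, e_partner, p2) == pytest.approx(expected, abs=1e-9)


def test_response_slope_matches_finite_differences(any_params):
    h = 1e-6
    for a, e_partner in [(0.2, 0.1), (0.7, 0.4), (1.0, 0.25)]:
        fd = (
            best_response(a, e_partner + h, any_params)
            - best_response(a, e_partner - h, any_params)
        ) / (2.0 * h)
        assert response_slope(a, e_partner, any_params) == pytest.approx(fd, abs=1e-5)


@given(abilities, st.floats(0.0, 0.95))
def test_response_slope_strictly_inside_unit_interval(any_params, a, e_partner):
    """Partial compensation: the best response falls by less than the partner's rise."""
    slope = response_slope(a, e_partner, any_params)
    assert -1.0 < slope < 0.0


def test_response_slope_zero_at_corner(p2):
    assert response_slope(0.5, 1.5, p2) == 0.0


def test_responsiveness_greater_for_low_cost_exponent():
    """At the symmetric a=0.5 equilibrium, effort compensation is stronger for
    p = 1.25 than for p = 2.0 — the mechanism behind selection for low ability."""
    slopes = {}
    for p in (1.25, 2.0):
        params = ModelParams(p=p)
        e_star = nash_efforts(0.5, 0.5, params).efforts.e_focal
        slopes[p] = abs(response_slope(0.5, e_star, params))
    assert slopes[1.25] > slopes[2.0]


def test_solo_optimum_example(p2):
    effort, w = solo_optimal_payoff(0.5, 0.0, p2)
    assert effort == pytest.approx(0.4, abs=1e-10)
    assert w == pytest.approx(0.40, abs=1e-10)


def test_solo_payoff_increasing_in_ability():
    """Against a non-responding environment selection always favours ability."""
    for p in (1.25, 2.0):
        params = ModelParams(p=p)
        payoffs = [solo_optimal_payoff(a, 0.3, params)[1] for a in np.linspace(0.0, 1.0, 11)]
        assert np.all(np.diff(payoffs) > 0)


def test_solo_optimum_saturated_environment(p2):
    effort, w = solo_optimal_payoff(0.8, 1.5, p2)
    assert effort == 0.0
    assert w == 1.0


def test_invalid_inputs(p2):
    with pytest.raises(DomainError):
        best_response(1.5, 0.2, p2)
    with pytest.raises(DomainError):
        best_response(0.5, -0.1, p2)
    with pytest.raises(DomainError):
        nash_efforts(-0.2, 0.5, p2)
    with pytest.raises(DomainError):
        nash_efforts_batch(np.array([0.5]), np.array([1.2]), p2)
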
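import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from abilitygame import ModelParams  # noqa: E402


@pytest.fixture(scope="session")
def p2():
    """The quadratic-cost game, where the Nash system is linear and closed-form."""
    return ModelParams(p=2.0)


@pytest.fixture(scope="session", params=[1.25, 1.5, 2.0])
def any_params(request):
    """The three cost exponents studied throughout."""
    return ModelParams(p=request.param)


def closed_form_nash_p2(a1, a2):
    """Independent closed-form Nash efforts for p = 2 (linear FOC system).

    With u = 1/(2-a1), v = 1/(2-a2) the total effort is
    s = (u+v)/(1+u+v) and e_i = (1-s)/(2-a_i).
    """
    u, v = 1.0 / (2.0 - a1), 1.0 / (2.0 - a2)
    s = (u + v) / (1.0 + u + v)
    return (1.0 - s) / (2.0 - a1), (1.0 - s) / (2.0 - a2)


def analytic_gradient_p2(a):
    """Closed-form selection gradient for p = 2.

    V(u, v) = s(2-s) - u(1-s)^2 with u = 1/(2-ã), v = 1/(2-a) and
    s = (u+v)/(1+u+v); differentiating in the mutant direction and
    evaluating at ã = a gives (1-s)^2 (2(1-s) - 1 + 2u(1-s)) u^2.
    """
    u = 1.0 / (2.0 - a)
    s = 2.0 * u / (1.0 + 2.0 * u)
    oms = 1.0 - s
    return oms**2 * (2.0 * oms - 1.0 + 2.0 * u * oms) * u**2


def alternating_best_response(a1, a2, params, tol=1e-12, max_iter=10000):
    """Independent fixed-point oracle: iterate best responses until stable."""
    from abilitygame import best_response

    e1 = e2 = 0.25
    for _ in range(max_iter):
        e1_new = best_response(a1, e2, params)
        e2_new = best_response(a2, e1_new, params)
        if abs(e1_new - e1) < tol and abs(e2_new - e2) < tol:
            return e1_new, e2_new
        e1, e2 = e1_new, e2_new
    raise AssertionError("alternating best responses did not converge")


def brute_force_best_response(a, e_partner, params, n=2_000_001):
    """Grid-search maximizer of the payoff over effort in [0, 1]."""
    from abilitygame import payoff

    e = np.linspace(0.0, 1.0, n)
    return e[np.argmax(payoff(a, e, e_partner, params))]
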
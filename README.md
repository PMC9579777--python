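# abilitygame

Why would natural selection ever favour *less* able individuals?  When
fitness comes from a joint task, it can.  This package analyses a
two-player public-goods game in which each individual carries a heritable
ability trait `a ∈ [0, 1]`: pairs form at random, each player contributes
an effort to a common good, and efforts settle at the Nash equilibrium
given both abilities.  The payoff to a player of ability `ã` expending
effort `ẽ` against a partner expending `e` is

    W(ẽ, e) = B(ẽ + e) − K(ã, ẽ),

with a saturating common benefit and an accelerating, ability-discounted
private cost

    B(t) = 2t − t²  (t < 1),  B(t) = 1  (t ≥ 1),     K(a, e) = (2 − a) e^p,  p > 1.

Because the benefit has diminishing returns, each player partially
compensates for a lazier partner.  A low-ability individual therefore
free-rides on its partner's compensation — and when compensation is strong
(cost exponent `p` near 1), a rare mutant's invasion fitness

    V(ã, a) = B(e*(ã, a) + e*(a, ã)) − K(ã, e*(ã, a))

*decreases* with its ability: selection drives ability down.  The package
computes all of this end to end: Nash efforts, selection gradients
`∂V/∂ã|_{ã=a}`, pairwise invasibility plots, classification of singular
points (CSS / branching point / repeller / boundary attractors), and
agent-based evolutionary simulations under sexual (infinitesimal-model)
and asexual (clonal + mutation) inheritance, where disruptive selection at
a branching point can split the population into a bimodal ability
distribution.

Intended users: researchers and students in evolutionary game theory and
adaptive dynamics who want a worked, tested, reproducible instance of
"social interaction selects against ability" to build on.

## Worked example

Equilibrium efforts for an unequal pair under strong compensation
(`p = 1.25`):

```
$ abilitygame nash --a1 1 --a2 0 --p 1.25
abilities      a1=1  a2=0  (p=1.25)
Nash efforts   e1=0.4574172875  e2=0.0285885805
payoffs        w1=0.3596343496  w2=0.7122990521
```

The able player works sixteen times harder — and earns *half* the payoff
of its zero-ability partner, who free-rides on the compensation.  That
asymmetry is exactly what makes reduced ability selectively favoured here:

```
$ abilitygame singular --p 1.25
a*=0.00000000  boundary_attractor_low  gradient=-3.343e-02  d2V=+2.349e-02
```

The selection gradient is negative everywhere, so the adaptive dynamics
converge to ability 0.  At an intermediate cost exponent the attractor
moves inside the trait range and becomes a branching point (convergence
stable, but with positive invasion-fitness curvature — disruptive
selection):

```
$ abilitygame singular --p 1.5
a*=0.66666687  branching_point  gradient=-8.477e-09  d2V=+7.292e-02
```

An asexual population simulated at this exponent splits in two
(`abilitygame evolve --config examples/sim.toml`), while sexual
(infinitesimal-model) inheritance keeps the distribution unimodal at every
generation; see `docs/methods.md` for the inheritance models and their
declared parameters, and `docs/formats.md` for every file schema.  Other
subcommands: `gradient` (selection-gradient curve CSV), `pip` (pairwise
invasibility plot), `figures` (regenerate all standard data tables).
Everything is also available as a library:

```python
import numpy as np
from abilitygame import ModelParams, find_attractors, run_evolution, SimConfig

find_attractors(ModelParams(p=2.0), 101)   # -> [a = 1, boundary attractor]
```

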
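"""Optional matplotlib convenience plots.

Never required by the analysis pipeline or the test suite; requires the
``plot`` extra (matplotlib).
"""

from __future__ import annotations

import numpy as np


def plot_gradient(curve, ax=None):
    """Selection gradient versus resident ability, with the zero line."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.plot(curve.ability_grid, curve.gradient_values, color="C0")
    ax.set_xlabel("resident ability $a$")
    ax.set_ylabel("selection gradient")
    return ax


def plot_pip(pip, ax=None):
    """Shade the (resident, mutant) region where the mutant invades."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.pcolormesh(
        pip.resident_grid,
        pip.mutant_grid,
        pip.invades().astype(float),
        cmap="Greys",
        vmin=0,
        vmax=1.6,
        shading="nearest",
    )
    ax.plot([0, 1], [0, 1], color="k", lw=0.8)
    ax.set_xlabel("resident ability $a$")
    ax.set_ylabel(r"mutant ability $\tilde a$")
    return ax


def plot_quantile_series(result, ax=None):
    """Median ability and 95% quantile band over generations."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    gens = result.generations
    q = result.quantile_series
    ax.fill_between(gens, q[:, 0], q[:, 2], alpha=0.3, color="C0", lw=0)
    ax.plot(gens, q[:, 1], color="C0")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("generation")
    ax.set_ylabel("ability")
    return ax


def plot_final_histogram(result, ax=None):
    """Final ability distribution of an evolutionary run."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    edges, counts = result.final_histogram
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", color="C0")
    ax.set_xlabel("ability")
    ax.set_ylabel("count")
    return ax
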
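"""Tabular data behind the package's four standard analyses.

Each generator writes plain CSV tables (no timestamps, 17 significant
digits) so that runs with the same request are byte-identical:

* ``fig1`` — how a single rare mutant's Nash effort, its resident partner's
  effort, and the mutant's benefit/cost/net payoff change with mutant
  ability (resident ability 0.5, cost exponent 1.25 by default).
* ``fig2`` — selection-gradient curves and pairwise-invasibility tables for
  a list of cost exponents.
* ``fig3`` — sexual (infinitesimal-model) evolutionary runs: ability
  quantile series for the standard initial-condition x cost-exponent
  combinations.
* ``fig4`` — asexual runs: quantile series plus final ability histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .evolution import SimConfig, run_evolution
from .invasion import gradient_curve, pip_grid
from .model import ModelParams
from .nash import nash_efforts
from . import model

__all__ = ["FigureRequest", "generate_figure_data", "FLOAT_FORMAT"]

#: text float format used by every CSV writer: lossless round-trip
FLOAT_FORMAT = "%.17g"

FIGURE_IDS = ("fig1", "fig2", "fig3", "fig4")

#: (cost exponent, founder ability) combinations of the standard runs
RUN_COMBOS = ((1.25, 1.0), (1.5, 1.0), (1.5, 0.0), (2.0, 0.0))


@dataclass(frozen=True)
class FigureRequest:
    """A request for one figure's data tables."""

    figure_id: str
    p_values: tuple[float, ...] = (1.25, 1.5, 2.0)
    resolution: int = 201
    n_individuals: int = 1000
    n_generations: int = 10001
    record_every: int = 10
    seed: int = 0
    outdir: Path = Path(".")

    def __post_init__(self) -> None:
        if self.figure_id not in FIGURE_IDS:
            raise ConfigError(
                f"unknown figure_id {self.figure_id!r}; expected one of {FIGURE_IDS}"
            )
        for p in self.p_values:
            ModelParams(p=p)  # raises DomainError if p <= 1
        object.__setattr__(self, "p_values", tuple(float(p) for p in self.p_values))
        object.__setattr__(self, "outdir", Path(self.outdir))


def write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def _ptag(p: float) -> str:
    return f"p{p:g}".replace(".", "_")


def mutant_sweep_table(
    a_resident: float = 0.5, p: float = 1.25, n_points: int = 101
) -> pd.DataFrame:
    """Efforts, benefit, cost and payoffs across mutant abilities.

    One row per mutant ability on a uniform grid; the resident payoff
    column is the constant payoff in the monomorphic resident population.
    """
    params = ModelParams(p=p)
    resident_payoff = nash_efforts(a_resident, a_resident, params).payoff_focal
    rows = []
    for a_mut in np.linspace(0.0, 1.0, n_points):
        sol = nash_efforts(a_mut, a_resident, params)
        e_mut, e_res = sol.efforts.e_focal, sol.efforts.e_partner
        rows.append(
            {
                "mutant_ability": a_mut,
                "mutant_effort": e_mut,
                "partner_effort": e_res,
                "total_effort": e_mut + e_res,
                "benefit": model.benefit(e_mut + e_res),
                "cost": model.cost(a_mut, e_mut, params),
                "net_payoff": sol.payoff_focal,
                "resident_payoff": resident_payoff,
            }
        )
    return pd.DataFrame(rows)


def gradient_table(p: float, n_points: int = 101) -> pd.DataFrame:
    curve = gradient_curve(np.linspace(0.0, 1.0, n_points), ModelParams(p=p))
    return pd.DataFrame(
        {"ability": curve.ability_grid, "gradient": curve.gradient_values}
    )


def pip_table(p: float, n_points: int = 201) -> pd.DataFrame:
    """Long-format PIP: one row per (resident, mutant) cell."""
    grid = np.linspace(0.0, 1.0, n_points)
    pip = pip_grid(grid, grid, ModelParams(p=p))
    res, mut = np.meshgrid(pip.resident_grid, pip.mutant_grid)
    return pd.DataFrame(
        {
            "resident": res.ravel(),
            "mutant": mut.ravel(),
            "delta": pip.delta_matrix.ravel(),
            "invades": pip.invades().ravel().astype(int),
        }
    )


def series_table(result) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "generation": result.generations,
            "q025": result.quantile_series[:, 0],
            "median": result.quantile_series[:, 1],
            "q975": result.quantile_series[:, 2],
        }
    )


def histogram_table(result) -> pd.DataFrame:
    edges, counts = result.final_histogram
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def _evolution_tables(request: FigureRequest, mode: str, outdir: Path) -> list[Path]:
    written = []
    for i, (p, a0) in enumerate(RUN_COMBOS):
        config = SimConfig(
            mode=mode,
            n_individuals=request.n_individuals,
            n_generations=request.n_generations,
            initial_ability=a0,
            record_every=request.record_every,
            seed=request.seed + i,
        )
        result = run_evolution(config, ModelParams(p=p))
        stem = f"{mode}_{_ptag(p)}_from{a0:g}".replace(".", "_")
        written.append(write_csv(series_table(result), outdir / f"series_{stem}.csv"))
        written.append(
            write_csv(histogram_table(result), outdir / f"final_hist_{stem}.csv")
        )
    return written


def generate_figure_data(request: FigureRequest) -> list[Path]:
    """Generate one figure's data tables; returns the written file paths."""
    outdir = request.outdir
    if request.figure_id == "fig1":
        table = mutant_sweep_table(n_points=request.resolution)
        return [write_csv(table, outdir / "fig1_mutant_sweep.csv")]
    if request.figure_id == "fig2":
        written = []
        for p in request.p_values:
            tag = _ptag(p)
            written.append(
                write_csv(
                    gradient_table(p, min(request.resolution, 101)),
                    outdir / f"fig2_gradient_{tag}.csv",
                )
            )
            written.append(
                write_csv(pip_table(p, request.resolution), outdir / f"fig2_pip_{tag}.csv")
            )
        return written
    mode = "sexual" if request.figure_id == "fig3" else "asexual"
    return _evolution_tables(request, mode, outdir)
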
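"""Lifecycle composition, equilibrium iteration, parameter sweeps, and
figure presets.

One generation applies, in lifecycle order: fitness (social payoff times
parasite multiplier) -> selection -> free recombination -> Trait/Choice
mutation -> census (Resist frequencies appended to history).

Runs terminate at a fixed point (L-infinity frequency change below
``fixed_point_tol``), at a detected limit cycle (two consecutive
generation windows whose observable means agree to 1e-6 -- the expected
outcome under Red Queen oscillations), or at ``max_generations``.
Equilibrium observables are means over the final window so that cycling
cells are summarized stably.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_core import (
    AX_RESIST,
    GenotypeSpace,
    InitSpec,
    ModelParams,
    PopulationState,
    ResistHistory,
    _clean_simplex,
    allele_frequencies,
    build_space,
    initialize_population,
    mutate,
    recombine_free,
)
from .observables import ObservableRecord, snapshot, _SCALAR_FIELDS
from .parasite_dynamics import parasite_payoff_vector
from .social_payoffs import p_interact, relatedness_rtag, social_payoff_vector

__all__ = [
    "StepResult",
    "Trajectory",
    "SweepResult",
    "step_generation",
    "run_to_equilibrium",
    "sweep",
    "preset",
    "PRESET_NAMES",
]

#: limit-cycle detection tolerance on window-mean observables
CYCLE_TOL = 1e-6

#: quantities whose window means drive limit-cycle detection
_CYCLE_KEYS = ("div_resist_scaled", "div_neutral_scaled", "p_bar", "choice_freq", "susceptibility")


class StepResult(NamedTuple):
    state: PopulationState
    history: ResistHistory
    mean_fitness: float


def step_generation(
    state: PopulationState,
    history: ResistHistory,
    params: ModelParams,
    space: GenotypeSpace,
) -> StepResult:
    """Advance the population one generation.  Pure: inputs untouched."""
    payoff, _ = social_payoff_vector(state, params, space)
    pmult = parasite_payoff_vector(state, history, params, space)
    w = payoff * pmult
    fw = state.freqs * w
    wbar = float(fw.sum())
    if not np.isfinite(wbar) or wbar <= 0:
        raise ValueError(f"mean fitness {wbar!r} is not positive at generation {state.generation}")
    selected = fw / wbar
    recombined = recombine_free(selected, space)
    mutated = mutate(recombined, params.mu_trait, params.mu_choice, space)
    freqs = _clean_simplex(mutated)
    if not np.all(np.isfinite(freqs)):
        raise FloatingPointError(f"non-finite frequencies at generation {state.generation + 1}")
    new_state = PopulationState(freqs, state.generation + 1)
    new_history = history.copy()
    new_history.append(allele_frequencies(freqs, space, AX_RESIST))
    return StepResult(new_state, new_history, wbar)


@dataclass
class Trajectory:
    """Result of an equilibrium run."""

    records: List[ObservableRecord]
    final_state: PopulationState
    final_record: ObservableRecord
    status: str                    # fixed_point | limit_cycle | max_generations
    generations: int
    equilibrium: Dict[str, float]  # window means of the scalar observables


def run_to_equilibrium(
    params: ModelParams,
    init: Optional[InitSpec] = None,
    space: Optional[GenotypeSpace] = None,
    record_every: Optional[int] = None,
) -> Trajectory:
    """Iterate the deterministic recursion until convergence.

    ``record_every`` thins the stored trajectory records (full per-tag
    arrays are kept only on the final record); by default at most ~5000
    records are stored.
    """
    if init is None:
        init = InitSpec()
    if space is None:
        space = build_space(params.L_resist, params.L_neutral)
    if record_every is None:
        record_every = max(1, params.max_generations // 5000)

    state = initialize_population(space, init, params.seed)
    history = ResistHistory(allele_frequencies(state.freqs, space, AX_RESIST), params.lag)

    window = deque(maxlen=params.cycle_window)
    records: List[ObservableRecord] = []
    rec0 = snapshot(state, history, params, space, per_tag=False)
    records.append(rec0)
    window.append(rec0.scalars())

    status = "max_generations"
    prev_window_mean: Optional[np.ndarray] = None
    cycle_hits = 0
    gens_in_window = 0

    for gen in range(1, params.max_generations + 1):
        prev_freqs = state.freqs
        state, history, wbar = step_generation(state, history, params, space)
        rec = snapshot(state, history, params, space, per_tag=False, mean_fitness=wbar)
        window.append(rec.scalars())
        if gen % record_every == 0:
            records.append(rec)

        delta = float(np.max(np.abs(state.freqs - prev_freqs)))
        if delta < params.fixed_point_tol:
            status = "fixed_point"
            break

        gens_in_window += 1
        if gens_in_window == params.cycle_window:
            gens_in_window = 0
            mean = np.array([
                np.mean([r[k] for r in window]) for k in _CYCLE_KEYS
            ])
            if prev_window_mean is not None and np.max(np.abs(mean - prev_window_mean)) < CYCLE_TOL:
                cycle_hits += 1
                if cycle_hits >= 2:
                    status = "limit_cycle"
                    break
            else:
                cycle_hits = 0
            prev_window_mean = mean

    final_record = snapshot(state, history, params, space, per_tag=True)
    if records[-1].generation != state.generation:
        records.append(final_record)
    equilibrium = {
        k: float(np.mean([r[k] for r in window])) for k in _SCALAR_FIELDS
    }
    return Trajectory(
        records=records,
        final_state=state,
        final_record=final_record,
        status=status,
        generations=state.generation,
        equilibrium=equilibrium,
    )


@dataclass
class SweepResult:
    """Equilibrium observables over a parameter grid, one row per cell."""

    table: pd.DataFrame
    params_base: ModelParams


#: canonical sweep-table columns (stable CSV schema)
SWEEP_COLUMNS = [
    "lag", "d", "alpha", "mu_choice",
    "div_resist_scaled", "div_neutral_scaled",
    "div_resist_eff", "div_neutral_eff", "p_bar", "choice_freq",
    "susceptibility", "susceptibility_baseline",
    "ld_assoc_resist", "ld_assoc_neutral", "status",
]


def _cell_row(params: ModelParams, traj: Trajectory, baseline_susc: float) -> Dict:
    eq = traj.equilibrium
    return {
        "lag": params.lag,
        "d": params.d,
        "alpha": params.alpha,
        "mu_choice": params.mu_choice,
        "div_resist_scaled": eq["div_resist_scaled"],
        "div_neutral_scaled": eq["div_neutral_scaled"],
        "div_resist_eff": eq["div_resist_eff"],
        "div_neutral_eff": eq["div_neutral_eff"],
        "p_bar": eq["p_bar"],
        "choice_freq": eq["choice_freq"],
        "susceptibility": eq["susceptibility"],
        "susceptibility_baseline": baseline_susc,
        "ld_assoc_resist": eq["assoc_resist"],
        "ld_assoc_neutral": eq["assoc_neutral"],
        "status": traj.status,
    }


def sweep(
    params_base: ModelParams,
    grid: Dict[str, Sequence],
    init: Optional[InitSpec] = None,
    baseline: bool = False,
    progress: Optional[callable] = None,
) -> SweepResult:
    """Run :func:`run_to_equilibrium` over the cartesian product of the
    grid values.  Deterministic given the seed in ``params_base``.

    With ``baseline=True`` each cell is paired with a matched run with
    b = c = 0 (no social selection) whose equilibrium susceptibility is
    reported in ``susceptibility_baseline`` -- the no-recognition
    reference for the susceptibility-cost comparison.

    Per-cell errors are recorded in the ``status`` column; the sweep
    continues.
    """
    keys = list(grid)
    rows = []
    for values in itertools.product(*(grid[k] for k in keys)):
        cell = dict(zip(keys, values))
        params = params_base.with_(**cell)
        try:
            traj = run_to_equilibrium(params, init=init)
            baseline_susc = float("nan")
            if baseline:
                btraj = run_to_equilibrium(params.with_(b=0.0, c=0.0), init=init)
                baseline_susc = btraj.equilibrium["susceptibility"]
            row = _cell_row(params, traj, baseline_susc)
        except Exception as exc:  # record and continue
            row = {k: float("nan") for k in SWEEP_COLUMNS if k != "status"}
            row.update({
                "lag": params.lag, "d": params.d, "alpha": params.alpha,
                "mu_choice": params.mu_choice, "status": f"error: {exc}",
            })
        for k, v in cell.items():
            if k not in row:
                row[k] = v
        rows.append(row)
        if progress is not None:
            progress(cell, row)
    extra = [k for k in keys if k not in SWEEP_COLUMNS]
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS + extra)
    return SweepResult(table=table, params_base=params_base)


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("fig1b", "fig3", "fig4b", "fig5a", "fig5b", "fig6")

_DEFAULT_LAG_GRID = (0, 2, 10, 20)
_DEFAULT_D_GRID = (0.1, 0.5, 0.9)


def _fixed_resist(params: ModelParams) -> ModelParams:
    return params.with_(mu_choice=0.0)


def preset(name: str, overrides: Optional[Dict] = None,
           lag_grid: Sequence[int] = _DEFAULT_LAG_GRID,
           d_grid: Sequence[float] = _DEFAULT_D_GRID,
           progress: Optional[callable] = None):
    """Run one of the canned experiment presets.

    * ``fig1b`` -- analytic curve: tag-match probability vs tag frequency
      at alpha = 0, with the pedigree-only baseline theta.
    * ``fig4b`` -- analytic curve: R_tag vs tag frequency with p = p_bar,
      with the random-partner baseline theta.
    * ``fig3``  -- lag x d sweep at alpha = 0, Choice fixed on Resist,
      with the matched no-social-selection susceptibility baseline.
    * ``fig5a`` -- lag x d sweep at alpha = 1 with evolving Choice;
      adds the Neutral-minus-Resist diversity column.
    * ``fig5b`` -- lag x d sweep at alpha = 0.99 comparing evolving
      Choice against both fixed-locus cases.
    * ``fig6``  -- one low-lag intermediate-d cell at alpha = 0.99:
      equilibrium diversity at each locus under fixed vs evolving Choice.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}")
    overrides = overrides or {}
    base = ModelParams(**{**dict(theta=0.25, b=0.3, c=0.1, L_resist=10, L_neutral=10,
                                 L_max=10, mu_trait=1e-3, max_generations=30_000),
                          **overrides})

    if name == "fig1b":
        X = np.linspace(0.0, 1.0, 101)
        return pd.DataFrame({
            "X": X,
            "recognition_prob": [p_interact(x, base.theta, 0.0) for x in X],
            "pedigree_baseline": base.theta,
        })

    if name == "fig4b":
        X = np.linspace(0.01, 1.0, 100)
        p = 0.5
        return pd.DataFrame({
            "X": X,
            "rtag": [relatedness_rtag(x, p, p, base.theta) for x in X],
            "random_partner_baseline": base.theta,
        })

    grid = {"lag": list(lag_grid), "d": list(d_grid)}

    if name == "fig3":
        params = base.with_(alpha=0.0, mu_choice=0.0)
        init = InitSpec(q0=1.0)  # everyone uses Resist
        return sweep(params, grid, init=init, baseline=True, progress=progress)

    if name == "fig5a":
        params = base.with_(alpha=1.0, mu_choice=1e-3)
        res = sweep(params, grid, init=InitSpec(q0=0.5), progress=progress)
        res.table["div_neutral_minus_resist"] = (
            res.table["div_neutral_scaled"] - res.table["div_resist_scaled"]
        )
        return res

    if name == "fig5b":
        alpha = 0.99
        evolving = sweep(base.with_(alpha=alpha, mu_choice=1e-3), grid,
                         init=InitSpec(q0=0.5), progress=progress)
        fix_r = sweep(base.with_(alpha=alpha, mu_choice=0.0), grid,
                      init=InitSpec(q0=1.0), progress=progress)
        fix_n = sweep(base.with_(alpha=alpha, mu_choice=0.0), grid,
                      init=InitSpec(q0=0.0), progress=progress)
        t = evolving.table[["lag", "d"]].copy()
        ev = evolving.table
        # diversity at the locus actually used (Choice-majority locus), and
        # the per-cell maximum over loci
        used = np.where(ev["choice_freq"] >= 0.5,
                        ev["div_resist_scaled"], ev["div_neutral_scaled"])
        t["div_evolving_used"] = used
        t["div_evolving_max"] = ev[["div_resist_scaled", "div_neutral_scaled"]].max(axis=1)
        t["div_fixed_resist"] = fix_r.table["div_resist_scaled"].values
        t["div_fixed_neutral"] = fix_n.table["div_neutral_scaled"].values
        t["div_fixed_best"] = np.maximum(t["div_fixed_resist"], t["div_fixed_neutral"])
        t["div_gain"] = t["div_evolving_max"] - t["div_fixed_best"]
        return t

    if name == "fig6":
        alpha = 0.99
        lag = overrides.get("lag", 1)
        d = overrides.get("d", 0.5)
        cell = base.with_(alpha=alpha, lag=lag, d=d)
        # start with depleted Neutral standing variation so the build-up
        # (hitchhiking) is visible rather than assumed
        skew = np.array([0.91] + [0.01] * (cell.L_neutral - 1))

        def init(q0):
            return InitSpec(q0=q0, neutral_freqs=skew, epsilon=1e-5)

        runs = {
            ("resist", "fixed"): (cell.with_(mu_choice=0.0), init(1.0)),
            ("neutral", "fixed"): (cell.with_(mu_choice=0.0), init(0.0)),
        }
        rows = []
        for (locus, cond), (p_, i_) in runs.items():
            traj = run_to_equilibrium(p_, init=i_)
            key = f"div_{locus}_scaled"
            rows.append({"locus": locus, "condition": cond,
                         "div_scaled": traj.equilibrium[key],
                         "status": traj.status})
        ev = run_to_equilibrium(cell.with_(mu_choice=1e-3), init=init(0.5))
        for locus in ("resist", "neutral"):
            rows.append({"locus": locus, "condition": "evolving",
                         "div_scaled": ev.equilibrium[f"div_{locus}_scaled"],
                         "status": ev.status})
        return pd.DataFrame(rows)
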
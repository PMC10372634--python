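import numpy as np
import pandas as pd
import pytest

from kintag import (
    InitSpec,
    ModelParams,
    build_space,
    initialize_population,
    mutate,
    preset,
    recombine_free,
    run_to_equilibrium,
    step_generation,
    sweep,
)
from kintag.equilibrium_runner import SWEEP_COLUMNS
from kintag.genotype_core import AX_RESIST, ResistHistory, allele_frequencies
from kintag.parasite_dynamics import parasite_payoff_vector
from kintag.social_payoffs import social_payoff_vector

from conftest import history_for, random_state


def fresh(space, init, params):
    state = initialize_population(space, init, params.seed)
    hist = ResistHistory(allele_frequencies(state.freqs, space, AX_RESIST), params.lag)
    return state, hist


class TestStepGeneration:
    def test_neutral_linkage_equilibrium_fixed_point(self, default_space):
        params = ModelParams(b=0.0, c=0.0, d=0.0, mu_trait=0.0, mu_choice=0.0)
        state, hist = fresh(default_space, InitSpec(epsilon=0.0), params)
        out, _, _ = step_generation(state, hist, params, default_space)
        assert np.allclose(out.freqs, state.freqs, atol=1e-14)

    def test_monomorphic_fixed_point_any_parameters(self):
        space = build_space(1, 1)
        params = ModelParams(L_resist=1, L_neutral=1, L_max=10,
                             b=0.3, c=0.1, d=0.7, lag=2, alpha=0.4,
                             mu_trait=0.0, mu_choice=0.0)
        state, hist = fresh(space, InitSpec(p0=1.0, q0=1.0, epsilon=0.0), params)
        out, _, _ = step_generation(state, hist, params, space)
        assert np.allclose(out.freqs, state.freqs, atol=1e-14)

    def test_equals_composition_of_stage_operations(self, small_space, small_params):
        params = small_params.with_(d=0.3, lag=0, alpha=0.2,
                                    mu_trait=1e-3, mu_choice=1e-3)
        state = random_state(small_space, 5)
        hist = history_for(state, small_space, 0)
        out, _, wbar = step_generation(state, hist, params, small_space)
        # independent composition
        payoff, _ = social_payoff_vector(state, params, small_space)
        pmult = parasite_payoff_vector(state, hist, params, small_space)
        w = payoff * pmult
        sel = state.freqs * w / np.dot(state.freqs, w)
        expected = mutate(recombine_free(sel, small_space),
                          params.mu_trait, params.mu_choice, small_space)
        expected /= expected.sum()
        assert np.allclose(out.freqs, expected, atol=1e-14)
        assert wbar == pytest.approx(float(np.dot(state.freqs, w)), abs=1e-14)

    def test_inputs_untouched_and_history_appended(self, small_space, small_params):
        state = random_state(small_space, 6)
        hist = history_for(state, small_space, small_params.lag)
        before = state.freqs.copy()
        out, hist2, _ = step_generation(state, hist, small_params, small_space)
        assert np.array_equal(state.freqs, before)
        assert len(hist) == 1  # original untouched
        assert np.allclose(hist2[-1], allele_frequencies(out.freqs, small_space, AX_RESIST))
        assert out.generation == state.generation + 1

    def test_choice_moves_toward_more_diverse_locus(self, default_space):
        """One generation of selection increases the Choice allele that
        points at the locus with more tag diversity (helping segregating,
        no mutation confound)."""
        skew = np.array([0.82] + [0.02] * 9)
        for alpha in (0.0, 0.99):
            params = ModelParams(theta=0.25, b=0.3, c=0.1, d=0.0, lag=0,
                                 alpha=alpha, mu_trait=0.0, mu_choice=0.0)
            # Neutral more diverse -> USE_RESIST should fall
            init = InitSpec(p0=0.5, q0=0.5, resist_freqs=skew, epsilon=0.0)
            state, hist = fresh(default_space, init, params)
            out, _, _ = step_generation(state, hist, params, default_space)
            q1 = out.freqs.reshape(default_space.shape)[:, :, 0, :].sum()
            assert q1 < 0.5
            # Resist more diverse -> USE_RESIST should rise
            init = InitSpec(p0=0.5, q0=0.5, neutral_freqs=skew, epsilon=0.0)
            state, hist = fresh(default_space, init, params)
            out, _, _ = step_generation(state, hist, params, default_space)
            q1 = out.freqs.reshape(default_space.shape)[:, :, 0, :].sum()
            assert q1 > 0.5


class TestRunToEquilibrium:
    def test_symmetric_neutral_start_is_fixed_point(self):
        params = ModelParams(b=0.0, c=0.0, d=0.0, mu_trait=0.0, mu_choice=0.0,
                             L_resist=3, L_neutral=3, L_max=3, max_generations=50)
        traj = run_to_equilibrium(params, init=InitSpec(epsilon=0.0))
        assert traj.status == "fixed_point"
        assert traj.generations <= 2

    def test_crozier_collapse_two_tags(self):
        # no parasites, single encounter: the common tag runs to fixation
        params = ModelParams(theta=0.25, b=0.3, c=0.1, d=0.0, lag=0, alpha=0.0,
                             L_resist=2, L_neutral=2, L_max=10,
                             mu_trait=1e-3, mu_choice=0.0,
                             max_generations=10_000, seed=1)
        init = InitSpec(q0=1.0, resist_freqs=[0.55, 0.45],
                        neutral_freqs=[0.55, 0.45], epsilon=1e-3)
        traj = run_to_equilibrium(params, init=init)
        assert traj.equilibrium["div_resist_scaled"] < 0.01

    def test_red_queen_cell_keeps_cycling_with_converged_window_means(self):
        # higher lag*d inside the cycling regime: sustained oscillation of
        # Resist frequencies while window means settle
        params = ModelParams(theta=0.25, b=0.3, c=0.1, d=0.9, lag=30, alpha=0.0,
                             mu_trait=1e-3, mu_choice=0.0,
                             max_generations=60_000, cycle_window=2000, seed=1)
        traj = run_to_equilibrium(params, init=InitSpec(q0=1.0), record_every=10)
        tail = [r.div_resist_raw for r in traj.records
                if r.generation > traj.generations - 10_000]
        assert np.var(tail) > 1e-6  # still oscillating
        assert traj.status in ("limit_cycle", "max_generations")

    def test_trajectory_contract(self, small_params):
        params = small_params.with_(max_generations=200, d=0.2)
        traj = run_to_equilibrium(params, record_every=1)
        gens = [r.generation for r in traj.records]
        assert gens == sorted(gens)
        assert traj.final_record.rtag_resist is not None
        assert 0 <= traj.equilibrium["div_resist_scaled"] <= 1
        assert 0 <= traj.equilibrium["div_neutral_scaled"] <= 1
        if traj.status == "fixed_point":
            assert traj.generations < params.max_generations


class TestSweep:
    def test_single_cell_matches_single_run(self, small_params):
        params = small_params.with_(max_generations=300, d=0.3)
        res = sweep(params, {"lag": [0], "d": [0.3]})
        traj = run_to_equilibrium(params.with_(lag=0, d=0.3))
        row = res.table.iloc[0]
        assert row["div_resist_scaled"] == pytest.approx(
            traj.equilibrium["div_resist_scaled"], abs=1e-12)
        assert row["status"] == traj.status

    def test_grid_shape_and_schema(self, small_params):
        params = small_params.with_(max_generations=100)
        res = sweep(params, {"lag": [0, 1, 2], "d": [0.1, 0.5, 0.9]})
        assert len(res.table) == 9
        assert list(res.table.columns) == SWEEP_COLUMNS

    def test_rerun_identical(self, small_params):
        params = small_params.with_(max_generations=100)
        a = sweep(params, {"lag": [0, 1], "d": [0.2]})
        b = sweep(params, {"lag": [0, 1], "d": [0.2]})
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_scaled_diversity_bounds_hold_across_cells(self, small_params):
        params = small_params.with_(max_generations=500)
        res = sweep(params, {"lag": [0, 3], "d": [0.2, 0.8]})
        for col in ("div_resist_scaled", "div_neutral_scaled",
                    "div_resist_eff", "div_neutral_eff"):
            assert res.table[col].between(0, 1).all()

    def test_cell_error_recorded_not_raised(self, small_params):
        # an extreme cost forces a negative payoff in helper-rich states
        params = small_params.with_(max_generations=50)
        res = sweep(params, {"c": [0.1, 3.0]}, init=InitSpec(p0=1.0, epsilon=0.0))
        statuses = res.table["status"].tolist()
        assert any(s.startswith("error") for s in statuses)
        assert any(not s.startswith("error") for s in statuses)


class TestPreset:
    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError, match="fig1b"):
            preset("nope")

    def test_fig1b_curve(self):
        t = preset("fig1b")
        assert t["recognition_prob"].iloc[-1] == pytest.approx(1.0)  # X = 1
        at0 = t["recognition_prob"].iloc[0]
        assert at0 == pytest.approx(0.25)  # theta: pedigree only
        assert (np.diff(t["recognition_prob"]) > 0).all()

    def test_fig4b_curve(self):
        t = preset("fig4b")
        assert t["rtag"].iloc[-1] == pytest.approx(0.25, abs=1e-12)  # X=1 -> theta
        assert (np.diff(t["rtag"]) < 0).all()
        assert t["rtag"].iloc[0] > 0.9

    def test_fig3_sweep_schema(self):
        res = preset("fig3", overrides={"max_generations": 50},
                     lag_grid=[0], d_grid=[0.5])
        assert len(res.table) == 1
        assert not np.isnan(res.table["susceptibility_baseline"].iloc[0])

    def test_fig6_table_shape(self):
        t = preset("fig6", overrides={"max_generations": 50})
        assert set(t["condition"]) == {"fixed", "evolving"}
        assert len(t) == 4
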
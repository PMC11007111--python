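"""Objective definition, seeded ensemble fitting, and ensemble summaries."""

import numpy as np
import pandas as pd
import pytest

import textode as tx
from textode.estimate import (
    ExperimentTable,
    FitConfig,
    ensemble_summary,
    fit,
    objective,
)
from textode.simulate import SimulationCondition

TWO_PARAM_TEXT = """A is synthesized
A is degraded
@obs A: A
@init A = 1
@sim_condition control: A=1
"""


@pytest.fixture
def two_param_setup():
    m = tx.ReactionNetworkModel.from_text(TWO_PARAM_TEXT)
    true = m.compiled.parameter_values()
    true[m.compiled.parameter_index("kf_r1")] = 0.3
    true[m.compiled.parameter_index("kf_r2")] = 0.6
    conds = [SimulationCondition("control", {"A": 1.0}, 10.0, 50)]
    data, _ = tx.fixtures.make_synthetic_timecourse(
        m.compiled, true, conds, n_times=50, noise_cv=0.0, seed=5
    )
    return m, true, conds, data


class TestExperimentTable:
    def test_required_columns(self):
        with pytest.raises(ValueError, match="missing columns"):
            ExperimentTable(pd.DataFrame({"observable": [], "time": []}))

    def test_negative_values_rejected(self):
        df = pd.DataFrame(
            {"observable": ["x"], "condition": ["c"], "time": [1.0], "value": [-1.0]}
        )
        with pytest.raises(ValueError, match="nonnegative"):
            ExperimentTable(df)

    def test_duplicate_keys_rejected(self):
        df = pd.DataFrame({
            "observable": ["x", "x"], "condition": ["c", "c"],
            "time": [1.0, 1.0], "value": [1.0, 2.0],
        })
        with pytest.raises(ValueError, match="duplicate"):
            ExperimentTable(df)

    def test_csv_round_trip(self, tmp_path, two_param_setup):
        _, _, _, data = two_param_setup
        path = tmp_path / "data.tsv"
        data.to_csv(path)
        back = ExperimentTable.from_csv(path)
        pd.testing.assert_frame_equal(back.frame, data.frame)


class TestObjective:
    def test_self_consistency_at_truth(self, two_param_setup):
        m, true, conds, data = two_param_setup
        free = m.compiled.free_parameter_indices()
        assert objective(true[free], m.compiled, m.constraints, data, conds) < 1e-10

    def test_all_zero_data_cost_is_sum_of_squared_sim(self, two_param_setup):
        m, true, conds, data = two_param_setup
        zero = ExperimentTable(data.frame.assign(value=0.0))
        free = m.compiled.free_parameter_indices()
        cost = objective(true[free], m.compiled, m.constraints, zero, conds)
        from textode.estimate import _simulate_normalized

        sim = _simulate_normalized(m.compiled, true, conds, zero)
        assert cost == pytest.approx(float(np.sum(sim**2)))

    def test_unknown_condition_in_table_is_an_error(self, two_param_setup):
        m, true, conds, data = two_param_setup
        bad = ExperimentTable(data.frame.assign(condition="nosuch"))
        free = m.compiled.free_parameter_indices()
        with pytest.raises(ValueError, match="unknown condition"):
            objective(true[free], m.compiled, m.constraints, bad, conds)

    def test_unknown_observable_is_an_error(self, two_param_setup):
        m, true, conds, data = two_param_setup
        bad = ExperimentTable(data.frame.assign(observable="nosuch"))
        free = m.compiled.free_parameter_indices()
        with pytest.raises(ValueError, match="unknown observable"):
            objective(true[free], m.compiled, m.constraints, bad, conds)


class TestFit:
    def test_noiseless_two_parameter_recovery(self, two_param_setup):
        m, true, conds, data = two_param_setup
        config = FitConfig(n_parameter_sets=3, seed=1, max_evaluations=5000)
        ens = fit(m.compiled, m.constraints, data, config, conds)
        assert ens.best.cost < 1e-4
        for name in ("kf_r1", "kf_r2"):
            i = m.compiled.parameter_index(name)
            assert ens.best.parameters[i] == pytest.approx(true[i], rel=0.05)

    def test_seeded_determinism(self, two_param_setup):
        m, _, conds, data = two_param_setup
        config = FitConfig(n_parameter_sets=2, seed=9, max_evaluations=400)
        e1 = fit(m.compiled, m.constraints, data, config, conds)
        e2 = fit(m.compiled, m.constraints, data, config, conds)
        for a, b in zip(e1.members, e2.members):
            assert a.cost == b.cost
            assert np.array_equal(a.parameters, b.parameters)

    def test_single_set_ensemble(self, two_param_setup):
        m, _, conds, data = two_param_setup
        ens = fit(m.compiled, m.constraints, data,
                  FitConfig(n_parameter_sets=1, seed=2, max_evaluations=300), conds)
        assert len(ens) == 1

    def test_costs_sorted_ascending(self, two_param_setup):
        m, _, conds, data = two_param_setup
        ens = fit(m.compiled, m.constraints, data,
                  FitConfig(n_parameter_sets=3, seed=4, max_evaluations=300), conds)
        costs = [mm.cost for mm in ens.members]
        assert costs == sorted(costs)

    def test_monotone_improvement_with_budget(self, two_param_setup):
        m, _, conds, data = two_param_setup
        best = []
        for evals in (300, 1500):
            ens = fit(m.compiled, m.constraints, data,
                      FitConfig(n_parameter_sets=2, seed=6, max_evaluations=evals), conds)
            best.append(ens.best.cost)
        assert best[1] <= best[0]

    def test_nothing_to_fit_is_an_error(self, two_param_setup):
        m, _, conds, data = two_param_setup
        for p in m.compiled.parameters:
            p.status = "fixed"
        with pytest.raises(ValueError, match="nothing to fit"):
            fit(m.compiled, m.constraints, data, FitConfig(n_parameter_sets=1), conds)

    def test_constraints_hold_for_every_member(self):
        text = tx.fixtures.make_diamond_model() + "@obs complex: ABC\n"
        m = tx.ReactionNetworkModel.from_text(text)
        conds = [SimulationCondition("control", {}, 10.0, 10)]
        data, _ = tx.fixtures.make_synthetic_timecourse(
            m.compiled, m.compiled.parameter_values(), conds, n_times=10,
            noise_cv=0.05, seed=2,
        )
        ens = fit(m.compiled, m.constraints, data,
                  FitConfig(n_parameter_sets=2, seed=3, max_evaluations=200), conds)
        for member in ens.members:
            assert m.constraints[0].cycle_product(member.parameters) == \
                pytest.approx(1.0, abs=1e-10)

    def test_ensemble_table_round_trip(self, tmp_path, two_param_setup):
        m, _, conds, data = two_param_setup
        ens = fit(m.compiled, m.constraints, data,
                  FitConfig(n_parameter_sets=2, seed=8, max_evaluations=300), conds)
        path = tmp_path / "ens.tsv"
        ens.save(path)
        df = pd.read_csv(path, sep="\t")
        assert list(df["seed"]) == [mm.seed for mm in ens.members]


class TestEnsembleSummary:
    def _tiny_ensemble(self, model, vectors):
        from textode.estimate import EnsembleMember, ParameterEnsemble

        members = [EnsembleMember(np.asarray(v, dtype=float), 0.0, i, 0)
                   for i, v in enumerate(vectors)]
        return ParameterEnsemble(members, model.parameter_names,
                                 model.free_parameter_indices())

    def test_single_member_mean_is_member_sd_zero(self, two_param_setup):
        m, true, conds, _ = two_param_setup
        ens = self._tiny_ensemble(m.compiled, [true])
        df = ensemble_summary(ens, m.compiled, m.constraints, conds, np.linspace(0, 10, 11))
        assert (df["sd"] == 0).all()

    def test_duplicated_members_have_zero_sd(self, two_param_setup):
        m, true, conds, _ = two_param_setup
        ens = self._tiny_ensemble(m.compiled, [true, true, true])
        df = ensemble_summary(ens, m.compiled, m.constraints, conds, np.linspace(0, 10, 11))
        assert np.allclose(df["sd"], 0.0)

    def test_mean_bounded_by_member_envelope(self, two_param_setup):
        m, true, conds, _ = two_param_setup
        rng = np.random.default_rng(0)
        vectors = [true * rng.uniform(0.5, 2.0, true.shape) for _ in range(5)]
        ens = self._tiny_ensemble(m.compiled, vectors)
        times = np.linspace(0, 10, 11)
        df = ensemble_summary(ens, m.compiled, m.constraints, conds, times)
        singles = [
            ensemble_summary(self._tiny_ensemble(m.compiled, [v]),
                             m.compiled, m.constraints, conds, times)["mean"].to_numpy()
            for v in vectors
        ]
        stack = np.vstack(singles)
        mean = df["mean"].to_numpy()
        assert np.all(mean <= stack.max(axis=0) + 1e-12)
        assert np.all(mean >= stack.min(axis=0) - 1e-12)

    def test_empty_ensemble_rejected(self, two_param_setup):
        m, _, conds, _ = two_param_setup
        from textode.estimate import ParameterEnsemble

        with pytest.raises(ValueError, match="empty"):
            ensemble_summary(ParameterEnsemble([], m.compiled.parameter_names, []),
                             m.compiled, m.constraints, conds, [0.0, 1.0])
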
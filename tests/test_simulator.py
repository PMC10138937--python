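"""ODE construction, integration accuracy, and observables.

Conservation-law checks use an independent oracle: vectors in the left null
space of the stoichiometric matrix must give constant linear combinations of
concentrations along any trajectory.
"""

import numpy as np
import pytest
import sympy as sp
from scipy.linalg import null_space

from kintext import (
    ModelError,
    Observable,
    SimulationError,
    build_model,
    build_odes,
    evaluate_observable,
    simulate,
    translate,
)
from kintext.builder import KineticModel, Species


def _s(name):
    return sp.Symbol(name)


class TestBuildOdes:
    def test_decay_rhs_is_minus_k_x(self, models):
        sys = build_odes(models["decay"], overrides={"k1": 0.25})
        assert np.allclose(sys.rhs(0.0, np.array([2.0])), [-0.5])

    def test_no_reaction_model_has_zero_derivatives(self):
        m = KineticModel(species=[Species("A", 1.0)])
        sys = build_odes(m)
        assert np.allclose(sys.rhs(0.0, np.array([1.0])), [0.0])

    def test_dimerization_stoichiometry(self):
        # stoichiometric-matrix oracle: d[M]/dt = -2 kf M^2, d[E]/dt = +kf M^2
        m = build_model(translate("Two monomers M bind to form an active enzyme E."))
        sys = build_odes(m, overrides={"kr1": 0.0, "kf1": 1.0})
        y = np.array([3.0, 0.0])  # M, E
        assert np.allclose(sys.rhs(0.0, y), [-18.0, 9.0])

    def test_modifiers_have_zero_stoichiometry(self, models):
        m = models["three_step"]
        sys = build_odes(m)
        i_e1 = sys.species.index("E1")
        j_mm = next(j for j, r in enumerate(m.reactions) if r.modifiers == ["E1"])
        assert sys.stoichiometry[i_e1, j_mm] == 0


class TestSimulate:
    @pytest.mark.parametrize("k", [0.1, 1.0, 10.0])
    def test_decay_matches_closed_form(self, models, k):
        tr = simulate(models["decay"], t_end=10, n_points=101, overrides={"k1": k})
        assert np.max(np.abs(tr.series("P") - np.exp(-k * tr.times))) < 1e-6

    def test_no_reaction_model_stays_constant(self):
        m = KineticModel(species=[Species("A", 2.5)])
        tr = simulate(m, t_end=5, n_points=11)
        assert np.allclose(tr.series("A"), 2.5)

    def test_invalid_grid_rejected(self, models):
        with pytest.raises(SimulationError):
            simulate(models["decay"], t_end=-1)
        with pytest.raises(SimulationError):
            simulate(models["decay"], t_end=1, n_points=1)

    def test_unknown_override_rejected(self, models):
        with pytest.raises(ModelError):
            simulate(models["decay"], t_end=1, overrides={"nope": 1.0})

    def test_hiv_ej_is_nondecreasing(self, problems, models):
        tr = simulate(models["hiv"], t_end=50, n_points=201,
                      overrides=problems["hiv"].demo_overrides)
        assert np.all(np.diff(tr.series("EJ")) >= -1e-9)
        assert tr.series("EJ")[-1] > tr.series("EJ")[0]

    def test_hiv_conservation_laws(self, problems, models):
        # oracle: left null space of the stoichiometric matrix
        m = models["hiv"]
        sys = build_odes(m)
        ns = null_space(sys.stoichiometry.T)
        assert ns.shape[1] == 3  # substrate pool, enzyme pool, inhibitor pool
        tr = simulate(m, t_end=50, n_points=201,
                      overrides=problems["hiv"].demo_overrides)
        for k in range(ns.shape[1]):
            series = ns[:, k] @ tr.values
            scale = max(abs(series[0]), 1.0)
            assert np.max(np.abs(series - series[0])) / scale < 1e-6
        # the two named pools from the null-space basis
        idx = {s: i for i, s in enumerate(sys.species)}
        pool1 = sum(tr.values[idx[s]] for s in ("S", "ES", "P", "EP"))
        pool2 = (sum(tr.values[idx[s]] for s in ("E", "ES", "EP", "EI", "EJ"))
                 + tr.values[idx["M"]] / 2)
        for pool in (pool1, pool2):
            assert np.max(np.abs(pool - pool[0])) / pool[0] < 1e-6

    def test_nonnegativity_on_all_fixture_simulations(self, problems, models):
        for name, m in models.items():
            tr = simulate(m, t_end=20, n_points=101,
                          overrides=problems[name].demo_overrides)
            assert tr.values.min() > -1e-8

    def test_heat_shock_yield_dips_and_recovers(self, problems, models):
        p = problems["heat_shock"]
        tr = simulate(models["heat_shock"], t_end=p.demo_t_end, n_points=401,
                      overrides=p.demo_overrides)
        yield_obs = next(o for o in p.observables if o.name == "Yield")
        y = evaluate_observable(tr, yield_obs)
        assert np.all((y >= 0) & (y <= 1 + 1e-12))
        assert y.min() < 0.8 * y[0]          # clear dip after the heat step
        assert y[-1] > 0.9 * y[0]            # recovery within 10% of the start


class TestObservables:
    def test_single_species_observable_equals_its_series(self, models):
        tr = simulate(models["decay"], t_end=1, n_points=11)
        obs = Observable("just_P", _s("P"))
        assert np.array_equal(evaluate_observable(tr, obs), tr.series("P"))

    def test_total_pools_on_hiv(self, problems, models):
        p = problems["hiv"]
        tr = simulate(models["hiv"], t_end=10, n_points=51,
                      overrides=p.demo_overrides)
        frame = tr.to_frame(p.observables)
        assert {"Stotal", "Ptotal"} <= set(frame.columns)
        total = frame["Stotal"] + frame["Ptotal"]
        assert np.max(np.abs(total - total.iloc[0])) / total.iloc[0] < 1e-6

    def test_unknown_species_rejected(self, models):
        tr = simulate(models["decay"], t_end=1, n_points=11)
        with pytest.raises(ModelError):
            evaluate_observable(tr, Observable("bad", _s("Q")))

    def test_csv_export_has_time_species_and_observable_columns(self, models, tmp_path):
        tr = simulate(models["decay"], t_end=1, n_points=3)
        out = tmp_path / "traj.csv"
        tr.to_csv(out, [Observable("double_P", 2 * _s("P"))])
        header = out.read_text().splitlines()[0]
        assert header == "time,P,double_P"
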
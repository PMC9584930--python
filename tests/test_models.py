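"""Learning models: single-step semantics, full-run trajectories, agents.

``oracle_run`` below is an independent, dictionary-based re-implementation of
the five models used to validate the packed/jitted engine.
"""

import numpy as np
import pytest

from traitlearn.design import build_design
from traitlearn.models import (
    ModelSpec,
    RunSet,
    compute_pe,
    default_spec,
    init_state,
    predict,
    predict_series,
    run_model,
    simulate_agent,
    standard_model_set,
    update,
)


# ---------------------------------------------------------------------------
# independent oracle: plain dict-and-loop stepper, no shared code paths

def oracle_run(spec, params, order, feedback, design, rp=None, sim=None):
    """Brute-force per-trial evaluation of one run."""
    factors = [design.factor_of[design.item_ids[i]] for i in range(design.n_items)]
    if spec.model_id == "M1":
        return [rp[i] * params["b1"] + params["b0"] for i in order]
    if spec.model_id in ("M2", "M3"):
        values = {f: params["start"] for f in design.factors}
    else:
        values = {i: params["start"] for i in range(design.n_items)}
    preds = []
    for i in order:
        if spec.model_id in ("M2", "M3"):
            stored = values[factors[i]]
        else:
            stored = values[i]
        if spec.model_id in ("M3", "M5"):
            g = params["gamma"]
            p = g * rp[i] + (1 - g) * stored
        else:
            p = stored
        preds.append(p)
        pe = feedback[i] - p
        if spec.dual_alpha:
            a = params["alpha_neg"] if pe < 0 else params["alpha_pos"]
        else:
            a = params["alpha"]
        if spec.model_id in ("M2", "M3"):
            values[factors[i]] += a * pe
        else:
            for j in range(design.n_items):
                values[j] += a * pe * sim[j, i]
    return preds


def random_setup(design, rng):
    rp = rng.uniform(design.scale_min, design.scale_max, design.n_items)
    a = rng.uniform(-1, 1, (design.n_items, design.n_items))
    sim = (a + a.T) / 2
    np.fill_diagonal(sim, 1.0)
    sim = np.clip(sim, -1, 1)
    order = rng.permutation(design.n_items)
    feedback = rng.integers(design.scale_min, design.scale_max + 1, design.n_items)
    return rp, sim, order, feedback.astype(float)


def make_params(spec, rng, design):
    p = {}
    for name in spec.param_names:
        if name in ("alpha", "alpha_pos", "alpha_neg", "gamma"):
            p[name] = float(rng.uniform(0, 1))
        elif name == "start":
            p[name] = float(rng.uniform(design.scale_min, design.scale_max))
        else:
            p[name] = float(rng.uniform(-1, 2))
    return p


class TestPredictionError:
    @pytest.mark.parametrize("f,p,pe", [(7, 5, 2), (3, 3, 0), (1, 8, -7)])
    def test_examples(self, f, p, pe):
        assert compute_pe(f, p) == pe


class TestSingleStep:
    def test_m1_is_linear_in_rp(self, tiny_design):
        spec = default_spec("M1")
        rp = np.array([6.0, 2.0, 5.0, 4.0])
        state = init_state(spec, tiny_design, {})
        assert predict(state, spec, {"b0": 0.0, "b1": 1.0}, 0, tiny_design, rp) == 6.0
        assert predict(state, spec, {"b0": 1.0, "b1": 0.5}, 1, tiny_design, rp) == 2.0

    def test_fresh_state_predicts_start(self, tiny_design):
        for mid in ("M2", "M4"):
            spec = default_spec(mid)
            state = init_state(spec, tiny_design, {"start": 4.5})
            for item in range(4):
                assert predict(state, spec, {"start": 4.5}, item, tiny_design) == 4.5

    def test_gamma_one_predicts_rp(self, tiny_design):
        rp = np.array([6.0, 2.0, 5.0, 4.0])
        for mid in ("M3", "M5"):
            spec = default_spec(mid)
            params = {"alpha": 0.7, "gamma": 1.0, "start": 2.0}
            state = init_state(spec, tiny_design, params)
            assert predict(state, spec, params, 1, tiny_design, rp) == 2.0

    def test_m2_update_moves_factor_value(self, tiny_design):
        spec = default_spec("M2")
        state = np.array([4.0, 4.0])
        new = update(state, spec, {"alpha": 0.5, "start": 4.0}, 0, 2.0, tiny_design)
        np.testing.assert_allclose(new, [5.0, 4.0])
        np.testing.assert_allclose(state, [4.0, 4.0])  # input untouched

    def test_m4_update_scales_with_similarity(self, tiny_design):
        spec = default_spec("M4")
        sim = np.eye(4)
        sim[0, 1] = sim[1, 0] = 0.5
        state = np.full(4, 4.0)
        new = update(state, spec, {"alpha": 0.4, "start": 4.0}, 0, 2.0,
                     tiny_design, sim=sim)
        np.testing.assert_allclose(new, [4.8, 4.4, 4.0, 4.0])

    def test_m1_never_learns(self, tiny_design):
        spec = default_spec("M1")
        state = init_state(spec, tiny_design, {})
        assert update(state, spec, {"b0": 0, "b1": 1}, 0, 3.0, tiny_design) is state

    def test_missing_inputs_raise(self, tiny_design):
        with pytest.raises(ValueError, match="similarity"):
            update(np.zeros(4), default_spec("M4"), {"alpha": 0.1, "start": 4},
                   0, 1.0, tiny_design)
        with pytest.raises(ValueError, match="reference"):
            predict(np.zeros(2), default_spec("M3"),
                    {"alpha": 0.1, "gamma": 0.5, "start": 4}, 0, tiny_design)


class TestModelSpec:
    @pytest.mark.parametrize(
        "mid,names",
        [
            ("M1", ("b0", "b1")),
            ("M2", ("alpha", "start")),
            ("M3", ("alpha", "gamma", "start")),
            ("M4", ("alpha", "start")),
            ("M5", ("alpha", "gamma", "start")),
        ],
    )
    def test_parameter_enumeration(self, mid, names):
        spec = default_spec(mid)
        assert spec.param_names == names
        assert spec.k_free == len(names)

    def test_dual_alpha_adds_one_parameter(self):
        spec = default_spec("M5", dual_alpha=True)
        assert spec.k_free == 4
        assert "alpha_pos" in spec.param_names and "alpha_neg" in spec.param_names

    def test_rp_source_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("M5", rp_source="none")
        with pytest.raises(ValueError):
            ModelSpec("M2", rp_source="population")
        assert ModelSpec("M5", rp_source="stereotype").label == "M5-STE"


class TestRunModel:
    def test_full_update_carries_feedback_forward(self, tiny_design):
        # alpha=1: after seeing feedback 7 for a factor-A item, the next
        # factor-A item is predicted at 7
        spec = default_spec("M2")
        seq = run_model(spec, {"alpha": 1.0, "start": 4.0}, [0, 1, 2, 3],
                        [7.0, 5.0, 3.0, 2.0], tiny_design)
        assert seq.predictions[0] == 4.0
        assert seq.predictions[1] == 7.0

    def test_m1_constant_across_repeats(self, tiny_design):
        spec = default_spec("M1")
        rp = np.array([6.0, 2.0, 5.0, 4.0])
        params = {"b0": 1.0, "b1": 0.5}
        a = run_model(spec, params, [0, 1, 2, 3], [7, 5, 3, 2], tiny_design, rp=rp)
        b = run_model(spec, params, [0, 1, 2, 3], [2, 2, 2, 2], tiny_design, rp=rp)
        np.testing.assert_allclose(a.predictions, b.predictions)

    def test_pe_uses_own_prediction(self, tiny_design):
        spec = default_spec("M2")
        seq = run_model(spec, {"alpha": 0.5, "start": 4.0}, [0, 1, 2, 3],
                        [8.0, 8.0, 1.0, 1.0], tiny_design)
        np.testing.assert_allclose(seq.pe, seq.feedback - seq.predictions)

    def test_duplicate_items_rejected(self, tiny_design):
        with pytest.raises(ValueError, match="duplicate"):
            run_model(default_spec("M2"), {"alpha": 0.5, "start": 4.0},
                      [0, 0, 2, 3], [7, 5, 3, 2], tiny_design)

    @pytest.mark.parametrize("mid", ["M1", "M2", "M3", "M4", "M5"])
    @pytest.mark.parametrize("dual", [False, True])
    def test_matches_brute_force_oracle(self, mid, dual, rng):
        if mid == "M1" and dual:
            pytest.skip("M1 has no learning rate")
        design = build_design(
            {"items": {f"i{k}": "ABC"[k % 3] for k in range(9)},
             "scale_min": 1, "scale_max": 8, "n_profiles": 1}
        )
        spec = default_spec(mid, dual_alpha=dual)
        for _ in range(5):
            rp, sim, order, feedback = random_setup(design, rng)
            params = make_params(spec, rng, design)
            got = run_model(spec, params, order, feedback, design, rp=rp, sim=sim)
            want = oracle_run(spec, params, order, feedback, design, rp=rp, sim=sim)
            np.testing.assert_allclose(got.predictions, want, atol=1e-10)

    @pytest.mark.parametrize("mid", ["M2", "M3", "M4", "M5"])
    def test_matches_stepped_predict_update(self, mid, rng):
        design = build_design(
            {"items": {f"i{k}": "AB"[k % 2] for k in range(6)},
             "scale_min": 1, "scale_max": 8, "n_profiles": 1}
        )
        spec = default_spec(mid)
        rp, sim, order, feedback = random_setup(design, rng)
        params = make_params(spec, rng, design)
        got = run_model(spec, params, order, feedback, design, rp=rp, sim=sim)
        state = init_state(spec, design, params)
        for t, item in enumerate(order):
            p = predict(state, spec, params, item, design, rp)
            assert got.predictions[t] == pytest.approx(p, abs=1e-12)
            state = update(state, spec, params, item, feedback[item] - p,
                           design, rp=rp, sim=sim)


class TestReductions:
    def _runs(self, design, rng, n_runs=2):
        orders = np.stack([rng.permutation(design.n_items) for _ in range(n_runs)])
        fb = rng.integers(design.scale_min, design.scale_max + 1,
                          (n_runs, design.n_items)).astype(float)
        return RunSet(orders, fb)

    def test_gamma_zero_reduces_rp_models(self, exp1_design, exp1_surrogate, rng):
        runs = self._runs(exp1_design, rng)
        rp, sim = exp1_surrogate.rp, exp1_surrogate.sim
        for rp_mid, plain_mid in (("M3", "M2"), ("M5", "M4")):
            p = {"alpha": 0.37, "gamma": 0.0, "start": 3.1}
            a = predict_series(default_spec(rp_mid), p, runs, exp1_design, rp=rp, sim=sim)
            b = predict_series(default_spec(plain_mid), {"alpha": 0.37, "start": 3.1},
                               runs, exp1_design, rp=rp, sim=sim)
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_identity_sim_reduces_m5_to_item_rw(self, exp1_design, exp1_surrogate, rng):
        runs = self._runs(exp1_design, rng)
        p = {"alpha": 0.42, "gamma": 0.0, "start": 4.0}
        got = predict_series(default_spec("M5"), p, runs, exp1_design,
                             rp=exp1_surrogate.rp, sim=np.eye(60))
        # per-item delta rule: each item keeps `start` until its own feedback
        # arrives, and every item appears once per run, so every prediction
        # is exactly `start`
        np.testing.assert_allclose(got, 4.0)

    def test_zero_alpha_predicts_start_forever(self, exp1_design, exp1_surrogate, rng):
        runs = self._runs(exp1_design, rng)
        for mid in ("M2", "M4"):
            got = predict_series(default_spec(mid), {"alpha": 0.0, "start": 2.5},
                                 runs, exp1_design, sim=exp1_surrogate.sim)
            np.testing.assert_allclose(got, 2.5)

    def test_gamma_one_pins_predictions_to_rp(self, exp1_design, exp1_surrogate, rng):
        runs = self._runs(exp1_design, rng)
        rp = exp1_surrogate.rp
        for mid in ("M3", "M5"):
            got = predict_series(default_spec(mid),
                                 {"alpha": 0.5, "gamma": 1.0, "start": 2.0},
                                 runs, exp1_design, rp=rp, sim=exp1_surrogate.sim)
            np.testing.assert_allclose(got, rp.rp[runs.orders], atol=1e-12)

    def test_dual_alpha_with_equal_rates_matches_single(self, exp1_design,
                                                        exp1_surrogate, rng):
        runs = self._runs(exp1_design, rng)
        a = predict_series(default_spec("M5", dual_alpha=True),
                           {"alpha_pos": 0.3, "alpha_neg": 0.3, "gamma": 0.4,
                            "start": 5.0},
                           runs, exp1_design, rp=exp1_surrogate.rp,
                           sim=exp1_surrogate.sim)
        b = predict_series(default_spec("M5"),
                           {"alpha": 0.3, "gamma": 0.4, "start": 5.0},
                           runs, exp1_design, rp=exp1_surrogate.rp,
                           sim=exp1_surrogate.sim)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_geometric_pe_decay_under_constant_feedback(self):
        # one item presented repeatedly (manual stepping): |PE| shrinks by
        # (1 - alpha) each presentation
        design = build_design({"items": {"i": "A"}, "scale_min": 1,
                               "scale_max": 8, "n_profiles": 1})
        spec = default_spec("M2")
        params = {"alpha": 0.35, "start": 2.0}
        state = init_state(spec, design, params)
        feedback = 7.0
        pes = []
        for _ in range(8):
            p = predict(state, spec, params, 0, design)
            pes.append(feedback - p)
            state = update(state, spec, params, 0, pes[-1], design)
        pes = np.array(pes)
        np.testing.assert_allclose(np.abs(pes[1:]), 0.65 * np.abs(pes[:-1]),
                                   rtol=1e-12)


class TestAgents:
    def test_noise_free_agent_equals_model(self, exp1_design, exp1_surrogate):
        spec = default_spec("M5")
        params = {"alpha": 0.3, "gamma": 0.3, "start": 4.5}
        runs = simulate_agent(spec, params, exp1_design, exp1_surrogate.profiles,
                              noise_sd=0.0, rp=exp1_surrogate.rp,
                              sim=exp1_surrogate.sim, seed=5)
        preds = predict_series(spec, params, runs, exp1_design,
                               rp=exp1_surrogate.rp, sim=exp1_surrogate.sim)
        np.testing.assert_allclose(runs.responses, preds)

    def test_discretized_responses_are_integers_in_bounds(self, exp1_design,
                                                          exp1_surrogate):
        runs = simulate_agent(default_spec("M2"), {"alpha": 0.5, "start": 4.5},
                              exp1_design, exp1_surrogate.profiles, noise_sd=1.0,
                              discretize=True, seed=6)
        r = runs.responses
        np.testing.assert_array_equal(r, np.round(r))
        assert r.min() >= 1 and r.max() <= 8

    def test_seeded_simulation_reproducible(self, exp1_design, exp1_surrogate):
        kw = dict(noise_sd=1.0, rp=exp1_surrogate.rp, sim=exp1_surrogate.sim, seed=7)
        spec = default_spec("M5")
        params = {"alpha": 0.3, "gamma": 0.3, "start": 4.5}
        a = simulate_agent(spec, params, exp1_design, exp1_surrogate.profiles, **kw)
        b = simulate_agent(spec, params, exp1_design, exp1_surrogate.profiles, **kw)
        np.testing.assert_array_equal(a.orders, b.orders)
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_negative_noise_rejected(self, exp1_design, exp1_surrogate):
        with pytest.raises(ValueError):
            simulate_agent(default_spec("M2"), {"alpha": 0.5, "start": 4.5},
                           exp1_design, exp1_surrogate.profiles, noise_sd=-1)

    def test_standard_model_set(self):
        labels = [s.label for s in standard_model_set()]
        assert labels == ["M1", "M2", "M3", "M4", "M5"]


class TestAlgebraicProperties:
    """Hypothesis-driven invariants of the delta rule."""

    from hypothesis import given, settings, strategies as st

    @given(
        alpha=st.floats(0.01, 0.99),
        start=st.floats(1.0, 8.0),
        feedback=st.floats(1.0, 8.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pe_shrinks_by_one_minus_alpha(self, alpha, start, feedback):
        design = build_design({"items": {"i": "A"}, "scale_min": 1,
                               "scale_max": 8, "n_profiles": 1})
        spec = default_spec("M2")
        params = {"alpha": alpha, "start": start}
        state = init_state(spec, design, params)
        p0 = predict(state, spec, params, 0, design)
        pe0 = feedback - p0
        state = update(state, spec, params, 0, pe0, design)
        pe1 = feedback - predict(state, spec, params, 0, design)
        assert pe1 == pytest.approx((1 - alpha) * pe0, abs=1e-9)

    @given(
        gamma=st.floats(0.0, 1.0),
        start=st.floats(1.0, 8.0),
        rp_val=st.floats(1.0, 8.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_blended_prediction_is_convex_combination(self, gamma, start, rp_val):
        design = build_design({"items": {"i": "A"}, "scale_min": 1,
                               "scale_max": 8, "n_profiles": 1})
        spec = default_spec("M3")
        params = {"alpha": 0.5, "gamma": gamma, "start": start}
        state = init_state(spec, design, params)
        p = predict(state, spec, params, 0, design, np.array([rp_val]))
        lo, hi = min(start, rp_val), max(start, rp_val)
        assert lo - 1e-9 <= p <= hi + 1e-9
        assert p == pytest.approx(gamma * rp_val + (1 - gamma) * start, abs=1e-12)
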
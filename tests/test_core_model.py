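import numpy as np
import pytest

from zganet.core_model import (
    ALL_GENOTYPES,
    ConfigError,
    GenotypeFlags,
    CoreModelSpec,
    build_core_model,
    simulate_core,
    sox19b_clearance_rate,
)


class TestStructure:
    def test_default_state_and_reaction_counts(self, default_model):
        assert default_model.n_states == 11
        assert default_model.n_reactions == 17

    def test_default_reaction_kinds(self, default_model):
        kinds = [r.kind for r in default_model.reaction_list]
        assert kinds.count("transcription") == 5
        assert kinds.count("mrna_degradation") == 6
        assert kinds.count("translation") == 3
        assert kinds.count("protein_degradation") == 3

    def test_reduced_topology_counts(self):
        # removing the zygotic pou5f3 and nanog pools drops 2 states and
        # their 2 transcription reactions; maternal pools keep their shared
        # degradation and translation reactions
        topo = {g: edges for g, edges in build_core_model("default").topology.items() if g not in ("pou5f3", "nanog")}
        m = build_core_model(topo)
        assert m.n_states == 9
        assert m.n_reactions == 15

    def test_sox19b_zygotic_transcription_rejected(self):
        with pytest.raises(ConfigError, match="maternal-only"):
            build_core_model({"sox19b": (("Nanog", +1),)})

    def test_unknown_regulator_rejected(self):
        with pytest.raises(ConfigError, match="unknown regulator"):
            build_core_model({"sox2": (("Oct4", +1),)})

    def test_every_topology_threshold_has_a_parameter(self, default_model):
        for gene, edges in default_model.topology.items():
            for reg, _ in edges:
                assert f"K_{gene}_{reg}" in default_model.params

    def test_yaml_round_trip(self, default_model):
        text = default_model.to_yaml()
        back = CoreModelSpec.from_yaml(text)
        assert back.state_names == default_model.state_names
        assert back.params == pytest.approx(default_model.params)
        assert back.topology == default_model.topology


class TestClearanceSwitch:
    def test_limits_and_midpoint(self):
        base, mx, tsw, s = 0.1, 2.0, 4.5, 10.0
        assert sox19b_clearance_rate(1e-9, base, mx, tsw, s) == pytest.approx(base, abs=1e-12)
        assert sox19b_clearance_rate(1e6, base, mx, tsw, s) == pytest.approx(mx, rel=1e-9)
        assert sox19b_clearance_rate(tsw, base, mx, tsw, s) == pytest.approx((base + mx) / 2)

    def test_monotone_non_decreasing(self):
        t = np.linspace(0.01, 10, 300)
        r = sox19b_clearance_rate(t, 0.1, 2.0, 4.5, 7.0)
        assert np.all(np.diff(r) >= -1e-12)

    @pytest.mark.parametrize("kwargs", [dict(base=-0.1, max_rate=1.0), dict(base=2.0, max_rate=1.0), dict(base=0.1, max_rate=1.0, steepness=0.0)])
    def test_invalid_rates_rejected(self, kwargs):
        full = dict(base=0.1, max_rate=1.0, t_sw=4.0, steepness=5.0)
        full.update(kwargs)
        with pytest.raises(ValueError):
            sox19b_clearance_rate(3.0, full["base"], full["max_rate"], full["t_sw"], full["steepness"])


class TestSimulation:
    def test_no_production_leaves_zygotic_states_zero(self, default_model, obs_times):
        m = default_model.with_params(v_pou5f3=0, v_nanog=0, v_sox19a=0, v_sox3=0, v_sox2=0)
        traj = simulate_core(m, GenotypeFlags(), obs_times)
        for s in ("pou5f3_z", "nanog_z", "sox19a", "sox3", "sox2"):
            assert np.allclose(traj.state(s), 0.0, atol=1e-9)
        # maternal pools strictly decay
        for s in ("pou5f3_m", "nanog_m", "sox19b_m"):
            assert np.all(np.diff(traj.state(s)) < 0)

    def test_maternal_decay_matches_closed_form(self, default_model):
        # switch disabled (base = max = d) and zygotic synthesis off:
        # sox19b mRNA(t) = x0 exp(-d (t - 2))
        x0, d = 100.0, 1.0
        m = default_model.with_params(
            x0_sox19b=x0, sw_base=d, sw_max=d, v_pou5f3=0, v_nanog=0, v_sox19a=0, v_sox3=0, v_sox2=0
        )
        t = np.linspace(2.0, 6.0, 9)
        traj = simulate_core(m, GenotypeFlags(), t, rtol=1e-10, atol=1e-12)
        expected = x0 * np.exp(-d * (t - 2.0))
        assert traj.observable("sox19b") == pytest.approx(expected, rel=1e-6)
        assert traj.observable("sox19b")[2] == pytest.approx(36.78794, rel=1e-4)  # t = 3
        # every maternal mRNA matches its analytic exponential decay
        for obs, dg, x0g in (("pou5f3", m.params["d_pou5f3"], m.params["x0_pou5f3"]), ("nanog", m.params["d_nanog"], m.params["x0_nanog"])):
            assert traj.observable(obs) == pytest.approx(x0g * np.exp(-dg * (t - 2.0)), rel=1e-6)

    def test_pou5f3_null_has_no_pou5f3_protein(self, default_model, obs_times):
        traj = simulate_core(default_model, GenotypeFlags(mz_spg=True), obs_times)
        assert np.allclose(traj.state("Pou5f3"), 0.0, atol=1e-9)
        assert np.allclose(traj.state("pou5f3_m"), 0.0, atol=1e-9)

    def test_observed_pou5f3_is_sum_of_pools(self, default_model, obs_times):
        traj = simulate_core(default_model, GenotypeFlags(), obs_times)
        assert np.array_equal(traj.observable("pou5f3"), traj.state("pou5f3_m") + traj.state("pou5f3_z"))
        assert np.array_equal(traj.observable("nanog"), traj.state("nanog_m") + traj.state("nanog_z"))

    def test_triple_knockout_equals_zeroed_production(self, default_model, obs_times):
        triple = simulate_core(default_model, GenotypeFlags(True, True, True), obs_times)
        zeroed = default_model.with_params(x0_pou5f3=0, x0_nanog=0, x0_sox19b=0, tl_pou5f3=0, tl_nanog=0)
        wt_like = simulate_core(zeroed, GenotypeFlags(), obs_times)
        assert triple.state_values == pytest.approx(wt_like.state_values, abs=1e-8)

    def test_states_non_negative_for_random_parameter_draws(self, obs_times):
        rng = np.random.default_rng(42)
        base = build_core_model("default")
        for trial in range(100):
            scale = {k: v * 10 ** rng.uniform(-0.7, 0.7) for k, v in base.params.items() if k != "h"}
            scale["sw_base"], scale["sw_max"] = sorted((scale["sw_base"], scale["sw_max"]))
            m = base.with_params(**scale)
            g = ALL_GENOTYPES[int(rng.integers(len(ALL_GENOTYPES)))]
            traj = simulate_core(m, g, obs_times, rtol=1e-7, atol=1e-9)
            assert traj.state_values.min() >= 0.0

    def test_time_grid_outside_window_rejected(self, default_model):
        with pytest.raises(ValueError, match=r"\[2, 6\]"):
            simulate_core(default_model, GenotypeFlags(), np.array([1.0, 3.0]))


class TestGenotypes:
    def test_all_eight_combinations_constructible(self):
        labels = {g.label() for g in ALL_GENOTYPES}
        assert len(labels) == 8
        assert "WT" in labels and "MZpsn" in labels

    def test_label_round_trip(self):
        for g in ALL_GENOTYPES:
            assert GenotypeFlags.from_label(g.label()) == g
        assert GenotypeFlags.from_label("MZtriple") == GenotypeFlags(True, True, True)
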
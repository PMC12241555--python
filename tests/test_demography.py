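import numpy as np
import pytest
from scipy import stats

from demosmc.demography import (
    GHOST_MODELS,
    MODEL_A_BEST_FIT,
    MODEL_IDS,
    ModelSpec,
    ParameterVector,
    PriorBox,
    SampleConfig,
    SimulationConstants,
    build_demography,
    default_priors,
    parameter_names,
    resolve_events,
    sample_prior,
)

# printed event times (kya) for the best-fit interval chain; rounding
# slack ±0.15 ky
PRINTED_EVENTS = {
    "T_DPM": 31.3,
    "T_AS_PA": 46.2,
    "T_EU_AS": 51.2,
    "T_NOM": 52.0,
    "T_B": 62.4,
    "T_AF": 105.6,
    "T_NI_NS": 252.6,
    "T_DI_DS": 307.4,
    "T_N_D": 321.6,
    "T_H_A": 591.5,
}


class TestSimulationConstants:
    def test_defaults(self):
        c = SimulationConstants()
        assert c.mutation_rate == 1.25e-8
        assert c.recombination_rate == 1e-8
        assert c.generation_time == 29.0

    @pytest.mark.parametrize("field", ["mutation_rate", "recombination_rate",
                                       "generation_time"])
    def test_positivity(self, field):
        with pytest.raises(ValueError):
            SimulationConstants(**{field: 0.0})


class TestParameterVector:
    def test_length_24_for_simple_models(self):
        assert len(parameter_names("A")) == 24
        assert len(parameter_names("O")) == 24

    def test_length_26_for_ghost_models(self):
        for mid in GHOST_MODELS:
            assert len(parameter_names(mid)) == 26

    def test_negative_size_rejected(self):
        vals = dict(MODEL_A_BEST_FIT, N_PA0=-1.0)
        with pytest.raises(ValueError, match="size"):
            ParameterVector("A", vals)

    def test_negative_interval_rejected(self):
        vals = dict(MODEL_A_BEST_FIT, T_B=-0.1)
        with pytest.raises(ValueError, match="interval"):
            ParameterVector("A", vals)

    def test_fraction_bounds(self):
        vals = dict(MODEL_A_BEST_FIT, NEA_m_OOA=1.5)
        with pytest.raises(ValueError, match="fraction"):
            ParameterVector("A", vals)

    def test_array_round_trip(self):
        pv = ParameterVector("A", MODEL_A_BEST_FIT)
        again = ParameterVector.from_array("A", pv.to_array())
        assert dict(again) == dict(pv)


class TestResolveEvents:
    def test_printed_event_times(self, model_a_spec, best_fit_params):
        ev = resolve_events(best_fit_params, model_a_spec)
        for name, printed in PRINTED_EVENTS.items():
            assert ev[name] == pytest.approx(printed, abs=0.15), name

    def test_first_event_equals_interval(self, model_a_spec, best_fit_params):
        ev = resolve_events(best_fit_params, model_a_spec)
        assert ev["T_DPM"] == best_fit_params["T_DPM"]

    def test_partial_chain_examples(self, model_a_spec):
        vals = dict(MODEL_A_BEST_FIT, T_DPM=31.3, T_AS_PA=14.9, T_EU_AS=5.0)
        ev = resolve_events(ParameterVector("A", vals), model_a_spec)
        assert ev["T_AS_PA"] == pytest.approx(46.2)
        assert ev["T_EU_AS"] == pytest.approx(51.2)

    def test_zero_intervals_give_zero_events(self, model_a_spec):
        vals = dict(MODEL_A_BEST_FIT)
        for t in [n for n in vals if n.startswith("T_")]:
            vals[t] = 0.0
        ev = resolve_events(ParameterVector("A", vals), model_a_spec)
        assert all(v == 0.0 for v in ev.events.values())

    def test_chain_monotone(self, model_a_spec, best_fit_params):
        ev = resolve_events(best_fit_params, model_a_spec)
        chain = ["T_DPM", "T_AS_PA", "T_EU_AS", "T_NOM", "T_B", "T_AF"]
        times = [ev[c] for c in chain]
        assert np.all(np.diff(times) > 0)


class TestPriors:
    def test_archaic_admixture_bounds(self, model_a_spec):
        box = default_priors(model_a_spec)
        assert box.bounds("NEA_m_OOA") == (0.01, 0.05)
        assert box.bounds("DEN_m_PAP") == (0.01, 0.05)

    def test_stated_text_bounds(self, model_a_spec):
        box = default_priors(model_a_spec)
        assert box.bounds("N_EU") == (10_000, 150_000)
        assert box.bounds("N_AS") == (10_000, 150_000)
        assert box.bounds("N_AF") == (10_000, 60_000)
        assert box.bounds("N_PA") == (10_000, 50_000)
        assert box.bounds("N_ND") == (500, 30_000)
        assert box.bounds("T_DPM") == (10, 100)
        assert box.bounds("T_AS_PA") == (0.5, 50)

    def test_ghost_admixture_bounds(self):
        box = default_priors(ModelSpec("AX"))
        assert box.bounds("ghost_m") == (0.01, 0.99)

    def test_best_fit_inside_default_priors(self):
        for mid in ("A", "O"):
            box = default_priors(ModelSpec(mid))
            pv = ParameterVector(mid, MODEL_A_BEST_FIT)
            assert box.contains(pv.to_array())

    def test_empty_box_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PriorBox(("a",), np.array([2.0]), np.array([1.0]))

    def test_scale_unscale_round_trip(self, model_a_spec):
        box = default_priors(model_a_spec)
        rng = np.random.default_rng(0)
        v = rng.uniform(box.lower, box.upper)
        assert np.allclose(box.unscale(box.scale(v)), v, atol=1e-12)


class TestSamplePrior:
    def test_zero_draws(self, model_a_spec):
        assert sample_prior(default_priors(model_a_spec), 0, seed=1) == []

    def test_reproducible(self, model_a_spec):
        box = default_priors(model_a_spec)
        a = sample_prior(box, 5, seed=3)
        b = sample_prior(box, 5, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_admixture_draws_inside_bounds(self, model_a_spec):
        box = default_priors(model_a_spec)
        draws = np.vstack(sample_prior(box, 1000, seed=4))
        i = box.names.index("NEA_m_OOA")
        assert draws[:, i].min() >= 0.01
        assert draws[:, i].max() <= 0.05

    def test_uniform_ks(self, model_a_spec):
        box = default_priors(model_a_spec)
        draws = np.vstack(sample_prior(box, 5000, seed=5))
        unit = (draws - box.lower) / (box.upper - box.lower)
        for j in range(unit.shape[1]):
            ks = stats.kstest(unit[:, j], "uniform").statistic
            assert ks < 0.05, box.names[j]


class TestBuildDemography:
    def test_best_fit_builds_and_validates(self, model_a_spec, best_fit_params):
        dem = build_demography(model_a_spec, best_fit_params)
        dem.validate()

    def test_split_times_match_events(self, model_a_spec, best_fit_params):
        dem = build_demography(model_a_spec, best_fit_params)
        const = SimulationConstants()
        split_times = sorted(
            e.time * const.generation_time / 1000.0
            for e in dem.events
            if type(e).__name__ == "PopulationSplit"
        )
        # modern splits at 46.2 and 51.2 kya, OOA merge at 62.4 kya
        assert split_times[0] == pytest.approx(46.2, abs=0.15)
        assert split_times[1] == pytest.approx(51.2, abs=0.15)
        assert split_times[2] == pytest.approx(62.4, abs=0.15)

    def test_pulse_proportions(self, model_a_spec, best_fit_params):
        dem = build_demography(model_a_spec, best_fit_params)
        props = sorted(
            e.proportion for e in dem.events
            if type(e).__name__ == "MassMigration"
        )
        assert props == pytest.approx([0.0323, 0.0404])

    def test_all_models_build(self):
        for mid in MODEL_IDS:
            spec = ModelSpec(mid)
            vals = dict(MODEL_A_BEST_FIT)
            if spec.has_ghost:
                vals.update(ghost_m=0.2, ghost_split_frac=0.5)
            build_demography(spec, ParameterVector(mid, vals)).validate()

    def test_model_o_topology(self):
        # in O the EUR-ASN split is the younger one; PNG is the outgroup
        spec = ModelSpec("O")
        dem = build_demography(spec, ParameterVector("O", MODEL_A_BEST_FIT))
        splits = {
            tuple(sorted(e.derived)): e.time
            for e in dem.events if type(e).__name__ == "PopulationSplit"
        }
        assert splits[("ASN", "EUR")] < splits[("PNG", "XPH")]

    def test_ghost_zero_pulse_matches_model_a(self):
        # AX with ghost_m = 0 adds only a zero-strength pulse
        vals = dict(MODEL_A_BEST_FIT, ghost_m=0.0, ghost_split_frac=0.5)
        dem = build_demography(ModelSpec("AX"), ParameterVector("AX", vals))
        ghost_pulses = [
            e for e in dem.events
            if type(e).__name__ == "MassMigration" and e.dest == "GHO"
        ]
        assert len(ghost_pulses) == 1
        assert ghost_pulses[0].proportion == 0.0

    def test_invalid_ordering_rejected(self, model_a_spec):
        # Denisovan pulse older than the inner split
        vals = dict(MODEL_A_BEST_FIT, T_DPM=50.0, T_AS_PA=0.0)
        with pytest.raises(ValueError):
            build_demography(model_a_spec, ParameterVector("A", vals))

    def test_archaic_ordering_rejected(self, model_a_spec):
        vals = dict(MODEL_A_BEST_FIT, T_NI_NS=400.0, T_DI_DS=50.0, T_N_D=1.0)
        with pytest.raises(ValueError):
            build_demography(model_a_spec, ParameterVector("A", vals))

    def test_migration_variant_adds_rates(self):
        spec = ModelSpec("A", migration_variant="low")
        names = spec.parameter_names()
        assert sum(n.startswith("m_") for n in names) == 6
        box = default_priors(spec)
        assert box.bounds("m_AFR_EUR") == (0.0, 5e-5)
        assert default_priors(
            ModelSpec("A", migration_variant="high")).bounds("m_AFR_EUR") == (0.0, 5e-4)


class TestSampleConfig:
    def test_canonical(self, canonical_samples):
        assert canonical_samples.counts == {
            "AFR": 5, "EUR": 5, "ASN": 5, "PNG": 5, "NEA": 1, "DEN": 1}

    def test_rccr_default(self):
        assert set(SampleConfig.rccr().counts.values()) == {40}

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            SampleConfig(counts={"AFR": -1})
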
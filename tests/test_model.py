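"""Structure, rate laws, driver interpolation and unit conversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cersim.model import (
    ModelDefinitionError,
    ModelSpec,
    ReactionSpec,
    SpeciesSpec,
    UnitConversion,
    evaluate_driver,
    model_from_dict,
    model_to_dict,
    ode_rhs,
    propensity,
    reaction_flux,
)


class TestReferenceModel:
    def test_counts(self, reference_model):
        assert len(reference_model.reactions) == 29
        assert len(reference_model.dynamic_species) == 10
        assert len(reference_model.driver_species) == 3

    def test_cers_mediates_both_acylations(self, reference_model):
        rids = reference_model.enzymes["CERS"]
        assert len(rids) == 2
        subs = {next(iter(reference_model.reaction(r).reactants)) for r in rids}
        assert subs == {"dhSph", "Sph"}  # de novo and salvage branches

    def test_validates(self, reference_model):
        reference_model.validate()
        # every enzyme-labelled reaction is covered by the map
        labelled = {r.id for r in reference_model.reactions if r.enzyme}
        mapped = {rid for rids in reference_model.enzymes.values() for rid in rids}
        assert labelled == mapped

    def test_rates_positive_and_free(self, reference_model):
        assert np.all(reference_model.rates > 0)
        assert len(reference_model.rates) == 29

    def test_yaml_round_trip_is_exact(self, reference_model, tmp_path):
        import yaml

        d1 = model_to_dict(reference_model)
        text1 = yaml.safe_dump(d1, sort_keys=False)
        m2 = model_from_dict(yaml.safe_load(text1))
        text2 = yaml.safe_dump(model_to_dict(m2), sort_keys=False)
        assert text1 == text2
        assert m2.dynamic_names == reference_model.dynamic_names
        assert np.array_equal(m2.rates, reference_model.rates)

    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_model_file_round_trip(self, reference_model, tmp_path, suffix):
        from cersim.io import read_model, write_model

        p1 = tmp_path / f"model{suffix}"
        p2 = tmp_path / f"model2{suffix}"
        write_model(reference_model, p1)
        back = read_model(p1)
        write_model(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert np.array_equal(back.rates, reference_model.rates)
        assert [s.name for s in back.species] == [
            s.name for s in reference_model.species
        ]


class TestSpeciesValidation:
    def test_roles_are_exclusive(self):
        with pytest.raises(ModelDefinitionError):
            SpeciesSpec("X", "dynamic", initial_value=1.0, driver_knots=((0, 1), (1, 2)))
        with pytest.raises(ModelDefinitionError):
            SpeciesSpec("X", "driver", driver_knots=((0, 1),))  # < 2 knots
        with pytest.raises(ModelDefinitionError):
            SpeciesSpec("X", "driver", driver_knots=((1, 1.0), (1, 2.0)))  # ties

    def test_negative_initial_rejected(self):
        with pytest.raises(ModelDefinitionError):
            SpeciesSpec("X", "dynamic", initial_value=-1.0)


class TestDriverInterpolation:
    def test_hand_cases(self):
        d = SpeciesSpec("CoA", "driver", driver_knots=((0.0, 2.0), (4.0, 6.0)))
        assert evaluate_driver(d, 0.0) == 2.0
        assert evaluate_driver(d, 2.0) == 4.0
        assert evaluate_driver(d, 10.0) == 6.0  # clamped past the last knot
        assert evaluate_driver(d, -3.0) == 2.0  # clamped before the first

    def test_non_driver_rejected(self):
        s = SpeciesSpec("A", "dynamic", initial_value=1.0)
        with pytest.raises(ValueError):
            evaluate_driver(s, 0.0)

    @given(
        knots=st.lists(
            st.tuples(
                st.floats(0, 24, allow_nan=False),
                st.floats(0.01, 100, allow_nan=False),
            ),
            min_size=2,
            max_size=8,
            unique_by=lambda kv: round(kv[0], 6),
        ),
        t=st.floats(-5, 30, allow_nan=False),
    )
    def test_matches_hand_interpolation_oracle(self, knots, t):
        knots = sorted(knots)
        if min(b - a for (a, _), (b, _) in zip(knots, knots[1:])) < 1e-6:
            return
        d = SpeciesSpec("D", "driver", driver_knots=tuple(knots))

        def oracle(tq):  # clamped piecewise-linear interpolation, from scratch
            if tq <= knots[0][0]:
                return knots[0][1]
            if tq >= knots[-1][0]:
                return knots[-1][1]
            for (t0, v0), (t1, v1) in zip(knots, knots[1:]):
                if t0 <= tq <= t1:
                    return v0 + (v1 - v0) * (tq - t0) / (t1 - t0)

        assert evaluate_driver(d, t) == pytest.approx(oracle(t), rel=1e-12, abs=1e-12)
        for tk, vk in knots:  # exact at knots
            assert evaluate_driver(d, tk) == pytest.approx(vk, rel=1e-12)


class TestRateLaws:
    drivers = {"PC": SpeciesSpec("PC", "driver", driver_knots=((0.0, 5.0), (24.0, 5.0)))}

    def test_flux_hand_case(self):
        r = ReactionSpec("R", reactants={"Cer": 1}, products={"SM": 1},
                         driver_modifiers=("PC",), rate_constant=0.2)
        assert reaction_flux(r, {"Cer": 3.0}, 0.0, self.drivers) == pytest.approx(3.0)

    def test_zero_reactant_gives_zero_flux(self):
        r = ReactionSpec("R", reactants={"Cer": 1}, rate_constant=0.7)
        assert reaction_flux(r, {"Cer": 0.0}, 1.0, {}) == 0.0

    def test_production_flux(self):
        coa = {"CoA": SpeciesSpec("CoA", "driver", driver_knots=((0.0, 2.0), (24.0, 2.0)))}
        r = ReactionSpec("R", products={"A": 1}, driver_modifiers=("CoA",), rate_constant=1.5)
        assert reaction_flux(r, {}, 0.0, coa) == pytest.approx(3.0)

    def test_negative_concentration_rejected(self):
        r = ReactionSpec("R", reactants={"A": 1}, rate_constant=1.0)
        with pytest.raises(ValueError):
            reaction_flux(r, {"A": -0.1}, 0.0, {})

    def test_rhs_zero_rates(self, reference_model):
        m = reference_model.with_rates(np.zeros(29))
        assert np.array_equal(ode_rhs(m, m.initial_values, 0.0), np.zeros(10))

    def test_rhs_bookkeeping(self):
        m = ModelSpec(
            species=[
                SpeciesSpec("A", "dynamic", initial_value=2.0),
                SpeciesSpec("B", "dynamic", initial_value=0.0),
            ],
            reactions=[ReactionSpec("R", reactants={"A": 1}, products={"B": 1},
                                    rate_constant=1.0)],
        ).validate()
        np.testing.assert_allclose(ode_rhs(m, np.array([2.0, 0.0]), 0.0), [-2.0, 2.0])

    def test_rhs_conserves_closed_subnetwork(self, reference_model):
        # zero out production (R1) and all pure-degradation reactions:
        # the remaining conversions conserve total backbone exactly
        rates = reference_model.rates
        for j, r in enumerate(reference_model.reactions):
            if not r.reactants or not r.products:
                rates[j] = 0.0
        m = reference_model.with_rates(rates)
        state = m.initial_values
        assert ode_rhs(m, state, 1.0).sum() == pytest.approx(0.0, abs=1e-12)

    def test_mass_action_positivity(self, reference_model):
        rng = np.random.default_rng(0)
        state = rng.uniform(0, 10, 10)
        assert np.all(ode_rhs(reference_model, state, 3.0) > -np.inf)
        flux_drv = reference_model.driver_map
        for r in reference_model.reactions:
            f = reaction_flux(r, dict(zip(reference_model.dynamic_names, state)),
                              3.0, flux_drv)
            assert f >= 0


class TestPropensity:
    def test_zero_counts_zero_propensity(self, reference_model):
        conv = UnitConversion()
        a = propensity(reference_model, np.zeros(10, dtype=int), 0.0, conv)
        # only the production reaction (R1) can fire from an empty state
        nonzero = {r.id for r, ai in zip(reference_model.reactions, a) if ai > 0}
        assert nonzero == {"R1"}

    def test_first_order_constant_unchanged(self):
        m = ModelSpec(
            species=[SpeciesSpec("A", "dynamic", initial_value=1.0)],
            reactions=[ReactionSpec("R", reactants={"A": 1}, rate_constant=0.5)],
        ).validate()
        conv = UnitConversion()
        # order-1 mass action is scale invariant: a = kf * n
        a = propensity(m, np.array([7]), 0.0, conv)
        assert a[0] == pytest.approx(0.5 * 7)

    def test_driver_modified_propensity_formula(self, reference_model):
        conv = UnitConversion()
        counts = np.arange(1, 11)
        a = propensity(reference_model, counts, 2.0, conv)
        m = reference_model
        j = [r.id for r in m.reactions].index("R2")  # dhSph + palmCoA -> dhCer
        r2 = m.reaction("R2")
        from cersim.model import evaluate_driver

        coa_count = evaluate_driver(m.driver_map["palmCoA"], 2.0) * conv.factor
        n_dhsph = counts[m.dynamic_names.index("dhSph")]
        expected = r2.rate_constant / conv.factor * n_dhsph * coa_count
        assert a[j] == pytest.approx(expected, rel=1e-12)

    def test_negative_counts_rejected(self, reference_model):
        with pytest.raises(ValueError):
            propensity(reference_model, -np.ones(10, dtype=int), 0.0, UnitConversion())


class TestUnitConversion:
    def test_zero_and_printed_value(self):
        conv = UnitConversion()
        assert conv.concentration_to_count(0.0) == 0
        assert conv.concentration_to_count(1.0) == 602

    @given(s=st.floats(0.5, 1e6, allow_nan=False))
    def test_factor_formula_any_scaling(self, s):
        conv = UnitConversion(scaling_factor=s)
        assert conv.concentration_to_count(1.0) == round(6.02214076e5 / s)

    @given(c=st.floats(0, 1e4, allow_nan=False))
    def test_round_trip_within_quantization(self, c):
        conv = UnitConversion()
        back = conv.count_to_concentration(conv.concentration_to_count(c))
        assert abs(back - c) <= 0.5 / conv.factor + 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            UnitConversion(scaling_factor=0.0)
        with pytest.raises(ValueError):
            UnitConversion().concentration_to_count(-1.0)
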
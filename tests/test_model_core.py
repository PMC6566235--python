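"""Forward model: GI prediction, GL, meal pooling, rounding."""

import dataclasses
import math

import pytest
from hypothesis import given, settings, strategies as st

from glyco import (
    Composition,
    GlycoError,
    MealComponent,
    NoGlycemicCarbohydrateError,
    NutrientSpec,
    UnknownNutrientError,
    combine_compositions,
    default_coefficients,
    fao_meal_gi,
    predict_gi,
    predict_gl,
    round_gi,
)

HS = settings(max_examples=60, deadline=None, database=None, derandomize=True)


class TestPredictGI:
    @pytest.mark.parametrize(
        "amounts, kwargs, gi_raw, gi_rounded",
        [
            # whole milk: lactose diluted by fat and protein
            ({"water": 88, "lactose": 4.9, "fat": 3.3, "protein": 3.1, "ashes": 0.7},
             {}, None, 26),
            # half glucose, half protein
            ({"glucose": 50, "protein": 50}, {}, 62.5, 63),
            # pure reference carbohydrate
            ({"glucose": 100}, {}, 100.0, 100),
            # syrup: weighted mean of sugar GIs, water inert
            ({"glucose": 3, "fructose": 2, "maltitol": 5, "water": 90}, {}, 51.5, 52),
        ],
    )
    def test_worked_examples(self, amounts, kwargs, gi_raw, gi_rounded):
        res = predict_gi(Composition(amounts), **kwargs)
        if gi_raw is not None:
            assert res.gi_raw == pytest.approx(gi_raw, abs=1e-12)
        assert res.gi_rounded == gi_rounded

    def test_fully_unavailable_starch_gives_zero_gi(self):
        comp = Composition({"starch": 60, "protein": 10}, starch_availability=0.0)
        assert predict_gi(comp).gi_raw == 0.0

    def test_quotient_diagnostics_consistent(self, milk):
        res = predict_gi(milk)
        assert res.gi_raw == pytest.approx(res.numerator / res.denominator)
        # milk has no starch so no availability needed to be resolved
        assert res.resolved_availability is None

    def test_starch_availability_resolution_order(self):
        comp = Composition({"starch": 50}, starch_availability=0.7)
        assert predict_gi(comp).resolved_availability == 0.7
        # preset by process when no override
        comp = Composition({"starch": 50})
        res = predict_gi(comp, process="Extruded")
        assert res.resolved_availability == 0.88
        # fallback to 1.0 with a warning
        res = predict_gi(comp)
        assert res.resolved_availability == 1.0
        assert any("availability" in w for w in res.warnings)

    def test_no_glycemic_carbohydrate_raises(self):
        with pytest.raises(NoGlycemicCarbohydrateError):
            predict_gi(Composition({"fat": 10, "protein": 5}))

    def test_unknown_nutrient_raises_unless_opted_in(self):
        comp = Composition({"glucose": 10, "polyphenols": 1})
        with pytest.raises(UnknownNutrientError):
            predict_gi(comp)
        res = predict_gi(comp, unknown_as_inert=True)
        assert res.gi_raw == 100.0
        assert any("polyphenols" in w for w in res.warnings)

    @given(
        glucose=st.floats(1, 80),
        fat=st.floats(0, 30),
        k=st.floats(0.01, 100),
    )
    @HS
    def test_scale_invariance(self, glucose, fat, k):
        comp = Composition({"glucose": glucose, "fat": fat})
        assert predict_gi(comp.scaled(k)).gi_raw == pytest.approx(
            predict_gi(comp).gi_raw, abs=1e-9
        )

    @given(
        sucrose=st.floats(1, 40),
        starch=st.floats(1, 70),
        water=st.floats(0, 500),
        availability=st.floats(0, 1),
    )
    @HS
    def test_water_neutrality(self, sucrose, starch, water, availability):
        base = {"sucrose": sucrose, "starch": starch}
        gi0 = predict_gi(Composition(base, starch_availability=availability)).gi_raw
        gi1 = predict_gi(
            Composition({**base, "water": water}, starch_availability=availability)
        ).gi_raw
        assert gi1 == gi0

    @given(fat=st.floats(0.1, 50), extra=st.floats(0.1, 50))
    @HS
    def test_lowering_nutrient_strictly_decreases_gi(self, fat, extra):
        lo = predict_gi(Composition({"glucose": 30, "fat": fat + extra})).gi_raw
        hi = predict_gi(Composition({"glucose": 30, "fat": fat})).gi_raw
        assert lo < hi

    @given(a=st.floats(0, 1), da=st.floats(0.001, 1))
    @HS
    def test_gi_strictly_increases_with_starch_availability(self, a, da):
        hi = min(a + da, 1.0)
        if hi <= a:
            return
        comp = lambda av: Composition(
            {"starch": 50, "protein": 8}, starch_availability=av
        )
        assert predict_gi(comp(a)).gi_raw < predict_gi(comp(hi)).gi_raw

    @given(
        amounts=st.dictionaries(
            st.sampled_from(["glucose", "fructose", "sucrose", "lactose", "maltose"]),
            st.floats(0.1, 50),
            min_size=1,
        )
    )
    @HS
    def test_sugar_mix_equals_plain_weighted_mean(self, amounts, coeffs):
        """With no lowering nutrients and all availabilities 1, the model
        degenerates to the carbohydrate-weighted mean of the sugar GIs."""
        expected = sum(x * coeffs[n].gi for n, x in amounts.items()) / sum(
            amounts.values()
        )
        assert predict_gi(Composition(amounts)).gi_raw == pytest.approx(expected)

    def test_gi_bounded_by_component_gis(self, coeffs):
        res = predict_gi(
            Composition({"starch": 50, "sucrose": 20}, starch_availability=0.8)
        )
        assert 0 <= res.gi_raw <= 110


class TestPredictGL:
    def test_benchmark_row_p01(self):
        # GI 83 on 21.9 g of glycemic carbohydrate in a 30 g serving
        comp = Composition(
            {"sucrose": 11.8, "starch": 61.2, "soluble fiber": 2.4,
             "insoluble fiber": 7.1, "fat": 2.2, "protein": 9.1}
        )
        assert predict_gl(83, comp, 30.0) == pytest.approx(18.177)

    def test_zero_gi_gives_zero_gl(self):
        assert predict_gl(0.0, Composition({"glucose": 10}), 50.0) == 0.0

    def test_milk_serving(self, milk):
        gl = predict_gl(27, milk, 125.0)
        assert gl == pytest.approx(1.65375)
        assert round(gl, 1) == 1.7

    def test_missing_serving_raises(self, milk):
        with pytest.raises(GlycoError):
            predict_gl(27, milk)

    @given(serving=st.floats(1, 500), k=st.floats(0.1, 10))
    @HS
    def test_gl_linear_in_serving(self, serving, k):
        comp = Composition({"sucrose": 20, "fat": 5})
        assert predict_gl(60, comp, k * serving) == pytest.approx(
            k * predict_gl(60, comp, serving)
        )

    def test_availability_does_not_weight_carb_mass(self):
        """The availability factor acts on GI only; GL uses the unweighted
        glycemic carbohydrate grams."""
        comp = Composition({"starch": 60}, starch_availability=0.5, serving_g=30)
        res = predict_gi(comp)
        assert res.glycemic_carb_per_serving_g == pytest.approx(18.0)
        assert res.gl_g == pytest.approx(res.gi_raw * 18.0 / 100)

    def test_sugar_alcohol_mass_excludable(self):
        comp = Composition({"glucose": 10, "maltitol": 10})
        full = predict_gl(50, comp, 100)
        reduced = predict_gl(50, comp, 100, count_sugar_alcohols=False)
        assert full == pytest.approx(10.0)
        assert reduced == pytest.approx(5.0)


class TestFaoMealGI:
    @pytest.mark.parametrize(
        "foods, expected",
        [
            ([(50, 88), (0, 0)], 88.0),  # butter adds carbs of zero: no effect
            ([(25, 100), (25, 50)], 75.0),
            ([(12.3, 41.0)], 41.0),
        ],
    )
    def test_weighted_average(self, foods, expected):
        assert fao_meal_gi(foods) == pytest.approx(expected)

    def test_no_carbohydrate_raises(self):
        with pytest.raises(GlycoError):
            fao_meal_gi([(0, 50), (0, 80)])


class TestCombineCompositions:
    def test_single_component_identity(self, milk):
        pooled = combine_compositions([MealComponent(milk, 100.0)])
        assert pooled.amounts == pytest.approx(milk.amounts)
        assert pooled.serving_g == 100.0

    def test_equal_mass_glucose_solutions(self):
        a = Composition({"glucose": 10, "water": 90})
        b = Composition({"glucose": 20, "water": 80})
        pooled = combine_compositions(
            [MealComponent(a, 50.0), MealComponent(b, 50.0)]
        )
        assert pooled.amounts["glucose"] == pytest.approx(15.0)

    def test_pooled_availability_is_starch_mass_weighted(self):
        a = Composition({"starch": 40}, starch_availability=0.6)
        b = Composition({"starch": 80}, starch_availability=0.9)
        pooled = combine_compositions(
            [MealComponent(a, 100.0), MealComponent(b, 100.0)]
        )
        # starch masses 40 g and 80 g -> weights 1/3 and 2/3
        assert pooled.starch_availability == pytest.approx(0.8)

    def test_milk_on_cereal_gl_below_additive(self, milk, benchmark):
        """Pooling lets milk fat/protein dilute the cereal carbohydrates, so
        meal GL sits below the sum of the separate GLs for every product."""
        from glyco import solve_starch_availability

        milk_mass = 125 * 1.03
        gl_milk = predict_gl(predict_gi(milk).gi_raw, milk, milk_mass)
        for rec in benchmark:
            a, _ = solve_starch_availability(
                rec.composition, rec.gi_predicted_printed
            )
            cereal = dataclasses.replace(
                rec.composition, starch_availability=min(max(a, 0.0), 1.0)
            )
            gl_cereal = predict_gl(predict_gi(cereal).gi_raw, cereal, 30.0)
            meal = combine_compositions(
                [MealComponent(cereal, 30.0), MealComponent(milk, milk_mass)]
            )
            gl_meal = predict_gi(meal).gl_g
            assert gl_meal < gl_cereal + gl_milk

    def test_empty_meal_raises(self):
        with pytest.raises(GlycoError):
            combine_compositions([])


class TestRoundGI:
    @pytest.mark.parametrize(
        "raw, mode, expected",
        [
            (62.5, "half-away", 63),
            (26.0, "half-away", 26),
            (51.5, "half-away", 52),
            (51.5, "truncate", 51),
            (0.4, "half-away", 0),
        ],
    )
    def test_modes(self, raw, mode, expected):
        assert round_gi(raw, mode) == expected

    def test_negative_raises(self):
        with pytest.raises(GlycoError):
            round_gi(-1.0)


class TestDomainTypes:
    def test_role_field_exclusivity(self):
        with pytest.raises(GlycoError):
            NutrientSpec("x", "glycemic")  # no GI
        with pytest.raises(GlycoError):
            NutrientSpec("x", "lowering", gi=50, b=0.1)
        with pytest.raises(GlycoError):
            NutrientSpec("x", "inert", b=0.5)

    def test_inert_equals_lowering_with_zero_b(self, coeffs):
        table = coeffs.with_b({"ashes": 0.0})
        comp = Composition({"glucose": 10, "ashes": 5, "water": 50})
        via_zero_b = predict_gi(comp, table).gi_raw
        assert via_zero_b == predict_gi(
            Composition({"glucose": 10, "water": 55})
        ).gi_raw

    def test_negative_amount_rejected(self):
        with pytest.raises(GlycoError):
            Composition({"glucose": -1})

    def test_name_normalization_merges_aliases(self):
        comp = Composition({"Fiber_Sol": 1.0, "fiber sol.": 2.0})
        assert comp.amounts == {"soluble fiber": 3.0}
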
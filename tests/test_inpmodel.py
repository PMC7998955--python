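"""Unit and property tests of the ice-nucleation statistics and population model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icedrop import inpmodel as m
from icedrop.exceptions import (
    CensoredPointError,
    EmptySampleError,
    InconsistentCountsError,
)

V75 = m.sphere_volume_ml(75.0)


class TestFrozenFraction:
    @pytest.mark.parametrize(
        "nf,n,expected",
        [(0, 100, 0.0), (100, 100, 1.0), (9000, 18000, 0.5), (25, 100, 0.25)],
    )
    def test_ratio(self, nf, n, expected):
        assert m.frozen_fraction(nf, n) == expected

    def test_empty_sample_errors(self):
        with pytest.raises(EmptySampleError):
            m.frozen_fraction(0, 0)

    def test_inconsistent_counts_error(self):
        with pytest.raises(InconsistentCountsError):
            m.frozen_fraction(101, 100)


class TestActiveSiteDensity:
    def test_zero_fraction_gives_zero(self):
        assert m.active_site_density(0.0, 1e-6, 1.0) == 0.0

    def test_unit_exponent(self):
        # f = 1 - 1/e makes -ln(1-f) = 1, so nm = 1/(V Cm)
        f = 1.0 - math.exp(-1.0)
        assert m.active_site_density(f, 1e-6, 1.0) == pytest.approx(1e6, rel=1e-12)

    def test_half_frozen_75um_droplet(self):
        # independent recomputation: V = (pi/6) d^3 for d = 75 um = 7.5e-3 cm,
        # nm = ln 2 / (V * 1 mg/mL)
        v = math.pi / 6.0 * (7.5e-3) ** 3
        assert v == pytest.approx(2.209e-7, rel=1e-3)
        expected = math.log(2.0) / v
        got = m.active_site_density(0.5, V75, 1.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(3.1379285e6, rel=1e-6)

    def test_fully_frozen_is_censored_not_infinite(self):
        with pytest.raises(CensoredPointError):
            m.active_site_density(1.0, V75, 1.0)

    @pytest.mark.parametrize("f", [-0.1, 1.5])
    def test_domain_errors(self, f):
        with pytest.raises(ValueError):
            m.active_site_density(f, V75, 1.0)

    def test_strictly_increasing_in_f(self):
        fs = np.linspace(0.0, 0.999, 50)
        nms = [m.active_site_density(f, V75, 1.0) for f in fs]
        assert np.all(np.diff(nms) > 0)


class TestExpectedFrozenFraction:
    def test_zero_density(self):
        assert m.expected_frozen_fraction(0.0, V75, 1.0) == 0.0

    def test_unit_exponent(self):
        f = m.expected_frozen_fraction(1.0 / (V75 * 1.0), V75, 1.0)
        assert f == pytest.approx(1.0 - math.exp(-1.0), rel=1e-12)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            m.expected_frozen_fraction(-1.0, V75, 1.0)

    @pytest.mark.parametrize("f", [0.01, 0.5, 0.99])
    def test_round_trip_examples(self, f):
        nm = m.active_site_density(f, V75, 1.0)
        assert m.expected_frozen_fraction(nm, V75, 1.0) == pytest.approx(f, abs=1e-12)

    @given(st.floats(min_value=1e-9, max_value=1.0 - 1e-9))
    def test_round_trip_property(self, f):
        nm = m.active_site_density(f, V75, 1.0)
        assert m.expected_frozen_fraction(nm, V75, 1.0) == pytest.approx(
            f, abs=1e-12, rel=1e-9
        )


def _random_population(rng: np.random.Generator) -> m.INPPopulation:
    classes = []
    for i in range(rng.integers(1, 4)):
        if rng.random() < 0.5:
            lo = rng.uniform(-12, -3)
            dist = m.ActivationDistribution(
                "uniform", lower=lo, upper=lo + rng.uniform(0.5, 4)
            )
        else:
            dist = m.ActivationDistribution(
                "truncnorm",
                mean=rng.uniform(-10, -4),
                sd=rng.uniform(0.2, 2.0),
                lower=-20.0,
                upper=rng.uniform(-4, 0),
            )
        classes.append(
            m.INPClassSpec(f"X{i}", float(rng.uniform(1e5, 1e8)), dist)
        )
    return m.INPPopulation(tuple(classes))


class TestPopulationModel:
    def test_warmer_than_all_supports_is_zero(self):
        pop = m.default_population()
        assert m.population_nm(pop, 5.0) == 0.0

    def test_colder_than_all_supports_is_total_density(self):
        pop = m.default_population()
        assert m.population_nm(pop, -100.0) == pytest.approx(
            pop.total_density, rel=1e-9
        )

    def test_uniform_class_midpoint(self):
        d = 3.7e6
        pop = m.INPPopulation(
            (
                m.INPClassSpec(
                    "B",
                    d,
                    m.ActivationDistribution("uniform", lower=-6.5, upper=-4.5),
                ),
            )
        )
        assert m.population_nm(pop, -5.5) == pytest.approx(0.5 * d, rel=1e-12)

    @given(st.integers(min_value=0, max_value=200))
    def test_nm_monotone_nonincreasing_in_temperature(self, seed):
        pop = _random_population(np.random.default_rng(seed))
        t = np.linspace(-25.0, 2.0, 120)
        nm = m.population_nm(pop, t)
        assert np.all(np.diff(nm) <= 1e-6 * pop.total_density)

    def test_class_window_validation(self):
        with pytest.raises(ValueError, match="window"):
            m.INPClassSpec(
                "A",
                1e6,
                m.ActivationDistribution("uniform", lower=-6.0, upper=-3.0),
            )

    def test_spec_round_trip(self, tmp_path):
        pop = m.default_population()
        for name in ("pop.yaml", "pop.json"):
            path = tmp_path / name
            pop.save(path)
            back = m.INPPopulation.load(path)
            t = np.linspace(-12, 0, 30)
            np.testing.assert_allclose(
                m.population_nm(back, t), m.population_nm(pop, t), rtol=1e-12
            )


class TestTreatments:
    def test_identity_transform(self):
        pop = m.default_population()
        treated = m.apply_treatment(pop, m.TreatmentTransform())
        t = np.linspace(-12, 0, 40)
        np.testing.assert_allclose(
            m.population_nm(treated, t), m.population_nm(pop, t), rtol=0
        )

    def test_shift_is_exact_translation(self):
        pop = m.default_population()
        treated = m.apply_treatment(pop, m.TreatmentTransform(shift=-1.3))
        t = np.linspace(-12, 0, 40)
        np.testing.assert_allclose(
            m.population_nm(treated, t),
            m.population_nm(pop, t + 1.3),
            rtol=1e-12,
            atol=1e-9,
        )

    def test_class_a_depletion_leaves_bc_contribution(self):
        pop = m.default_population()
        treated = m.apply_treatment(pop, m.TreatmentTransform(depletion={"A": 0.0}))
        bc_only = m.INPPopulation(tuple(c for c in pop.classes if c.name != "A"))
        t = np.linspace(-12, -2, 40)
        np.testing.assert_allclose(
            m.population_nm(treated, t), m.population_nm(bc_only, t), rtol=1e-12
        )

    def test_depletion_factor_bounds(self):
        with pytest.raises(ValueError):
            m.TreatmentTransform(depletion={"A": 1.5})

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            m.treatment_preset("microwave")


class TestSimulateCounts:
    def test_degenerate_probabilities(self):
        pop = m.default_population()
        assert m.simulate_counts(pop, 5.0, 100, V75, 1.0, 0) == 0  # p = 0
        assert m.simulate_counts(pop, -100.0, 100, V75, 1.0, 0) == 100  # p ~ 1

    def test_binomial_scale(self):
        # a single-class population tuned so expected f = 0.5 at the test T
        nm_half = m.active_site_density(0.5, V75, 1.0)
        pop = m.INPPopulation(
            (
                m.INPClassSpec(
                    "X",
                    nm_half,
                    m.ActivationDistribution("uniform", lower=-8.0, upper=-6.0),
                ),
            )
        )
        nf = m.simulate_counts(pop, -9.0, 18000, V75, 1.0, 42)
        se = math.sqrt(0.25 / 18000)
        assert abs(nf / 18000 - 0.5) < 3 * se

    def test_reproducible_given_seed(self):
        pop = m.default_population()
        a = m.simulate_counts(pop, -6.0, 2000, V75, 1.0, 7)
        b = m.simulate_counts(pop, -6.0, 2000, V75, 1.0, 7)
        assert a == b


class TestCountLevelParameterRecovery:
    def test_nm_recovered_within_binomial_interval(self):
        """Counts simulated from a known A/B/C population re-yield its nm(T)
        inside the Wilson-propagated 95 % band at every non-censored point."""
        pop = m.default_population()
        temps = np.linspace(-3.0, -9.0, 12)
        curve = m.simulate_curve(pop, temps, 2000, V75, 1.0, 123)
        n_checked = 0
        for p in curve.points:
            if p.f == 1:
                continue
            truth = m.population_nm(pop, p.temperature_c)
            nm_lo = m.active_site_density(p.f_lo, V75, 1.0)
            nm_hi = (
                math.inf
                if p.f_hi == 1
                else m.active_site_density(p.f_hi, V75, 1.0)
            )
            assert nm_lo <= truth <= nm_hi, (p.temperature_c, truth, nm_lo, nm_hi)
            n_checked += 1
        assert n_checked >= 8


class TestCurveContainers:
    def test_temperature_point_invariants(self):
        p = m.TemperaturePoint(-5.0, 200, 50)
        assert p.f == 0.25
        assert 0 <= p.f_lo <= p.f <= p.f_hi <= 1

    def test_curve_requires_descending_temperatures(self):
        pts = (m.TemperaturePoint(-5.0, 10, 1), m.TemperaturePoint(-4.0, 10, 2))
        with pytest.raises(ValueError):
            m.FreezingCurve(pts, V75, 1.0)

    def test_csv_round_trip(self, tmp_path):
        curve = m.simulate_curve(
            m.default_population(), [-4, -5, -6, -7, -8], 500, V75, 1.0, 3
        )
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = m.FreezingCurve.from_csv(path, V75, 1.0)
        assert [(p.temperature_c, p.n, p.nf) for p in back.points] == [
            (p.temperature_c, p.n, p.nf) for p in curve.points
        ]

    def test_censored_point_has_empty_nm(self):
        pts = (m.TemperaturePoint(-4.0, 10, 2), m.TemperaturePoint(-9.0, 10, 10))
        df = m.FreezingCurve(pts, V75, 1.0).to_frame()
        assert math.isnan(df.nm_per_mg.iloc[1])
        assert not math.isnan(df.nm_per_mg.iloc[0])
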
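"""E2SFCA accessibility, SPAR normalization, quantile classes, shortage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spar_access.e2sfca import (AccessRecord, DecayScheme, Facility,
                                FacilityRatio, PopulationPoint,
                                accessibility_analysis, classify_quantiles,
                                shortage_summary, spar, step1_provider_ratio,
                                step2_accessibility, zone_weight)

SCHEME = DecayScheme()


@pytest.mark.parametrize("t,w", [
    (0.0, 1.00), (5.0, 1.00), (10.0, 1.00),
    (10.5, 0.42), (15.0, 0.42), (20.0, 0.42),
    (20.5, 0.09), (25.0, 0.09), (30.0, 0.09),
    (30.5, 0.0), (35.0, 0.0),
])
def test_zone_weight_three_zone_decay(t, w):
    assert zone_weight(t, SCHEME) == w


def test_zone_weight_rejects_negative_time():
    with pytest.raises(ValueError):
        zone_weight(-1.0, SCHEME)


def test_decay_scheme_validation():
    with pytest.raises(ValueError):
        DecayScheme((10, 20), (1.0, 0.42, 0.09))
    with pytest.raises(ValueError):
        DecayScheme((20, 10, 30), (1.0, 0.42, 0.09))
    with pytest.raises(ValueError):
        DecayScheme((10, 20, 30), (0.42, 1.0, 0.09))


def worked_example():
    """Hand-checkable fixture: one 2-provider facility, three population
    points at 5 / 15 / 25 minutes with 500 / 600 / 400 people."""
    fac = Facility("f", (0, 0), providers=2)
    pops = {
        "p1": PopulationPoint("p1", (1, 0), 500),
        "p2": PopulationPoint("p2", (2, 0), 600),
        "p3": PopulationPoint("p3", (3, 0), 400),
    }
    times = {"p1": 5.0, "p2": 15.0, "p3": 25.0}
    return fac, pops, times


class TestStep1:
    def test_worked_example_ratio(self):
        fac, pops, times = worked_example()
        # independent arithmetic: 500*1.00 + 600*0.42 + 400*0.09 = 788
        denom = 500 * 1.00 + 600 * 0.42 + 400 * 0.09
        assert denom == pytest.approx(788.0)
        r = step1_provider_ratio(fac, times, pops, SCHEME)
        assert r.r_j == pytest.approx(2.0 / 788.0, rel=1e-12)
        assert not r.catchment_empty

    def test_single_population_point(self):
        fac = Facility("f", (0, 0), providers=1)
        pops = {"p": PopulationPoint("p", (0, 0), 1000)}
        r = step1_provider_ratio(fac, {"p": 5.0}, pops, SCHEME)
        assert r.r_j == pytest.approx(0.001)

    def test_empty_catchment_flagged(self):
        fac = Facility("f", (0, 0), providers=3)
        r = step1_provider_ratio(fac, {}, {}, SCHEME)
        assert r.r_j == 0.0
        assert r.catchment_empty


class TestStep2:
    def test_single_reachable_facility(self):
        fac, pops, times = worked_example()
        r = step1_provider_ratio(fac, times, pops, SCHEME)
        a = step2_accessibility(pops["p1"], {"f": r}, {"f": 5.0}, SCHEME)
        assert a == pytest.approx(2.0 / 788.0, rel=1e-12)

    def test_no_reachable_facility_is_zero(self):
        p = PopulationPoint("p", (0, 0), 100)
        assert step2_accessibility(p, {}, {}, SCHEME) == 0.0

    def test_duplicated_facility_doubles_access(self):
        fac, pops, times = worked_example()
        r = step1_provider_ratio(fac, times, pops, SCHEME)
        one = step2_accessibility(pops["p1"], {"f": r}, {"f": 5.0}, SCHEME)
        two = step2_accessibility(pops["p1"], {"f": r, "g": FacilityRatio("g", r.r_j)},
                                  {"f": 5.0, "g": 5.0}, SCHEME)
        assert two == pytest.approx(2 * one, rel=1e-12)


class TestSpar:
    def test_equal_access_normalizes_to_one(self):
        assert spar([0.3, 0.3, 0.3]) == pytest.approx([1.0, 1.0, 1.0])

    def test_worked_example_ratios(self):
        rj = 2.0 / 788.0
        a = [rj * 1.00, rj * 0.42, rj * 0.09]
        expected = [ai / (sum(a) / 3) for ai in a]  # hand normalization
        got = spar(a)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx([1.986755, 0.834437, 0.178808], abs=5e-7)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            spar([0.0, 0.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1e3), min_size=2, max_size=30),
           st.floats(1e-3, 1e3))
    def test_scale_invariance_and_unit_mean(self, a, c):
        a = [x for x in a]
        if not any(x > 0 for x in a):
            a[0] = 1.0
        s1 = spar(a)
        s2 = spar([c * x for x in a])
        assert np.allclose(s1, s2, rtol=1e-9, atol=1e-12)
        assert np.mean(s1) == pytest.approx(1.0, abs=1e-9)
        assert ((s1 == 0) == (np.asarray(a) == 0)).all()


class TestQuantiles:
    def test_all_zeros_all_no_access(self):
        assert classify_quantiles([0, 0, 0]) == ["no access"] * 3

    def test_ten_values_two_per_class(self):
        vals = [0.1 * (i + 1) for i in range(10)]
        labels = classify_quantiles(vals, n_classes=5)
        from collections import Counter
        assert Counter(labels) == {f"Q{k}": 2 for k in range(1, 6)}
        assert labels[0] == "Q1" and labels[-1] == "Q5"

    def test_zeros_isolated_from_classes(self):
        vals = [0.0, 0.5, 0.0, 1.0, 1.5, 2.0, 2.5]
        for n_classes in (3, 5):
            labels = classify_quantiles(vals, n_classes)
            assert labels.count("no access") == 2


class TestShortage:
    def test_direct_summation(self):
        pops = {
            "a": PopulationPoint("a", (0, 0), 500, area_km2=1.2),
            "b": PopulationPoint("b", (0, 0), 600, area_km2=0.8),
            "c": PopulationPoint("c", (0, 0), 700, area_km2=1.0),
            "d": PopulationPoint("d", (0, 0), 400, area_km2=1.0),
        }
        recs = [AccessRecord("a", 0.0, spar=0.0), AccessRecord("b", 0.0, spar=0.0),
                AccessRecord("c", 1.0, spar=1.5), AccessRecord("d", 1.0, spar=1.2)]
        s = shortage_summary(recs, pops)
        assert s["area_km2"] == pytest.approx(2.0)
        assert s["population"] == 1100
        assert s["percent_of_total"] == pytest.approx(50.0)

    def test_no_shortage(self):
        pops = {"a": PopulationPoint("a", (0, 0), 500)}
        recs = [AccessRecord("a", 1.0, spar=1.0)]
        s = shortage_summary(recs, pops)
        assert s == {"area_km2": 0, "population": 0, "percent_of_total": 0.0}

    def test_mismatched_ids_error(self):
        pops = {"a": PopulationPoint("a", (0, 0), 500)}
        with pytest.raises(ValueError):
            shortage_summary([AccessRecord("b", 0.0, spar=0.0)], pops)


class TestConservationAndMonotonicity:
    """Structural identities of the two-step computation."""

    def _run(self, clinics, city, net):
        recs, ratios = accessibility_analysis(net, clinics, city.das)
        return recs, ratios

    def test_supply_conservation_small_city(self, small_city):
        from spar_access.modes import SpeedMap
        from spar_access.pipeline import build_mode_networks
        net = build_mode_networks(small_city, SpeedMap(), ["drive"])["drive"]
        recs, ratios = self._run(small_city.clinics, small_city, net)
        pops = {p.id: p.population for p in small_city.das}
        lhs = sum(pops[r.location_id] * r.a_index for r in recs)
        rhs = sum(c.providers for c, fr in zip(small_city.clinics, ratios)
                  if not fr.catchment_empty)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_adding_facility_never_decreases_access(self, small_city):
        from spar_access.modes import SpeedMap
        from spar_access.pipeline import build_mode_networks
        net = build_mode_networks(small_city, SpeedMap(), ["drive"])["drive"]
        base, _ = self._run(small_city.clinics, small_city, net)
        extra = Facility("extra", small_city.das[0].location, providers=2)
        more, _ = self._run(list(small_city.clinics) + [extra], small_city, net)
        for b, m in zip(base, more):
            assert m.a_index >= b.a_index - 1e-15

    def test_increasing_supply_never_decreases_access(self, small_city):
        from spar_access.modes import SpeedMap
        from spar_access.pipeline import build_mode_networks
        net = build_mode_networks(small_city, SpeedMap(), ["drive"])["drive"]
        base, _ = self._run(small_city.clinics, small_city, net)
        boosted = [Facility(c.id, c.location,
                            c.providers + (3 if c.id == small_city.clinics[0].id else 0))
                   for c in small_city.clinics]
        more, _ = self._run(boosted, small_city, net)
        for b, m in zip(base, more):
            assert m.a_index >= b.a_index - 1e-15
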
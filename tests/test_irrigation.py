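"""Irrigation indices, category tables and diagram classes."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwqual.chemistry import UndefinedRatioError
from gwqual.irrigation import (CATEGORY_TABLES, assess, categorize,
                               kelley_index, magnesium_hazard, na_percent,
                               permeability_index, potential_salinity, rsc,
                               sar, ussl_class, wilcox_class)

# survey mean composition in meq/L
NA, K, CA, MG = 61.87 / 22.99, 3.57 / 39.10, 65.0 / 20.04, 34.89 / 12.15
CL, SO4, HCO3, CO3 = 81.43 / 35.45, 156.67 / 48.03, 183.33 / 61.02, 0.19 / 30.0


class TestIndexValues:
    def test_na_percent_symmetry_and_mean(self):
        assert na_percent(1, 1, 1, 1) == pytest.approx(50.0)
        assert na_percent(NA, K, CA, MG) == pytest.approx(31.27, abs=0.005)
        assert na_percent(0, 0, 1, 1) == 0.0

    def test_sar(self):
        assert sar(0, 1, 1) == 0.0
        assert sar(NA, CA, MG) == pytest.approx(1.539, abs=5e-4)
        assert sar(1, 1, 1) == pytest.approx(1.0)

    def test_rsc(self):
        assert rsc(1, 1, 1, 1) == 0.0
        assert rsc(HCO3, CO3, CA, MG) == pytest.approx(-3.10, abs=5e-3)

    def test_kelley_index(self):
        assert kelley_index(2, 1, 1) == pytest.approx(1.0)
        assert kelley_index(NA, CA, MG) == pytest.approx(0.440, abs=5e-4)
        assert kelley_index(0, 1, 1) == 0.0

    def test_permeability_index(self):
        assert permeability_index(NA, CA, MG, HCO3) == pytest.approx(50.24, abs=0.01)
        assert permeability_index(0, 1, 1, 0) == 0.0
        # Na-poor HCO3-rich water exceeds 100
        assert permeability_index(1, 0, 0, 1) == pytest.approx(200.0)

    def test_magnesium_hazard(self):
        assert magnesium_hazard(1, 1) == pytest.approx(50.0)
        assert magnesium_hazard(CA, MG) == pytest.approx(46.96, abs=0.01)
        assert magnesium_hazard(1, 0) == 0.0

    def test_potential_salinity_reproduces_published_mean(self):
        # PS is linear, so PS at the mean composition equals the printed
        # cohort-mean 3.93 meq/L
        assert potential_salinity(CL, SO4) == pytest.approx(3.93, abs=5e-3)
        assert potential_salinity(0, 0) == 0.0
        assert potential_salinity(1, 4) == pytest.approx(3.0)

    def test_zero_denominators_raise(self):
        for fn in (lambda: na_percent(0, 0, 0, 0), lambda: sar(1, 0, 0),
                   lambda: kelley_index(1, 0, 0), lambda: magnesium_hazard(0, 0),
                   lambda: permeability_index(0, 0, 0, 1)):
            with pytest.raises(UndefinedRatioError):
                fn()


class TestProperties:
    @given(st.floats(min_value=0.01, max_value=50),
           st.floats(min_value=0.01, max_value=50))
    @settings(max_examples=100, deadline=None)
    def test_mh_partition(self, ca, mg):
        assert magnesium_hazard(ca, mg) + magnesium_hazard(mg, ca) == pytest.approx(100.0)

    @given(st.floats(min_value=0, max_value=50), st.floats(min_value=0, max_value=5),
           st.floats(min_value=0.01, max_value=50), st.floats(min_value=0.01, max_value=50))
    @settings(max_examples=100, deadline=None)
    def test_na_percent_bounded(self, na, k, ca, mg):
        assert 0.0 <= na_percent(na, k, ca, mg) <= 100.0

    def test_linearity_of_ps_and_rsc_on_cohort(self, cohort):
        # index(mean of samples) == mean of index(samples)
        pss, rscs, cls_, so4s, hco3s, co3s, cas, mgs = [], [], [], [], [], [], [], []
        for s in cohort:
            cls_.append(s.ion_meq("Cl")); so4s.append(s.ion_meq("SO4"))
            hco3s.append(s.ion_meq("HCO3")); co3s.append(s.ion_meq("CO3"))
            cas.append(s.ion_meq("Ca")); mgs.append(s.ion_meq("Mg"))
            pss.append(potential_salinity(cls_[-1], so4s[-1]))
            rscs.append(rsc(hco3s[-1], co3s[-1], cas[-1], mgs[-1]))
        n = len(cohort)
        mean = lambda xs: sum(xs) / n
        assert potential_salinity(mean(cls_), mean(so4s)) == pytest.approx(mean(pss), rel=1e-12)
        assert rsc(mean(hco3s), mean(co3s), mean(cas), mean(mgs)) == pytest.approx(mean(rscs), rel=1e-12)


class TestCategorization:
    def test_boundary_ties_go_to_lower_band(self):
        assert categorize("na_percent", 20.0) == "excellent"
        assert categorize("na_percent", 20.0001) == "good"
        assert categorize("mh", 50.0) == "suitable"
        assert categorize("ps", 3.0) == "suitable"
        assert categorize("ki", 1.0) == "suitable"
        # RSC band is "good" strictly below 1.25
        assert categorize("rsc", 1.25) == "doubtful"
        assert categorize("rsc", -3.15) == "good"

    def test_pi_classes(self):
        assert categorize("pi", 80.0) == "excellent"
        assert categorize("pi", 49.11) == "suitable"
        assert categorize("pi", 13.45) == "unsuitable"

    def test_lookup_agrees_with_bisect_oracle(self):
        # independent oracle: scan the ordered bound list directly
        rng = random.Random(42)
        for _ in range(1000):
            idx = rng.choice(list(CATEGORY_TABLES))
            v = rng.uniform(-20.0 if idx == "rsc" else 0.0, 120.0)
            table = CATEGORY_TABLES[idx]
            label = table[-1][1]
            for bound, lab in table[:-1]:
                ok = v < bound if idx == "rsc" else v <= bound
                if ok:
                    label = lab
                    break
            assert categorize(idx, v) == label


class TestDiagrams:
    @pytest.mark.parametrize("ec, sarv, expected", [
        (830.0, 0.98, "C3S1"),
        (249.9, 9.99, "C1S1"),
        (3000.0, 30.0, "C4S4"),
        (250.0, 10.0, "C2S2"),  # closed-left bin edges
    ])
    def test_ussl_bins(self, ec, sarv, expected):
        assert ussl_class(ec, sarv) == expected

    def test_ussl_rejects_nonpositive_ec(self):
        with pytest.raises(ValueError):
            ussl_class(0.0, 1.0)

    @pytest.mark.parametrize("ec, napct, expected", [
        (400.0, 20.0, "excellent-to-good"),
        (830.0, 31.4, "good-to-permissible"),
        (5000.0, 95.0, "unsuitable"),
    ])
    def test_wilcox_zones(self, ec, napct, expected):
        assert wilcox_class(ec, napct) == expected

    def test_wilcox_domain_errors(self):
        with pytest.raises(ValueError):
            wilcox_class(-1.0, 50.0)
        with pytest.raises(ValueError):
            wilcox_class(500.0, 101.0)


class TestAssess:
    def test_worked_cohort_matches_oracle(self, cohort, expected):
        for s in cohort:
            a = assess(s)
            e = expected[s.site_id]
            for attr in ("na_percent", "sar", "rsc", "ki", "pi", "mh", "ps"):
                assert getattr(a, attr) == pytest.approx(e[attr], abs=1e-6), attr
            assert a.ussl_class == e["ussl_class"]
            for idx in ("na_percent", "sar", "rsc", "ki", "pi", "mh", "ps"):
                assert a.categories[idx] == e[f"{idx}_category"], idx

    def test_single_conversion_path(self, mean_sample):
        # calling the meq-level functions with the sample's own conversions
        # must equal the assess() wrapper exactly
        a = assess(mean_sample)
        assert a.sar == sar(mean_sample.ion_meq("Na"), mean_sample.ion_meq("Ca"),
                            mean_sample.ion_meq("Mg"))
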
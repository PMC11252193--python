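"""Data model, unit conversion and charge-balance QC."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwqual.chemistry import (ANIONS, CATIONS, DEFAULT_COLUMNS, ION_REGISTRY,
                              RegistryError, SchemaError, UndefinedRatioError,
                              WaterSample, charge_balance_error,
                              exceedance_table, load_samples, to_meq, to_mgl,
                              to_mmol)
from gwqual.dwqi import DEFAULT_REGISTRY

IONS_TEMPLATE = {"Na": 50.0, "K": 3.0, "Ca": 60.0, "Mg": 20.0, "Cl": 70.0,
                 "SO4": 100.0, "HCO3": 180.0, "CO3": 0.0, "NO3": 3.0, "F": 0.5}


def make_sample(site="X", **overrides):
    ions = dict(IONS_TEMPLATE)
    ions.update({k: v for k, v in overrides.items() if k in IONS_TEMPLATE})
    fields = {k: v for k, v in overrides.items() if k not in IONS_TEMPLATE}
    base = dict(ph=7.5, ec=800.0, tds=500.0, turbidity=5.0, hardness=250.0)
    base.update(fields)
    return WaterSample(site_id=site, ions=ions, **base)


class TestConversion:
    @pytest.mark.parametrize("mgl, ion, expected", [
        (0.0, "Na", 0.0),
        (81.43, "Cl", 81.43 / 35.45),   # 2.297 meq/L
        (65.0, "Ca", 65.0 / 20.04),     # 3.244 meq/L
    ])
    def test_to_meq_hand_values(self, mgl, ion, expected):
        assert to_meq(mgl, ion) == pytest.approx(expected, rel=1e-12)

    def test_unknown_ion_rejected(self):
        with pytest.raises(RegistryError):
            to_meq(1.0, "Li")

    def test_to_mmol_uses_molar_mass(self):
        assert to_mmol(96.06, "SO4") == pytest.approx(1.0)
        # equivalent weight differs from molar mass for divalent ions
        assert to_meq(96.06, "SO4") == pytest.approx(2.0, rel=1e-3)

    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False),
           st.sampled_from(sorted(ION_REGISTRY)))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, mgl, ion):
        assert to_mgl(to_meq(mgl, ion), ion) == pytest.approx(mgl, rel=1e-9, abs=1e-12)


class TestChargeBalance:
    def test_balanced_sample_is_zero(self):
        # equal meq on both sides by construction
        s = make_sample(Na=5 * 22.99, K=0.0, Ca=0.0, Mg=0.0,
                        Cl=5 * 35.45, SO4=0.0, HCO3=0.0, CO3=0.0, NO3=0.0, F=0.0)
        q = charge_balance_error(s)
        assert q.cbe_percent == pytest.approx(0.0, abs=1e-12)
        assert q.passed

    @pytest.mark.parametrize("cat_meq, an_meq, expected, passes", [
        (6.0, 4.0, 20.0, False),
        (5.2, 4.8, 4.0, True),
    ])
    def test_printed_formula_arithmetic(self, cat_meq, an_meq, expected, passes):
        s = make_sample(Na=cat_meq * 22.99, K=0, Ca=0, Mg=0,
                        Cl=an_meq * 35.45, SO4=0, HCO3=0, CO3=0, NO3=0, F=0)
        q = charge_balance_error(s)
        assert q.cbe_percent == pytest.approx(expected, rel=1e-9)
        assert q.passed is passes

    @given(st.floats(min_value=0.1, max_value=100),
           st.floats(min_value=0.1, max_value=100))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_under_side_swap(self, cat, an):
        a = make_sample(Na=cat * 22.99, K=0, Ca=0, Mg=0,
                        Cl=an * 35.45, SO4=0, HCO3=0, CO3=0, NO3=0, F=0)
        b = make_sample(Na=an * 22.99, K=0, Ca=0, Mg=0,
                        Cl=cat * 35.45, SO4=0, HCO3=0, CO3=0, NO3=0, F=0)
        assert charge_balance_error(a).cbe_percent == pytest.approx(
            -charge_balance_error(b).cbe_percent, rel=1e-9, abs=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, c):
        base = make_sample()
        scaled = make_sample(**{ion: IONS_TEMPLATE[ion] * c for ion in IONS_TEMPLATE})
        assert charge_balance_error(scaled).cbe_percent == pytest.approx(
            charge_balance_error(base).cbe_percent, rel=1e-9)

    def test_all_zero_ions_error_not_nan(self):
        s = make_sample(**{ion: 0.0 for ion in IONS_TEMPLATE})
        with pytest.raises(UndefinedRatioError):
            charge_balance_error(s)

    def test_missing_side_rejected(self):
        s = WaterSample("X", ph=7.0, ec=1, tds=1, turbidity=1, hardness=1,
                        ions={"Na": 10.0})
        with pytest.raises(RegistryError):
            charge_balance_error(s)


class TestLoadSamples:
    def _write(self, tmp_path, rows, drop=None):
        cols = list(DEFAULT_COLUMNS.values())
        if drop:
            cols = [c for c in cols if c != drop]
        lines = [",".join(cols)]
        for r in rows:
            lines.append(",".join(str(r.get(c, "1")) for c in cols))
        p = tmp_path / "in.csv"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_round_trip_preserves_rows_and_ids(self, tmp_path):
        rows = [{"site_id": f"W{i}", "pH": 7.0 + 0.1 * i} for i in range(3)]
        samples = load_samples(self._write(tmp_path, rows))
        assert [s.site_id for s in samples] == ["W0", "W1", "W2"]
        assert samples[2].ph == pytest.approx(7.2)

    def test_missing_column_names_the_column(self, tmp_path):
        p = self._write(tmp_path, [{"site_id": "W0"}], drop="Ca_mgL")
        with pytest.raises(SchemaError, match="Ca_mgL"):
            load_samples(p)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        rows = [{"site_id": "W0"}, {"site_id": "W1", "F_mgL": "n.d."}]
        with pytest.raises(SchemaError, match="row 1"):
            load_samples(self._write(tmp_path, rows))

    def test_missing_ion_is_absent_not_zero(self, tmp_path):
        rows = [{"site_id": "W0", "CO3_mgL": ""}]
        s = load_samples(self._write(tmp_path, rows))[0]
        assert "CO3" not in s.ions
        with pytest.raises(RegistryError):
            s.ion("CO3")


class TestInvariantsOfModel:
    def test_ph_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_sample(ph=15.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            make_sample(Cl=-1.0)


class TestExceedance:
    def test_counting_fractions(self):
        # 1 of 30 above the Cl limit of 250, 2 of 30 above F 1.5
        samples = [make_sample(site=f"W{i}") for i in range(30)]
        samples[0] = make_sample(site="W0", Cl=300.0)
        samples[1] = make_sample(site="W1", F=1.8)
        samples[2] = make_sample(site="W2", F=1.9)
        frac = exceedance_table(samples, DEFAULT_REGISTRY)
        assert frac["Cl"] == pytest.approx(1 / 30)
        assert frac["F"] == pytest.approx(2 / 30)
        assert frac["Na"] == 0.0

    def test_ph_checked_as_interval(self):
        low = [make_sample(site="A", ph=6.0), make_sample(site="B", ph=7.0)]
        frac = exceedance_table(low, DEFAULT_REGISTRY)
        assert frac["pH"] == pytest.approx(0.5)
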
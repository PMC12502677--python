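import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trichodiel.model_core import CarbonParams, EnergyParams
from trichodiel.phototrophy_energy import (allocate_energy,
                                           carbon_skeleton_production,
                                           energy_production, o2_evolution,
                                           partition_electrons, pet_rate)

EN = EnergyParams()
CB = CarbonParams()


class TestPetRate:
    def test_zero_light_or_fe(self):
        assert pet_rate(0.0, 100.0, 0.0, EN) == 0.0
        assert pet_rate(500.0, 0.0, 0.0, EN) == 0.0

    def test_respiratory_protection_inhibits(self):
        grid = [(i, fe) for i in (50.0, 200.0, 500.0)
                for fe in (10.0, 50.0, 200.0)]
        for i, fe in grid:
            assert pet_rate(i, fe, 5e-5, EN) < pet_rate(i, fe, 0.0, EN)

    def test_monotone_in_light_and_fe(self):
        rates_i = [pet_rate(i, 50.0, 0.0, EN) for i in np.linspace(0, 800, 30)]
        rates_fe = [pet_rate(200.0, f, 0.0, EN)
                    for f in np.linspace(0, 300, 30)]
        assert np.all(np.diff(rates_i) > 0)
        assert np.all(np.diff(rates_fe) > 0)


class TestPartition:
    def test_atp_only_demand_routes_all_aet(self):
        lpet, aet = partition_electrons(1e-4, 1.0, 0.0, EN)
        assert lpet == 0.0 and aet == 1e-4

    def test_lpet_intrinsic_ratio_needs_no_aet(self):
        rho = EN.y_ATP_LPET_per_e / EN.y_NADPH_per_e
        lpet, aet = partition_electrons(1e-4, rho, 1.0, EN)
        assert aet == pytest.approx(0.0, abs=1e-18)
        assert lpet == pytest.approx(1e-4, rel=1e-12)

    def test_intermediate_ratio_matches_algebraic_solution(self):
        """The split must solve the 2x2 yield system: ATP and NADPH
        production in the exact demanded proportion."""
        v_pet, atp_d, nadph_d = 2e-4, 3.0, 1.0
        lpet, aet = partition_electrons(v_pet, atp_d, nadph_d, EN)
        assert lpet + aet == pytest.approx(v_pet, rel=1e-14)
        atp, nadph = energy_production(lpet, aet, EN)
        assert atp / nadph == pytest.approx(atp_d / nadph_d, rel=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(v=st.floats(0, 1e-3), a=st.floats(0, 10), n=st.floats(0, 10))
    def test_electron_conservation(self, v, a, n):
        lpet, aet = partition_electrons(v, a, n, EN)
        assert lpet + aet == pytest.approx(v, rel=1e-14, abs=1e-20)
        assert lpet >= 0 and aet >= 0


class TestO2Evolution:
    def test_exclusively_lpet(self):
        assert o2_evolution(0.0, 1e-3, EN) == 0.0
        full = o2_evolution(1e-3, 0.0, EN)
        assert full == pytest.approx(EN.y_O2_per_e * 1e-3, rel=1e-15)

    def test_linearity_in_lpet(self):
        assert o2_evolution(2e-4, 5e-4, EN) == \
            pytest.approx(2 * o2_evolution(1e-4, 1e-4, EN), rel=1e-15)


def _oracle_waterfall(v_atp, v_nadph, demands, en):
    """Independent reference allocation: literal sequential bookkeeping."""
    ledger = {"ATP": v_atp, "NADPH": v_nadph}
    maint = min(demands.get("maintenance", 0.0), ledger["ATP"])
    ledger["ATP"] -= maint
    pr = min(demands.get("photorespiration", 0.0), ledger["ATP"] / 7.0,
             ledger["NADPH"] / 4.0)
    pr = max(pr, 0.0)
    ledger["ATP"] -= 7 * pr
    ledger["NADPH"] -= 4 * pr
    nf = min(demands.get("n2_fixation", 0.0), ledger["ATP"] / en.q_ATP_NF,
             ledger["NADPH"] / en.q_NADPH_NF)
    nf = max(nf, 0.0)
    ledger["ATP"] -= en.q_ATP_NF * nf
    ledger["NADPH"] -= en.q_NADPH_NF * nf
    cf = max(0.0, min(ledger["ATP"] / (en.q_ATP_CF + en.q_ATP_CCM),
                      ledger["NADPH"] / en.q_NADPH_CF))
    return maint, pr, nf, cf


class TestAllocateEnergy:
    def test_zero_supply_starves(self):
        r = allocate_energy(0.0, 0.0, {"maintenance": 1e-6}, EN)
        assert r["starved"]
        assert r["carbon_fixation"] == 0.0 and r["n2_fixation"] == 0.0

    def test_supply_equal_maintenance_leaves_nothing(self):
        r = allocate_energy(1e-6, 0.0, {"maintenance": 1e-6}, EN)
        assert not r["starved"]
        assert r["carbon_fixation"] == 0.0 and r["n2_fixation"] == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        v_atp=st.floats(0, 1e-3),
        v_nadph=st.floats(0, 1e-3),
        m=st.floats(0, 1e-5),
        pr=st.floats(0, 1e-4),
        nf=st.floats(0, 1e-4),
    )
    def test_matches_oracle_and_closes(self, v_atp, v_nadph, m, pr, nf):
        demands = {"maintenance": m, "photorespiration": pr,
                   "n2_fixation": nf}
        r = allocate_energy(v_atp, v_nadph, demands, EN)
        om, opr, onf, ocf = _oracle_waterfall(v_atp, v_nadph, demands, EN)
        assert r["maintenance"] == pytest.approx(om, rel=1e-12, abs=1e-22)
        assert r["photorespiration"] == pytest.approx(opr, rel=1e-12, abs=1e-22)
        assert r["n2_fixation"] == pytest.approx(onf, rel=1e-12, abs=1e-22)
        assert r["carbon_fixation"] == pytest.approx(ocf, rel=1e-12, abs=1e-22)
        # closure: production equals consumption + dissipation
        atp_used = (r["maintenance"] + 7 * r["photorespiration"]
                    + EN.q_ATP_NF * r["n2_fixation"]
                    + (EN.q_ATP_CF + EN.q_ATP_CCM) * r["carbon_fixation"]
                    + r["diss_ATP"])
        nadph_used = (4 * r["photorespiration"]
                      + EN.q_NADPH_NF * r["n2_fixation"]
                      + EN.q_NADPH_CF * r["carbon_fixation"]
                      + r["diss_NADPH"])
        assert atp_used == pytest.approx(v_atp, rel=1e-12, abs=1e-20)
        assert nadph_used == pytest.approx(v_nadph, rel=1e-12, abs=1e-20)
        # no demand over-satisfied
        assert r["photorespiration"] <= pr * (1 + 1e-12)
        assert r["n2_fixation"] <= nf * (1 + 1e-12)


class TestCarbonSkeletons:
    def test_no_carbohydrate_no_production(self):
        assert carbon_skeleton_production(0.0, 0.1, CB) == 0.0

    def test_product_inhibition(self):
        ch2o = 0.5
        rates = [carbon_skeleton_production(ch2o, cs, CB)
                 for cs in np.linspace(0, 2, 30)]
        assert np.all(np.diff(rates) < 0)

    def test_saturates_below_cap(self):
        for ch2o in np.geomspace(1e-3, 1e3, 30):
            assert carbon_skeleton_production(ch2o, 0.0, CB) < CB.v_CS_max
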
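from dataclasses import replace
from math import comb

import numpy as np
import pandas as pd
import pytest

from metaboqtl.kp import (
    HUMAN_CONSTANTS,
    KPParameters,
    KPState,
    analytic_steady_state,
    group_compare_wilcoxon,
    hk_equivalence_check,
    integrate_to_steady_state,
    kp_rhs,
)
from metaboqtl.simulate import simulate_kp_cohort


def _params(**kw):
    base = dict(k_tdo_ido=1.0, k_kat1=2.08, k_kynu1=0.46, k_kmo=22.0,
                k_kat2=1.0, k_kynu2=1.0, k_3hao=1.0, k_clear=1.0)
    base.update(kw)
    return KPParameters(**base)


class TestRHS:
    def test_only_kyn_produced_from_trp(self):
        d = kp_rhs(KPState(Trp=1.0), _params())
        assert d[1] > 0  # KYN
        assert np.all(d[2:] == 0) and d[0] == 0

    def test_zero_at_analytic_steady_state(self):
        ss = analytic_steady_state(_params(), trp=1.0)
        d = kp_rhs(ss.state, _params())
        assert np.max(np.abs(d)) < 1e-10

    def test_rate_scaling_is_time_rescaling(self):
        # doubling all constants doubles every derivative (linearity)
        p1 = _params()
        p2 = _params(k_tdo_ido=2, k_kat1=4.16, k_kynu1=0.92, k_kmo=44,
                     k_kat2=2, k_kynu2=2, k_3hao=2, k_clear=2.0)
        s = KPState(Trp=1.0, KYN=0.05, HK=0.3, KA=0.1, AA=0.02, XA=0.2, HAA=0.2, QUIN=0.15)
        np.testing.assert_allclose(kp_rhs(s, p2), 2 * kp_rhs(s, p1), rtol=1e-12)

    def test_negative_concentration_errors(self):
        with pytest.raises(ValueError, match="negative"):
            kp_rhs(KPState(Trp=1.0, KYN=-0.1), _params())


class TestAnalyticSteadyState:
    def test_human_constant_hand_values(self):
        # KYNss = k_TDO/IDO·Trp/(k_KAT1+k_KYNU1+k_KMO) = 1/24.54
        # HKss = k_KMO·KYNss/(k_KAT2+k_KYNU2) = 22/(24.54·2)
        ss = analytic_steady_state(_params(), trp=1.0).state
        assert ss.KYN == pytest.approx(1 / 24.54, rel=1e-12)
        assert ss.HK == pytest.approx(22 / (24.54 * 2), rel=1e-12)

    def test_kmo_zero_removes_hk_branch(self):
        ss = analytic_steady_state(_params(k_kmo=0.0), trp=1.0).state
        assert ss.HK == 0.0
        assert ss.KYN == pytest.approx(1 / (2.08 + 0.46), rel=1e-12)

    def test_first_order_homogeneity_in_trp(self):
        s1 = analytic_steady_state(_params(), trp=1.0).state.as_array()
        s2 = analytic_steady_state(_params(), trp=2.0).state.as_array()
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-12)

    def test_mass_balance_and_flux_partition(self):
        p = _params()
        ss = analytic_steady_state(p, trp=1.0).state
        # influx = outflux for every non-terminal species
        assert p.k_tdo_ido * ss.Trp == pytest.approx(
            (p.k_kat1 + p.k_kynu1 + p.k_kmo) * ss.KYN, rel=1e-12)
        assert p.k_kmo * ss.KYN == pytest.approx(
            (p.k_kat2 + p.k_kynu2) * ss.HK, rel=1e-12)
        # KA:AA:HK production fluxes proportional to k_KAT1:k_KYNU1:k_KMO
        fluxes = np.array([p.k_kat1, p.k_kynu1, p.k_kmo]) * ss.KYN
        np.testing.assert_allclose(
            fluxes / fluxes.sum(),
            np.array([p.k_kat1, p.k_kynu1, p.k_kmo]) / (p.k_kat1 + p.k_kynu1 + p.k_kmo),
            rtol=1e-12,
        )

    def test_monotone_in_kmo(self):
        """More KMO activity depletes KYN (and its KA/AA branches) but
        increases flux into HK."""
        kyn, ka, aa, flux = [], [], [], []
        for kmo in (5.0, 22.0, 80.0):
            p = _params(k_kmo=kmo)
            ss = analytic_steady_state(p, trp=1.0).state
            kyn.append(ss.KYN); ka.append(ss.KA); aa.append(ss.AA)
            flux.append(kmo * ss.KYN)
        assert kyn == sorted(kyn, reverse=True)
        assert ka == sorted(ka, reverse=True)
        assert aa == sorted(aa, reverse=True)
        assert flux == sorted(flux)

    def test_no_clearance_errors(self):
        with pytest.raises(ValueError, match="no steady state"):
            analytic_steady_state(_params(k_clear=0.0), trp=1.0)


class TestIntegration:
    def test_matches_analytic(self):
        ss_a = analytic_steady_state(_params(), trp=1.0).state.as_array()
        ss_n = integrate_to_steady_state(_params(), trp=1.0).state.as_array()
        np.testing.assert_allclose(ss_n[1:], ss_a[1:], rtol=1e-6)

    def test_random_parameter_sets(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            k = rng.uniform(0.2, 5.0, size=8)
            p = KPParameters(k_tdo_ido=k[0], k_kat1=k[1], k_kynu1=k[2], k_kmo=k[3],
                             k_kat2=k[4], k_kynu2=k[5], k_3hao=k[6], k_clear=float(k[7]))
            a = analytic_steady_state(p, trp=1.0).state.as_array()
            n = integrate_to_steady_state(p, trp=1.0).state.as_array()
            np.testing.assert_allclose(n, a, rtol=1e-6, atol=1e-12)

    def test_start_at_steady_state_returns_immediately(self):
        ss = analytic_steady_state(_params(), trp=1.0)
        out = integrate_to_steady_state(_params(), trp=1.0, state0=ss.state, tol=1e-8)
        assert out.residual < 1e-8

    def test_zero_trp_all_zero(self):
        out = integrate_to_steady_state(_params(), trp=0.0).state.as_array()
        np.testing.assert_allclose(out, 0.0, atol=1e-12)


class TestEquivalence:
    def test_human_constants_hk_insensitive_kyn_halved(self):
        pg = _params()
        pa = _params(k_kmo=44.0)
        rep = hk_equivalence_check(pg, pa)
        assert rep.hk_relative_change == pytest.approx(0.0546, abs=0.002)
        assert rep.kyn_relative_change == pytest.approx(0.4727, abs=0.002)
        assert rep.near_equal

    def test_large_kmo_limit_insensitive(self):
        pg = _params(k_kmo=1e6)
        pa = _params(k_kmo=2e6)
        rep = hk_equivalence_check(pg, pa)
        assert rep.hk_relative_change < 1e-4

    def test_small_kmo_limit_linear(self):
        pg = _params(k_kmo=1e-4)
        pa = _params(k_kmo=2e-4)
        rep = hk_equivalence_check(pg, pa)
        assert rep.hk_relative_change == pytest.approx(1.0, rel=1e-3)

    def test_sensitivity_formula(self):
        rep = hk_equivalence_check(_params(), _params(k_kmo=44.0))
        assert rep.sensitivity == pytest.approx((2.08 + 0.46) / (2.08 + 0.46 + 22.0))

    def test_other_parameter_difference_errors(self):
        with pytest.raises(ValueError, match="outside k_KMO"):
            hk_equivalence_check(_params(), _params(k_kat1=3.0))


class TestWilcoxon:
    def test_identical_groups_large_p(self):
        rng = np.random.default_rng(11)
        vals = rng.standard_normal(8)
        tab = pd.DataFrame({
            "KYN": np.concatenate([vals, vals]),
            "genotype": ["AA"] * 8 + ["GG"] * 8,
        })
        res = group_compare_wilcoxon(tab, "KYN", "genotype")
        assert res.pvalue > 0.9

    def test_complete_separation_exact_p(self):
        tab = pd.DataFrame({
            "KYN": np.concatenate([np.arange(8.0), np.arange(100.0, 108.0)]),
            "genotype": ["AA"] * 8 + ["GG"] * 8,
        })
        res = group_compare_wilcoxon(tab, "KYN", "genotype")
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(2 / comb(16, 8), rel=1e-12)

    def test_all_tied_flagged(self):
        tab = pd.DataFrame({"KYN": [1.0] * 10, "genotype": ["AA"] * 5 + ["GG"] * 5})
        res = group_compare_wilcoxon(tab, "KYN", "genotype")
        assert res.pvalue == 1.0
        assert res.flag == "all-tied"


class TestKPCohort:
    def _param_pair(self, ratio=2.0):
        aa = _params()
        gg = _params(k_kmo=22.0 * ratio)
        return {"AA": aa, "GG": gg}

    def test_zero_noise_exact_steady_states(self):
        tab = simulate_kp_cohort(3, self._param_pair(), (1.0, 2.0), noise_cv=0.0, seed=1)
        basal_aa = tab[(tab.genotype == "AA") & (tab.timepoint == "basal")]
        ss = analytic_steady_state(_params(), 1.0).state
        np.testing.assert_allclose(basal_aa["KYN"], ss.KYN, rtol=1e-12)
        np.testing.assert_allclose(basal_aa["HK"], ss.HK, rtol=1e-12)

    def test_equal_kmo_identical_group_distributions(self):
        tab = simulate_kp_cohort(4, self._param_pair(ratio=1.0), (1.0, 2.0),
                                 noise_cv=0.0, seed=2)
        a = tab[tab.genotype == "AA"].drop(columns=["animal", "genotype"]).reset_index(drop=True)
        g = tab[tab.genotype == "GG"].drop(columns=["animal", "genotype"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, g)

    def test_genotype_contrast_kyn_not_hk(self):
        """KMO-activity doubling shifts KYN but not HK in the cohort —
        the nutrigenetic design's expected signature."""
        kyn_sig = hk_sig = 0
        reps = 10
        for rep in range(reps):
            tab = simulate_kp_cohort(8, self._param_pair(), (1.0, 2.0),
                                     noise_cv=0.1, seed=100 + rep)
            basal = tab[tab.timepoint == "basal"]
            kyn_sig += group_compare_wilcoxon(basal, "KYN", "genotype").pvalue < 0.05
            hk_sig += group_compare_wilcoxon(basal, "HK", "genotype").pvalue < 0.05
        assert kyn_sig >= 9
        assert hk_sig <= 3

    def test_nonpositive_trp_errors(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_kp_cohort(2, self._param_pair(), (0.0, 2.0), seed=1)
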
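"""Unit tests for the disproportionality statistics.

Frozen expected values were computed from independent oracles: direct
arithmetic for ROR/PRR, scipy's Yates-corrected chi-squared, and numerical
integration of the posterior densities for the Bayesian bounds.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from dispro.stats import (MGPS, ContingencyTable, MgpsPrior, SignalResult,
                          _mixture_loglik, apply_criteria, bcpnn_ic,
                          build_tables, mgps_ebgm, mgps_fit_prior,
                          prr_with_chi2, ror_with_ci)

T = ContingencyTable(10, 90, 100, 9900)


class TestContingencyTable:
    def test_expected_count(self):
        assert T.expected == pytest.approx(100 * 110 / 10100)

    def test_rejects_negative_and_empty(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 5)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


class TestRor:
    def test_point_estimate(self):
        ror, lo, hi = ror_with_ci(T)
        assert ror == pytest.approx(11.0)
        # closed form recomputed independently: exp(ln11 +- 1.96*se)
        assert lo == pytest.approx(5.559584639943105, rel=1e-12)
        assert hi == pytest.approx(21.764215824806342, rel=1e-12)

    def test_independence_gives_one(self):
        t = ContingencyTable(10, 90, 20, 180)  # a*d == b*c
        assert ror_with_ci(t)[0] == pytest.approx(1.0)

    def test_zero_cell_undefined_without_correction(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(0, 10, 5, 100))
        assert math.isnan(ror) and math.isnan(lo)

    def test_continuity_correction_mode(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(0, 10, 5, 100), continuity=0.5)
        assert 0 < ror < 2 and lo < ror < hi


class TestPrr:
    def test_point_estimate(self):
        prr, chi2 = prr_with_chi2(T)
        assert prr == pytest.approx(10.0)

    def test_chi2_matches_scipy_yates(self):
        _, chi2 = prr_with_chi2(T, yates=True)
        oracle = chi2_contingency(np.array([[10, 90], [100, 9900]]),
                                  correction=True).statistic
        assert chi2 == pytest.approx(oracle, rel=1e-12)

    def test_chi2_uncorrected_matches_scipy(self):
        _, chi2 = prr_with_chi2(T, yates=False)
        oracle = chi2_contingency(np.array([[10, 90], [100, 9900]]),
                                  correction=False).statistic
        assert chi2 == pytest.approx(oracle, rel=1e-12)

    def test_proportional_table_gives_one(self):
        prr, _ = prr_with_chi2(ContingencyTable(10, 90, 100, 900))
        assert prr == pytest.approx(1.0)

    def test_zero_comparator_undefined(self):
        prr, _ = prr_with_chi2(ContingencyTable(5, 5, 0, 100))
        assert math.isnan(prr)


class TestBcpnn:
    def test_ic_point_value(self):
        ic, ic025 = bcpnn_ic(T)
        assert ic == pytest.approx(math.log2(10.5 / (T.expected + 0.5)), rel=1e-12)
        # 2.5th percentile of Gamma(10.5, rate E+0.5), frozen from
        # numerical integration of the posterior density
        assert ic025 == pytest.approx(1.69396, abs=1e-3)

    def test_independence_limit(self):
        # a == E and large: shrinkage is negligible, IC ~ 0
        t = ContingencyTable(1000, 9000, 10000, 90000)
        ic, _ = bcpnn_ic(t)
        assert abs(ic) < 0.01

    def test_defined_at_zero_count(self):
        ic, ic025 = bcpnn_ic(ContingencyTable(0, 10, 50, 1000))
        assert math.isfinite(ic) and math.isfinite(ic025) and ic025 < ic

    def test_bate_variant_close_to_gamma_for_large_counts(self):
        t = ContingencyTable(500, 4500, 5000, 500000)
        ic_g, _ = bcpnn_ic(t, variant="gamma")
        ic_b, lo_b = bcpnn_ic(t, variant="bate1998")
        assert ic_b == pytest.approx(ic_g, abs=0.05)
        assert lo_b < ic_b

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            bcpnn_ic(T, variant="nope")


class TestMgps:
    PRIOR = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1 / 3)

    def test_ebgm_matches_quadrature(self):
        # both values frozen from trapezoid/quad integration of the
        # posterior gamma-mixture density at (a=10, E=1.0891)
        ebgm, ebgm05 = mgps_ebgm(T, self.PRIOR)
        assert ebgm == pytest.approx(8.157667726, rel=1e-6)
        assert ebgm05 == pytest.approx(4.681625, abs=1e-3)

    def test_quantile_below_geometric_mean(self):
        for a, e in [(0, 1.0), (3, 0.5), (50, 60.0)]:
            t = ContingencyTable(a, 100, int(10 * e) + 1, 1000)
            ebgm, ebgm05 = mgps_ebgm(t, self.PRIOR)
            assert ebgm05 < ebgm

    def test_weak_prior_limit_recovers_observed_over_expected(self):
        # with a flat prior and many counts, EBGM -> a/E: the regime in
        # which published EBGM columns coincide with PRR
        weak = MgpsPrior(0.01, 0.01, 0.02, 0.01, 0.5)
        t = ContingencyTable(659, 3747, 66000, 930000)
        ebgm, _ = mgps_ebgm(t, weak)
        assert ebgm == pytest.approx(t.a / t.expected, rel=0.01)

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            MgpsPrior(0, 1, 1, 1, 0.5)
        with pytest.raises(ValueError):
            MgpsPrior(1, 1, 1, 1, 1.5)

    def test_fit_recovers_generating_likelihood(self):
        rng = np.random.default_rng(42)
        true = self.PRIOR
        m = 100_000
        e = rng.lognormal(0, 1, size=m) * 2
        comp = rng.random(m) < true.p
        lam = np.where(comp, rng.gamma(true.alpha1, 1 / true.beta1, m),
                       rng.gamma(true.alpha2, 1 / true.beta2, m))
        n = rng.poisson(lam * e)
        model = MGPS().fit(np.column_stack([n, e]))
        ll_true = _mixture_loglik(true, n.astype(float), e)
        assert model.loglik_ >= ll_true - abs(ll_true) * 1e-3

    def test_single_component_regime(self):
        rng = np.random.default_rng(7)
        m = 20_000
        e = rng.lognormal(0, 1, size=m) * 2
        lam = rng.gamma(2.0, 1 / 4.0, m)
        n = rng.poisson(lam * e)
        model = MGPS().fit(np.column_stack([n, e]))
        p = model.prior_.p
        assert max(p, 1 - p) >= 0.95

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            MGPS().fit(np.empty((0, 2)))
        with pytest.raises(ValueError):
            MGPS().fit(np.array([[0.0, 1.0], [0.0, 2.0]]))

    def test_sklearn_param_interface(self):
        model = MGPS(alpha1=0.5)
        assert model.get_params()["alpha1"] == 0.5
        model.set_params(p=0.25)
        assert model.p == 0.25


class TestBuildTables:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["primaryid", "pt", "soc"])

    def test_bookkeeping(self):
        cohort = self._pairs([(f"t{i}", "Diarrhoea", "GI") for i in range(10)]
                             + [(f"t{i+10}", "Other", "GI") for i in range(90)])
        bg = self._pairs([(f"b{i}", "Diarrhoea", "GI") for i in range(100)]
                         + [(f"b{i+100}", "Other", "GI") for i in range(9900)])
        tab = build_tables(cohort, bg, level="pt")
        row = tab.loc["Diarrhoea"]
        assert (row.a, row.b, row.c, row.d) == (10, 90, 100, 9900)

    def test_repeated_term_in_one_report_counts_once(self):
        cohort = self._pairs([("t1", "Diarrhoea", "GI"), ("t1", "Diarrhoea", "GI"),
                              ("t2", "Nausea", "GI")])
        bg = self._pairs([("b1", "Diarrhoea", "GI"), ("b2", "Other", "GI")])
        tab = build_tables(cohort, bg, level="pt")
        assert tab.loc["Diarrhoea", "a"] == 1

    def test_empty_background_rejected(self):
        cohort = self._pairs([("t1", "Diarrhoea", "GI")])
        with pytest.raises(ValueError, match="background"):
            build_tables(cohort, cohort.iloc[:0], level="pt")


class TestCriteria:
    @staticmethod
    def _result(n, ror_lo, prr, chi2, ic025, ebgm05):
        return SignalResult(stratum="x", n=n, ror=2.0, ror_lo=ror_lo,
                            ror_hi=9.0, prr=prr, chi2=chi2, ic=1.0,
                            ic025=ic025, ebgm=2.0, ebgm05=ebgm05)

    def test_published_soc_row_triggers_all_four(self):
        res = self._result(659, 2.41, 2.36, 554.70, 1.14, 2.17)
        flags = apply_criteria(res)
        assert all(flags.values())

    def test_minimum_count_gate(self):
        res = self._result(2, 5.0, 50.0, 100.0, 2.0, 5.0)
        flags = apply_criteria(res)
        assert not flags["ror"] and not flags["prr"] and not flags["all"]
        assert flags["bcpnn"] and flags["mgps"]

    def test_ic025_strict_inequality(self):
        res = self._result(100, 2.0, 3.0, 50.0, 0.0, 3.0)
        assert not apply_criteria(res)["bcpnn"]

    def test_undefined_statistics_fail_closed(self):
        res = self._result(100, float("nan"), float("nan"), float("nan"),
                           1.0, 3.0)
        flags = apply_criteria(res)
        assert not flags["ror"] and not flags["prr"] and not flags["all"]
        assert "ror" in res.reasons
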
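"""Wald ratio, IVW, heterogeneity, Egger intercept, Steiger, Bonferroni."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drugtarget_mr.instruments import LDMatrix, SelectionConfig
from drugtarget_mr.mr import (
    MendelianRandomization,
    bonferroni_threshold,
    cochran_q,
    egger_intercept,
    ivw,
    reverse_mr,
    steiger_filter,
    wald_ratio,
)
from drugtarget_mr.sumstats import GeneRegion, SumstatsTable

from conftest import make_assoc, make_inst


class TestWaldRatio:
    def test_null_effect(self):
        res = wald_ratio(make_inst(beta_out=0.0))
        assert res.beta == 0.0 and res.or_ == 1.0 and res.pval == 1.0

    def test_hand_delta_method(self):
        res = wald_ratio(make_inst(beta_exp=1.0, se_exp=0.2, beta_out=0.5, se_out=0.1))
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)
        assert res.or_ == pytest.approx(1.6487, abs=1e-4)
        # exp(0.5 -/+ 1.959964 * 0.1)
        assert res.ci_low == pytest.approx(1.35529, abs=1e-4)
        assert res.ci_high == pytest.approx(2.00571, abs=1e-4)

    def test_sign_symmetry(self):
        a = wald_ratio(make_inst(beta_exp=0.2, beta_out=0.05))
        b = wald_ratio(make_inst(beta_exp=-0.2, beta_out=0.05))
        assert b.beta == pytest.approx(-a.beta)
        assert b.se == pytest.approx(a.se)
        assert b.pval == pytest.approx(a.pval)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError, match="rs1"):
            wald_ratio(make_inst(beta_exp=0.0))


class TestIVW:
    def test_degenerate_consensus(self):
        insts = [
            make_inst(variant_id="a", beta_exp=0.1, beta_out=0.03, se_out=0.01),
            make_inst(variant_id="b", beta_exp=0.2, beta_out=0.06, se_out=0.05),
        ]
        for mode in ("fixed", "multiplicative_random"):
            assert ivw(insts, mode).beta == pytest.approx(0.3)

    def test_weighted_mean_example(self):
        insts = [
            make_inst(variant_id="a", beta_exp=1.0, beta_out=0.2, se_out=0.1),
            make_inst(variant_id="b", beta_exp=1.0, beta_out=0.4, se_out=0.1),
        ]
        res = ivw(insts, "fixed")
        assert res.beta == pytest.approx(0.3)
        assert res.se == pytest.approx(0.070711, abs=1e-6)

    def test_single_instrument_routes_to_wald(self):
        inst = make_inst()
        with pytest.raises(ValueError):
            ivw([inst])
        model = MendelianRandomization([inst])
        res = model.fit("auto")
        ref = wald_ratio(inst)
        assert res.method == "wald_ratio"
        assert (res.beta, res.se) == (ref.beta, ref.se)

    @pytest.mark.parametrize("seed", range(5))
    def test_fixed_effect_matches_analytic_weighted_mean(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 12))
        insts = [
            make_inst(
                variant_id=f"v{i}",
                beta_exp=rng.uniform(0.05, 0.5) * rng.choice([-1, 1]),
                se_exp=rng.uniform(0.005, 0.05),
                beta_out=rng.normal(0, 0.1),
                se_out=rng.uniform(0.005, 0.05),
            )
            for i in range(k)
        ]
        r = np.array([i.beta_out / i.beta_exp for i in insts])
        s = np.array([i.se_out / abs(i.beta_exp) for i in insts])
        w = 1 / s**2
        res = ivw(insts, "fixed")
        assert res.beta == pytest.approx(float(np.sum(w * r) / np.sum(w)), abs=1e-12)
        assert res.se == pytest.approx(float(np.sqrt(1 / np.sum(w))), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_mre_se_at_least_fixed(self, seed):
        rng = np.random.default_rng(100 + seed)
        insts = [
            make_inst(variant_id=f"v{i}", beta_exp=0.1,
                      beta_out=rng.normal(0.02, 0.05), se_out=0.01)
            for i in range(6)
        ]
        fe, mre = ivw(insts, "fixed"), ivw(insts, "multiplicative_random")
        q, df, _ = cochran_q(insts)
        assert mre.se >= fe.se
        assert (mre.se == pytest.approx(fe.se)) == (q <= df)


class TestCochranQ:
    def test_identical_ratios(self):
        insts = [make_inst(variant_id="a"), make_inst(variant_id="b", se_out=0.02)]
        q, df, p = cochran_q(insts)
        assert q == pytest.approx(0.0, abs=1e-24) and p == pytest.approx(1.0)

    def test_hand_chi_square(self):
        insts = [
            make_inst(variant_id="a", beta_exp=1.0, beta_out=0.2, se_out=0.1),
            make_inst(variant_id="b", beta_exp=1.0, beta_out=0.4, se_out=0.1),
        ]
        q, df, p = cochran_q(insts)
        assert q == pytest.approx(2.0)
        assert df == 1
        assert p == pytest.approx(0.1573, abs=1e-4)

    def test_scale_invariance(self):
        insts = [
            make_inst(variant_id="a", beta_exp=1.0, beta_out=0.2, se_out=0.1),
            make_inst(variant_id="b", beta_exp=1.0, beta_out=0.5, se_out=0.2),
        ]
        scaled = [
            make_inst(variant_id=i.variant_id, beta_exp=1.0,
                      beta_out=3 * i.beta_out, se_out=3 * i.se_out)
            for i in insts
        ]
        assert cochran_q(scaled)[0] == pytest.approx(cochran_q(insts)[0])

    def test_requires_two(self):
        with pytest.raises(ValueError):
            cochran_q([make_inst()])


class TestEgger:
    def test_no_pleiotropy_identity(self):
        theta = 0.3
        insts = [
            make_inst(variant_id=f"v{i}", beta_exp=bx, beta_out=theta * bx,
                      se_out=0.01 * (i + 1))
            for i, bx in enumerate([0.1, 0.2, 0.35, 0.5])
        ]
        res = egger_intercept(insts)
        assert res.egger_computable
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_recovered(self):
        insts = [
            make_inst(variant_id=f"v{i}", beta_exp=bx, beta_out=0.2 * bx + 0.1,
                      se_out=0.02)
            for i, bx in enumerate([0.1, 0.3, 0.5])
        ]
        res = egger_intercept(insts)
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 10))
        insts = [
            make_inst(
                variant_id=f"v{i}",
                beta_exp=rng.uniform(0.05, 0.5) * rng.choice([-1, 1]),
                beta_out=rng.normal(0, 0.1),
                se_out=rng.uniform(0.01, 0.05),
            )
            for i in range(k)
        ]
        sign = np.array([1.0 if i.beta_exp > 0 else -1.0 for i in insts])
        bx = sign * np.array([i.beta_exp for i in insts])
        by = sign * np.array([i.beta_out for i in insts])
        w = 1 / np.array([i.se_out for i in insts]) ** 2
        X = np.column_stack([np.ones(k), bx])
        xtwx = X.T @ (w[:, None] * X)
        coef = np.linalg.solve(xtwx, X.T @ (w * by))
        resid = by - X @ coef
        scale = float(resid @ (w * resid)) / (k - 2)
        se0 = math.sqrt(scale * np.linalg.inv(xtwx)[0, 0])

        res = egger_intercept(insts)
        assert res.egger_intercept == pytest.approx(coef[0], abs=1e-10)
        assert res.egger_intercept_se == pytest.approx(se0, abs=1e-10)

    def test_too_few_instruments_flagged(self):
        res = egger_intercept([make_inst(variant_id="a"), make_inst(variant_id="b")])
        assert not res.egger_computable
        assert math.isnan(res.egger_intercept)


class TestSteiger:
    def test_stated_criterion(self):
        # r2_exp = z²/(z²+n); build z to hit 0.02 vs 0.001
        n = 10_000.0
        zx = math.sqrt(0.02 * n / 0.98)
        zy = math.sqrt(0.001 * n / 0.999)
        inst = make_inst(beta_exp=zx * 0.01, se_exp=0.01,
                         beta_out=zy * 0.01, se_out=0.01, n_exp=n, n_out=n)
        retained, results = steiger_filter([inst])
        assert retained == [inst]
        assert results[0].correct_direction
        assert results[0].r2_exp == pytest.approx(0.02)
        assert results[0].r2_out == pytest.approx(0.001)
        assert 0 < results[0].steiger_pval < 0.05

    def test_boundary_equality_removed(self):
        inst = make_inst(beta_exp=0.05, se_exp=0.01, beta_out=0.05, se_out=0.01,
                         n_exp=10_000, n_out=10_000)
        retained, results = steiger_filter([inst])
        assert retained == [] and not results[0].correct_direction


class TestBonferroni:
    def test_paper_thresholds(self):
        t = bonferroni_threshold(0.05, 2619)
        assert t == pytest.approx(1.9091e-5, rel=1e-4)
        assert math.floor(t * 1e7) / 1e7 == pytest.approx(1.90e-5)  # printed truncation
        assert bonferroni_threshold(0.05, 13) == pytest.approx(0.003846, abs=5e-7)
        assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_zero_tests_domain_error(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestReverseMR:
    def test_no_significant_disease_variant_not_testable(self):
        gene = GeneRegion("ENSG1", "G1", "1", tss=1_000_000)
        disease = SumstatsTable.from_records(
            [make_assoc(variant_id="rs1", pval=1e-4)],
            trait_id="disease", trait_type="binary", n_cases=10, n_controls=90,
        )
        eqtl = SumstatsTable.from_records([make_assoc(variant_id="rs1")])
        ld = LDMatrix(["rs1"], np.array([[1.0]]))
        res = reverse_mr(disease, eqtl, gene, ld)
        assert not res.testable and "no genome-wide-significant" in res.reason


@given(
    beta=st.floats(-2, 2),
    se=st.floats(1e-4, 1.0),
)
@settings(max_examples=200, derandomize=True)
def test_estimate_ci_invariants(beta, se):
    """Every estimate's OR interval brackets the OR with the 1.959964 quantile."""
    res = wald_ratio(make_inst(beta_exp=1.0, se_exp=0.01, beta_out=beta, se_out=se))
    assert res.ci_low == pytest.approx(math.exp(res.beta - 1.959964 * res.se))
    assert res.ci_high == pytest.approx(math.exp(res.beta + 1.959964 * res.se))
    assert res.ci_low <= res.or_ <= res.ci_high
    assert 0 < res.pval <= 1
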
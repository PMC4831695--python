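"""Unit tests for the parameter table and its derivation chain."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uparsim.parameters import (
    EstimationContext,
    ParameterSet,
    ParameterValidationError,
    baseline_parameter_set,
    decay_rate_from_half_life,
    derivation_table,
    diffusion_from_molecular_weight,
    estimate_diffusion_coefficients,
    estimate_misc_steadystates,
    estimate_pai1_rates,
    estimate_plasmin_constants,
    estimate_upa_rates,
    estimate_upar_production,
)
from uparsim.parameters import InconsistentAnchorError


CTX = EstimationContext()


class TestDiffusionScaling:
    @pytest.mark.parametrize(
        "mw, expected",
        [(92, 0.212), (35, 0.111), (43, 0.127), (38, 0.117)],
    )
    def test_printed_values(self, mw, expected):
        got = diffusion_from_molecular_weight(mw, 24, 8.64e-2)
        assert got == pytest.approx(expected, rel=5e-3)

    def test_identity_case(self):
        assert diffusion_from_molecular_weight(24, 24, 8.64e-2) == 8.64e-2

    def test_full_coefficient_table(self):
        got = estimate_diffusion_coefficients(CTX)
        expected = {"D_P": 0.212, "D_uP": 0.117, "D_T": 0.111, "D_PA": 0.127}
        assert set(got) == set(expected)
        for key, value in expected.items():
            assert got[key] == pytest.approx(value, rel=5e-3)

    @pytest.mark.parametrize("bad", [(-1, 24, 1), (24, 0, 1), (24, 24, -2)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            diffusion_from_molecular_weight(*bad)

    @given(
        mw=st.floats(1.0, 500.0),
        scale=st.floats(0.5, 8.0),
        ref_D=st.floats(1e-4, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_homogeneity(self, mw, scale, ref_D):
        # degree 2/3 in mw, degree 1 in ref_D
        base = diffusion_from_molecular_weight(mw, 24.0, ref_D)
        scaled = diffusion_from_molecular_weight(scale * mw, 24.0, ref_D)
        assert scaled == pytest.approx(base * scale ** (2.0 / 3.0), rel=1e-12)
        assert diffusion_from_molecular_weight(mw, 24.0, 3.0 * ref_D) == pytest.approx(
            3.0 * base, rel=1e-12
        )


class TestDecayRate:
    def test_tissue_factor_nine_hours(self):
        assert decay_rate_from_half_life(9 / 24) == pytest.approx(1.85, abs=5e-3)

    def test_plasmin_half_day(self):
        assert decay_rate_from_half_life(0.5) == pytest.approx(1.39, abs=5e-3)

    def test_ln2_closed_form(self):
        assert decay_rate_from_half_life(math.log(2)) == pytest.approx(1.0, rel=1e-14)

    @given(t=st.floats(1e-6, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_product_is_ln2(self, t):
        assert decay_rate_from_half_life(t) * t == pytest.approx(
            math.log(2), rel=1e-12
        )

    def test_nonpositive(self):
        with pytest.raises(ValueError):
            decay_rate_from_half_life(0.0)


class TestSteadyStateEstimates:
    def test_plasmin_constants(self):
        P_dis, lam_Pu, lam_P, K_P = estimate_plasmin_constants(CTX)
        assert P_dis == pytest.approx(4.4e-6, rel=0.02)
        assert lam_Pu == pytest.approx(10.5, rel=0.01)
        assert lam_P == pytest.approx(2.42e-6, rel=0.01)
        assert K_P == 4.4e-6

    def test_upar_production(self):
        lam_M, lam_C = estimate_upar_production(CTX)
        assert lam_M == pytest.approx(6.21e-6, rel=1e-6)
        assert lam_C == pytest.approx(1.242e-6, rel=1e-6)

    def test_upar_boundary_of_feasibility(self):
        # disease anchor exactly covered by the macrophage term -> lam_C = 0
        lam_M = CTX.d_uPR * CTX.uPR_healthy / CTX.M_healthy
        uPR_dis = lam_M * CTX.M_disease / CTX.d_uPR
        ctx = EstimationContext(uPR_disease=uPR_dis, uPR_healthy=uPR_dis / 10)
        lam_M2, lam_C = estimate_upar_production(ctx)
        # healthy anchor scales with the disease anchor, so recompute lam_M
        assert lam_C == pytest.approx(
            (ctx.d_uPR * uPR_dis - lam_M2 * ctx.M_disease) / ctx.C_disease, abs=1e-18
        )

    def test_upar_inconsistent_anchor(self):
        # a huge disease macrophage density makes the macrophage term alone
        # exceed uPAR turnover, forcing a negative cancer-cell rate
        ctx = EstimationContext(M_disease=3.0)
        with pytest.raises(InconsistentAnchorError):
            estimate_upar_production(ctx)

    def test_upa_rates(self):
        lam_uf, lam_u = estimate_upa_rates(CTX)
        assert lam_uf == pytest.approx(2.057e-4, rel=1e-3)
        # exact: 3.2 * 2 * (1.8/6)
        assert lam_u == pytest.approx(1.92, rel=1e-12)

    def test_upa_saturation_limit_halves(self):
        # receptor at half-saturation doubles the required rate versus
        # a fully saturated receptor
        _, lam_u = estimate_upa_rates(CTX)
        lam_u_saturated = CTX.d_uPa * CTX.uPa_disease / CTX.uPi_healthy
        assert lam_u == pytest.approx(2.0 * lam_u_saturated, rel=1e-12)

    def test_pai1_rates(self):
        with pytest.warns(UserWarning, match="8.4e-4"):
            PA, lam_PC, lam_Pf, lam_PM = estimate_pai1_rates(CTX)
        assert PA == pytest.approx(8.39e-6, rel=1e-3)
        assert CTX.d_PA * PA == pytest.approx(7e-5, rel=0.005)
        assert lam_PC == pytest.approx(8e-5, rel=0.005)
        assert lam_PM == pytest.approx(4e-4, rel=0.005)
        assert lam_Pf == 8.4e-4  # tabled value kept over the 8.571e-4 arithmetic

    def test_misc_steadystates(self):
        f_h, P0, V, K_V, K_p = estimate_misc_steadystates(CTX)
        assert f_h == pytest.approx(6.02e-2, rel=1e-3)
        assert P0 == pytest.approx(1.74e-6, rel=1e-3)
        assert V == pytest.approx(7e-8, rel=1e-12)
        assert K_V == V
        assert K_p == 2e-7

    def test_order_invariance(self):
        # evaluating the estimators in any order gives identical numbers
        a = estimate_upa_rates(CTX)
        estimate_plasmin_constants(CTX)
        estimate_misc_steadystates(CTX)
        b = estimate_upa_rates(CTX)
        assert a == b


class TestBaselineParameterSet:
    def test_tabled_spot_values(self):
        p = baseline_parameter_set()
        assert p.D_q == 0.013
        assert p.d_C == 0.5
        assert p.chi_C == 10.0

    def test_referentially_pure(self):
        assert baseline_parameter_set() == baseline_parameter_set()

    def test_crosscheck_within_two_percent(self):
        rows = derivation_table()
        for row in rows:
            if row["override"]:
                continue
            assert abs(row["rel_diff"]) <= 0.02, row

    def test_documented_overrides_present(self):
        overrides = {r["parameter"] for r in derivation_table() if r["override"]}
        assert "lam_Pf" in overrides

    def test_negative_entry_rejected(self):
        with pytest.raises(ParameterValidationError):
            ParameterSet(d_C=-0.5)

    def test_unknown_override_rejected(self):
        with pytest.raises(ParameterValidationError):
            ParameterSet().replace(lambda_XX=1.0)

    def test_roundtrip_steady_states(self):
        # plugging the estimates back reproduces the anchors within 2%
        p = baseline_parameter_set()
        ctx = CTX
        # healthy uPAR: lam_uPRM * M / d_uPR
        assert p.lam_uPRM * ctx.M_healthy / p.d_uPR == pytest.approx(
            ctx.uPR_healthy, rel=0.02
        )
        # disease uPAR
        assert (
            p.lam_uPRM * ctx.M_disease + p.lam_uPRC * ctx.C_disease
        ) / p.d_uPR == pytest.approx(ctx.uPR_disease, rel=0.02)
        # healthy inactive uPA
        assert p.lam_uf * ctx.f_healthy / p.d_uPi == pytest.approx(
            ctx.uPi_healthy, rel=0.02
        )
        # disease active uPA (receptor at half-saturation)
        assert p.lam_u * ctx.uPi_healthy * 0.5 / p.d_uPa == pytest.approx(
            ctx.uPa_disease, rel=0.02
        )
        # healthy fibroblasts
        assert p.A_f / p.d_f == pytest.approx(6.02e-2, rel=0.02)


class TestSerialization:
    def test_yaml_roundtrip(self, tmp_path):
        p = baseline_parameter_set().replace(beta=0.4)
        path = tmp_path / "params.yaml"
        p.to_file(str(path))
        assert ParameterSet.from_file(str(path)) == p

    def test_json_roundtrip(self, tmp_path):
        p = baseline_parameter_set()
        path = tmp_path / "params.json"
        p.to_file(str(path))
        assert ParameterSet.from_file(str(path)) == p

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("schema: uparsim-params-1\nlambda_XX: 3.0\n")
        with pytest.raises(ParameterValidationError, match="lambda_XX"):
            ParameterSet.from_file(str(path))

    def test_bad_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("schema: other-0\n")
        with pytest.raises(ParameterValidationError, match="schema"):
            ParameterSet.from_file(str(path))
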
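"""Model parameters and the derivation chain behind the estimated ones.

The baseline table mixes literature values with rates estimated from
steady-state balances of the reaction network.  Every estimated entry can be
recomputed here from a small set of anchor concentrations, half-lives and
molecular weights (:class:`EstimationContext`), so the table is reproducible
rather than a block of opaque numbers.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, fields, replace
from typing import Any, Dict, Iterator, Tuple

import yaml

__all__ = [
    "ParameterSet",
    "EstimationContext",
    "ParameterValidationError",
    "diffusion_from_molecular_weight",
    "decay_rate_from_half_life",
    "estimate_diffusion_coefficients",
    "estimate_plasmin_constants",
    "estimate_upar_production",
    "estimate_upa_rates",
    "estimate_pai1_rates",
    "estimate_misc_steadystates",
    "baseline_parameter_set",
    "derivation_table",
    "PARAM_UNITS",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "uparsim-params-1"


class ParameterValidationError(ValueError):
    """A parameter set violates a positivity/consistency invariant."""


class InconsistentAnchorError(ValueError):
    """Steady-state anchors imply a negative rate constant."""


# ---------------------------------------------------------------------------
# Estimation context: anchors scattered through the derivation prose.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EstimationContext:
    """Anchor values used to re-derive the estimated rate constants.

    Concentrations in g/ml (= g/cm^3), half-lives in days, molecular
    weights in kDa.
    """

    # reference protein for the molecular-weight diffusion scaling (VEGF)
    mw_ref: float = 24.0
    D_ref: float = 8.64e-2  # cm^2/day
    mw_plasmin: float = 92.0
    mw_uPA: float = 38.0
    mw_TF: float = 35.0
    mw_PAI1: float = 43.0

    # half-lives (days)
    t_half_TF: float = 9.0 / 24.0
    t_half_plasmin: float = 0.5
    t_half_uPAR: float = 0.5
    t_half_uPa_active: float = 5.0 / 24.0

    # steady-state anchor concentrations (g/ml)
    uPa_disease: float = 1.8e-6
    uPR_disease: float = 1.8e-6
    # measured only as "about ten times below disease"; fixed at exactly /10
    uPR_healthy: float = 1.8e-7
    PA_disease: float = 8.39e-6
    uPi_healthy: float = 6.0e-6
    M_healthy: float = 0.04
    M_disease: float = 0.3
    C_disease: float = 0.5
    f_healthy: float = 0.07
    f_disease: float = 0.14

    # tabled decay rates entering the solves (per day)
    d_uPR: float = 1.38
    d_uPa: float = 3.2
    d_uPi: float = 2.4
    d_PA: float = 8.32
    d_V: float = 12.6
    d_f: float = 1.66e-2

    A_f: float = 1.0e-3  # g/ml/day
    lam_VM: float = 2.0e-6  # per day

    def __post_init__(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not (v > 0 and math.isfinite(v)):
                raise ParameterValidationError(
                    f"EstimationContext.{f_.name} must be positive, got {v!r}"
                )
        if not math.isclose(self.uPR_healthy, self.uPR_disease / 10.0, rel_tol=1e-12):
            raise ParameterValidationError(
                "healthy uPAR anchor must be one tenth of the disease anchor"
            )


# ---------------------------------------------------------------------------
# Elementary estimators
# ---------------------------------------------------------------------------


def diffusion_from_molecular_weight(mw: float, ref_mw: float, ref_D: float) -> float:
    """Diffusion coefficient from the 2/3-power molecular-weight scaling.

    D scales with molecular surface area, i.e. with mw**(2/3), relative to a
    reference protein of known diffusivity.
    """
    if mw <= 0 or ref_mw <= 0 or ref_D <= 0:
        raise ValueError("molecular weights and reference diffusivity must be positive")
    return ref_D * (mw / ref_mw) ** (2.0 / 3.0)


def decay_rate_from_half_life(t_half: float) -> float:
    """First-order decay rate ln(2)/t_half (per day for t_half in days)."""
    if t_half <= 0:
        raise ValueError(f"half-life must be positive, got {t_half!r}")
    return math.log(2.0) / t_half


def estimate_diffusion_coefficients(ctx: EstimationContext) -> Dict[str, float]:
    """Protein diffusivities from the molecular-weight scaling (cm^2/day)."""
    return {
        "D_P": diffusion_from_molecular_weight(ctx.mw_plasmin, ctx.mw_ref, ctx.D_ref),
        "D_uP": diffusion_from_molecular_weight(ctx.mw_uPA, ctx.mw_ref, ctx.D_ref),
        "D_T": diffusion_from_molecular_weight(ctx.mw_TF, ctx.mw_ref, ctx.D_ref),
        "D_PA": diffusion_from_molecular_weight(ctx.mw_PAI1, ctx.mw_ref, ctx.D_ref),
    }


def estimate_plasmin_constants(
    ctx: EstimationContext,
) -> Tuple[float, float, float, float]:
    """(P_disease, lam_Pu, lam_P, K_P) from the plasmin steady state.

    Plasmin tracks uPA protein counts, so P_disease = (92/38)*uPa.  The
    uPA-enhancement factor solves lam_Pu*uPa/(K_PA + PA) = 3/2 with
    K_PA = PA/2, and the basal activation rate solves
    lam_P*(1 + 3/2) = d_P*P_disease with d_P = ln2 / t_half.
    """
    P_disease = (ctx.mw_plasmin / ctx.mw_uPA) * ctx.uPa_disease
    K_PA = ctx.PA_disease / 2.0
    lam_Pu = 1.5 * (K_PA + ctx.PA_disease) / ctx.uPa_disease
    d_P = decay_rate_from_half_life(ctx.t_half_plasmin)
    lam_P = d_P * P_disease / (1.0 + 1.5)
    K_P = 4.4e-6  # plasmin anchor rounded to 2 s.f., as tabled
    return P_disease, lam_Pu, lam_P, K_P


def estimate_upar_production(ctx: EstimationContext) -> Tuple[float, float]:
    """(lam_uPRM, lam_uPRC) from healthy and disease uPAR steady states."""
    lam_uPRM = ctx.d_uPR * ctx.uPR_healthy / ctx.M_healthy
    lam_uPRC = (
        ctx.d_uPR * ctx.uPR_disease - lam_uPRM * ctx.M_disease
    ) / ctx.C_disease
    if lam_uPRC < 0:
        raise InconsistentAnchorError(
            "uPAR anchors imply a negative cancer-cell production rate "
            f"({lam_uPRC:.3e}); check uPR_disease vs macrophage contribution"
        )
    return lam_uPRM, lam_uPRC


def estimate_upa_rates(ctx: EstimationContext) -> Tuple[float, float]:
    """(lam_uf, lam_u) from the uPA steady states.

    lam_uf balances fibroblast production against inactive-uPA turnover in
    healthy tissue; lam_u solves the active-uPA balance with the receptor
    at its half-saturation value (Michaelis factor exactly 1/2), keeping
    the uPi/uPa concentration ratio unrounded.
    """
    lam_uf = ctx.d_uPi * ctx.uPi_healthy / ctx.f_healthy
    # lam_u * uPi * 1/2 = d_uPa * uPa
    lam_u = 2.0 * ctx.d_uPa * ctx.uPa_disease / ctx.uPi_healthy
    return lam_uf, lam_u


def estimate_pai1_rates(ctx: EstimationContext) -> Tuple[float, float, float, float]:
    """(PA_disease, lam_PC, lam_Pf, lam_PM) from the PAI-1 budget.

    The tissue concentration converts 12 ng/mg protein through the 1.43
    protein-per-tissue factor; total production is taken 4x the turnover
    d_PA*PA (growing tumor), allocated 1/7 to cancer cells and 3/7 each to
    fibroblasts and macrophages.

    The fibroblast share arithmetic gives 1.2e-4/0.14 = 8.571e-4/day but the
    canonical tabled value is 8.4e-4/day; the tabled value is returned and a
    warning emitted.
    """
    PA = 12e-9 / 1.43 / 1e-3
    turnover = ctx.d_PA * PA  # ~7e-5 g/ml/day
    total = 4.0 * turnover
    lam_PC = (total / 7.0) / ctx.C_disease
    lam_Pf_arith = (3.0 * total / 7.0) / ctx.f_disease
    lam_PM = (3.0 * total / 7.0) / ctx.M_disease
    lam_Pf = 8.4e-4
    if abs(lam_Pf_arith - lam_Pf) / lam_Pf > 1e-3:
        warnings.warn(
            "lam_Pf: tabled value 8.4e-4/day kept as canonical; the stated "
            f"allocation arithmetic gives {lam_Pf_arith:.3e}/day",
            stacklevel=2,
        )
    return PA, lam_PC, lam_Pf, lam_PM


def estimate_misc_steadystates(
    ctx: EstimationContext,
) -> Tuple[float, float, float, float, float]:
    """(f_healthy, P_nouPA, V_approx, K_V, K_p) from assorted balances."""
    f_healthy = ctx.A_f / ctx.d_f
    # basal plasmin level with no active uPA, using the tabled (rounded) rates
    P_nouPA = 2.42e-6 / 1.39
    # VEGF scale: (1+eps)*lam_VM*M = d_V*V with eps = 1/2, M = 0.3
    V_approx_exact = 1.5 * ctx.lam_VM * ctx.M_disease / ctx.d_V
    V_approx = float(f"{V_approx_exact:.0e}")  # rounded to 1 s.f. (7e-8)
    K_V = V_approx
    K_p = 2e-7
    return f_healthy, P_nouPA, V_approx, K_V, K_p


# ---------------------------------------------------------------------------
# ParameterSet
# ---------------------------------------------------------------------------

PARAM_UNITS: Dict[str, str] = {
    # diffusion / dispersion coefficients
    "D_T": "cm^2/day", "D_V": "cm^2/day", "D_P": "cm^2/day",
    "D_uPR": "cm^2/day", "D_uP": "cm^2/day", "D_PA": "cm^2/day",
    "D_q": "cm^2/day", "D_p": "cm^2/day", "D_M": "cm^2/day",
    "D_E": "cm^2/day", "D_f": "cm^2/day", "D_C": "cm^2/day",
    "D_w": "cm^2/day", "D_Q": "cm^2/day", "D_Qr": "cm^2/day",
    # production / activation
    "A_T": "g/ml/day", "lam_TC": "1/day", "lam_VC": "g/ml/day",
    "lam_VT": "1", "lam_VM": "g/ml/day", "lam_P": "g/ml/day",
    "lam_Pu": "1", "lam_uPRM": "1/day", "lam_uPRC": "1/day",
    "lam_uf": "1/day", "lam_u": "1/day", "lam_PC": "1/day",
    "lam_Pf": "1/day", "lam_PM": "1/day", "lam_qC": "1/day",
    "lam_p": "1/day", "lam_E": "1/day", "A_f": "g/ml/day",
    "lam_fC": "1/day", "beta": "1/day", "lam_Cf": "1/day",
    "lam_CuP": "1/day", "lam_wC": "1/day", "lam_w": "1/day",
    "lam_QM": "1/day", "lam_QP": "1", "lam_QrM": "1/day",
    "lam_rhof": "1/day",
    # degradation / consumption
    "d_T": "1/day", "d_V": "1/day", "d_P": "1/day", "d_uPR": "1/day",
    "d_uPa": "1/day", "d_uPi": "1/day", "d_PA": "1/day", "d_q": "1/day",
    "d_p": "1/day", "d_M": "1/day", "d_E": "1/day", "d_f": "1/day",
    "d_C": "1/day", "d_wM": "ml/g/day", "d_wC": "ml/g/day",
    "d_wf": "ml/g/day", "d_QQr": "cm^3/g/day", "d_Q": "1/day",
    "d_QrQ": "cm^3/g/day", "d_Qr": "1/day", "d_rho": "1/day",
    "d_rhoQ": "cm^3/g/day",
    # saturations / thresholds / capacities
    "K_T": "g/cm^3", "K_PA": "g/ml", "K_uPR": "g/ml", "K_p": "g/ml",
    "K_E": "g/cm^3", "K_C": "g/cm^3", "K_f": "g/cm^3", "K_P": "g/ml",
    "K_V": "g/ml", "M0": "g/ml", "V0": "g/cm^3", "C0": "g/cm^3",
    "q0": "g/cm^3", "w0": "g/ml", "E0": "g/ml", "rho0": "g/ml",
    "chi_C": "cm^2/day", "w_h": "g/cm^3", "alpha_w": "1/cm", "alpha_E": "1/cm",
}

# entries that are only allowed to be zero or negative never
_NONNEGATIVE_OK: frozenset = frozenset()


@dataclass(frozen=True)
class ParameterSet:
    """The full baseline rate/diffusion/saturation table.

    Densities and concentrations in g/cm^3 (g/ml treated as identical),
    times in days, lengths in cm.
    """

    # diffusion coefficients
    D_T: float = 0.111
    D_V: float = 8.64e-2
    D_P: float = 0.212
    D_uPR: float = 8.64e-7
    D_uP: float = 0.117
    D_PA: float = 0.127
    D_q: float = 0.013
    D_p: float = 1.29e-2
    D_M: float = 8.64e-7
    D_E: float = 8.64e-7
    D_f: float = 8.64e-7
    D_C: float = 8.64e-7
    D_w: float = 4.32e-2
    D_Q: float = 4.32e-2
    D_Qr: float = 4.32e-2
    # production / activation rates
    A_T: float = 3.23e-5
    lam_TC: float = 5.7e-5
    lam_VC: float = 2e-8
    lam_VT: float = 2.0
    lam_VM: float = 2e-6
    lam_P: float = 2.42e-6
    lam_Pu: float = 10.5
    lam_uPRM: float = 6.21e-6
    lam_uPRC: float = 1.242e-6
    lam_uf: float = 2.057e-4
    lam_u: float = 1.92
    lam_PC: float = 8e-5
    lam_Pf: float = 8.4e-4
    lam_PM: float = 4e-4
    lam_qC: float = 3e-8
    lam_p: float = 1.9e-6
    lam_E: float = 0.7
    A_f: float = 1e-3
    lam_fC: float = 5e-3
    beta: float = 0.3
    lam_Cf: float = 0.06
    lam_CuP: float = 0.05
    lam_wC: float = 0.6
    lam_w: float = 7e-2
    lam_QM: float = 3e-4
    lam_QP: float = 2.0
    lam_QrM: float = 6e-5
    lam_rhof: float = 3e-3
    # degradation / consumption rates
    d_T: float = 1.85
    d_V: float = 12.6
    d_P: float = 1.39
    d_uPR: float = 1.38
    d_uPa: float = 3.2
    d_uPi: float = 2.4
    d_PA: float = 8.32
    d_q: float = 4.8
    d_p: float = 1.73
    d_M: float = 0.015
    d_E: float = 0.69
    d_f: float = 1.66e-2
    d_C: float = 0.5
    d_wM: float = 80.0
    d_wC: float = 40.0
    d_wf: float = 80.0
    d_QQr: float = 4.98e8
    d_Q: float = 4.32
    d_QrQ: float = 1.04e9
    d_Qr: float = 21.6
    d_rho: float = 0.37
    d_rhoQ: float = 2.59e7
    # saturations, thresholds, capacities
    K_T: float = 1e-4
    K_PA: float = 4.19e-6
    K_uPR: float = 1.8e-6
    K_p: float = 2e-7
    K_E: float = 5e-3
    K_C: float = 0.5
    K_f: float = 0.1
    K_P: float = 4.4e-6
    K_V: float = 7e-8
    M0: float = 5e-5
    V0: float = 3.65e-10
    C0: float = 0.75
    q0: float = 1e-9
    w0: float = 4.65e-4
    E0: float = 2.5e-3
    rho0: float = 1e-3
    chi_C: float = 10.0
    w_h: float = 1e-4
    alpha_w: float = 1.0
    alpha_E: float = 1.0

    def __post_init__(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ParameterValidationError(
                    f"parameter {f_.name} must be a finite number, got {v!r}"
                )
            if v <= 0:
                raise ParameterValidationError(
                    f"parameter {f_.name} must be strictly positive, got {v!r}"
                )
        if self.C0 > 1.0:
            raise ParameterValidationError("carrying capacity C0 must satisfy C0 <= 1")

    # -- convenience ----------------------------------------------------

    def replace(self, **overrides: float) -> "ParameterSet":
        unknown = set(overrides) - {f_.name for f_ in fields(self)}
        if unknown:
            raise ParameterValidationError(
                f"unknown parameter name(s): {sorted(unknown)}"
            )
        return replace(self, **overrides)

    def to_dict(self) -> Dict[str, float]:
        return {f_.name: float(getattr(self, f_.name)) for f_ in fields(self)}

    def units(self, name: str) -> str:
        return PARAM_UNITS[name]

    def __iter__(self) -> Iterator[Tuple[str, float]]:
        return iter(self.to_dict().items())

    # -- serialization --------------------------------------------------

    def to_file(self, path: str) -> None:
        payload: Dict[str, Any] = {"schema": SCHEMA_VERSION}
        payload.update(self.to_dict())
        text = (
            json.dumps(payload, indent=1)
            if str(path).endswith(".json")
            else yaml.safe_dump(payload, sort_keys=False)
        )
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def from_file(cls, path: str) -> "ParameterSet":
        with open(path) as fh:
            text = fh.read()
        # YAML 1.1 resolves "2e-08" (no dot) as a string, so parse JSON as JSON
        if str(path).endswith(".json"):
            payload = json.loads(text) if text.strip() else {}
        else:
            payload = yaml.safe_load(text) or {}
        schema = payload.pop("schema", SCHEMA_VERSION)
        if schema != SCHEMA_VERSION:
            raise ParameterValidationError(
                f"unsupported parameter schema {schema!r} (expected {SCHEMA_VERSION!r})"
            )
        known = {f_.name for f_ in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ParameterValidationError(
                f"unknown parameter name(s): {sorted(unknown)}"
            )
        return cls(**payload)


# ---------------------------------------------------------------------------
# Baseline table with cross-check against the estimators
# ---------------------------------------------------------------------------

# estimated entries whose tabled value is knowingly NOT reproduced by the
# stated balance; the tabled value is canonical and the mismatch documented.
_CROSSCHECK_OVERRIDES: Dict[str, str] = {
    "A_T": "tabled 3.23e-5 matches d_T*(3.5e-5/2), not the stated healthy "
           "steady state d_T*2e-4",
    "lam_TC": "tabled 5.7e-5; the stated disease balance gives ~6.5e-5",
    "lam_Pf": "tabled 8.4e-4; the stated 3/7 allocation gives 8.571e-4",
}


def _crosschecks(ctx: EstimationContext) -> Dict[str, float]:
    """Recomputed values for every estimated entry that has a stated balance."""
    out: Dict[str, float] = {}
    out.update(estimate_diffusion_coefficients(ctx))
    _, lam_Pu, lam_P, K_P = estimate_plasmin_constants(ctx)
    out["lam_Pu"] = lam_Pu
    out["lam_P"] = lam_P
    out["K_P"] = K_P
    out["lam_uPRM"], out["lam_uPRC"] = estimate_upar_production(ctx)
    out["lam_uf"], out["lam_u"] = estimate_upa_rates(ctx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        PA, lam_PC, _, lam_PM = estimate_pai1_rates(ctx)
    out["lam_PC"] = lam_PC
    out["lam_PM"] = lam_PM
    # the stated 3/7 allocation, which disagrees with the tabled 8.4e-4
    out["lam_Pf"] = (3.0 * 4.0 * ctx.d_PA * PA / 7.0) / ctx.f_disease
    out["K_PA"] = PA / 2.0
    _, _, _, K_V, K_p = estimate_misc_steadystates(ctx)
    out["K_V"] = K_V
    out["K_p"] = K_p
    out["d_T"] = decay_rate_from_half_life(ctx.t_half_TF)
    out["d_P"] = decay_rate_from_half_life(ctx.t_half_plasmin)
    out["d_uPR"] = decay_rate_from_half_life(ctx.t_half_uPAR)
    return out


def baseline_parameter_set(
    ctx: EstimationContext | None = None, *, crosscheck: bool = True
) -> ParameterSet:
    """The canonical tabled parameter set.

    With ``crosscheck=True`` every estimated entry that has a stated
    steady-state balance is re-derived and required to agree with the
    tabled value within 2%, except the documented overrides.
    """
    params = ParameterSet()
    if crosscheck:
        ctx = ctx or EstimationContext()
        recomputed = _crosschecks(ctx)
        for name, value in recomputed.items():
            if name in _CROSSCHECK_OVERRIDES:
                continue
            tabled = getattr(params, name)
            if abs(value - tabled) / tabled > 0.02:
                raise ParameterValidationError(
                    f"estimated parameter {name}: tabled {tabled:g} differs "
                    f"from re-derived {value:g} by more than 2%"
                )
    return params


def derivation_table(ctx: EstimationContext | None = None) -> "list[dict]":
    """Printed-vs-recomputed rows for every re-derivable estimated entry."""
    ctx = ctx or EstimationContext()
    params = ParameterSet()
    rows = []
    for name, value in sorted(_crosschecks(ctx).items()):
        tabled = getattr(params, name)
        rows.append(
            {
                "parameter": name,
                "units": PARAM_UNITS[name],
                "tabled": tabled,
                "recomputed": value,
                "rel_diff": (value - tabled) / tabled,
                "override": _CROSSCHECK_OVERRIDES.get(name, ""),
            }
        )
    return rows
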
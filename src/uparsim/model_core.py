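"""Right-hand sides of the tumor model on a radial mesh.

Seventeen fields share one moving mesh: nine cytokine/protein concentrations
(T, V, P, uPR, uPi, uPa, PA, q, p), four cell densities (M, E, f, C), oxygen
(w), the MMP/TIMP pair (Q, Qr) and the extracellular matrix (rho).  The four
cell species and the ECM are advected with a common tissue velocity u that is
determined by the constant-total-density constraint; everything else only
diffuses and reacts.  Plasminogen itself is a constant background and is not
a field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .mesh import MovingMesh, first_derivative, radial_laplacian
from .parameters import ParameterSet

__all__ = [
    "FIELD_NAMES",
    "ADVECTED_FIELDS",
    "StateFields",
    "StateError",
    "HypoxiaRule",
    "hypoxia_factor",
    "reaction_terms",
    "reaction_rates",
    "chemotaxis_flux_divergence",
    "chemotaxis_terms",
    "velocity_source",
    "velocity_from_source",
    "velocity_field",
    "divergence_of_velocity",
    "robin_boundary",
    "free_boundary_rate",
    "diffusion_coefficients",
    "initial_state",
]

FIELD_NAMES: Tuple[str, ...] = (
    "T", "V", "P", "uPR", "uPi", "uPa", "PA", "q", "p",
    "M", "E", "f", "C", "w", "Q", "Qr", "rho",
)
FIELD_INDEX: Dict[str, int] = {name: i for i, name in enumerate(FIELD_NAMES)}

#: species advected with the tissue velocity (all cells plus ECM)
ADVECTED_FIELDS: Tuple[str, ...] = ("M", "E", "f", "C", "rho")
ADVECTED_INDICES = tuple(FIELD_INDEX[n] for n in ADVECTED_FIELDS)

#: fields initialised to zero (all secreted proteins, incl. MMP/TIMP)
ZERO_INITIAL_FIELDS: Tuple[str, ...] = (
    "T", "V", "P", "uPR", "uPi", "uPa", "PA", "q", "p", "Q", "Qr",
)

#: fields entering the total-density constraint and their initial values
INITIAL_CELL_VALUES: Dict[str, float] = {
    "M": 0.07, "E": 0.05, "f": 0.06, "C": 0.4, "rho": 0.02,
}


class StateError(ValueError):
    """State contains NaN or negative field values."""


class MeshMismatchError(ValueError):
    """Fields defined on different meshes were combined."""


@dataclass
class StateFields:
    """Per-node values of all 17 fields plus the radial velocity.

    ``data`` has shape (17, N) in the order of :data:`FIELD_NAMES`;
    ``u`` has shape (N,), with u(0) = 0 by radial symmetry.
    """

    data: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(FIELD_NAMES):
            raise StateError(
                f"state data must have shape (17, N), got {self.data.shape}"
            )
        if self.u.shape != (self.data.shape[1],):
            raise StateError("velocity and field arrays have different node counts")

    @classmethod
    def zeros(cls, n_nodes: int) -> "StateFields":
        return cls(np.zeros((len(FIELD_NAMES), n_nodes)), np.zeros(n_nodes))

    @classmethod
    def from_dict(cls, values: Dict[str, np.ndarray], n_nodes: int) -> "StateFields":
        state = cls.zeros(n_nodes)
        for name, v in values.items():
            state[name] = v
        return state

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[FIELD_INDEX[name]]

    def __setitem__(self, name: str, value) -> None:
        self.data[FIELD_INDEX[name]] = value

    def copy(self) -> "StateFields":
        return StateFields(self.data.copy(), self.u.copy())

    def validate(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise StateError("state contains non-finite values")
        if np.any(self.data < 0):
            bad = [
                FIELD_NAMES[i]
                for i in np.unique(np.nonzero(self.data < 0)[0])
            ]
            raise StateError(f"negative field values in {bad}")

    def cell_density_sum(self) -> np.ndarray:
        """M + E + f + C + rho, the conserved total of the constraint."""
        return sum(self[name] for name in ADVECTED_FIELDS)


def initial_state(mesh: MovingMesh, params: ParameterSet) -> StateFields:
    """Uniform initial condition: fixed cell/ECM values, oxygen at the
    hypoxia threshold, every secreted protein zero."""
    state = StateFields.zeros(mesh.n_nodes)
    for name, value in INITIAL_CELL_VALUES.items():
        state[name] = value
    state["w"] = params.w_h
    return state


def diffusion_coefficients(params: ParameterSet) -> np.ndarray:
    """Per-field diffusion/dispersion coefficients in field order.

    The ECM does not diffuse (purely hyperbolic transport).
    """
    by_name = {
        "T": params.D_T, "V": params.D_V, "P": params.D_P,
        "uPR": params.D_uPR, "uPi": params.D_uP, "uPa": params.D_uP,
        "PA": params.D_PA, "q": params.D_q, "p": params.D_p,
        "M": params.D_M, "E": params.D_E, "f": params.D_f, "C": params.D_C,
        "w": params.D_w, "Q": params.D_Q, "Qr": params.D_Qr, "rho": 0.0,
    }
    return np.array([by_name[n] for n in FIELD_NAMES])


# ---------------------------------------------------------------------------
# Hypoxia modulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HypoxiaRule:
    """Linear ramp below the hypoxic threshold, plateau above it."""

    threshold: float  # w_h, g/cm^3
    plateau: float  # per day

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("hypoxia threshold must be positive")


def hypoxia_factor(w, rule: HypoxiaRule):
    """plateau * min(w / w_h, 1); continuous and nondecreasing in w."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("oxygen concentration must be nonnegative")
    out = rule.plateau * np.minimum(w / rule.threshold, 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Reaction terms
# ---------------------------------------------------------------------------


def reaction_terms(
    state: StateFields, params: ParameterSet, *, check: bool = True
) -> Tuple[np.ndarray, np.ndarray]:
    """Split reaction right-hand sides into (production, loss_rate).

    The rate for field i is ``production[i] - loss_rate[i] * X[i]`` with
    ``loss_rate >= 0``; signed per-capita growth (cancer-cell and
    endothelial logistic terms) is routed to whichever side keeps the loss
    coefficient nonnegative.  This split is what makes the stiff MMP/TIMP
    mutual-depletion terms tractable for the semi-implicit reaction update.
    """
    if check:
        state.validate()
    p_ = params
    n = state.n_nodes
    prod = np.zeros((len(FIELD_NAMES), n))
    loss = np.zeros((len(FIELD_NAMES), n))

    T = state["T"]; V = state["V"]; P = state["P"]; uPR = state["uPR"]
    uPi = state["uPi"]; uPa = state["uPa"]; PA = state["PA"]
    q = state["q"]; pp = state["p"]; M = state["M"]; E = state["E"]
    f = state["f"]; C = state["C"]; w = state["w"]; Q = state["Q"]
    Qr = state["Qr"]; rho = state["rho"]

    def put(name, production, loss_rate):
        i = FIELD_INDEX[name]
        prod[i] = production
        loss[i] = loss_rate

    put("T", p_.A_T + p_.lam_TC * C, p_.d_T)
    put(
        "V",
        p_.lam_VC * C * (1.0 + p_.lam_VT * T / (p_.K_T + T)) + p_.lam_VM * M,
        p_.d_V,
    )
    put("P", p_.lam_P * (1.0 + p_.lam_Pu * uPa / (p_.K_PA + PA)), p_.d_P)
    put("uPR", p_.lam_uPRM * M + p_.lam_uPRC * C, p_.d_uPR)
    put("uPi", p_.lam_uf * f, p_.d_uPi)
    put("uPa", p_.lam_u * uPi * uPR / (p_.K_uPR + uPR), p_.d_uPa)
    put("PA", p_.lam_PC * C + p_.lam_Pf * f + p_.lam_PM * M, p_.d_PA)
    put("q", p_.lam_qC * C, p_.d_q)

    lam_p_w = hypoxia_factor(w, HypoxiaRule(p_.w_h, p_.lam_p))
    put("p", lam_p_w * q / (p_.q0 + q) * M, p_.d_p)

    put("M", p_.beta * pp / (p_.K_p + pp) * p_.M0, p_.d_M)

    # endothelial logistic growth gated by the VEGF threshold; the
    # per-capita rate can turn negative above the carrying capacity
    g_E = p_.lam_E * (1.0 - E / p_.K_E) * np.maximum(V - p_.V0, 0.0)
    put("E", np.maximum(g_E, 0.0) * E, p_.d_E + np.maximum(-g_E, 0.0))

    put("f", p_.A_f + p_.lam_fC * f * C / (p_.K_C + C), p_.d_f)

    lam_C_w = hypoxia_factor(w, HypoxiaRule(p_.w_h, p_.lam_wC))
    g_C = (
        lam_C_w
        + p_.lam_Cf * f / (p_.K_f + f)
        + p_.lam_CuP * (uPa / (p_.K_PA + PA)) * (uPR / (p_.K_uPR + uPR))
    ) * (1.0 - C / p_.C0)
    put("C", np.maximum(g_C, 0.0) * C, p_.d_C + np.maximum(-g_C, 0.0))

    put("w", p_.lam_w * E, p_.d_wM * M + p_.d_wC * C + p_.d_wf * f)
    put(
        "Q",
        p_.lam_QM * M * (1.0 + p_.lam_QP * P / (p_.K_P + P)),
        p_.d_QQr * Qr + p_.d_Q,
    )
    put("Qr", p_.lam_QrM * M, p_.d_QrQ * Q + p_.d_Qr)
    put(
        "rho",
        p_.lam_rhof * f * np.maximum(1.0 - rho / p_.rho0, 0.0),
        p_.d_rho + p_.d_rhoQ * Q,
    )
    return prod, loss


def reaction_rates(
    state: StateFields, params: ParameterSet, *, check: bool = True
) -> np.ndarray:
    """Non-transport right-hand side per field, shape (17, N), g/cm^3/day."""
    prod, loss = reaction_terms(state, params, check=check)
    return prod - loss * state.data


# ---------------------------------------------------------------------------
# Chemotaxis and velocity
# ---------------------------------------------------------------------------


def chemotaxis_flux_divergence(
    carrier: np.ndarray, attractant: np.ndarray, chi: float, mesh: MovingMesh
) -> np.ndarray:
    """Literal chemotaxis term -div(chi grad(attractant)) = -chi * lap.

    The printed flux has the bare coefficient inside the divergence (no
    carrier density factor), so the carrier enters only through the shape
    check; zero at a uniform attractant and linear in chi.
    """
    carrier = np.asarray(carrier, dtype=float)
    attractant = np.asarray(attractant, dtype=float)
    if carrier.shape != attractant.shape or carrier.shape != mesh.r.shape:
        raise MeshMismatchError("carrier/attractant/mesh node counts differ")
    return -chi * radial_laplacian(attractant, mesh)


def chemotaxis_terms(
    state: StateFields, params: ParameterSet, mesh: MovingMesh
) -> Dict[str, np.ndarray]:
    """Chemotaxis contributions: macrophages follow MCP-1, endothelial
    cells follow VEGF (one shared coefficient chi_C)."""
    return {
        "M": chemotaxis_flux_divergence(state["M"], state["p"], params.chi_C, mesh),
        "E": chemotaxis_flux_divergence(state["E"], state["V"], params.chi_C, mesh),
    }


def velocity_source(
    state: StateFields, params: ParameterSet, mesh: MovingMesh
) -> np.ndarray:
    """div(u) * total_density: reaction + chemotaxis of the five advected
    species minus the common cell dispersion applied to the ECM.

    Summing the cell equations under the constant-total-density constraint
    turns the sum of their dispersion terms into -D * lap(rho).
    """
    rates = reaction_rates(state, params)
    chemo = chemotaxis_terms(state, params, mesh)
    S = np.zeros(state.n_nodes)
    for name in ADVECTED_FIELDS:
        S += rates[FIELD_INDEX[name]]
    S += chemo["M"] + chemo["E"]
    S -= params.D_C * radial_laplacian(state["rho"], mesh)
    return S


def velocity_from_source(
    S: np.ndarray, mesh: MovingMesh, total_density: float = 1.0
) -> np.ndarray:
    """Solve div(u) = S / total_density for the radial velocity.

    u(r) = (1 / (c r^2)) * integral_0^r s^2 S(s) ds with u(0) = 0 by
    symmetry.  S is treated as piecewise linear on the nodes and the moment
    integral taken exactly, which keeps the near-origin velocity accurate
    (plain trapezoid on s^2 S is badly biased there).
    """
    r = mesh.r
    S = np.asarray(S, dtype=float) / total_density
    a, b = r[:-1], r[1:]
    Sa, Sb = S[:-1], S[1:]
    slope = (Sb - Sa) / (b - a)
    m2 = (b**3 - a**3) / 3.0
    m3 = (b**4 - a**4) / 4.0
    increments = Sa * m2 + slope * (m3 - a * m2)
    u = np.empty_like(r)
    u[0] = 0.0
    u[1:] = np.cumsum(increments) / r[1:] ** 2
    return u


def velocity_field(
    state: StateFields,
    params: ParameterSet,
    mesh: MovingMesh,
    total_density: float = 1.0,
) -> np.ndarray:
    """Radial velocity (cm/day) from the total-density constraint."""
    return velocity_from_source(velocity_source(state, params, mesh), mesh, total_density)


def divergence_of_velocity(u: np.ndarray, mesh: MovingMesh) -> np.ndarray:
    """div(u) = u_r + 2 u / r in radial coordinates; 3 u_r(0) at the origin."""
    r = mesh.r
    u = np.asarray(u, dtype=float)
    du = first_derivative(u, mesh)
    out = np.empty_like(u)
    out[1:] = du[1:] + 2.0 * u[1:] / r[1:]
    # u(0) = 0, so u_r(0) is finite and div -> 3 u_r(0)
    out[0] = 3.0 * (u[1] - u[0]) / r[1]
    return out


# ---------------------------------------------------------------------------
# Boundary behaviour
# ---------------------------------------------------------------------------


def robin_boundary(state: StateFields, params: ParameterSet) -> Dict[str, float]:
    """Flux coefficients for oxygen and endothelial cells at r = R.

    alpha_w = alpha_w~ * E / (K_E + E) and alpha_E = alpha_E~ * V / (K_V + V),
    both evaluated at the boundary node.  The flux condition
    dX/dn + alpha_X (X - X0)^+ = 0 only acts when X exceeds its vascular
    level X0; every other diffusing species gets zero flux, and the ECM
    carries no boundary condition at all.
    """
    E_b = float(state["E"][-1])
    V_b = float(state["V"][-1])
    return {
        "w": params.alpha_w * E_b / (params.K_E + E_b),
        "E": params.alpha_E * V_b / (params.K_V + V_b),
    }


def free_boundary_rate(state: StateFields, mesh: MovingMesh) -> float:
    """dR/dt = u(R, t): the boundary moves with the outermost node."""
    if state.u.shape != mesh.r.shape:
        raise MeshMismatchError("velocity and mesh node counts differ")
    return float(state.u[-1])
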
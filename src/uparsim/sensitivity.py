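"""Latin hypercube screening of production parameters with PRCC readout.

The design stratifies each parameter into n equal-probability uniform bins
with exactly one draw per bin and an independent permutation per column.
The readout (tumor radius at the readout day) is rank-transformed together
with the sample matrix, and each parameter's partial rank correlation
coefficient is the correlation of the two residual vectors after linearly
regressing out all other parameters' ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .parameters import ParameterSet

__all__ = [
    "PRODUCTION_PARAMETERS",
    "SensitivityDesign",
    "SensitivityResult",
    "latin_hypercube",
    "prcc",
    "run_sensitivity",
    "default_design",
]

#: the production/activation-rate entries of the parameter table
PRODUCTION_PARAMETERS: Tuple[str, ...] = (
    "A_T", "lam_TC", "lam_VC", "lam_VT", "lam_VM", "lam_P", "lam_Pu",
    "lam_uPRM", "lam_uPRC", "lam_uf", "lam_u", "lam_PC", "lam_Pf", "lam_PM",
    "lam_qC", "lam_p", "lam_E", "A_f", "lam_fC", "beta", "lam_Cf", "lam_CuP",
    "lam_wC", "lam_w", "lam_QM", "lam_QP", "lam_QrM", "lam_rhof",
)


@dataclass(frozen=True)
class SensitivityDesign:
    """Sampled parameters, their uniform ranges, sample count and seed."""

    names: Tuple[str, ...]
    lows: np.ndarray
    highs: np.ndarray
    n_samples: int
    seed: int = 0
    readout_day: float = 600.0

    def __post_init__(self) -> None:
        lows = np.asarray(self.lows, dtype=float)
        highs = np.asarray(self.highs, dtype=float)
        object.__setattr__(self, "lows", lows)
        object.__setattr__(self, "highs", highs)
        object.__setattr__(self, "names", tuple(self.names))
        k = len(self.names)
        if lows.shape != (k,) or highs.shape != (k,):
            raise ValueError("range arrays must match the number of parameters")
        if np.any(lows <= 0) or np.any(highs <= lows):
            raise ValueError("ranges must be positive with low < high")
        if self.n_samples < 2 + k:
            raise ValueError(
                f"need at least {2 + k} samples for {k} parameters"
            )

    @property
    def k(self) -> int:
        return len(self.names)


def default_design(
    params: ParameterSet,
    n_samples: int = 1000,
    seed: int = 0,
    readout_day: float = 600.0,
    names: Optional[Sequence[str]] = None,
    spread: float = 0.5,
) -> SensitivityDesign:
    """Uniform +-spread ranges around the baseline production parameters."""
    names = tuple(names if names is not None else PRODUCTION_PARAMETERS)
    base = np.array([getattr(params, n) for n in names])
    return SensitivityDesign(
        names=names,
        lows=(1.0 - spread) * base,
        highs=(1.0 + spread) * base,
        n_samples=n_samples,
        seed=seed,
        readout_day=readout_day,
    )


def latin_hypercube(design: SensitivityDesign) -> np.ndarray:
    """Stratified (n, k) sample matrix, deterministic given the seed."""
    rng = np.random.default_rng(design.seed)
    n, k = design.n_samples, design.k
    samples = np.empty((n, k))
    for j in range(k):
        perm = rng.permutation(n)
        jitter = rng.uniform(size=n)
        unit = (perm + jitter) / n
        samples[:, j] = design.lows[j] + unit * (design.highs[j] - design.lows[j])
    return samples


@dataclass
class SensitivityResult:
    """Per-parameter PRCC and p-value plus the raw design realization."""

    names: Tuple[str, ...]
    prcc: np.ndarray
    p_values: np.ndarray
    samples: np.ndarray
    readout: np.ndarray
    n_failed: int = 0
    unreliable: bool = False
    excluded: Tuple[str, ...] = ()

    def ranking(self) -> List[Tuple[str, float, float]]:
        """(name, prcc, p) sorted by signed PRCC, most positive first."""
        order = np.argsort(-self.prcc)
        return [
            (self.names[i], float(self.prcc[i]), float(self.p_values[i]))
            for i in order
        ]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": list(self.names),
                "prcc": self.prcc,
                "p_value": self.p_values,
            }
        ).sort_values("prcc", ascending=False, ignore_index=True)


def _residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, X] by least squares."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ coef


def prcc(
    samples: np.ndarray,
    readout: np.ndarray,
    names: Optional[Sequence[str]] = None,
) -> SensitivityResult:
    """Partial rank correlation of each sample column with the readout.

    p-values use the t statistic prcc * sqrt((n-2-k) / (1-prcc^2)) with
    n-2-k degrees of freedom, k the number of sampled parameters.
    Rank-deficient regressor blocks flag the offending parameter, which is
    excluded with a warning (PRCC/p set to NaN).
    """
    samples = np.asarray(samples, dtype=float)
    readout = np.asarray(readout, dtype=float)
    n, k = samples.shape
    if readout.shape != (n,):
        raise ValueError("readout length must match the number of samples")
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 samples (n={n}, k={k})")
    names = tuple(names if names is not None else (f"x{j}" for j in range(k)))

    rank_x = np.column_stack([stats.rankdata(samples[:, j]) for j in range(k)])
    rank_y = stats.rankdata(readout)

    coeffs = np.full(k, np.nan)
    pvals = np.full(k, np.nan)
    excluded: List[str] = []
    dof = n - 2 - k
    for j in range(k):
        others = np.delete(rank_x, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        if np.linalg.matrix_rank(A) < A.shape[1]:
            warnings.warn(
                f"parameter {names[j]!r}: rank-deficient co-regressors, excluded",
                stacklevel=2,
            )
            excluded.append(names[j])
            continue
        rx = _residuals(rank_x[:, j], others)
        ry = _residuals(rank_y, others)
        denom = np.linalg.norm(rx) * np.linalg.norm(ry)
        if denom == 0.0:
            excluded.append(names[j])
            warnings.warn(
                f"parameter {names[j]!r}: degenerate residuals, excluded",
                stacklevel=2,
            )
            continue
        r = float(np.dot(rx, ry) / denom)
        r = float(np.clip(r, -1.0, 1.0))
        coeffs[j] = r
        if abs(r) >= 1.0:
            pvals[j] = 0.0
        else:
            t = r * np.sqrt(dof / (1.0 - r**2))
            pvals[j] = 2.0 * stats.t.sf(abs(t), dof)
    return SensitivityResult(
        names=names,
        prcc=coeffs,
        p_values=pvals,
        samples=samples,
        readout=readout,
        excluded=tuple(excluded),
    )


def run_sensitivity(
    params: ParameterSet,
    design: SensitivityDesign,
    solver_options=None,
    R0: float = 0.01,
) -> SensitivityResult:
    """Simulate per LHS sample and correlate R(readout_day) with each rate.

    Failed (blown-up) runs are dropped; more than 10% failures marks the
    result unreliable.
    """
    from . import solver

    for name in design.names:
        if not hasattr(params, name):
            raise ValueError(f"design targets unknown parameter {name!r}")

    if solver_options is None:
        # reduced fidelity: screening needs ranks, not converged magnitudes
        solver_options = solver.SolverOptions(
            n_nodes=32, tau=0.02, output_every=design.readout_day
        )
    solver_options = solver_options.replace(
        t_end=design.readout_day, output_every=solver_options.output_every
    )

    samples = latin_hypercube(design)
    readout = np.full(design.n_samples, np.nan)
    for i in range(design.n_samples):
        overrides = dict(zip(design.names, samples[i]))
        try:
            traj = solver.simulate(R0, params.replace(**overrides), solver_options)
            readout[i] = traj.R[-1]
        except (solver.BlowUpError, solver.MeshError):
            continue

    ok = np.isfinite(readout)
    n_failed = int((~ok).sum())
    result = prcc(samples[ok], readout[ok], names=design.names)
    result.n_failed = n_failed
    result.unreliable = n_failed > 0.1 * design.n_samples
    if result.unreliable:
        warnings.warn(
            f"{n_failed}/{design.n_samples} simulations failed; "
            "sensitivity result marked unreliable",
            stacklevel=2,
        )
    return result
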
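"""Radial moving mesh and nonuniform finite-difference stencils.

The mesh is a monotone set of radii 0 = r_0 < ... < r_N = R(t) whose nodes
are advected with the tissue velocity; the free boundary is the outermost
node.  Derivatives use three-point stencils written for the signed spacings
h_-1 = r_{i-1} - r_i (< 0) and h_1 = r_{i+1} - r_i (> 0), which are exact on
quadratics and reduce to central differences on a uniform mesh.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "MovingMesh",
    "MeshError",
    "nonuniform_derivatives",
    "first_derivative",
    "second_derivative",
    "radial_laplacian",
]


class MeshError(ValueError):
    """Degenerate or non-monotone mesh."""


@dataclass(frozen=True)
class MovingMesh:
    """Monotone radial node set with the free boundary at the last node."""

    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        if r.ndim != 1 or r.size < 3:
            raise MeshError("mesh needs at least 3 nodes")
        if r[0] != 0.0:
            raise MeshError("first node must sit at r = 0")
        if not np.all(np.diff(r) > 0):
            raise MeshError("mesh nodes must be strictly increasing")

    @classmethod
    def uniform(cls, n_nodes: int, R: float) -> "MovingMesh":
        if R <= 0:
            raise MeshError(f"outer radius must be positive, got {R!r}")
        return cls(np.linspace(0.0, R, n_nodes))

    @property
    def R(self) -> float:
        """Free-boundary radius (cm)."""
        return float(self.r[-1])

    @property
    def n_nodes(self) -> int:
        return self.r.size

    @property
    def min_spacing(self) -> float:
        return float(np.diff(self.r).min())

    def moved(self, velocity: np.ndarray, tau: float) -> "MovingMesh":
        """Advect nodes by velocity*tau (the origin never moves)."""
        v = np.asarray(velocity, dtype=float)
        if v.shape != self.r.shape:
            raise MeshError("velocity and mesh node counts differ")
        r_new = self.r + tau * v
        r_new[0] = 0.0
        if not np.all(np.diff(r_new) > 0):
            raise MeshError("mesh tangled: node crossing after advection")
        return MovingMesh(r_new)


def nonuniform_derivatives(
    values: np.ndarray, mesh: MovingMesh, i: int
) -> Tuple[float, float]:
    """(X_r, X_rr) at interior node i from the three-point stencils.

    X_r  = [h_-1^2 X_{i+1} - h_1^2 X_{i-1} + (h_1^2 - h_-1^2) X_i]
           / [h_1 (h_-1^2 - h_1 h_-1)]
    X_rr = 2 [h_-1 X_{i+1} - h_1 X_{i-1} + (h_1 - h_-1) X_i]
           / [h_1 (h_1 h_-1 - h_-1^2)]

    with the signed spacings h_-1 = r_{i-1} - r_i and h_1 = r_{i+1} - r_i.
    """
    r = mesh.r
    if not 0 < i < r.size - 1:
        raise IndexError(f"node {i} is not interior")
    hm = r[i - 1] - r[i]
    h1 = r[i + 1] - r[i]
    if h1 == 0.0 or hm == 0.0:
        raise MeshError("degenerate spacing at node %d" % i)
    x_m, x_0, x_p = values[i - 1], values[i], values[i + 1]
    x_r = (hm**2 * x_p - h1**2 * x_m + (h1**2 - hm**2) * x_0) / (
        h1 * (hm**2 - h1 * hm)
    )
    x_rr = 2.0 * (hm * x_p - h1 * x_m + (h1 - hm) * x_0) / (
        h1 * (h1 * hm - hm**2)
    )
    return float(x_r), float(x_rr)


def _interior_derivatives(
    values: np.ndarray, r: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized (X_r, X_rr) at nodes 1..N-1.  values may be (..., N)."""
    hm = r[:-2] - r[1:-1]
    h1 = r[2:] - r[1:-1]
    x_m = values[..., :-2]
    x_0 = values[..., 1:-1]
    x_p = values[..., 2:]
    denom_r = h1 * (hm**2 - h1 * hm)
    denom_rr = h1 * (h1 * hm - hm**2)
    x_r = (hm**2 * x_p - h1**2 * x_m + (h1**2 - hm**2) * x_0) / denom_r
    x_rr = 2.0 * (hm * x_p - h1 * x_m + (h1 - hm) * x_0) / denom_rr
    return x_r, x_rr


def _onesided_end(values: np.ndarray, r: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Quadratic-fit first and second derivative at the last node."""
    a, b, c = r[-3], r[-2], r[-1]
    xa = values[..., -3]
    xb = values[..., -2]
    xc = values[..., -1]
    d1 = (
        xa * (c - b) / ((a - b) * (a - c))
        + xb * (c - a) / ((b - a) * (b - c))
        + xc * (2 * c - a - b) / ((c - a) * (c - b))
    )
    d2 = 2.0 * (
        xa / ((a - b) * (a - c))
        + xb / ((b - a) * (b - c))
        + xc / ((c - a) * (c - b))
    )
    return d1, d2


def first_derivative(values: np.ndarray, mesh: MovingMesh) -> np.ndarray:
    """d/dr on the whole mesh; X_r(0) = 0 by radial symmetry."""
    r = mesh.r
    out = np.empty_like(np.asarray(values, dtype=float))
    out[..., 1:-1], _ = _interior_derivatives(values, r)
    out[..., 0] = 0.0
    out[..., -1], _ = _onesided_end(values, r)
    return out


def second_derivative(values: np.ndarray, mesh: MovingMesh) -> np.ndarray:
    r = mesh.r
    out = np.empty_like(np.asarray(values, dtype=float))
    _, out[..., 1:-1] = _interior_derivatives(values, r)
    # symmetry ghost X(-r_1) = X(r_1)
    out[..., 0] = 2.0 * (values[..., 1] - values[..., 0]) / r[1] ** 2
    _, out[..., -1] = _onesided_end(values, r)
    return out


def radial_laplacian(values: np.ndarray, mesh: MovingMesh) -> np.ndarray:
    """X_rr + (2/r) X_r with the symmetry limit 3 X_rr at the origin."""
    r = mesh.r
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    x_r, x_rr = _interior_derivatives(values, r)
    out[..., 1:-1] = x_rr + 2.0 * x_r / r[1:-1]
    # L'Hopital: lap(0) = 3 X_rr(0); with the symmetric ghost node this is
    # 6 (X_1 - X_0) / r_1^2
    out[..., 0] = 6.0 * (values[..., 1] - values[..., 0]) / r[1] ** 2
    d1, d2 = _onesided_end(values, r)
    out[..., -1] = d2 + 2.0 * d1 / r[-1]
    return out
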
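"""Boundary traces of dipole test functions.

The Factorization Method tests each sampling point z with the boundary
trace of the dipole function Φ_{z,d}: the solution of

    ∇·σ₀∇Φ_{z,d} = d·∇δ_z in Ω,     σ₀ ∂_ν Φ_{z,d}|_{∂Ω} = 0,

where the distributional derivative is taken in x.  For the homogeneous
unit disk the trace has the closed form (image/Neumann-function
construction)

    Φ_{z,d}(x(θ))|_{|x|=1} = (1/π) · d·(x(θ) − z) / |x(θ) − z|²  + const,

and for a conductivity that is constant near z it is computed by a
mollified FEM solve: the dipole source is realized weakly as
∫ ψ_ε(x − z) d·∇w dx with a compactly supported radial bump ψ_ε, which
keeps the zero-total-flux compatibility exact.  Traces are always
mean-subtracted on Σ before projection (the PDE only fixes Φ up to an
additive constant).

Sign convention: with the x-derivative reading of the source, the
closed form above carries a + sign; the mollified FEM construction
reproduces it, which fixes the global sign once for the package.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .boundary_forward import (
    BoundaryBasis,
    BoundaryFunction,
    ConductivityField,
    FemSystem,
    TriangleMesh,
    homogeneous_field,
    project_trace,
)

__all__ = ["DipoleTrace", "dipole_trace_disk", "dipole_trace_numeric",
           "disk_dipole_provider", "fem_dipole_provider"]

logger = logging.getLogger("fmeit.dipole")


@dataclass
class DipoleTrace:
    """Boundary trace of Φ_{z,d} as coefficients in the active basis."""

    z: np.ndarray
    d: np.ndarray
    coefficients: BoundaryFunction

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).reshape(2)
        self.d = np.asarray(self.d, dtype=float).reshape(2)
        if abs(np.linalg.norm(self.d) - 1.0) > 1e-12:
            raise ValueError("dipole direction must be a unit vector")
        if np.hypot(*self.z) >= 1.0:
            raise ValueError("dipole point must lie strictly inside the domain")


def _normalize_direction(d) -> np.ndarray:
    d = np.asarray(d, dtype=float).reshape(2)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("dipole direction must be nonzero")
    return d / n


def dipole_trace_disk(z, d, basis: BoundaryBasis) -> DipoleTrace:
    """Closed-form dipole trace on the homogeneous unit disk (σ₀ = 1)."""
    z = np.asarray(z, dtype=float).reshape(2)
    if np.hypot(*z) >= 1.0:
        raise ValueError("dipole point must lie strictly inside the unit disk")
    d = _normalize_direction(d)
    theta = basis.nodes
    x = np.column_stack([np.cos(theta), np.sin(theta)])
    diff = x - z[None, :]
    vals = (diff @ d) / np.sum(diff * diff, axis=1) / np.pi
    return DipoleTrace(z, d, project_trace(vals, basis))


def _bump_values(pts: np.ndarray, z: np.ndarray, eps: float) -> np.ndarray:
    """Radial bump ψ_ε(x−z) = (4/πε²)(1 − |x−z|²/ε²)³ on its support."""
    r2 = np.sum((pts - z[None, :]) ** 2, axis=-1) / eps**2
    out = np.zeros(r2.shape)
    inside = r2 < 1.0
    out[inside] = (4.0 / (np.pi * eps**2)) * (1.0 - r2[inside]) ** 3
    return out


# degree-5 symmetric 7-point triangle quadrature (barycentric, weights sum to 1)
_TRI_QP = np.array([
    [1 / 3, 1 / 3, 1 / 3],
    [0.059715871789770, 0.470142064105115, 0.470142064105115],
    [0.470142064105115, 0.059715871789770, 0.470142064105115],
    [0.470142064105115, 0.470142064105115, 0.059715871789770],
    [0.797426985353087, 0.101286507323456, 0.101286507323456],
    [0.101286507323456, 0.797426985353087, 0.101286507323456],
    [0.101286507323456, 0.101286507323456, 0.797426985353087],
])
_TRI_QW = np.array([0.225,
                    0.132394152788506, 0.132394152788506, 0.132394152788506,
                    0.125939180544827, 0.125939180544827, 0.125939180544827])


def dipole_trace_numeric(mesh: TriangleMesh, sigma0, z, d,
                         eps: float | None = None,
                         system: FemSystem | None = None,
                         basis: BoundaryBasis | None = None) -> DipoleTrace:
    """Mollified-FEM dipole trace for σ₀ locally constant around z.

    The right-hand side d·∇δ_z is replaced by the directional derivative of
    a compactly supported bump of width ``eps`` (default 2h), applied weakly
    as  b_j = ∫ ψ_ε(x−z) d·∇φ_j dx.  Requirements checked: the mollifier
    support stays inside the domain and σ₀ is constant on it.
    """
    z = np.asarray(z, dtype=float).reshape(2)
    d = _normalize_direction(d)
    if eps is None:
        eps = 2.0 * mesh.h
    if system is not None:
        fem = system
    else:
        if basis is None:
            raise ValueError("either a FemSystem or a basis must be supplied")
        fem = FemSystem(mesh, sigma0, basis)
    if np.hypot(*z) >= 1.0:
        raise ValueError("dipole point lies outside the mesh interior")
    if np.hypot(*z) + eps >= 1.0 - 1e-12:
        raise ValueError("mollifier support touches the domain boundary")

    # triangles meeting the mollifier support (centroid within eps + circumscale)
    dist = np.hypot(*(mesh.centroids - z[None, :]).T)
    near = dist <= eps + 2.0 * mesh.h
    if not np.any(near):
        raise ValueError("dipole point lies outside the mesh interior")
    sig_near = fem.sigma_tri[dist <= eps]
    if len(sig_near) and (sig_near.max() - sig_near.min()) > 1e-12 * sig_near.max():
        raise ValueError("conductivity is not constant on the mollifier support")

    tris = np.flatnonzero(near)
    t = mesh.triangles[tris]
    verts = mesh.vertices
    # quadrature points: (n_tri, n_qp, 2)
    qp = np.einsum("qk,nkx->nqx", _TRI_QP, verts[t])
    psi = _bump_values(qp, z, eps)                       # (n_tri, n_qp)
    wpsi = np.einsum("q,nq->n", _TRI_QW, psi) * mesh.areas[tris]  # ∫_T ψ
    # ∇φ_j is constant per triangle, so ∫_T ψ d·∇φ_j = (∫_T ψ)(d·∇φ_j|_T)
    dgrad = np.einsum("nke,e->nk", mesh.grads[tris], d)  # (n_tri, 3)
    b = np.zeros(mesh.n_vertices)
    np.add.at(b, t.ravel(), (wpsi[:, None] * dgrad).ravel())

    u = fem.solve_rhs(b)
    trace = fem.trace_project(u)
    return DipoleTrace(z, d, trace)


def disk_dipole_provider(basis: BoundaryBasis):
    """Provider (z, d) ↦ DipoleTrace using the closed form (σ₀ = 1)."""
    def provider(z, d) -> DipoleTrace:
        return dipole_trace_disk(z, d, basis)
    return provider


def fem_dipole_provider(mesh: TriangleMesh, sigma0, basis: BoundaryBasis,
                        eps: float | None = None):
    """Provider (z, d) ↦ DipoleTrace via mollified FEM; reuses one factorization."""
    if sigma0 is None:
        sigma0 = homogeneous_field(1.0)
    fem = FemSystem(mesh, sigma0, basis)

    def provider(z, d) -> DipoleTrace:
        return dipole_trace_numeric(mesh, sigma0, z, d, eps=eps, system=fem)
    return provider
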
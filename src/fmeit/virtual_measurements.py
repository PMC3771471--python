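"""Virtual measurement operator L_D, its adjoint, and region Gram matrices.

For a region D ⊆ Ω and background conductivity σ₀, the virtual
measurement operator maps an interior vector field F ∈ L²(D)² to the
boundary trace v|_Σ of the grounded solution of

    ∫_Ω σ₀ ∇v·∇w dx = ∫_D F·∇w dx     for all test functions w.

Its adjoint restricts the gradient of the background potential to D:
L_D* g = ∇u₀^g |_D.  The Gram matrix M_E of L_E L_E* represents the
quadratic form g ↦ ∫_E |∇u₀^g|² dx on the boundary basis; it is the
positive-semidefinite shift used by the indefinite variant of the
Factorization Method.

Regions are resolved to whole triangles: a triangle belongs to the
region iff its centroid does (deterministic, exact for piecewise
constant data).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boundary_forward import (
    BoundaryBasis,
    BoundaryFunction,
    FemSystem,
    TriangleMesh,
)

__all__ = ["RegionMask", "VirtualGram", "apply_LD", "apply_LD_star",
           "assemble_virtual_gram"]

logger = logging.getLogger("fmeit.virtual_measurements")


@dataclass
class RegionMask:
    """Subregion of Ω given as a shape list or a per-triangle boolean mask."""

    shapes: tuple = None            # sequence of objects with .contains(points)
    triangle_mask: np.ndarray = None
    description: str = ""

    @classmethod
    def from_shapes(cls, shapes: Sequence, description: str = "") -> "RegionMask":
        return cls(shapes=tuple(shapes), triangle_mask=None,
                   description=description or f"{len(shapes)} shapes")

    @classmethod
    def from_mask(cls, mask: np.ndarray, description: str = "") -> "RegionMask":
        return cls(shapes=None, triangle_mask=np.asarray(mask, dtype=bool),
                   description=description or "triangle mask")

    @classmethod
    def empty(cls) -> "RegionMask":
        return cls(shapes=(), triangle_mask=None, description="empty")

    def on_mesh(self, mesh: TriangleMesh) -> np.ndarray:
        """Per-triangle boolean mask (centroid-in-region rule)."""
        if self.triangle_mask is not None:
            if self.triangle_mask.shape != (mesh.n_triangles,):
                raise ValueError("triangle mask does not match mesh triangle count")
            return self.triangle_mask
        mask = np.zeros(mesh.n_triangles, dtype=bool)
        for shape in self.shapes or ():
            mask |= np.asarray(shape.contains(mesh.centroids), dtype=bool)
        return mask

    def area(self, mesh: TriangleMesh) -> float:
        return float(mesh.areas[self.on_mesh(mesh)].sum())


@dataclass
class VirtualGram:
    """Symmetric PSD K×K matrix of the quadratic form g ↦ ∫_E |∇u₀^g|²."""

    matrix: np.ndarray
    basis: BoundaryBasis
    region: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float)
        if A.shape != (self.basis.order, self.basis.order):
            raise ValueError("Gram matrix shape does not match basis order")
        nrm = np.linalg.norm(A)
        if nrm > 0:
            if np.linalg.norm(A - A.T) > 1e-10 * nrm:
                raise ValueError("Gram matrix is not symmetric")
            if np.linalg.eigvalsh(A).min() < -1e-10 * nrm:
                raise ValueError("Gram matrix is not positive semidefinite")
        self.matrix = 0.5 * (A + A.T)


def apply_LD(mesh: TriangleMesh, sigma0, D: RegionMask, F: np.ndarray,
             basis: BoundaryBasis, system: FemSystem | None = None) -> BoundaryFunction:
    """Apply the virtual measurement operator to a per-triangle field F on D.

    ``F`` has shape (n_triangles, 2) and must vanish outside D.
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (mesh.n_triangles, 2):
        raise ValueError("F must be a per-triangle 2-vector field on the mesh")
    mask = D.on_mesh(mesh)
    if np.any(F[~mask] != 0):
        raise ValueError("F is nonzero on triangles outside D")
    fem = system if system is not None else FemSystem(mesh, sigma0, basis)
    # b_j = Σ_{T∈D} A_T F_T·∇φ_j|_T
    tris = np.flatnonzero(mask)
    contrib = np.einsum("nke,ne->nk", mesh.grads[tris], F[tris]) * mesh.areas[tris, None]
    b = np.zeros(mesh.n_vertices)
    np.add.at(b, mesh.triangles[tris].ravel(), contrib.ravel())
    v = fem.solve_rhs(b)
    return fem.trace_project(v)


def apply_LD_star(mesh: TriangleMesh, sigma0, D: RegionMask, g: BoundaryFunction,
                  system: FemSystem | None = None) -> np.ndarray:
    """Adjoint: the background-potential gradient restricted to D.

    Returns a (n_triangles, 2) array that is zero outside D.
    """
    fem = system if system is not None else FemSystem(mesh, sigma0, g.basis)
    u0 = fem.solve_current(g)
    grad = u0.gradient()
    grad[~D.on_mesh(mesh)] = 0.0
    return grad


def assemble_virtual_gram(mesh: TriangleMesh, sigma0, E: RegionMask,
                          basis: BoundaryBasis,
                          system: FemSystem | None = None) -> VirtualGram:
    """Dense K×K Gram matrix of L_E L_E* on the boundary basis."""
    if basis.order < 1:
        raise ValueError("empty basis")
    fem = system if system is not None else FemSystem(mesh, sigma0, basis)
    mask = E.on_mesh(mesh)
    if not np.any(mask):
        M = np.zeros((basis.order, basis.order))
    else:
        U = fem.solve_basis_currents()
        tris = np.flatnonzero(mask)
        # per-triangle gradients of all K background potentials: (n_tris, 2, K)
        G = np.einsum("nke,nkj->nej", mesh.grads[tris], U[mesh.triangles[tris]])
        M = np.einsum("n,nej,nei->ji", mesh.areas[tris], G, G)
        M = 0.5 * (M + M.T)
    prov = {"mesh_h": mesh.h, "region": E.description,
            "region_area": E.area(mesh), "sigma0": fem.description}
    return VirtualGram(M, basis, region=E.description, provenance=prov)
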
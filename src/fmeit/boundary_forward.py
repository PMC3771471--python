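"""Continuum-model EIT forward problem on the unit disk.

This module discretizes the zero-mean boundary-current space L^2_⋄(Σ),
solves the Neumann conductivity problem

    ∇·σ∇u = 0 in Ω,   σ ∂_ν u = g on Σ (0 elsewhere),   ∫_{∂Ω} u ds = 0,

with piecewise-linear finite elements, and assembles discrete
Neumann-to-Dirichlet (NtD) operators  Λ(σ): g ↦ u|_Σ  as symmetric K×K
matrices in an orthonormal trigonometric boundary basis.  Analytic NtD
oracles for the homogeneous disk and for a concentric-disk inclusion are
provided for verification.

Conventions
-----------
* The domain is the unit disk; general smooth domains enter only through
  mesh import (``read_msh``).
* Angles are measured counterclockwise from the positive x-axis; boundary
  arcs are half-open ``[theta_start, theta_end)``.
* The conductivity is evaluated once per triangle, at the centroid, so
  piecewise-constant phantoms are represented exactly and the discrete
  monotonicity identities hold to round-off.
* The pure-Neumann problem is grounded by a single mean-value constraint
  over ∂Ω enforced with a Lagrange multiplier (no pinned vertex).
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import Delaunay

__all__ = [
    "BoundaryArc",
    "BoundaryBasis",
    "BoundaryFunction",
    "TriangleMesh",
    "ConductivityField",
    "PotentialField",
    "NtDOperator",
    "FemSystem",
    "disk_mesh",
    "refine_mesh",
    "write_msh",
    "read_msh",
    "make_boundary_basis",
    "project_trace",
    "solve_neumann",
    "assemble_ntd",
    "ntd_homogeneous_oracle",
    "ntd_concentric_oracle",
    "homogeneous_field",
]

logger = logging.getLogger("fmeit.boundary_forward")

TWO_PI = 2.0 * np.pi


# --------------------------------------------------------------------------
# boundary arc and basis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryArc:
    """Open arc Σ of the unit circle, counterclockwise, half-open."""

    theta_start: float
    theta_end: float

    def __post_init__(self) -> None:
        if not (self.theta_end > self.theta_start):
            raise ValueError("arc must have positive length")
        if self.length > TWO_PI + 1e-12:
            raise ValueError("arc length exceeds the full circle")

    @property
    def length(self) -> float:
        return self.theta_end - self.theta_start

    @property
    def is_full(self) -> bool:
        return abs(self.length - TWO_PI) <= 1e-12

    @classmethod
    def full_circle(cls) -> "BoundaryArc":
        return cls(0.0, TWO_PI)

    def contains(self, theta: np.ndarray | float) -> np.ndarray | bool:
        """Membership of angles in the half-open arc (mod 2π)."""
        t = np.mod(np.asarray(theta, dtype=float) - self.theta_start, TWO_PI)
        out = t < self.length - 1e-14
        # points exactly at the start belong to the arc
        out = out | (np.abs(t) <= 1e-14) | (np.abs(t - TWO_PI) <= 1e-14)
        return out


def _trig_table(theta: np.ndarray, n_funcs: int) -> np.ndarray:
    """Columns [1, cos θ, sin θ, cos 2θ, sin 2θ, ...], n_funcs non-constant ones."""
    cols = [np.ones_like(theta)]
    k = 1
    while len(cols) - 1 < n_funcs:
        cols.append(np.cos(k * theta))
        if len(cols) - 1 < n_funcs:
            cols.append(np.sin(k * theta))
        k += 1
    return np.column_stack(cols)


@dataclass
class BoundaryBasis:
    """Orthonormal, zero-mean basis of the current space on an arc.

    The basis spans mean-subtracted trigonometric polynomials restricted
    to the arc, Gram–Schmidt orthonormalized in the quadrature inner
    product (fixed order: cos before sin, increasing frequency).
    """

    arc: BoundaryArc
    order: int                      # K
    nodes: np.ndarray               # quadrature angles on the arc
    weights: np.ndarray             # quadrature weights (sum = arc length)
    samples: np.ndarray             # (n_nodes, K) basis values at the nodes
    raw_coeffs: np.ndarray          # (K, n_raw) coefficients over the trig table

    def evaluate(self, theta: np.ndarray) -> np.ndarray:
        """Basis values at arbitrary angles, shape (len(theta), K)."""
        theta = np.asarray(theta, dtype=float)
        table = _trig_table(theta, self.raw_coeffs.shape[1] - 1)
        return table @ self.raw_coeffs.T

    def gram(self) -> np.ndarray:
        return (self.samples * self.weights[:, None]).T @ self.samples

    def compatible_with(self, other: "BoundaryBasis") -> bool:
        return (
            self.order == other.order
            and abs(self.arc.theta_start - other.arc.theta_start) < 1e-12
            and abs(self.arc.theta_end - other.arc.theta_end) < 1e-12
        )


def make_boundary_basis(arc: BoundaryArc, K: int, *, n_panels: int | None = None) -> BoundaryBasis:
    """Build the orthonormal zero-mean trigonometric basis of order K on an arc.

    Deterministic given ``(arc, K)``.  Uses composite 4-point Gauss–Legendre
    quadrature; the Gram matrix is the identity to round-off.
    """
    if K < 1:
        raise ValueError("basis order K must be >= 1")
    if n_panels is None:
        n_panels = max(96, 12 * K)
    gl_x, gl_w = np.polynomial.legendre.leggauss(4)
    edges = np.linspace(arc.theta_start, arc.theta_end, n_panels + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    half = 0.5 * np.diff(edges)
    nodes = (mid[:, None] + half[:, None] * gl_x[None, :]).ravel()
    weights = (half[:, None] * gl_w[None, :]).ravel()

    n_raw = 2 * ((K + 3) // 2) + K  # generous surplus against near-dependence
    table = _trig_table(nodes, n_raw)
    total = weights.sum()

    basis_cols: list[np.ndarray] = []
    coeffs: list[np.ndarray] = []
    j = 1
    while len(basis_cols) < K and j < table.shape[1]:
        v = table[:, j].copy()
        c = np.zeros(table.shape[1])
        c[j] = 1.0
        # subtract the quadrature mean (a multiple of the constant column)
        m = weights @ v / total
        v -= m
        c[0] -= m
        # modified Gram–Schmidt, twice for stability
        for _ in range(2):
            for q, cq in zip(basis_cols, coeffs):
                r = weights @ (q * v)
                v -= r * q
                c -= r * cq
        nrm = np.sqrt(weights @ v**2)
        if nrm > 1e-8:
            basis_cols.append(v / nrm)
            coeffs.append(c / nrm)
        j += 1
    if len(basis_cols) < K:
        raise ValueError(f"could not build {K} independent basis functions on the arc")
    S = np.column_stack(basis_cols)
    C = np.vstack(coeffs)
    return BoundaryBasis(arc=arc, order=K, nodes=nodes, weights=weights,
                         samples=S, raw_coeffs=C)


@dataclass
class BoundaryFunction:
    """Zero-mean boundary current/voltage as coefficients in a BoundaryBasis."""

    coefficients: np.ndarray
    basis: BoundaryBasis

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.basis.order,):
            raise ValueError("coefficient length does not match basis order")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficients")

    def values_at_nodes(self) -> np.ndarray:
        return self.basis.samples @ self.coefficients

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.coefficients))


def project_trace(samples: np.ndarray, basis: BoundaryBasis) -> BoundaryFunction:
    """L²(Σ)-project samples given at the basis quadrature nodes.

    The samples are mean-subtracted on the arc first, so constants map to
    the zero coefficient vector.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape != basis.nodes.shape:
        raise ValueError("sample vector does not match quadrature nodes")
    mean = basis.weights @ samples / basis.weights.sum()
    coef = basis.samples.T @ (basis.weights * (samples - mean))
    return BoundaryFunction(coef, basis)


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """P1 triangulation of the unit disk (or an imported smooth domain).

    Boundary vertices must lie on the unit circle to 1e-8; boundary edges
    are stored ordered by angle, together with the angle of each boundary
    vertex (the arc parameter).
    """

    vertices: np.ndarray            # (n, 2)
    triangles: np.ndarray           # (m, 3) CCW
    h: float                        # nominal mesh size
    # derived, filled in __post_init__
    areas: np.ndarray = field(default=None, repr=False)
    grads: np.ndarray = field(default=None, repr=False)        # (m, 3, 2)
    centroids: np.ndarray = field(default=None, repr=False)
    boundary_vertices: np.ndarray = field(default=None, repr=False)  # ordered by angle
    boundary_theta: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.triangles, dtype=np.int64)
        p0, p1, p2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
        cross = (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1]) - \
                (p1[:, 1] - p0[:, 1]) * (p2[:, 0] - p0[:, 0])
        flip = cross < 0
        if np.any(flip):
            t[flip, 1], t[flip, 2] = t[flip, 2].copy(), t[flip, 1].copy()
            p1, p2 = v[t[:, 1]], v[t[:, 2]]
            cross = np.abs(cross)
        areas = 0.5 * cross
        if np.any(areas <= 0):
            raise ValueError("degenerate triangle (non-positive signed area)")
        # P1 barycentric gradients
        g = np.empty((len(t), 3, 2))
        for i, (a, b) in enumerate(((1, 2), (2, 0), (0, 1))):
            e = v[t[:, b]] - v[t[:, a]]
            g[:, i, 0] = -e[:, 1]
            g[:, i, 1] = e[:, 0]
        g /= (2.0 * areas)[:, None, None]
        self.vertices, self.triangles = v, t
        self.areas, self.grads = areas, g
        self.centroids = (p0 + p1 + p2) / 3.0
        # boundary = vertices on the unit circle
        r = np.hypot(v[:, 0], v[:, 1])
        bidx = np.flatnonzero(r > 1.0 - 1e-6)
        if len(bidx) < 3:
            raise ValueError("mesh has no identifiable circular boundary")
        if np.max(np.abs(r[bidx] - 1.0)) > 1e-8:
            raise ValueError("boundary vertices do not lie on the unit circle")
        theta = np.mod(np.arctan2(v[bidx, 1], v[bidx, 0]), TWO_PI)
        order = np.argsort(theta)
        self.boundary_vertices = bidx[order]
        self.boundary_theta = theta[order]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def boundary_edges(self) -> np.ndarray:
        """Consecutive boundary vertex pairs, ordered by angle, wrapping."""
        b = self.boundary_vertices
        return np.column_stack([b, np.roll(b, -1)])

    def gradient_per_triangle(self, u: np.ndarray) -> np.ndarray:
        """Constant gradient of a P1 field on every triangle, shape (m, 2)."""
        return np.einsum("mie,mi->me", self.grads, u[self.triangles])


def disk_mesh(h: float = 0.03) -> TriangleMesh:
    """Structured triangulation of the unit disk with mesh size ≈ h.

    Vertices sit on concentric rings (6·i points on ring i of n rings,
    n = round(1/h)); the connectivity is the Delaunay triangulation of the
    point set.  Boundary vertices lie exactly on the unit circle.
    """
    if not (0 < h < 1):
        raise ValueError("mesh size h must lie in (0, 1)")
    n_r = max(3, int(round(1.0 / h)))
    pts = [np.zeros((1, 2))]
    for i in range(1, n_r + 1):
        r = i / n_r
        n_i = 6 * i
        ang = TWO_PI * np.arange(n_i) / n_i
        pts.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
    pts = np.vstack(pts)
    tri = Delaunay(pts)
    simplices = tri.simplices
    # guard against sliver artifacts from cocircular boundary points
    p0, p1, p2 = (pts[simplices[:, k]] for k in range(3))
    a2 = np.abs((p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1])
                - (p1[:, 1] - p0[:, 1]) * (p2[:, 0] - p0[:, 0]))
    keep = a2 > 1e-12 * (1.0 / n_r) ** 2
    mesh = TriangleMesh(pts, simplices[keep], h=1.0 / n_r)
    logger.debug("disk_mesh h=%.4g: %d vertices, %d triangles",
                 h, mesh.n_vertices, mesh.n_triangles)
    return mesh


def refine_mesh(mesh: TriangleMesh) -> TriangleMesh:
    """Uniform 1→4 refinement; new boundary midpoints are snapped to the circle."""
    v = mesh.vertices
    t = mesh.triangles
    edge_index: dict[tuple[int, int], int] = {}
    new_pts: list[np.ndarray] = []
    r = np.hypot(v[:, 0], v[:, 1])
    on_bnd = r > 1.0 - 1e-6

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        idx = edge_index.get(key)
        if idx is None:
            p = 0.5 * (v[a] + v[b])
            if on_bnd[a] and on_bnd[b]:
                p = p / np.hypot(p[0], p[1])
            idx = len(v) + len(new_pts)
            new_pts.append(p)
            edge_index[key] = idx
        return idx

    new_tris = []
    for a, b, c in t:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_tris.extend([(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)])
    verts = np.vstack([v] + [np.asarray(p)[None, :] for p in new_pts]) if new_pts else v
    return TriangleMesh(verts, np.asarray(new_tris, dtype=np.int64), h=mesh.h / 2.0)


def write_msh(mesh: TriangleMesh, path) -> None:
    """Write the mesh in Gmsh 2.2 ASCII format (nodes + 2D triangle elements)."""
    buf = io.StringIO()
    buf.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
    buf.write(f"$Nodes\n{mesh.n_vertices}\n")
    for i, (x, y) in enumerate(mesh.vertices, start=1):
        buf.write(f"{i} {x:.17g} {y:.17g} 0\n")
    buf.write("$EndNodes\n")
    buf.write(f"$Elements\n{mesh.n_triangles}\n")
    for i, (a, b, c) in enumerate(mesh.triangles, start=1):
        buf.write(f"{i} 2 2 0 1 {a + 1} {b + 1} {c + 1}\n")
    buf.write("$EndElements\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_msh(path, h: float | None = None) -> TriangleMesh:
    """Read a Gmsh 2.2 ASCII mesh (triangles only, z ignored)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    try:
        i_nodes = lines.index("$Nodes")
        n_nodes = int(lines[i_nodes + 1])
        verts = np.empty((n_nodes, 2))
        for k in range(n_nodes):
            parts = lines[i_nodes + 2 + k].split()
            verts[int(parts[0]) - 1] = (float(parts[1]), float(parts[2]))
        i_el = lines.index("$Elements")
        n_el = int(lines[i_el + 1])
        tris = []
        for k in range(n_el):
            parts = lines[i_el + 2 + k].split()
            if int(parts[1]) == 2:  # 3-node triangle
                n_tags = int(parts[2])
                tris.append([int(p) - 1 for p in parts[3 + n_tags:6 + n_tags]])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed .msh file {path}: {exc}") from exc
    if not tris:
        raise ValueError(f"no triangles in {path}")
    if h is None:
        # nominal h from the median edge length
        t = np.asarray(tris, dtype=np.int64)
        e = verts[t[:, 1]] - verts[t[:, 0]]
        h = float(np.median(np.hypot(e[:, 0], e[:, 1])))
    return TriangleMesh(verts, np.asarray(tris, dtype=np.int64), h=h)


# --------------------------------------------------------------------------
# conductivity and potential fields
# --------------------------------------------------------------------------

@dataclass
class ConductivityField:
    """Positive conductivity coefficient σ with declared bounds.

    ``evaluator`` maps an (N, 2) array of points to N positive values;
    phantoms built from shape lists provide it.  Values are checked
    against ``(sigma_min, sigma_max)`` wherever the field is sampled.
    """

    evaluator: Callable[[np.ndarray], np.ndarray]
    sigma_min: float
    sigma_max: float
    description: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.sigma_min <= self.sigma_max < np.inf):
            raise ValueError("conductivity bounds must satisfy 0 < min <= max < inf")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vals = np.asarray(self.evaluator(pts), dtype=float)
        if np.any(vals <= 0):
            raise ValueError("conductivity evaluated non-positive")
        if np.any(vals < self.sigma_min - 1e-12) or np.any(vals > self.sigma_max + 1e-12):
            raise ValueError("conductivity outside declared bounds")
        return vals

    def per_triangle(self, mesh: TriangleMesh) -> np.ndarray:
        """One value per triangle, evaluated at the centroid."""
        return self(mesh.centroids)


def homogeneous_field(value: float = 1.0) -> ConductivityField:
    """Spatially constant conductivity."""
    if value <= 0:
        raise ValueError("conductivity must be positive")
    return ConductivityField(lambda p: np.full(len(p), float(value)),
                             sigma_min=value, sigma_max=value,
                             description=f"constant {value:g}")


@dataclass
class PotentialField:
    """P1 electric potential with zero integral mean over ∂Ω."""

    values: np.ndarray
    mesh: TriangleMesh
    boundary_mean: float = 0.0

    def gradient(self) -> np.ndarray:
        return self.mesh.gradient_per_triangle(self.values)

    def energy(self, sigma_tri: np.ndarray) -> float:
        g = self.gradient()
        return float(np.sum(sigma_tri * self.mesh.areas * np.sum(g * g, axis=1)))


@dataclass
class NtDOperator:
    """Discrete Neumann-to-Dirichlet operator in an orthonormal boundary basis."""

    matrix: np.ndarray
    basis: BoundaryBasis
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float)
        if A.shape != (self.basis.order, self.basis.order):
            raise ValueError("NtD matrix shape does not match basis order")
        nrm = np.linalg.norm(A)
        if nrm > 0 and np.linalg.norm(A - A.T) > 1e-10 * nrm:
            raise ValueError("NtD matrix is not symmetric to tolerance")
        self.matrix = 0.5 * (A + A.T)

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.matrix)[::-1]


# --------------------------------------------------------------------------
# FEM system
# --------------------------------------------------------------------------

def _sigma_per_triangle(mesh: TriangleMesh, sigma) -> np.ndarray:
    if isinstance(sigma, ConductivityField):
        return sigma.per_triangle(mesh)
    vals = np.asarray(sigma, dtype=float)
    if vals.shape != (mesh.n_triangles,):
        raise ValueError("per-triangle conductivity has wrong length")
    if np.any(vals <= 0):
        raise ValueError("conductivity must be positive on every triangle")
    return vals


class FemSystem:
    """Grounded P1 Galerkin system for one (mesh, σ, basis) triple.

    Caches the sparse LU factorization of the saddle-point matrix

        [ K   c ] [u]   [b]
        [ c'  0 ] [λ] = [0],

    where K is the σ-weighted stiffness matrix and c the boundary mass
    vector implementing the zero-mean grounding over ∂Ω.  Boundary loads
    use the same arc-parameter quadrature as the basis, which makes the
    discrete NtD exactly symmetric and the energy identity
    g'Λg = ∫σ|∇u|² exact to round-off.
    """

    def __init__(self, mesh: TriangleMesh, sigma, basis: BoundaryBasis):
        self.mesh = mesh
        self.basis = basis
        self.sigma_tri = _sigma_per_triangle(mesh, sigma)
        self.description = getattr(sigma, "description", "per-triangle values")

        m, n = mesh.n_triangles, mesh.n_vertices
        t = mesh.triangles
        # stiffness: K_ij = Σ_T σ_T A_T ∇φ_i·∇φ_j
        local = np.einsum("mie,mje->mij", mesh.grads, mesh.grads)
        local *= (self.sigma_tri * mesh.areas)[:, None, None]
        rows = np.repeat(t, 3, axis=1).ravel()
        cols = np.tile(t, (1, 3)).ravel()
        K = sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()

        # boundary mass vector over the full ∂Ω (arc-length = angle on the circle)
        b_idx = mesh.boundary_vertices
        th = mesh.boundary_theta
        dth = np.diff(np.append(th, th[0] + TWO_PI))
        c = np.zeros(n)
        np.add.at(c, b_idx, 0.5 * dth)
        np.add.at(c, np.roll(b_idx, -1), 0.5 * dth)
        self._c = c

        A = sp.bmat([[K, c[:, None]], [c[None, :], None]], format="csc")
        self._lu = spla.splu(A)
        self._K = K

        # hat interpolation: quadrature-node values of a P1 trace
        nodes = basis.nodes
        tmod = np.mod(nodes, TWO_PI)
        seg = np.searchsorted(th, tmod, side="right") - 1
        seg = np.mod(seg, len(th))
        t0 = th[seg]
        dt = dth[seg]
        frac = np.mod(tmod - t0, TWO_PI) / dt
        rowsT = np.repeat(np.arange(len(nodes)), 2)
        colsT = np.column_stack([b_idx[seg], b_idx[(seg + 1) % len(th)]]).ravel()
        valsT = np.column_stack([1.0 - frac, frac]).ravel()
        self._T = sp.coo_matrix((valsT, (rowsT, colsT)),
                                shape=(len(nodes), n)).tocsr()
        # boundary load matrix for the basis currents: B = T' W S   (n × K)
        self._B = self._T.T @ (basis.weights[:, None] * basis.samples)

    # -- solving ----------------------------------------------------------

    def solve_rhs(self, b: np.ndarray) -> np.ndarray:
        """Solve the grounded system for an interior/boundary load vector."""
        rhs = np.append(b, 0.0)
        sol = self._lu.solve(rhs)
        return sol[:-1]

    def solve_current(self, g: BoundaryFunction) -> PotentialField:
        if not self.basis.compatible_with(g.basis):
            raise ValueError("current is expressed in an incompatible basis")
        u = self.solve_rhs(self._B @ g.coefficients)
        mean = float(self._c @ u) / TWO_PI
        return PotentialField(u, self.mesh, boundary_mean=mean)

    def solve_basis_currents(self) -> np.ndarray:
        """Solutions for all K basis currents, shape (n_vertices, K)."""
        U = np.empty((self.mesh.n_vertices, self.basis.order))
        for k in range(self.basis.order):
            U[:, k] = self.solve_rhs(self._B[:, k])
        return U

    # -- traces and the NtD matrix ---------------------------------------

    def trace_project(self, u: np.ndarray) -> BoundaryFunction:
        return project_trace(self._T @ u, self.basis)

    def ntd_matrix(self) -> np.ndarray:
        U = self.solve_basis_currents()
        L = self._B.T @ U
        return 0.5 * (L + L.T)

    def ntd(self) -> NtDOperator:
        prov = {
            "mesh_h": self.mesh.h,
            "n_vertices": self.mesh.n_vertices,
            "sigma": self.description,
            "arc": [self.basis.arc.theta_start, self.basis.arc.theta_end],
            "K": self.basis.order,
        }
        return NtDOperator(self.ntd_matrix(), self.basis, prov)

    def region_energy(self, u: np.ndarray, weight: np.ndarray | None = None) -> float:
        """∫ w |∇u|² with a per-triangle weight (default 1)."""
        g = self.mesh.gradient_per_triangle(u)
        e = self.mesh.areas * np.sum(g * g, axis=1)
        if weight is not None:
            e = e * weight
        return float(e.sum())


# --------------------------------------------------------------------------
# top-level operations
# --------------------------------------------------------------------------

def solve_neumann(mesh: TriangleMesh, sigma, g: BoundaryFunction) -> PotentialField:
    """Solve the grounded Neumann conductivity problem for one current."""
    return FemSystem(mesh, sigma, g.basis).solve_current(g)


def assemble_ntd(mesh: TriangleMesh, sigma, basis: BoundaryBasis) -> NtDOperator:
    """Assemble the discrete NtD operator of σ on the given mesh and basis."""
    return FemSystem(mesh, sigma, basis).ntd()


def ntd_homogeneous_oracle(k: int) -> float:
    """NtD eigenvalue 1/k of the homogeneous unit disk for the degree-k mode.

    Separation of variables: u = r^k cos kθ / k has Neumann data cos kθ and
    trace cos kθ / k.
    """
    if k < 1:
        raise ValueError("mode order must be >= 1")
    return 1.0 / k


def ntd_concentric_oracle(k: int, rho: float, a: float) -> float:
    """NtD eigenvalue for σ = a inside the disk of radius ρ, 1 outside.

    Solving the 2×2 transmission system for u = A r^k (inside),
    B r^k + C r^{-k} (outside) with continuity of u and σ∂_r u at ρ and unit
    Neumann data at r = 1 gives

        λ_k = (1/k) · (1 − μ ρ^{2k}) / (1 + μ ρ^{2k}),   μ = (a−1)/(a+1).
    """
    if k < 1:
        raise ValueError("mode order must be >= 1")
    if not (0 <= rho < 1):
        raise ValueError("inclusion radius must lie in [0, 1)")
    if a <= 0:
        raise ValueError("conductivity ratio must be positive")
    mu = (a - 1.0) / (a + 1.0)
    q = mu * rho ** (2 * k)
    return (1.0 / k) * (1.0 - q) / (1.0 + q)
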
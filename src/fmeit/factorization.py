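"""Factorization Method core: spectral range test and monotonicity checks.

Given discrete NtD operators Λ(σ) and Λ(σ₀), a sampling point z belongs
to the anomaly iff the dipole trace Φ_{z,d}|_Σ lies in the range of
|Λ(σ)−Λ(σ₀)|^{1/2}.  The discrete surrogate is the truncated Picard
series: with eigenpairs (λ_k, v_k) of the spectral absolute value and a
unit-norm trace φ, the indicator

    I(z) = ( Σ_k ⟨φ, v_k⟩² / |λ_k| )^{-1}

is large inside the anomaly (convergent series) and small outside
(divergent series, saturated by the truncation).  The indefinite
variant shifts the data operator by a scaled virtual-measurement Gram
matrix on an a-priori excluded region E so that the definiteness
assumption is only needed on Ω∖E.

Monotonicity: pointwise σ₁ ≥ σ₀ implies the quadratic-form ordering of
the NtD operators with two-sided interior-energy bounds; the identities
behind the chain hold verbatim for Galerkin solutions on a shared mesh,
so ``monotonicity_verify`` checks them to round-off.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .boundary_forward import (
    BoundaryFunction,
    FemSystem,
    NtDOperator,
    TriangleMesh,
)
from .dipole import DipoleTrace
from .virtual_measurements import RegionMask, VirtualGram, assemble_virtual_gram

__all__ = [
    "SpectralDecomposition",
    "FMOptions",
    "IndicatorMap",
    "DegenerateOperatorError",
    "spectral_abs",
    "picard_ratio",
    "fm_indicator_map",
    "fm_indefinite_map",
    "definiteness_check",
    "monotonicity_verify",
]

logger = logging.getLogger("fmeit.factorization")


class DegenerateOperatorError(RuntimeError):
    """All eigenvalues of the data operator fall below the retention floor."""


@dataclass
class SpectralDecomposition:
    """Eigendecomposition of the spectral absolute value |A|.

    ``abs_eigenvalues`` are |λ_k| sorted decreasingly; ``signed_eigenvalues``
    keep the original signs in the same order; ``vectors[:, k]`` is the
    (orthonormal) eigenvector of the k-th mode.
    """

    abs_eigenvalues: np.ndarray
    signed_eigenvalues: np.ndarray
    vectors: np.ndarray
    source: str = ""

    def reconstruct_abs(self) -> np.ndarray:
        return (self.vectors * self.abs_eigenvalues[None, :]) @ self.vectors.T


@dataclass(frozen=True)
class FMOptions:
    """Tunable parameters of the discrete range test.

    eps_rel        relative eigenvalue floor for Picard truncation
    max_modes      hard cap on retained modes (default K−2)
    threshold_c    mask threshold as a fraction of the max finite indicator
    definiteness   'auto' | 'positive' | 'negative' (logged; |·| makes the
                   criterion direction-agnostic)
    gamma          indefinite shift factor multiplying α/β·M_E
    alpha, beta    shift magnitudes for the indefinite cases a/b
    directions     dipole directions, combined by harmonic mean
    noise_rel      optional relative symmetric Gaussian NtD perturbation
    """

    eps_rel: float = 1e-12
    max_modes: int | None = None
    threshold_c: float = 0.1
    definiteness: str = "auto"
    gamma: float = 2.0
    alpha: float | None = None
    beta: float | None = None
    directions: tuple = ((1.0, 0.0), (0.0, 1.0))
    noise_rel: float = 0.0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.eps_rel <= 0:
            raise ValueError("eps_rel must be positive")
        if not (0 < self.threshold_c < 1):
            raise ValueError("threshold fraction must lie in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.definiteness not in ("auto", "positive", "negative"):
            raise ValueError("definiteness mode must be auto/positive/negative")


@dataclass
class IndicatorMap:
    """Picard indicator values on a sampling grid with a thresholded mask."""

    points: np.ndarray              # (N, 2)
    values: np.ndarray              # (N,), nonnegative, +inf sentinel allowed
    mask: np.ndarray                # (N,) bool
    options: FMOptions
    metadata: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# spectral machinery
# --------------------------------------------------------------------------

def spectral_abs(A: np.ndarray, source: str = "") -> SpectralDecomposition:
    """Eigendecomposition of |A| for a (numerically) symmetric matrix A."""
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix has non-finite entries")
    nrm = np.linalg.norm(A)
    if nrm > 0 and np.linalg.norm(A - A.T) > 1e-8 * nrm:
        raise ValueError("matrix asymmetry exceeds tolerance")
    S = 0.5 * (A + A.T)
    lam, V = np.linalg.eigh(S)
    order = np.argsort(np.abs(lam))[::-1]
    return SpectralDecomposition(
        abs_eigenvalues=np.abs(lam[order]),
        signed_eigenvalues=lam[order],
        vectors=V[:, order],
        source=source,
    )


def _retained(decomp: SpectralDecomposition, options: FMOptions) -> np.ndarray:
    lam = decomp.abs_eigenvalues
    if lam.size == 0 or lam[0] <= 0:
        raise DegenerateOperatorError("operator has no nonzero eigenvalues")
    keep = lam >= options.eps_rel * lam[0]
    if not np.any(keep):
        raise DegenerateOperatorError("all eigenvalues below the retention floor")
    cap = options.max_modes if options.max_modes is not None else max(1, lam.size - 2)
    idx = np.flatnonzero(keep)[:cap]
    return idx


def picard_ratio(decomp: SpectralDecomposition, phi: DipoleTrace | BoundaryFunction,
                 options: FMOptions = FMOptions()) -> float:
    """Truncated-Picard indicator for one test function.

    The trace is normalized to unit coefficient norm; returns
    ``1 / Σ ⟨φ,v_k⟩²/|λ_k|`` over retained modes, +inf if the sum vanishes.
    """
    coef = phi.coefficients.coefficients if isinstance(phi, DipoleTrace) else phi.coefficients
    coef = np.asarray(coef, dtype=float)
    nrm = np.linalg.norm(coef)
    if nrm == 0:
        raise ValueError("zero test function")
    coef = coef / nrm
    idx = _retained(decomp, options)
    proj = decomp.vectors[:, idx].T @ coef
    s = float(np.sum(proj**2 / decomp.abs_eigenvalues[idx]))
    return np.inf if s == 0 else 1.0 / s


def definiteness_check(A: np.ndarray, tolerance: float = 1e-10) -> str:
    """Classify a symmetric matrix as 'PSD' | 'NSD' | 'indefinite' | 'zero'."""
    A = np.asarray(A, dtype=float)
    S = 0.5 * (A + A.T)
    lam = np.linalg.eigvalsh(S)
    scale = np.max(np.abs(lam)) if lam.size else 0.0
    if scale == 0.0:
        return "zero"
    has_pos = lam[-1] > tolerance * scale
    has_neg = lam[0] < -tolerance * scale
    if has_pos and has_neg:
        return "indefinite"
    if has_pos:
        return "PSD"
    if has_neg:
        return "NSD"
    return "zero"


# --------------------------------------------------------------------------
# indicator maps
# --------------------------------------------------------------------------

def _maybe_add_noise(A: np.ndarray, options: FMOptions) -> np.ndarray:
    if options.noise_rel <= 0:
        return A
    rng = np.random.default_rng(options.noise_seed)
    N = rng.standard_normal(A.shape)
    N = 0.5 * (N + N.T)
    return A + options.noise_rel * np.linalg.norm(A) / max(np.linalg.norm(N), 1e-300) * N


def _indicator_from_operator(op_matrix: np.ndarray, source: str,
                             dipole_provider: Callable,
                             grid: np.ndarray, options: FMOptions,
                             extra_meta: dict | None = None) -> IndicatorMap:
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    decomp = spectral_abs(op_matrix, source=source)
    idx = _retained(decomp, options)
    P = decomp.vectors[:, idx]
    invlam = 1.0 / decomp.abs_eigenvalues[idx]
    ndir = len(options.directions)
    sums = np.zeros(len(grid))
    for z_i, z in enumerate(grid):
        s_total = 0.0
        for d in options.directions:
            phi = dipole_provider(z, np.asarray(d, dtype=float))
            coef = phi.coefficients.coefficients
            coef = coef / np.linalg.norm(coef)
            proj = P.T @ coef
            s_total += float(np.sum(proj**2 * invlam))
        sums[z_i] = s_total
    with np.errstate(divide="ignore"):
        values = np.where(sums > 0, ndir / sums, np.inf)
    finite = np.isfinite(values)
    if np.any(finite):
        mx = values[finite].max()
        mask = finite & (values >= options.threshold_c * mx)
    else:
        mask = np.zeros(len(grid), dtype=bool)
    meta = {
        "eigenvalues": decomp.signed_eigenvalues.tolist(),
        "retained_modes": int(len(idx)),
        "degenerate": False,
        "source": source,
    }
    if extra_meta:
        meta.update(extra_meta)
    return IndicatorMap(points=grid, values=values, mask=mask,
                        options=options, metadata=meta)


def fm_indicator_map(ntd_sigma: NtDOperator, ntd_sigma0: NtDOperator,
                     dipole_provider: Callable, grid: np.ndarray,
                     options: FMOptions = FMOptions()) -> IndicatorMap:
    """Definite Factorization Method: range test for |Λ(σ)−Λ(σ₀)|^{1/2}.

    ``dipole_provider(z, d)`` must return the DipoleTrace of the sampling
    point in the operators' boundary basis.  The per-point indicator is
    the harmonic mean over the configured dipole directions; the decision
    mask keeps points with finite indicator ≥ c·(max finite indicator).
    """
    if not ntd_sigma.basis.compatible_with(ntd_sigma0.basis):
        raise ValueError("NtD operators use incompatible boundary bases")
    diff = _maybe_add_noise(ntd_sigma.matrix, options) - ntd_sigma0.matrix
    floor = 1e-13 * max(np.linalg.norm(ntd_sigma.matrix),
                        np.linalg.norm(ntd_sigma0.matrix), 1e-300)
    if np.linalg.norm(diff) <= floor:
        grid = np.atleast_2d(np.asarray(grid, dtype=float))
        logger.warning("NtD difference is numerically zero; empty mask")
        return IndicatorMap(points=grid, values=np.zeros(len(grid)),
                            mask=np.zeros(len(grid), dtype=bool), options=options,
                            metadata={"degenerate": True, "eigenvalues": [],
                                      "retained_modes": 0})
    direction = definiteness_check(diff) if options.definiteness == "auto" \
        else options.definiteness
    logger.info("data operator definiteness: %s", direction)
    return _indicator_from_operator(diff, "ntd-difference", dipole_provider,
                                    grid, options,
                                    extra_meta={"definiteness": direction})


def fm_indefinite_map(ntd_sigma: NtDOperator, ntd_sigma0: NtDOperator,
                      E: RegionMask | VirtualGram, case: str,
                      dipole_provider: Callable, grid: np.ndarray,
                      options: FMOptions = FMOptions(),
                      mesh: TriangleMesh | None = None,
                      sigma0=None) -> IndicatorMap:
    """Indefinite Factorization Method with excluded region E.

    Case 'a' assumes σ ≤ σ₀ outside E and shifts the data operator by
    +γ·α·M_E; case 'b' assumes σ ≥ σ₀ outside E and uses Λ(σ₀)−Λ(σ)+γ·β·M_E.
    The mask targets the outer support of supp(σ−σ₀) ∪ E.  With an empty E
    the definite routine is returned unchanged.
    """
    if case not in ("a", "b"):
        raise ValueError("case must be 'a' or 'b'")
    if not ntd_sigma.basis.compatible_with(ntd_sigma0.basis):
        raise ValueError("NtD operators use incompatible boundary bases")
    if isinstance(E, VirtualGram):
        if not E.basis.compatible_with(ntd_sigma.basis):
            raise ValueError("Gram matrix basis does not match the NtD basis")
        M = E.matrix
        region_desc = E.region
    else:
        mask_empty = (E.shapes is not None and len(E.shapes) == 0) or (
            E.triangle_mask is not None and not np.any(E.triangle_mask))
        if mask_empty:
            M = np.zeros_like(ntd_sigma.matrix)
        else:
            if mesh is None or sigma0 is None:
                raise ValueError("assembling M_E from a RegionMask needs mesh and sigma0")
            M = assemble_virtual_gram(mesh, sigma0, E, ntd_sigma.basis).matrix
        region_desc = E.description
    if np.linalg.norm(M) == 0.0:
        # exact reduction to the definite method
        return fm_indicator_map(ntd_sigma, ntd_sigma0, dipole_provider, grid, options)
    if case == "a":
        if options.alpha is None:
            raise ValueError("case 'a' requires the shift magnitude alpha")
        shifted = (ntd_sigma.matrix - ntd_sigma0.matrix) + options.gamma * options.alpha * M
    else:
        if options.beta is None:
            raise ValueError("case 'b' requires the shift magnitude beta")
        shifted = (ntd_sigma0.matrix - ntd_sigma.matrix) + options.gamma * options.beta * M
    return _indicator_from_operator(
        shifted, f"shifted-ntd-difference(case {case})", dipole_provider, grid,
        options, extra_meta={"excluded_region": region_desc, "case": case})


# --------------------------------------------------------------------------
# monotonicity verification
# --------------------------------------------------------------------------

def monotonicity_verify(mesh: TriangleMesh, sigma0, sigma1,
                        currents: Sequence[BoundaryFunction],
                        rel_tol: float = 1e-10):
    """Two-sided interior-energy bounds on the NtD difference, per current.

    For each current g returns (lower, middle, upper) with

        lower  = ∫ (σ₀−σ₁)|∇u₀|²,
        middle = g'(Λ₁−Λ₀)g,
        upper  = ∫ (σ₀/σ₁)(σ₀−σ₁)|∇u₀|²,

    all assembled on the same mesh and basis, plus a flag that the chain
    lower ≤ middle ≤ upper holds within ``rel_tol`` relative slack.
    """
    if not currents:
        raise ValueError("at least one current is required")
    basis = currents[0].basis
    fem0 = FemSystem(mesh, sigma0, basis)
    fem1 = FemSystem(mesh, sigma1, basis)
    L0 = fem0.ntd_matrix()
    L1 = fem1.ntd_matrix()
    w_lower = (fem0.sigma_tri - fem1.sigma_tri)
    w_upper = (fem0.sigma_tri / fem1.sigma_tri) * w_lower
    triples = []
    ok = True
    for g in currents:
        if not basis.compatible_with(g.basis):
            raise ValueError("currents use mixed boundary bases")
        u0 = fem0.solve_current(g)
        lower = fem0.region_energy(u0.values, weight=w_lower)
        upper = fem0.region_energy(u0.values, weight=w_upper)
        middle = float(g.coefficients @ ((L1 - L0) @ g.coefficients))
        scale = max(abs(lower), abs(middle), abs(upper), 1e-300)
        if lower > middle + rel_tol * scale or middle > upper + rel_tol * scale:
            ok = False
        triples.append((lower, middle, upper))
    return triples, ok
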
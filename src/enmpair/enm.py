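"""Elastic network models: GNM Kirchhoff matrix and ANM Hessian.

The Gaussian network model (GNM) represents a protein as Cα nodes joined by
uniform springs within a cutoff r_c; the contact topology is the Kirchhoff
(graph Laplacian) matrix Γ, and residue fluctuations follow from its
pseudo-inverse,

    ⟨ΔR_i · ΔR_j⟩ = (3 k_B T / γ) [Γ⁻¹]_ij .

The anisotropic network model (ANM) replaces Γ by the 3N×3N Hessian of the
harmonic network potential, so fluctuation directions become available:

    ⟨ΔR_i²⟩ = (3 k_B T / γ) · trace([H⁻¹]_ii) .

The spring constant γ is factored out of both matrices; it re-enters only
through the fitted k_B T / γ scale (Å²).  Crystallographic B-factors relate
to mean-square fluctuations by B_i = (8π²/3) ⟨ΔR_i²⟩.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .structures import CalphaStructure

#: Default GNM contact cutoff in Å (also used for contact numbers).
DEFAULT_GNM_CUTOFF = 7.3
#: Secondary cutoff used for fast-mode/contact analysis, Å.
FAST_MODE_CUTOFF_2 = 9.0
#: Default ANM contact cutoff in Å.
DEFAULT_ANM_CUTOFF = 15.0

BFACTOR_PER_MSF = 8.0 * np.pi**2 / 3.0

#: λ counts as zero iff λ < ZERO_MODE_RTOL · max(λ_max, 1).
ZERO_MODE_RTOL = 1e-10


class DisconnectedNetworkError(ValueError):
    """Raised when an operation requires a connected contact graph."""


@dataclass
class EigenDecomposition:
    """Ascending eigenpairs of a network matrix with zero modes identified."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # orthonormal columns, eigenvectors[:, k]
    n_zero: int

    @property
    def n_nonzero(self) -> int:
        return self.eigenvalues.size - self.n_zero


def decompose(matrix: np.ndarray, expected_zero: int | None = None) -> EigenDecomposition:
    """Eigendecompose a symmetric network matrix (Γ or H).

    Eigenvalues are returned ascending; eigenvector signs are fixed by
    making each vector's largest-magnitude component positive.  Zero modes
    are detected by the relative threshold ``ZERO_MODE_RTOL``.  If
    ``expected_zero`` is given and more zero modes are found, a warning
    reports the excess (a disconnected contact graph), but the
    decomposition proceeds.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("matrix must be symmetric within 1e-8")
    evals, evecs = scipy.linalg.eigh(matrix)
    # deterministic sign convention
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    tol = ZERO_MODE_RTOL * max(float(evals[-1]), 1.0)
    n_zero = int(np.sum(evals < tol))
    if expected_zero is not None and n_zero > expected_zero:
        # For a graph Laplacian the zero multiplicity equals the component
        # count; for the 3D Hessian each extra component adds up to 6.
        n_comp = n_zero if expected_zero == 1 else -(-n_zero // 6)
        warnings.warn(
            f"found {n_zero} zero modes where {expected_zero} expected: "
            f"the contact graph is disconnected (~{n_comp} components)",
            stacklevel=2,
        )
    return EigenDecomposition(eigenvalues=evals, eigenvectors=evecs, n_zero=n_zero)


def _contact_matrix(coords: np.ndarray, cutoff: float) -> np.ndarray:
    d = squareform(pdist(coords))
    contact = d <= cutoff
    np.fill_diagonal(contact, False)
    return contact


@dataclass
class GnmModel:
    """GNM Kirchhoff matrix with (lazily computed) eigendecomposition."""

    kirchhoff: np.ndarray
    cutoff_rc: float
    decomposition: EigenDecomposition | None = None

    @property
    def n_residues(self) -> int:
        return self.kirchhoff.shape[0]

    def decompose(self) -> EigenDecomposition:
        if self.decomposition is None:
            self.decomposition = decompose(self.kirchhoff, expected_zero=1)
        return self.decomposition

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.decompose().eigenvalues

    @property
    def eigenvectors(self) -> np.ndarray:
        return self.decompose().eigenvectors

    @property
    def n_zero(self) -> int:
        return self.decompose().n_zero

    def n_components(self) -> int:
        """Connected components of the contact graph."""
        adjacency = (self.kirchhoff < 0).astype(int)
        n, _ = connected_components(adjacency, directed=False)
        return int(n)


@dataclass
class AnmModel:
    """ANM Hessian (3N×3N) with lazily computed eigendecomposition."""

    hessian: np.ndarray
    cutoff_rc: float
    decomposition: EigenDecomposition | None = None

    @property
    def n_residues(self) -> int:
        return self.hessian.shape[0] // 3

    def decompose(self) -> EigenDecomposition:
        if self.decomposition is None:
            self.decomposition = decompose(self.hessian, expected_zero=6)
        return self.decomposition

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.decompose().eigenvalues

    @property
    def eigenvectors(self) -> np.ndarray:
        return self.decompose().eigenvectors

    @property
    def n_zero(self) -> int:
        return self.decompose().n_zero


@dataclass
class FluctuationProfile:
    """Per-residue mean-square fluctuations and predicted B-factors."""

    msf: np.ndarray  # Å²
    bfactor_pred: np.ndarray  # Å², (8π²/3)·msf
    scale_kbt_over_gamma: float  # Å²
    model_kind: str  # "GNM" or "ANM"
    mode_subset: str | tuple[int, ...] = "all"


def build_kirchhoff(s: CalphaStructure, cutoff: float = DEFAULT_GNM_CUTOFF) -> GnmModel:
    """Build the GNM Kirchhoff (connectivity) matrix.

    Γ_ij = −1 for i≠j with R_ij ≤ cutoff (inclusive), 0 otherwise; the
    diagonal holds each residue's contact degree, so rows sum to zero.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    contact = _contact_matrix(s.coords, cutoff)
    gamma = -contact.astype(float)
    np.fill_diagonal(gamma, contact.sum(axis=1))
    return GnmModel(kirchhoff=gamma, cutoff_rc=cutoff)


def contact_numbers(s: CalphaStructure, cutoff: float = DEFAULT_GNM_CUTOFF) -> np.ndarray:
    """Number of residues j≠i within the cutoff of residue i.

    Identical to the Kirchhoff diagonal; reported separately because packing
    density itself (not just topology) is a quantity of interest for
    kinetically hot residues.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return _contact_matrix(s.coords, cutoff).sum(axis=1).astype(int)


def build_hessian(s: CalphaStructure, cutoff: float = DEFAULT_ANM_CUTOFF) -> AnmModel:
    """Build the ANM Hessian of the harmonic network potential.

    For a contact pair i≠j the 3×3 superelement is the analytic second
    derivative at the equilibrium (input) geometry,
    H_ij = −(1/d_ij²)·(r_j−r_i)(r_j−r_i)ᵀ, and H_ii = −Σ_{j≠i} H_ij, so each
    superelement row sums to zero (translation invariance).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = s.n_residues
    if n < 2:
        raise ValueError("ANM requires at least two residues")
    coords = s.coords
    d = squareform(pdist(coords))
    contact = d <= cutoff
    np.fill_diagonal(contact, False)
    coincident = contact & (d < 1e-8)
    if np.any(coincident):
        i, j = np.argwhere(coincident)[0]
        raise ValueError(
            f"coincident Cα positions for residues {i} and {j} (d≈0) within cutoff"
        )
    hessian = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in np.flatnonzero(contact[i]):
            if j <= i:
                continue
            rij = coords[j] - coords[i]
            block = -np.outer(rij, rij) / (d[i, j] ** 2)
            hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            hessian[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
            hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
            hessian[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return AnmModel(hessian=hessian, cutoff_rc=cutoff)


def _resolve_modes(
    dec: EigenDecomposition, modes: str | Sequence[int]
) -> np.ndarray:
    """Resolve a mode selection to full-spectrum column indices.

    Mode ordinals count over the nonzero modes, 1-based: mode 1 is the
    slowest internal mode.  Zero (rigid-body) modes cannot be selected.
    """
    if isinstance(modes, str):
        if modes != "all":
            raise ValueError(f"unknown mode selection {modes!r}")
        return np.arange(dec.n_zero, dec.eigenvalues.size)
    idx = []
    for k in modes:
        k = int(k)
        if k < 1 or k > dec.n_nonzero:
            raise ValueError(
                f"mode {k} out of range: nonzero modes are 1..{dec.n_nonzero} "
                f"(zero modes are excluded)"
            )
        idx.append(dec.n_zero + k - 1)
    return np.array(idx, dtype=int)


def gnm_msf(
    g: GnmModel,
    scale: float = 1.0,
    modes: str | Sequence[int] = "all",
) -> FluctuationProfile:
    """Per-residue mean-square fluctuations from the GNM.

    msf_i = scale · 3 · Σ_k λ_k⁻¹ u_k[i]² over the selected nonzero modes;
    with ``modes="all"`` this is scale·3·diag(Γ⁺).  ``scale`` is k_B T/γ in
    Å²; mode ordinals are 1-based over nonzero modes (1 = slowest).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    dec = g.decompose()
    cols = _resolve_modes(dec, modes)
    lam = dec.eigenvalues[cols]
    u = dec.eigenvectors[:, cols]
    msf = scale * 3.0 * np.sum(u**2 / lam, axis=1)
    return FluctuationProfile(
        msf=msf,
        bfactor_pred=msf_to_bfactor(msf),
        scale_kbt_over_gamma=scale,
        model_kind="GNM",
        mode_subset="all" if isinstance(modes, str) else tuple(int(k) for k in modes),
    )


def msf_to_bfactor(msf: np.ndarray) -> np.ndarray:
    """Convert mean-square fluctuations (Å²) to B-factors: B = (8π²/3)·msf."""
    msf = np.asarray(msf, dtype=float)
    if np.any(msf < 0):
        raise ValueError("mean-square fluctuations must be non-negative")
    return BFACTOR_PER_MSF * msf


def anm_msf(a: AnmModel, scale: float = 1.0) -> FluctuationProfile:
    """Per-residue mean-square fluctuations from the ANM.

    msf_i = scale · 3 · trace of the i-th 3×3 diagonal superelement of H⁺
    (zero modes excluded).  The leading factor of 3 follows the same
    convention as the GNM expression, so the fitted scale absorbs any
    difference from the trace-only convention found elsewhere.
    """
    dec = a.decompose()
    if dec.n_nonzero < 1:
        raise ValueError("ANM has no nonzero modes")
    cols = np.arange(dec.n_zero, dec.eigenvalues.size)
    lam = dec.eigenvalues[cols]
    u = dec.eigenvectors[:, cols]
    per_coord = np.sum(u**2 / lam, axis=1)  # diag(H⁺)
    msf = scale * 3.0 * per_coord.reshape(-1, 3).sum(axis=1)
    return FluctuationProfile(
        msf=msf,
        bfactor_pred=msf_to_bfactor(msf),
        scale_kbt_over_gamma=scale,
        model_kind="ANM",
        mode_subset="all",
    )


def anm_mode_fluctuation(a: AnmModel, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue fluctuation and direction of one ANM mode.

    ``k`` is 1-based over nonzero modes (1 = slowest).  Returns
    ``(msf, directions)`` where msf_i = λ_k⁻¹·|u_k block i|² and
    ``directions`` is the N×3 array of eigenvector blocks (sign fixed by
    the decomposition's convention).
    """
    dec = a.decompose()
    cols = _resolve_modes(dec, [k])
    lam = float(dec.eigenvalues[cols[0]])
    u = dec.eigenvectors[:, cols[0]].reshape(-1, 3)
    msf = np.sum(u**2, axis=1) / lam
    return msf, u


@dataclass
class CrossCorrelationMap:
    """Normalized fluctuation cross-correlations C_ij ∈ [−1, 1]."""

    c: np.ndarray


def cross_correlation(g: GnmModel) -> CrossCorrelationMap:
    """Normalized cross-correlation of residue fluctuations over all GNM modes.

    C_ij = ⟨ΔR_i·ΔR_j⟩ / [⟨ΔR_i²⟩⟨ΔR_j²⟩]^{1/2}, computed from the full
    pseudo-inverse of Γ; the diagonal is 1 by construction.  Requires a
    connected contact graph (single zero mode).
    """
    dec = g.decompose()
    if dec.n_zero != 1:
        raise DisconnectedNetworkError(
            f"cross-correlation requires a connected network; found {dec.n_zero} "
            f"zero modes ({g.n_components()} components)"
        )
    cols = np.arange(dec.n_zero, dec.eigenvalues.size)
    u = dec.eigenvectors[:, cols]
    pinv = (u / dec.eigenvalues[cols]) @ u.T
    diag = np.diag(pinv)
    if np.any(diag <= 0):
        raise ValueError("zero mean-square fluctuation; cannot normalize")
    c = pinv / np.sqrt(np.outer(diag, diag))
    return CrossCorrelationMap(c=c)


def write_matrix_csv(matrix: np.ndarray, path: str | Path) -> None:
    """Export a dense matrix as unrounded CSV (no header)."""
    np.savetxt(path, np.asarray(matrix), delimiter=",", fmt="%.17g")


def write_matrix_sparse(matrix: np.ndarray, path: str | Path) -> None:
    """Export nonzero entries as coordinate-format text: i, j, value (1-based)."""
    matrix = np.asarray(matrix)
    rows, cols = np.nonzero(matrix)
    with open(path, "w") as fh:
        for i, j in zip(rows, cols):
            fh.write(f"{i + 1},{j + 1},{matrix[i, j]:.17g}\n")
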
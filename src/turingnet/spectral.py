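"""Graph Fourier analysis of node fields in the Laplacian eigenbasis.

A node field x decomposes as x = sum_i k_i gamma_i over the orthonormal
eigenvectors gamma_i of a layer Laplacian.  On a connected graph the zero
eigenvalue is simple and gamma_1 is the constant vector, so a field is
spatially homogeneous exactly when every non-constant coefficient
vanishes — the spectral fingerprint of a Turing pattern is non-trivial
mass at eigenvalues inside the unstable interval.

Lattices have highly degenerate eigenspaces; individual eigenvectors
within a multiple eigenvalue are solver-dependent, so only per-eigenvalue
summed squared coefficients are rotation-invariant quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GraphSpectralDecomposition",
    "DISPLAY_FLOOR",
    "eigendecompose",
    "fourier_coefficients",
    "scatter_points",
    "spectral_mass_by_eigenvalue",
]

#: Default display floor for scatter plots: coefficients below 2^-18 in
#: magnitude are suppressed.
DISPLAY_FLOOR: float = 2.0 ** -18


class SpectralInputError(ValueError):
    """Asymmetric matrix or mismatched dimensions."""


@dataclass
class GraphSpectralDecomposition:
    """Orthonormal Laplacian eigenbasis, eigenvalues sorted descending (0 first)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns gamma_1 .. gamma_N

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]


def eigendecompose(L: np.ndarray) -> GraphSpectralDecomposition:
    """Eigenbasis of a symmetric (semi-negative-definite) Laplacian.

    Eigenvalues are returned descending, so index 0 carries the zero mode;
    on a connected graph its eigenvector is normalized to all-ones/sqrt(N)
    with positive entries.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise SpectralInputError(f"expected a square matrix, got shape {L.shape}")
    if not np.allclose(L, L.T, atol=1e-10):
        raise SpectralInputError("Laplacian must be symmetric")
    w, V = np.linalg.eigh(L)
    order = np.argsort(-w)
    w, V = w[order], V[:, order]
    # fix the sign of the leading (zero-mode) vector: constant and positive
    # on connected graphs, where it is +-ones/sqrt(N)
    if V[:, 0].sum() < 0:
        V[:, 0] = -V[:, 0]
    return GraphSpectralDecomposition(w, V)


def fourier_coefficients(field: np.ndarray, basis: GraphSpectralDecomposition) -> np.ndarray:
    """Projections k_i = <field, gamma_i>; Parseval-exact by orthonormality."""
    field = np.asarray(field, dtype=float)
    if field.shape != (basis.n,):
        raise SpectralInputError(
            f"field length {field.shape} does not match basis size {basis.n}"
        )
    return basis.eigenvectors.T @ field


def reconstruct(coeffs: np.ndarray, basis: GraphSpectralDecomposition) -> np.ndarray:
    """Inverse transform sum_i k_i gamma_i."""
    return basis.eigenvectors @ np.asarray(coeffs, dtype=float)


def scatter_points(
    field: np.ndarray,
    basis: GraphSpectralDecomposition,
    floor: float = DISPLAY_FLOOR,
) -> list[tuple[float, float]]:
    """Spectral scatter data: (-eigenvalue, log2|k|) for |k| above the floor.

    Negating the (non-positive) eigenvalues puts every point in the right
    half-plane; the log2 ordinate matches the conventional display scale.
    """
    if floor <= 0:
        raise SpectralInputError("floor must be positive")
    k = fourier_coefficients(field, basis)
    return [
        (float(-lam), math.log2(abs(ki)))
        for lam, ki in zip(basis.eigenvalues, k)
        if abs(ki) > floor
    ]


def spectral_mass_by_eigenvalue(
    field: np.ndarray,
    basis: GraphSpectralDecomposition,
    decimals: int = 8,
) -> dict[float, float]:
    """Summed squared coefficients per (rounded) eigenvalue.

    Rotation-invariant within degenerate eigenspaces, unlike individual
    coefficients; the rounding merges numerically-split multiplets.
    """
    k = fourier_coefficients(field, basis)
    mass: dict[float, float] = {}
    for lam, ki in zip(np.round(basis.eigenvalues, decimals), k):
        mass[float(lam)] = mass.get(float(lam), 0.0) + float(ki) ** 2
    return mass
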
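"""Anisotropic network model (ANM) dynamics and matrix comparison.

The protein is a network of Cα beads joined by Hookean springs within a
15 Å cutoff. Springs are distance-dependent — closer node pairs get
stiffer springs; the default is gamma(d) = gamma0 * (d0/d)^2 with
d0 = 1 Å, gamma0 = 1 (arbitrary stiffness units) — so the model has no
absolute energy scale and fluctuations are reported in arbitrary units.
Normal modes are eigenvectors of the 3N x 3N Hessian; the six zero modes
are rigid-body motions. Analyses use the softest modes accounting for
80% of the variance (mode variance proportional to 1/lambda). Per-residue
square fluctuations are summed over those modes, trimmed of five residues
at each terminus, and z-scored. Motion coupling between residues is the
normalized cross-correlation matrix, and two such matrices are compared
with the Rv coefficient, a matrix-level Pearson analogue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AnmModel",
    "FluctuationProfile",
    "DisconnectedNetworkWarning",
    "inverse_square_spring",
    "uniform_spring",
    "build_anm",
    "select_modes_80",
    "square_fluctuations",
    "normalize_fluctuations",
    "cross_correlation",
    "rv_coefficient",
    "coupling_fraction",
]

ZERO_MODE_RTOL = 1e-8


class DisconnectedNetworkWarning(UserWarning):
    """Contact graph is disconnected: more than 6 zero modes."""


def inverse_square_spring(gamma0: float = 1.0, d0: float = 1.0) -> Callable:
    """Distance-dependent stiffness gamma(d) = gamma0 * (d0/d)**2."""

    def gamma(d: np.ndarray) -> np.ndarray:
        return gamma0 * (d0 / d) ** 2

    return gamma


def uniform_spring(gamma0: float = 1.0) -> Callable:
    def gamma(d: np.ndarray) -> np.ndarray:
        return gamma0 * np.ones_like(d)

    return gamma


@dataclass
class AnmModel:
    coords: np.ndarray
    cutoff: float
    hessian: np.ndarray
    eigenvalues: np.ndarray        # ascending
    eigenvectors: np.ndarray       # columns, same order
    zero_modes: int

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def nonzero_modes(self) -> np.ndarray:
        return np.arange(self.zero_modes, self.eigenvalues.size)

    def mode_vectors(self, k: int) -> np.ndarray:
        """Mode k reshaped to per-residue 3-vectors (N x 3)."""
        return self.eigenvectors[:, k].reshape(-1, 3)


@dataclass
class FluctuationProfile:
    raw: np.ndarray                # all residues, arbitrary Å²-scale units
    normalized: np.ndarray         # retained residues after trimming, z-scored
    trim: int

    @property
    def retained_slice(self) -> slice:
        return slice(self.trim, self.raw.size - self.trim)


def build_anm(
    coords: np.ndarray,
    cutoff: float = 15.0,
    spring: Callable | None = None,
) -> AnmModel:
    """Assemble and diagonalize the ANM Hessian.

    For a contacting pair (i, j) at native distance d the off-diagonal
    3x3 superblock is -gamma(d)/d^2 * r_ij r_ij^T (r_ij the separation
    vector); diagonal superblocks are minus the sum of the row's
    off-diagonal blocks, which enforces translation invariance. A
    disconnected contact graph yields more than six zero modes and is
    reported with a warning.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if coords.ndim != 2 or coords.shape[1] != 3 or n < 3:
        raise ValueError("need an N x 3 coordinate array with N >= 3")
    if np.linalg.matrix_rank(coords - coords.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("coordinates are collinear; ANM is degenerate")
    gamma = inverse_square_spring() if spring is None else spring

    dmat = squareform(pdist(coords))
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dmat[i, j]
            if d > cutoff or d == 0.0:
                continue
            rij = coords[j] - coords[i]
            block = -(float(gamma(d)) / d**2) * np.outer(rij, rij)
            hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            hess[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            hess[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block

    w, v = np.linalg.eigh(hess)
    w = np.where(np.abs(w) < ZERO_MODE_RTOL * max(np.abs(w).max(), 1.0), 0.0, w)
    zero_modes = int(np.sum(w == 0.0))
    if zero_modes > 6:
        warnings.warn(
            f"contact network disconnected: {zero_modes} zero modes",
            DisconnectedNetworkWarning,
        )
    return AnmModel(
        coords=coords,
        cutoff=cutoff,
        hessian=hess,
        eigenvalues=w,
        eigenvectors=v,
        zero_modes=zero_modes,
    )


def select_modes_80(m: AnmModel, fraction: float = 0.80) -> list[int]:
    """Softest modes whose cumulative variance reaches the target fraction.

    Mode variance is proportional to 1/lambda; zero modes are excluded.
    Modes are taken in ascending-eigenvalue order until the cumulative
    fraction of sum(1/lambda) first reaches ``fraction``.
    """
    nz = m.nonzero_modes()
    if nz.size == 0:
        raise ValueError("model has no non-zero modes")
    inv = 1.0 / m.eigenvalues[nz]
    cum = np.cumsum(inv) / inv.sum()
    k = int(np.searchsorted(cum, fraction - 1e-12)) + 1
    return [int(i) for i in nz[:k]]


def square_fluctuations(m: AnmModel, modes: Sequence[int]) -> np.ndarray:
    """Per-residue summed square fluctuation over the selected modes.

    flucs(i) = sum_k |v_k(i)|^2 / lambda_k with v_k(i) the residue's
    3-vector in mode k.
    """
    modes = np.asarray(modes, int)
    if np.any(m.eigenvalues[modes] <= 0):
        raise ValueError("fluctuations require strictly positive modes")
    flucs = np.zeros(m.n_residues)
    for k in modes:
        vk = m.mode_vectors(k)
        flucs += np.sum(vk**2, axis=1) / m.eigenvalues[k]
    return flucs


def normalize_fluctuations(
    flucs: np.ndarray, trim: int = 5
) -> FluctuationProfile:
    """Trim terminal residues then z-score the remainder.

    Drops ``trim`` residues from each end (the terminal tails dominate
    raw elastic-network fluctuations and would swamp the z-scores) and
    standardizes what is left. A constant profile has no z-score; it is
    returned as zeros with a warning.
    """
    flucs = np.asarray(flucs, float)
    if flucs.size <= 2 * trim:
        raise ValueError(
            f"profile of length {flucs.size} too short to trim {trim}+{trim}"
        )
    kept = flucs[trim : flucs.size - trim] if trim else flucs.copy()
    sd = kept.std()
    if sd == 0:
        warnings.warn("constant fluctuation profile; z-scores undefined")
        normalized = np.zeros_like(kept)
    else:
        normalized = (kept - kept.mean()) / sd
    return FluctuationProfile(raw=flucs, normalized=normalized, trim=trim)


def cross_correlation(m: AnmModel, modes: Sequence[int]) -> np.ndarray:
    """Normalized residue-residue motion correlation matrix in [-1, 1].

    C_ij = sum_k v_k(i).v_k(j) / lambda_k, normalized by
    sqrt(C_ii C_jj) over the same mode set; the diagonal is 1.
    """
    modes = np.asarray(modes, int)
    n = m.n_residues
    cov = np.zeros((n, n))
    for k in modes:
        vk = m.mode_vectors(k)
        cov += (vk @ vk.T) / m.eigenvalues[k]
    diag = np.sqrt(np.diag(cov))
    if np.any(diag == 0):
        raise ValueError("zero self-covariance; cannot normalize")
    c = cov / np.outer(diag, diag)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def rv_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Rv coefficient between two symmetric matrices.

    Rv = trace(AB) / sqrt(trace(AA) trace(BB)); equals 1 for A vs any
    positive multiple of A and lies in [0, 1] for positive semidefinite
    inputs.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    denom = np.sqrt(np.trace(a @ a) * np.trace(b @ b))
    if denom == 0:
        raise ValueError("Rv undefined for a zero matrix")
    return float(np.trace(a @ b) / denom)


def coupling_fraction(c: np.ndarray, threshold: float = 0.7) -> float:
    """Fraction of off-diagonal pairs with |C_ij| >= threshold (inclusive)."""
    c = np.asarray(c, float)
    n = c.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    vals = np.abs(c[iu])
    return float(np.mean(vals >= threshold))
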
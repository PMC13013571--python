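"""Takens delay embedding and the symmetric 2D projections that define SPAR.

An N-dimensional delay embedding of a signal x places the vectors
``(x(t), x(t+τ), ..., x(t+(N−1)τ))`` in phase space, with the delay τ chosen
as the average cycle length divided by N so the coordinates straddle one
beat.  The symmetric projection k views this cloud along directions
orthogonal to (1, 1, ..., 1):

    u_j = sqrt(2/N) · cos(2πkj/N),   v_j = sqrt(2/N) · sin(2πkj/N)

Both weight vectors sum to zero, so adding any constant to the signal leaves
the projected cloud unchanged — baseline offset cancels exactly.  For N=3,
k=1 this is the classic view down the (1,1,1) diagonal.  Valid projection
indices are k = 1 .. floor((N−1)/2); over N = 3..9 there are 16 (N, k)
combinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Supported embedding dimensions.
N_RANGE = range(3, 10)


@dataclass(frozen=True)
class DelayEmbedding:
    """Matrix of delay vectors: row t is (x(t), x(t+τ), ..., x(t+(N−1)τ))."""

    N: int
    tau: int
    vectors: np.ndarray
    source_fs: float


@dataclass(frozen=True)
class AttractorProjection:
    """2D point cloud from the (N, k) symmetric projection of an embedding."""

    N: int
    k: int
    points: np.ndarray  # (M, 2) array of (u, v) coordinates


def _check_N(N: int) -> None:
    if N not in N_RANGE:
        raise ValueError(f"embedding dimension N must be in 3..9, got {N}")


def embedding_delay(L_samples: float, N: int) -> int:
    """Delay τ = round(L/N) samples (half-away-from-zero), minimum 1.

    For N=3 this spaces the three delay coordinates one third of the average
    cycle length apart.
    """
    _check_N(N)
    if L_samples < N:
        raise ValueError(
            f"cycle too short for dimension: L={L_samples} samples < N={N}"
        )
    tau = int(math.floor(L_samples / N + 0.5))  # half-away-from-zero (L, N > 0)
    return max(tau, 1)


def delay_embed(signal: np.ndarray, N: int, tau: int) -> DelayEmbedding:
    """Build the Takens delay embedding with dimension N and delay τ.

    Every matrix entry is an exact copy of a signal sample; the row count is
    M = len(signal) − (N−1)·τ.
    """
    _check_N(N)
    if tau < 1 or int(tau) != tau:
        raise ValueError(f"delay tau must be a positive integer, got {tau}")
    x = np.asarray(signal, dtype=float)
    tau = int(tau)
    M = x.size - (N - 1) * tau
    if M < 1:
        raise ValueError(
            f"signal of length {x.size} too short for N={N}, tau={tau} "
            f"(needs > {(N - 1) * tau} samples)"
        )
    cols = [x[j * tau: j * tau + M] for j in range(N)]
    return DelayEmbedding(N=N, tau=tau, vectors=np.column_stack(cols), source_fs=0.0)


def valid_projections(N: int) -> list[int]:
    """Projection indices k = 1 .. floor((N−1)/2) for dimension N."""
    _check_N(N)
    return list(range(1, (N - 1) // 2 + 1))


def all_projection_cases(n_range=N_RANGE) -> list[tuple[int, int]]:
    """Every (N, k) combination; 16 cases over N = 3..9."""
    return [(N, k) for N in n_range for k in valid_projections(N)]


def projection_basis(N: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal projection weight pair (u, v) for dimension N, index k.

    ``u[j] = sqrt(2/N)·cos(2πkj/N)`` and ``v[j] = sqrt(2/N)·sin(2πkj/N)``;
    both are exactly orthogonal to (1, ..., 1) for 1 ≤ k ≤ floor((N−1)/2),
    which is what cancels baseline offset.
    """
    _check_N(N)
    if k not in valid_projections(N):
        raise ValueError(
            f"projection index k={k} invalid for N={N}; "
            f"valid: {valid_projections(N)}"
        )
    j = np.arange(N)
    scale = math.sqrt(2.0 / N)
    angles = 2.0 * np.pi * k * j / N
    return scale * np.cos(angles), scale * np.sin(angles)


def project(embedding: DelayEmbedding, k: int) -> AttractorProjection:
    """Project a delay embedding onto the (N, k) symmetric 2D view."""
    u_w, v_w = projection_basis(embedding.N, k)
    pts = np.column_stack([embedding.vectors @ u_w, embedding.vectors @ v_w])
    return AttractorProjection(N=embedding.N, k=k, points=pts)


def spar_projection(signal: np.ndarray, L_samples: float, N: int, k: int) -> AttractorProjection:
    """Convenience: delay-embed with τ = round(L/N) and project in one call."""
    tau = embedding_delay(L_samples, N)
    return project(delay_embed(signal, N, tau), k)
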
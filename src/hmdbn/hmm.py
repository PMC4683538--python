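"""Scaled forward-backward, Viterbi and Baum-Welch re-estimation.

This is the inference engine for one node's hidden-graph chain: an HMM
whose ``H`` states are candidate parent-set configurations and whose
emission matrix ``B[h, t] = P(x_i(t) | graph h, x(t-1))`` is precomputed
from the multinomial CPDs (so emissions vary freely with ``t``).

Rabiner-style per-step scaling keeps the recursions in the normalised
domain; the log-likelihood is recovered as the sum of log scaling factors.
The hot loops are numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "NodeHMMSpec",
    "Posteriors",
    "forward_backward",
    "viterbi",
    "reestimate_pi",
    "reestimate_A",
]

#: emissions are clipped below at this floor before any recursion, so a
#: configuration with zero expected counts cannot zero out a time column
EMISSION_FLOOR = 1e-12


@dataclass
class NodeHMMSpec:
    """HMM over hidden graphs: prior ``pi``, transitions ``A``, emissions ``B``.

    ``B`` has shape ``H × T`` with ``B[h, t]`` the probability of the
    observed child state at time ``t`` under graph ``h``.
    """

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=np.float64)
        self.A = np.asarray(self.A, dtype=np.float64)
        self.B = np.ascontiguousarray(self.B, dtype=np.float64)
        H = self.pi.shape[0]
        if self.A.shape != (H, H) or self.B.shape[0] != H:
            raise ValueError("inconsistent pi/A/B dimensions")
        if self.B.shape[1] < 1:
            raise ValueError("need at least one emission column (T >= 1)")
        self.validate()

    def validate(self, atol: float = 1e-8) -> None:
        if np.any(self.pi < 0) or np.any(self.A < 0):
            raise ValueError("negative probabilities in pi or A")
        if abs(self.pi.sum() - 1.0) > atol:
            raise ValueError("pi does not sum to 1")
        if np.max(np.abs(self.A.sum(axis=1) - 1.0)) > atol:
            raise ValueError("rows of A do not sum to 1")

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]

    @property
    def n_obs(self) -> int:
        return self.B.shape[1]


@dataclass
class Posteriors:
    """Smoothed posteriors from forward-backward.

    ``gamma[h, t] = P(q(t) = h | x)``; ``xi[t, h, h'] = P(q(t)=h,
    q(t+1)=h' | x)`` for the T-1 transitions; ``loglik = log P(x)``.
    """

    gamma: np.ndarray
    xi: np.ndarray
    loglik: float


@njit(cache=True)
def _forward_backward(pi, A, B):
    H, T = B.shape
    alpha = np.empty((T, H))
    beta = np.empty((T, H))
    scale = np.empty(T)

    a = pi * B[:, 0]
    s = a.sum()
    if s <= 0.0:
        return alpha, beta, scale, 0
    alpha[0] = a / s
    scale[0] = s
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[:, t]
        s = a.sum()
        if s <= 0.0:
            return alpha, beta, scale, t
        alpha[t] = a / s
        scale[t] = s

    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[:, t + 1] * beta[t + 1])) / scale[t + 1]
    return alpha, beta, scale, -1


@njit(cache=True)
def _pairwise_xi(alpha, beta, scale, A, B):
    H, T = B.shape
    xi = np.empty((T - 1, H, H))
    for t in range(T - 1):
        denom = scale[t + 1]
        for h in range(H):
            for g in range(H):
                xi[t, h, g] = (
                    alpha[t, h] * A[h, g] * B[g, t + 1] * beta[t + 1, g] / denom
                )
    return xi


def forward_backward(spec: NodeHMMSpec) -> Posteriors:
    """Exact smoothed posteriors of the hidden-graph chain.

    Raises ``FloatingPointError`` (naming the time point) if a time column
    of the emission matrix is numerically zero even after flooring.
    """
    B = np.maximum(spec.B, EMISSION_FLOOR)
    alpha, beta, scale, bad_t = _forward_backward(spec.pi, spec.A, B)
    if bad_t >= 0:
        raise FloatingPointError(
            f"forward recursion vanished at time point {bad_t}: "
            "emission column is zero under every hidden graph"
        )
    gamma = (alpha * beta).T
    gamma /= gamma.sum(axis=0, keepdims=True)
    T = spec.n_obs
    if T > 1:
        xi = _pairwise_xi(alpha, beta, scale, spec.A, B)
    else:
        xi = np.zeros((0, spec.n_states, spec.n_states))
    return Posteriors(gamma=gamma, xi=xi, loglik=float(np.log(scale).sum()))


@njit(cache=True)
def _viterbi(log_pi, log_A, log_B):
    H, T = log_B.shape
    delta = log_pi + log_B[:, 0]
    back = np.zeros((T, H), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(H)
        for g in range(H):
            best = delta[0] + log_A[0, g]
            arg = 0
            for h in range(1, H):
                v = delta[h] + log_A[h, g]
                if v > best:  # strict: ties stay at the lower index
                    best = v
                    arg = h
            new[g] = best + log_B[g, t]
            back[t, g] = arg
        delta = new
    path = np.empty(T, dtype=np.int64)
    last = 0
    for h in range(1, H):
        if delta[h] > delta[last]:
            last = h
    path[T - 1] = last
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def viterbi(spec: NodeHMMSpec) -> np.ndarray:
    """Joint-MAP hidden-graph path; ties break toward the lower index."""
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.maximum(spec.pi, 1e-300))
        log_A = np.log(np.maximum(spec.A, 1e-300))
        log_B = np.log(np.maximum(spec.B, EMISSION_FLOOR))
    return _viterbi(log_pi, log_A, log_B)


def reestimate_pi(post: Posteriors) -> np.ndarray:
    """Baum-Welch update of the initial distribution: posterior at t=1."""
    pi = post.gamma[:, 0].copy()
    return pi / pi.sum()


def reestimate_A(post: Posteriors, prev_A: np.ndarray | None = None) -> np.ndarray:
    """Baum-Welch update of the transition matrix from pairwise posteriors.

    ``â[h, h'] = Σ_t ξ[t, h, h'] / Σ_t γ[h, t]``.  A row with zero expected
    occupancy carries no information; it keeps its previous value when
    ``prev_A`` is given, else falls back to uniform.
    """
    H = post.gamma.shape[0]
    if post.xi.shape[0] == 0:
        return np.eye(H) if prev_A is None else np.asarray(prev_A, float).copy()
    num = post.xi.sum(axis=0)
    occ = post.gamma[:, :-1].sum(axis=1)
    A = np.empty((H, H))
    for h in range(H):
        if occ[h] > 1e-12:
            A[h] = num[h] / occ[h]
        elif prev_A is not None:
            A[h] = prev_A[h]
        else:
            A[h] = 1.0 / H
        A[h] /= A[h].sum()
    return A
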
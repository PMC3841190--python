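"""Profile similarity scores.

Two profile columns P, Q (27-dim probability vectors) are compared with the
Jensen-Shannon divergence in log base 2,

    D_JS(P, Q) = 1/2 KL(P || M) + 1/2 KL(Q || M),   M = (P + Q) / 2,

which is symmetric, always finite (M dominates both arguments) and bounded
in [0, 1].  Two equal-length fragments are compared with the maximum of the
column-wise divergences over the paired positions (MJS): 0 means identical
profiles, and a single mismatching position suffices to raise the score —
an intentionally strict, ungapped criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import SAProfile

__all__ = ["FragmentWindow", "kl_divergence", "js_distance", "mjs", "js_rows", "js_matrix"]

_NORM_TOL = 1e-6


def _check_normalized(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > _NORM_TOL or np.min(p) < -_NORM_TOL:
        raise ValueError(f"{name} is not a normalized probability vector")
    return np.clip(p, 0.0, None)


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Kullback-Leibler divergence KL(P || Q) in bits.

    Convention 0·log(0/q) = 0; a position with P(i) > 0 and Q(i) = 0 gives
    +inf (never hit when Q is a JS mixture).
    """
    P = _check_normalized(P, "P")
    Q = _check_normalized(Q, "Q")
    mask = P > 0
    if np.any(Q[mask] == 0):
        return float("inf")
    return float(np.sum(P[mask] * np.log2(P[mask] / Q[mask])))


def _entropy_rows(A: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits of each row (0 log 0 := 0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(A > 0, A * np.log2(np.where(A > 0, A, 1.0)), 0.0)
    return -t.sum(axis=-1)


def js_distance(P: np.ndarray, Q: np.ndarray) -> float:
    """Jensen-Shannon divergence (base 2) between two probability vectors;
    symmetric, in [0, 1], zero iff P = Q."""
    P = _check_normalized(P, "P")
    Q = _check_normalized(Q, "Q")
    M = 0.5 * (P + Q)
    val = _entropy_rows(M[None, :])[0] - 0.5 * (
        _entropy_rows(P[None, :])[0] + _entropy_rows(Q[None, :])[0]
    )
    return float(min(max(val, 0.0), 1.0))


def js_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-paired JS divergences of two (n, k) row stacks."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    M = 0.5 * (A + B)
    val = _entropy_rows(M) - 0.5 * (_entropy_rows(A) + _entropy_rows(B))
    return np.clip(val, 0.0, 1.0)


def js_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs JS divergences: (nA, nB) matrix for row stacks A, B.

    Uses D_JS(p, q) = H((p+q)/2) - (H(p) + H(q))/2, so the pairwise cost is
    one entropy evaluation of the mixtures.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    hA = _entropy_rows(A)
    hB = _entropy_rows(B)
    M = 0.5 * (A[:, None, :] + B[None, :, :])
    hM = _entropy_rows(M)
    return np.clip(hM - 0.5 * (hA[:, None] + hB[None, :]), 0.0, 1.0)


@dataclass(frozen=True)
class FragmentWindow:
    """A contiguous run of profile columns describing one fragment.

    A fragment of n amino acids spans n - 3 columns; the search considers
    fragments of 6-27 aa, i.e. 3-24 columns.
    """

    profile: SAProfile
    start_col: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.start_col < 0 or self.n_cols < 1:
            raise ValueError("invalid window bounds")
        if self.start_col + self.n_cols > self.profile.n_rows:
            raise ValueError("window exceeds profile length")

    @property
    def cols(self) -> np.ndarray:
        return self.profile.window(self.start_col, self.n_cols)

    @property
    def n_res(self) -> int:
        return self.n_cols + 3


def mjs(a: FragmentWindow, b: FragmentWindow) -> float:
    """Maximum Jensen-Shannon score of two equal-length fragment windows:
    the max over paired columns of the column JS divergence."""
    if a.n_cols != b.n_cols:
        raise ValueError("fragment windows must have equal length")
    return float(np.max(js_rows(a.cols, b.cols)))
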
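"""Geometric superposition and quality metrics.

A matched bank fragment is a true positive when its Cα RMSD after optimal
rigid superposition (cRMSD) to the corresponding query fragment falls below
a size-dependent cutoff.  Because random same-size fragment pairs have a
size-dependent cRMSD distribution, the cutoff for size n is derived from
that background as max(mu_n - k*sigma_n, floor), with k = 2 by default and
a 0.5 Å floor so the rule never becomes vacuous.

Reported metrics: Prec = TP/(TP+FP) in %, Cov = % query residues covered by
at least one hit, TPCov = % covered by at least one true positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sa_alphabet import CaTrace

__all__ = [
    "kabsch_crmsd",
    "kabsch_crmsd_many",
    "TPRule",
    "EvalReport",
    "background_stats",
    "evaluate",
]


def kabsch_crmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Minimal Cα RMSD (Å) of two equal-size point sets over proper
    rotations and translations (Kabsch, determinant-corrected SVD; no
    reflections), symmetric in its arguments."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected two (n, 3) arrays of equal size")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    U, _, Vt = np.linalg.svd(Xc.T @ Yc)
    d = np.sign(np.linalg.det(U @ Vt))
    R = (U * np.array([1.0, 1.0, d])) @ Vt  # optimal proper rotation
    # explicit residual after superposition: immune to the catastrophic
    # cancellation of the trace-based closed form near zero RMSD
    diff = Xc @ R - Yc
    return float(np.sqrt(np.sum(diff * diff) / n))


def kabsch_crmsd_many(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Batched ``kabsch_crmsd``: X, Y of shape (m, n, 3) -> (m,) cRMSDs.
    Same determinant-corrected SVD solution, vectorized over the batch."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 3 or X.shape[2] != 3 or X.shape[1] < 3:
        raise ValueError("expected two (m, n, 3) arrays with n >= 3")
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    H = np.einsum("mni,mnj->mij", Xc, Yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("mij,mjk->mik", U, Vt)))
    Ud = U * np.stack([np.ones_like(d), np.ones_like(d), d], axis=1)[:, None, :]
    R = np.einsum("mij,mjk->mik", Ud, Vt)
    diff = np.einsum("mni,mij->mnj", Xc, R) - Yc
    return np.sqrt(np.sum(diff * diff, axis=(1, 2)) / n)


@dataclass
class TPRule:
    """Size-dependent true-positive cutoff from background cRMSD statistics.

    cutoff(n) = max(mu_n - k * sigma_n, floor)  [Å]
    """

    mu: dict[int, float]
    sigma: dict[int, float]
    k: float = 2.0
    floor: float = 0.5

    def cutoff(self, size: int) -> float:
        if size not in self.mu:
            raise KeyError(f"no background statistics for size {size}")
        return max(self.mu[size] - self.k * self.sigma[size], self.floor)

    def is_tp(self, size: int, crmsd: float) -> bool:
        return crmsd < self.cutoff(size)


@dataclass
class EvalReport:
    """Coverage / precision summary of a hit list against a known query
    structure.  ``prec`` is None (reported as NA) when there are no hits."""

    cov: float
    tpcov: float
    prec: float | None
    n_tp: int
    n_fp: int
    per_size: dict[int, dict[str, float]] = field(default_factory=dict)


def background_stats(
    bank,
    sizes=range(6, 28),
    n_samples: int = 500,
    seed: int = 0,
) -> dict[int, tuple[float, float]]:
    """Per-size mean and SD of the cRMSD over random same-size fragment
    pairs drawn from the bank (uniform over valid fragments, break-free)."""
    rng = np.random.default_rng(seed)
    out: dict[int, tuple[float, float]] = {}
    for n in sizes:
        frags = []
        for entry in bank.entries:
            mask = entry.trace.fragment_valid_mask(n)
            for s in np.nonzero(mask)[0]:
                frags.append(entry.trace.coords[s : s + n])
        if len(frags) < 2:
            raise ValueError(f"bank has fewer than 2 fragments of size {n}")
        i = rng.integers(0, len(frags), size=n_samples)
        j = rng.integers(0, len(frags) - 1, size=n_samples)
        j = np.where(j >= i, j + 1, j)  # distinct partner
        F = np.asarray(frags)
        vals = kabsch_crmsd_many(F[i], F[j])
        out[int(n)] = (float(vals.mean()), float(vals.std()))
    return out


def evaluate(kept_hits, query_trace: CaTrace, rule: TPRule) -> EvalReport:
    """Label hits TP/FP against the query structure and compute Prec, Cov
    and TPCov (percentages over query residues)."""
    n_res = len(query_trace)
    covered = np.zeros(n_res, dtype=bool)
    tp_covered = np.zeros(n_res, dtype=bool)
    n_tp = n_fp = 0
    per_size: dict[int, dict[str, list]] = {}
    for hit in kept_hits:
        s, n = hit.query_start, hit.query_len_aa
        if s < 0 or s + n > n_res:
            raise ValueError(f"hit span [{s}, {s + n}) outside query of length {n_res}")
        crmsd = kabsch_crmsd(hit.coords, query_trace.coords[s : s + n])
        is_tp = rule.is_tp(n, crmsd)
        covered[s : s + n] = True
        if is_tp:
            tp_covered[s : s + n] = True
            n_tp += 1
        else:
            n_fp += 1
        rec = per_size.setdefault(n, {"crmsd": [], "tp": []})
        rec["crmsd"].append(crmsd)
        rec["tp"].append(is_tp)
    prec = 100.0 * n_tp / (n_tp + n_fp) if (n_tp + n_fp) else None
    summary = {
        n: {
            "n_hits": len(r["crmsd"]),
            "mean_crmsd": float(np.mean(r["crmsd"])),
            "n_tp": int(sum(r["tp"])),
        }
        for n, r in per_size.items()
    }
    return EvalReport(
        cov=100.0 * covered.mean() if n_res else 0.0,
        tpcov=100.0 * tp_covered.mean() if n_res else 0.0,
        prec=prec,
        n_tp=n_tp,
        n_fp=n_fp,
        per_size=summary,
    )
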
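"""Hidden-Markov-model structural alphabet: Cα traces, 4-residue geometric
descriptors, and encoding of structures into letter strings (Viterbi) or
posterior probability profiles (forward-backward).

A structural alphabet is a finite set of canonical local backbone
conformations ("letters").  Each letter is a hidden state of an HMM whose
emission is a multivariate Gaussian over the geometry of one 4-residue
fragment; successive fragments overlap by three residues, so an N-residue
chain maps to a series of N-3 states.  The default alphabet has 27 letters.

Descriptors for one fragment C1..C4 are the three non-consecutive Cα-Cα
distances d13, d14, d24 (Å) and the signed volume of the Cα tetrahedron
(Å³), whose sign distinguishes mirror-image conformations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "SA_LETTERS_27",
    "CA_DIST_MIN",
    "CA_DIST_MAX",
    "COVARIANCE_RIDGE",
    "SAModel",
    "CaTrace",
    "DescriptorVector",
    "fragment_descriptors",
    "trace_descriptors",
    "encode_viterbi",
    "posterior_profile",
    "fit_baum_welch",
    "fit_descriptor_hmm",
    "read_ca_trace",
]

# 27 distinct single-character state labels for the default alphabet.
SA_LETTERS_27: str = "ABCDEFGHIJKLMNOPQRSTUVWXYZa"

#: Consecutive Cα-Cα distances outside this window (Å) flag a chain break.
CA_DIST_MIN: float = 2.0
CA_DIST_MAX: float = 4.5

#: Ridge (Å²) added to the diagonal of degenerate emission covariances.
COVARIANCE_RIDGE: float = 1e-6

#: Marker emitted for positions whose 4-residue fragment spans a chain break.
GAP_CHAR: str = "-"

_PROB_TOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorVector:
    """Geometry of one 4-residue fragment.

    Attributes
    ----------
    d13, d14, d24 : float
        Non-consecutive Cα-Cα distances in Å.
    v : float
        Signed volume of the Cα tetrahedron in Å³ (scalar triple product
        over six); mirror-image fragments have opposite signs.
    """

    d13: float
    d14: float
    d24: float
    v: float

    def as_array(self) -> np.ndarray:
        return np.array([self.d13, self.d14, self.d24, self.v])


@dataclass
class CaTrace:
    """An ordered Cα trace of one protein chain.

    ``residue_ids`` preserves author numbering (1-based); ``coords`` is an
    (n, 3) array in Å.  Positions where the consecutive Cα-Cα distance falls
    outside [CA_DIST_MIN, CA_DIST_MAX] are flagged as chain breaks; no
    fragment spanning a break is ever encoded or emitted downstream.
    """

    chain_id: str
    residue_ids: list[int]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.residue_ids) != len(self.coords):
            raise ValueError("residue_ids and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def breaks(self) -> np.ndarray:
        """Sorted indices i such that the bond i -> i+1 is a chain break."""
        d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        return np.nonzero((d < CA_DIST_MIN) | (d > CA_DIST_MAX))[0]

    def fragment_valid_mask(self, n_res: int = 4) -> np.ndarray:
        """Boolean mask over fragment start positions: True where the
        n_res-residue fragment starting there spans no chain break."""
        n = len(self) - n_res + 1
        if n <= 0:
            return np.zeros(0, dtype=bool)
        mask = np.ones(n, dtype=bool)
        for b in self.breaks:
            lo = max(0, b - n_res + 2)
            mask[lo : b + 1] = False
        return mask

    def segments(self, min_len: int = 4) -> list[tuple[int, int]]:
        """Contiguous break-free residue ranges [start, stop) of length >=
        min_len."""
        edges = [0, *(b + 1 for b in self.breaks), len(self)]
        return [
            (edges[k], edges[k + 1])
            for k in range(len(edges) - 1)
            if edges[k + 1] - edges[k] >= min_len
        ]


@dataclass
class SAModel:
    """The structural-alphabet HMM.

    Parameters
    ----------
    state_labels : str or sequence of single characters, unique.
    emission_means : (k, 4) descriptor means (d13, d14, d24 in Å; v in Å³).
    emission_covariances : (k, 4, 4) symmetric positive-definite.
    transitions : (k, k) row-stochastic.
    initial_probs : (k,) summing to 1.
    """

    state_labels: str
    emission_means: np.ndarray
    emission_covariances: np.ndarray
    transitions: np.ndarray
    initial_probs: np.ndarray

    def __post_init__(self) -> None:
        self.state_labels = "".join(self.state_labels)
        self.emission_means = np.asarray(self.emission_means, dtype=float)
        self.emission_covariances = np.asarray(self.emission_covariances, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        k = self.n_states
        if len(set(self.state_labels)) != k:
            raise ValueError("state labels must be unique")
        if self.emission_means.shape != (k, 4):
            raise ValueError("emission_means must be (n_states, 4)")
        if self.emission_covariances.shape != (k, 4, 4):
            raise ValueError("emission_covariances must be (n_states, 4, 4)")
        if self.transitions.shape != (k, k):
            raise ValueError("transitions must be (n_states, n_states)")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=_PROB_TOL):
            raise ValueError("transition rows must sum to 1")
        if abs(self.initial_probs.sum() - 1.0) > _PROB_TOL:
            raise ValueError("initial_probs must sum to 1")
        for s in range(k):
            c = self.emission_covariances[s]
            if not np.allclose(c, c.T, atol=1e-8):
                raise ValueError(f"covariance of state {s} not symmetric")
            if np.min(np.linalg.eigvalsh(c)) <= 0:
                raise ValueError(f"covariance of state {s} not positive-definite")
        # cached Cholesky factors for emission log-densities
        self._chol = np.linalg.cholesky(self.emission_covariances)
        self._logdet = 2.0 * np.sum(
            np.log(np.diagonal(self._chol, axis1=1, axis2=2)), axis=1
        )

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def log_emission(self, descriptors: np.ndarray) -> np.ndarray:
        """Gaussian log-densities, shape (T, n_states), for a (T, 4) array."""
        from scipy.linalg import solve_triangular

        X = np.atleast_2d(np.asarray(descriptors, dtype=float))
        T = X.shape[0]
        out = np.empty((T, self.n_states))
        for s in range(self.n_states):
            diff = X - self.emission_means[s]
            y = solve_triangular(self._chol[s], diff.T, lower=True)
            maha = np.sum(y * y, axis=0)
            out[:, s] = -0.5 * (maha + self._logdet[s] + 4 * np.log(2 * np.pi))
        return out

    # -- JSON persistence ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "labels": list(self.state_labels),
            "means": self.emission_means.tolist(),
            "covariances": self.emission_covariances.tolist(),
            "transitions": self.transitions.tolist(),
            "initial": self.initial_probs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SAModel":
        return cls(
            state_labels="".join(d["labels"]),
            emission_means=np.array(d["means"]),
            emission_covariances=np.array(d["covariances"]),
            transitions=np.array(d["transitions"]),
            initial_probs=np.array(d["initial"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SAModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_default_model() -> SAModel:
    """The 27-letter toy alphabet shipped with the package (fitted by
    ``fit_baum_welch`` on a generated motif bank; a stand-in trained on
    synthetic geometry, not a published parameter set)."""
    from importlib.resources import files

    return SAModel.from_dict(
        json.loads(files("safrag.data").joinpath("sa27_toy_model.json").read_text())
    )


# ---------------------------------------------------------------------------
# Geometric descriptors
# ---------------------------------------------------------------------------

def fragment_descriptors(four_ca_coords: np.ndarray) -> DescriptorVector:
    """Descriptors of one 4-residue fragment.

    d13 = |C1-C3|, d14 = |C1-C4|, d24 = |C2-C4|; v is the signed volume of
    the tetrahedron C1..C4, positive or negative according to the scalar
    triple product (C2-C1)·((C3-C1)×(C4-C1))/6, so a fragment and its mirror
    image share distances but have opposite v.
    """
    X = np.asarray(four_ca_coords, dtype=float)
    if X.shape != (4, 3):
        raise ValueError("expected 4 Cα coordinates of dimension 3")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite coordinates")
    d13 = float(np.linalg.norm(X[0] - X[2]))
    d14 = float(np.linalg.norm(X[0] - X[3]))
    d24 = float(np.linalg.norm(X[1] - X[3]))
    a, b, c = X[1] - X[0], X[2] - X[0], X[3] - X[0]
    v = float(np.dot(a, np.cross(b, c)) / 6.0)
    return DescriptorVector(d13, d14, d24, v)


def trace_descriptors(trace: CaTrace) -> np.ndarray:
    """Descriptors for all N-3 overlapping fragments of a trace, shape
    (N-3, 4).  Rows spanning chain breaks are computed but should be masked
    via ``trace.fragment_valid_mask()``."""
    X = trace.coords
    if len(X) < 4:
        raise ValueError("trace must have at least 4 residues")
    C1, C2, C3, C4 = X[:-3], X[1:-2], X[2:-1], X[3:]
    d13 = np.linalg.norm(C1 - C3, axis=1)
    d14 = np.linalg.norm(C1 - C4, axis=1)
    d24 = np.linalg.norm(C2 - C4, axis=1)
    v = np.einsum("ij,ij->i", C2 - C1, np.cross(C3 - C1, C4 - C1)) / 6.0
    return np.column_stack([d13, d14, d24, v])


# ---------------------------------------------------------------------------
# Decoding (Viterbi and forward-backward), natural-log space
# ---------------------------------------------------------------------------

def _viterbi(logB: np.ndarray, logA: np.ndarray, logpi: np.ndarray) -> np.ndarray:
    T, k = logB.shape
    delta = logpi + logB[0]
    back = np.zeros((T, k), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(k)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _forward_backward(logB: np.ndarray, logA: np.ndarray, logpi: np.ndarray) -> np.ndarray:
    T, k = logB.shape
    alpha = np.empty((T, k))
    alpha[0] = logpi + logB[0]
    for t in range(1, T):
        alpha[t] = logB[t] + logsumexp(alpha[t - 1][:, None] + logA, axis=0)
    beta = np.zeros((T, k))
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(logA + (logB[t + 1] + beta[t + 1])[None, :], axis=1)
    g = alpha + beta
    g -= logsumexp(g, axis=1, keepdims=True)
    return np.exp(g)


def _model_logs(model: SAModel) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore"):
        return np.log(model.transitions), np.log(model.initial_probs)


def encode_viterbi(trace: CaTrace, model: SAModel) -> str:
    """Most probable letter string (length N-3) for a Cα trace.

    Chain breaks split the trace: each break-free segment is decoded
    independently and positions whose fragment spans a break are emitted as
    the gap marker '-'.
    """
    if len(trace) < 4:
        raise ValueError("trace must have at least 4 residues")
    logA, logpi = _model_logs(model)
    letters = [GAP_CHAR] * (len(trace) - 3)
    for start, stop in trace.segments():
        seg = CaTrace(trace.chain_id, trace.residue_ids[start:stop], trace.coords[start:stop])
        logB = model.log_emission(trace_descriptors(seg))
        path = _viterbi(logB, logA, logpi)
        for j, s in enumerate(path):
            letters[start + j] = model.state_labels[s]
    return "".join(letters)


def posterior_profile(trace: CaTrace, model: SAModel):
    """Forward-backward posterior profile of a trace: an (N-3) x n_states
    matrix of state probabilities, each row summing to 1.

    Positions spanning a chain break carry the uniform distribution (no
    geometric evidence); downstream search never emits fragments across
    breaks, so these rows are placeholders only.
    """
    from .profiles import SAProfile

    if len(trace) < 4:
        raise ValueError("trace must have at least 4 residues")
    logA, logpi = _model_logs(model)
    k = model.n_states
    rows = np.full((len(trace) - 3, k), 1.0 / k)
    for start, stop in trace.segments():
        seg = CaTrace(trace.chain_id, trace.residue_ids[start:stop], trace.coords[start:stop])
        logB = model.log_emission(trace_descriptors(seg))
        rows[start : start + logB.shape[0]] = _forward_backward(logB, logA, logpi)
    return SAProfile(source_id=trace.chain_id, rows=rows, letter_order=model.state_labels)


# ---------------------------------------------------------------------------
# Baum-Welch fitting (delegated to hmmlearn's Gaussian HMM EM)
# ---------------------------------------------------------------------------

def fit_baum_welch(
    traces: Iterable[CaTrace],
    n_states: int,
    seed: int,
    max_iter: int = 100,
    tol: float = 1e-3,
    labels: str | None = None,
    transition_stickiness: float = 0.0,
    covariance_floor: float = COVARIANCE_RIDGE,
    covariance_cap: float | None = None,
    n_init: int = 1,
) -> SAModel:
    """Fit a structural-alphabet HMM to descriptor sequences by EM.

    Each break-free segment of each trace contributes one observation
    sequence.  Deterministic for a fixed seed.  The per-iteration
    log-likelihood history is attached as ``model.log_likelihoods``
    (non-decreasing for plain maximum likelihood, an EM guarantee).

    ``transition_stickiness`` adds Dirichlet pseudocounts on the transition
    diagonal (a sticky-HMM prior).  With many states and few underlying
    conformations, plain EM splits one conformation across phase-alternating
    state pairs, making the encoding of identical geometries depend on an
    arbitrary symmetry break; a sticky prior keeps each conformation in one
    self-looping state so that equal geometry encodes to equal profiles.
    """
    seqs = []
    for tr in traces:
        for start, stop in tr.segments():
            seg = CaTrace(tr.chain_id, tr.residue_ids[start:stop], tr.coords[start:stop])
            seqs.append(trace_descriptors(seg))
    if not seqs:
        raise ValueError("no encodable segments in the input traces")
    return fit_descriptor_hmm(
        seqs,
        n_states,
        seed,
        max_iter=max_iter,
        tol=tol,
        labels=labels,
        transition_stickiness=transition_stickiness,
        covariance_floor=covariance_floor,
        covariance_cap=covariance_cap,
        n_init=n_init,
    )


def fit_descriptor_hmm(
    sequences: Sequence[np.ndarray],
    n_states: int,
    seed: int,
    max_iter: int = 100,
    tol: float = 1e-3,
    labels: str | None = None,
    transition_stickiness: float = 0.0,
    covariance_floor: float = COVARIANCE_RIDGE,
    covariance_cap: float | None = None,
    n_init: int = 1,
) -> SAModel:
    """EM fit of the alphabet HMM directly on descriptor sequences (each a
    (T_i, 4) array); ``fit_baum_welch`` delegates here after extracting
    break-free descriptor segments from traces.

    ``n_init`` > 1 runs EM from that many seed-derived initializations and
    keeps the highest-likelihood solution (EM is only locally convergent);
    still deterministic for a fixed seed.

    ``covariance_cap`` (Å²), when given, caps the eigenvalues of the fitted
    emission covariances.  Letters of a structural alphabet are meant to be
    *specific* local shapes; on geometrically sparse training sets EM can
    park a catch-all state with a huge covariance over heterogeneous
    regions, and runs of such a letter then score as mutual matches between
    unrelated structures.  Capping keeps every letter geometrically
    committed.
    """
    from hmmlearn.hmm import GaussianHMM
    from hmmlearn.base import ConvergenceMonitor

    class _FullHistoryMonitor(ConvergenceMonitor):
        def __init__(self, tol, n_iter, verbose):
            super().__init__(tol, n_iter, verbose)
            self.full_history: list[float] = []

        def report(self, log_prob):
            self.full_history.append(float(log_prob))
            super().report(log_prob)

    seqs = [np.asarray(s, dtype=float) for s in sequences]
    X = np.concatenate(seqs)
    lengths = [len(s) for s in seqs]
    if len(X) < n_states:
        raise ValueError("fewer fragments than states")

    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    hmm = None
    for restart in range(n_init):
        cand = GaussianHMM(
            n_components=n_states,
            covariance_type="full",
            min_covar=covariance_floor,
            n_iter=max_iter,
            tol=tol,
            random_state=seed + restart * 9973,
            transmat_prior=1.0 + transition_stickiness * np.eye(n_states),
        )
        cand.monitor_ = _FullHistoryMonitor(cand.tol, cand.n_iter, cand.verbose)
        cand.fit(X, lengths)
        if hmm is None or cand.monitor_.full_history[-1] > hmm.monitor_.full_history[-1]:
            hmm = cand

    covs = np.asarray(hmm.covars_)
    # symmetrise and ridge against numerically degenerate components
    covs = 0.5 * (covs + np.transpose(covs, (0, 2, 1)))
    for s in range(n_states):
        if covariance_cap is not None:
            w, V = np.linalg.eigh(covs[s])
            covs[s] = (V * np.minimum(w, covariance_cap)) @ V.T
            covs[s] = 0.5 * (covs[s] + covs[s].T)
        if np.min(np.linalg.eigvalsh(covs[s])) <= COVARIANCE_RIDGE:
            covs[s] += np.eye(4) * COVARIANCE_RIDGE
    trans = hmm.transmat_ / hmm.transmat_.sum(axis=1, keepdims=True)
    start = hmm.startprob_ / hmm.startprob_.sum()
    if labels is None:
        labels = SA_LETTERS_27[:n_states] if n_states <= 27 else None
    if labels is None:
        raise ValueError("labels must be given for n_states > 27")
    model = SAModel(
        state_labels=labels,
        emission_means=hmm.means_,
        emission_covariances=covs,
        transitions=trans,
        initial_probs=start,
    )
    model.log_likelihoods = list(hmm.monitor_.full_history)  # type: ignore[attr-defined]
    return model


# ---------------------------------------------------------------------------
# Structure input (PDB / mmCIF via gemmi)
# ---------------------------------------------------------------------------

def read_ca_trace(path: str | Path, chain: str | None = None) -> CaTrace:
    """Read the Cα trace of one chain from a PDB or mmCIF file.

    The first model of a multi-model file is used; alternate locations are
    resolved by highest occupancy.  ``chain=None`` selects the first chain
    containing Cα atoms.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        residue_ids: list[int] = []
        coords: list[list[float]] = []
        for res in ch:
            cas = [a for a in res if a.name == "CA"]
            if not cas:
                continue
            ca = max(cas, key=lambda a: a.occ)
            residue_ids.append(res.seqid.num)
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        if coords:
            return CaTrace(ch.name, residue_ids, np.array(coords))
    raise ValueError(f"no Cα atoms found in {path} (chain={chain!r})")
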
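"""Brute-force ungapped profile mining and hit clustering.

For every query sub-sequence of 6-27 amino acids, every same-length window
of every bank protein is scored with the MJS criterion (no gaps: a single
insertion or deletion changes the local conformation, so alignment is by
rigid sliding only).  Windows under a size-specific threshold become hits;
hits are capped at the N best, clustered incrementally by Cα RMSD, and only
the heaviest cluster's representative survives as the candidate for that
(position, size) cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .assess import kabsch_crmsd
from .compare import FragmentWindow, js_matrix
from .profiles import SAProfile
from .sa_alphabet import CaTrace

__all__ = [
    "Bank",
    "BankEntry",
    "Hit",
    "Cluster",
    "Candidate",
    "CellResult",
    "SearchConfig",
    "default_crmsd_threshold",
    "scan_fragment",
    "cluster_hits",
    "select_cluster",
    "search_all",
]

MIN_FRAGMENT_AA = 6
MAX_FRAGMENT_AA = 27
DEFAULT_TOP_N = 500


@dataclass
class BankEntry:
    id: str
    trace: CaTrace
    profile: SAProfile

    def __post_init__(self) -> None:
        if self.profile.n_rows != len(self.trace) - 3:
            raise ValueError(
                f"bank entry {self.id}: profile has {self.profile.n_rows} rows "
                f"for a {len(self.trace)}-residue trace"
            )


@dataclass
class Bank:
    """A collection of (structure, profile) pairs mined by the search."""

    entries: list[BankEntry]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("bank ids must be unique")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Hit:
    """One matched bank fragment for one query sub-sequence.

    Spans are 0-based residue indices internally; ``query_len_aa`` equals
    ``bank_len_aa`` (ungapped matching).  ``coords`` holds the bank
    fragment's Cα coordinates.
    """

    query_start: int
    query_len_aa: int
    bank_id: str
    bank_start: int
    bank_len_aa: int
    mjs_score: float
    coords: np.ndarray

    def sort_key(self):
        return (self.mjs_score, self.bank_id, self.bank_start)


@dataclass
class Cluster:
    """Structurally coherent group of hits.  The representative is the
    lowest-MJS member; the weight W is the member count ("effectives")."""

    members: list[Hit]

    @property
    def weight(self) -> int:
        return len(self.members)

    @property
    def representative(self) -> Hit:
        return min(self.members, key=lambda h: h.sort_key())


@dataclass
class Candidate:
    """The surviving cluster representative for one (position, size) cell,
    annotated with the cluster weight and, later, an expected precision."""

    hit: Hit
    weight: int
    expected_precision: float | None = None
    kept: bool = True


def default_crmsd_threshold(size_aa: int) -> float:
    """Length-dependent clustering radius (Å): looser for longer fragments,
    0.5 Å at 6 aa growing 0.04 Å per residue, capped at 1.5 Å."""
    return min(0.5 + 0.04 * (size_aa - MIN_FRAGMENT_AA), 1.5)


@dataclass
class SearchConfig:
    """Search-stage parameters.

    mjs_thresholds maps fragment size (aa) to the hit-acceptance MJS value
    (calibrated so that hits under the threshold are ~95% precise);
    crmsd_thresholds maps size to the clustering radius in Å.
    """

    mjs_thresholds: dict[int, float]
    min_len: int = MIN_FRAGMENT_AA
    max_len: int = MAX_FRAGMENT_AA
    top_n: int = DEFAULT_TOP_N
    crmsd_thresholds: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        for n, t in self.mjs_thresholds.items():
            if not (0 < t <= 1):
                raise ValueError(f"MJS threshold for size {n} outside (0, 1]")

    def mjs_threshold(self, size_aa: int) -> float:
        return self.mjs_thresholds[size_aa]

    def crmsd_threshold(self, size_aa: int) -> float:
        return self.crmsd_thresholds.get(size_aa, default_crmsd_threshold(size_aa))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mjs_thresholds": {str(k): v for k, v in self.mjs_thresholds.items()},
                    "min_len": self.min_len,
                    "max_len": self.max_len,
                    "top_n": self.top_n,
                    "crmsd_thresholds": {str(k): v for k, v in self.crmsd_thresholds.items()},
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path) -> "SearchConfig":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mjs_thresholds={int(k): v for k, v in d["mjs_thresholds"].items()},
            min_len=d.get("min_len", MIN_FRAGMENT_AA),
            max_len=d.get("max_len", MAX_FRAGMENT_AA),
            top_n=d.get("top_n", DEFAULT_TOP_N),
            crmsd_thresholds={int(k): v for k, v in d.get("crmsd_thresholds", {}).items()},
        )


def default_search_config() -> SearchConfig:
    """Config with the MJS thresholds shipped with the package (calibrated
    on the bundled synthetic motif set at 0.95 precision)."""
    from importlib.resources import files

    d = json.loads(files("safrag.data").joinpath("default_mjs_thresholds.json").read_text())
    return SearchConfig(mjs_thresholds={int(k): v for k, v in d.items()})


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _window_scores(J: np.ndarray, qstart: int, n_cols: int) -> np.ndarray:
    """MJS of the query window [qstart, qstart + n_cols) against every bank
    window start j, given the full column-pair JS matrix J (nq, nb):
    score[j] = max_k J[qstart + k, j + k]."""
    nb = J.shape[1]
    m = nb - n_cols + 1
    if m <= 0:
        return np.zeros(0)
    stack = np.empty((n_cols, m))
    for k in range(n_cols):
        stack[k] = J[qstart + k, k : k + m]
    return stack.max(axis=0)


def _bank_start_mask(entry: BankEntry, size_aa: int) -> np.ndarray:
    """Valid bank window starts for a fragment of size_aa residues
    (break-free, within bounds)."""
    return entry.trace.fragment_valid_mask(size_aa)


def scan_fragment(
    query_window: FragmentWindow,
    bank: Bank,
    threshold: float,
    top_n: int = DEFAULT_TOP_N,
) -> list[Hit]:
    """Score one query window against every same-length bank window.

    Returns hits with MJS <= threshold, sorted ascending by (mjs, bank_id,
    bank_start) and truncated to the top_n best.  Bank windows spanning
    chain breaks are never emitted.
    """
    size_aa = query_window.n_res
    Q = query_window.cols
    hits: list[Hit] = []
    for entry in bank.entries:
        if entry.profile.n_rows < query_window.n_cols:
            continue
        J = js_matrix(Q, entry.profile.rows)
        scores = _window_scores(J, 0, query_window.n_cols)
        valid = _bank_start_mask(entry, size_aa)[: len(scores)]
        for j in np.nonzero(valid & (scores <= threshold))[0]:
            hits.append(
                Hit(
                    query_start=query_window.start_col,
                    query_len_aa=size_aa,
                    bank_id=entry.id,
                    bank_start=int(j),
                    bank_len_aa=size_aa,
                    mjs_score=float(scores[j]),
                    coords=entry.trace.coords[j : j + size_aa],
                )
            )
    hits.sort(key=Hit.sort_key)
    return hits[:top_n]


# ---------------------------------------------------------------------------
# Clustering and selection
# ---------------------------------------------------------------------------

def cluster_hits(hits: Sequence[Hit], crmsd_threshold: float) -> list[Cluster]:
    """Single-pass incremental clustering of MJS-sorted hits.

    Each hit joins the first existing cluster whose representative it
    superposes onto within crmsd_threshold (Kabsch cRMSD), else founds a
    new cluster.  Because hits arrive in ascending MJS order, the founder
    of each cluster is its lowest-MJS representative.
    """
    clusters: list[Cluster] = []
    for hit in hits:
        for cl in clusters:
            if kabsch_crmsd(hit.coords, cl.representative.coords) <= crmsd_threshold:
                cl.members.append(hit)
                break
        else:
            clusters.append(Cluster(members=[hit]))
    return clusters


def select_cluster(clusters: Sequence[Cluster]) -> Cluster | None:
    """The densest cluster: largest weight W; W-ties broken by lowest
    representative MJS, then by (bank_id, bank_start).  None on empty input."""
    if not clusters:
        return None
    return min(clusters, key=lambda c: (-c.weight, *c.representative.sort_key()))


# ---------------------------------------------------------------------------
# Full scan over positions and sizes
# ---------------------------------------------------------------------------

@dataclass
class CellResult:
    """All per-cell intermediates of one (position, size) search: the
    thresholded-and-capped hits, their clusters, and the selected cluster."""

    query_start: int
    size_aa: int
    hits: list[Hit]
    clusters: list[Cluster]
    best: Cluster


def search_all(
    query_profile: SAProfile,
    bank: Bank,
    cfg: SearchConfig,
    query_trace: CaTrace | None = None,
    collect_cells: bool = False,
) -> list[Candidate] | tuple[list[Candidate], list["CellResult"]]:
    """Run the scan -> cluster -> best-cluster protocol for every fragment
    size in [min_len, max_len] and every admissible query position.

    Emits at most one candidate per (position, size) cell.  The column-pair
    JS matrix against each bank entry is computed once and shared by all
    cells (the per-window MJS is a running diagonal maximum over it).  When
    the query structure is known, query windows spanning chain breaks are
    skipped.
    """
    nq = query_profile.n_rows
    if nq < cfg.min_len - 3:
        raise ValueError(f"query shorter than {cfg.min_len} residues")

    Js = [js_matrix(query_profile.rows, e.profile.rows) for e in bank.entries]

    candidates: list[Candidate] = []
    cells: list[CellResult] = []
    # M[e] holds the running diagonal max over windows of the current
    # column count c: M[e][i, j] = max_{k < c} J[e][i + k, j + k].
    M = [J.copy() for J in Js]
    c = 1
    for size_aa in range(cfg.min_len, cfg.max_len + 1):
        n_cols = size_aa - 3
        while c < n_cols:
            M = [np.maximum(Mi[:-1, :-1], Ji[c:, c:]) for Mi, Ji in zip(M, Js)]
            c += 1
        if nq - n_cols + 1 <= 0:
            break
        threshold = cfg.mjs_threshold(size_aa)
        bank_masks = [_bank_start_mask(e, size_aa) for e in bank.entries]
        query_valid = (
            query_trace.fragment_valid_mask(size_aa)
            if query_trace is not None
            else np.ones(nq - n_cols + 1, dtype=bool)
        )
        for i in range(nq - n_cols + 1):
            if not query_valid[i]:
                continue
            hits: list[Hit] = []
            for e_idx, entry in enumerate(bank.entries):
                Mi = M[e_idx]
                if Mi.shape[1] < 1 or i >= Mi.shape[0]:
                    continue
                scores = Mi[i]
                valid = bank_masks[e_idx][: len(scores)]
                for j in np.nonzero(valid & (scores <= threshold))[0]:
                    hits.append(
                        Hit(
                            query_start=i,
                            query_len_aa=size_aa,
                            bank_id=entry.id,
                            bank_start=int(j),
                            bank_len_aa=size_aa,
                            mjs_score=float(scores[j]),
                            coords=entry.trace.coords[j : j + size_aa],
                        )
                    )
            if not hits:
                continue
            hits.sort(key=Hit.sort_key)
            hits = hits[: cfg.top_n]
            clusters = cluster_hits(hits, cfg.crmsd_threshold(size_aa))
            best = select_cluster(clusters)
            if best is not None:
                candidates.append(
                    Candidate(
                        hit=best.representative,
                        weight=best.weight,
                        expected_precision=None,
                    )
                )
                if collect_cells:
                    cells.append(CellResult(i, size_aa, hits, clusters, best))
    if collect_cells:
        return candidates, cells
    return candidates
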
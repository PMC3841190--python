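"""Threshold calibration, the (MJS, W) expected-precision grid, and the
final redundancy elimination.

Two empirical relationships drive hit filtering.  First, among scored
fragment pairs the precision (fraction of true positives) rises as the MJS
score falls; the per-size hit threshold is the largest MJS at which the
cumulative precision still reaches 0.95.  Second, among clusters, high
weight W and low representative MJS jointly predict correctness: binning
clusters on a (0.001 MJS x 1 W) grid and storing the cumulative precision
over all clusters with mjs <= x and W >= y yields a lookup table from which
each candidate receives an expected precision.  The final step keeps every
candidate above an upper expected-precision threshold, discards everything
below a lower one, uses the mid-band greedily to patch uncovered query
regions, and drops nested same-protein hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assess import TPRule
from .search import Candidate

__all__ = [
    "MJS_BIN_WIDTH",
    "PrecisionGrid",
    "FilterConfig",
    "redundant_bank_config",
    "calibrate_mjs_thresholds",
    "calibrate_precision_grid",
    "expected_precision",
    "annotate_expected_precision",
    "redundancy_eliminate",
    "collect_scored_pairs",
    "collect_labeled_clusters",
    "calibrate_protocol",
]

MJS_BIN_WIDTH = 0.001
N_MJS_BINS = 1000
TARGET_PRECISION = 0.95


@dataclass
class FilterConfig:
    """Expected-precision band for redundancy elimination.

    Candidates with expected precision >= upper are always kept; < lower
    always discarded; the band in between is spent greedily on query
    regions not yet covered.  Cells of the precision grid without enough
    calibration support yield ``fallback`` (just under the lower threshold
    by default: unknown regions are treated as unreliable).
    """

    upper_precision: float = 0.99
    lower_precision: float = 0.82
    min_grid_support: int = 10
    fallback: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.lower_precision < self.upper_precision <= 1):
            raise ValueError("need 0 < lower < upper <= 1")
        if self.fallback is None:
            self.fallback = self.lower_precision - 1e-6


def redundant_bank_config() -> FilterConfig:
    """Looser preset (0.995 / 0.65) trading precision for coverage, as
    appropriate when mining a more redundant, higher-identity bank."""
    return FilterConfig(upper_precision=0.995, lower_precision=0.65)


# ---------------------------------------------------------------------------
# Per-size MJS threshold calibration
# ---------------------------------------------------------------------------

def _mjs_bin(m: float) -> int:
    if not (0.0 <= m <= 1.0):
        raise ValueError(f"MJS value {m} outside [0, 1]")
    return min(int(m / MJS_BIN_WIDTH), N_MJS_BINS - 1)


def calibrate_mjs_thresholds(
    scored_pairs,
    tp_rule: TPRule,
    min_pairs: int = 50,
    target_precision: float = TARGET_PRECISION,
    with_provenance: bool = False,
) -> dict[int, float]:
    """Per-size hit thresholds from labeled (size, mjs, crmsd) pairs.

    For each size, sweep the 0.001 MJS grid and return the largest value t
    such that the precision among pairs with mjs <= t reaches
    ``target_precision`` (never beyond the largest observed mjs, rounded up
    to the grid).  Sizes with fewer than ``min_pairs`` pairs, or no
    attainable threshold, borrow the nearest calibrated size's value.

    ``with_provenance=True`` additionally returns the set of sizes whose
    threshold was calibrated from their own pairs (the rest borrowed).
    """
    by_size: dict[int, list[tuple[float, bool]]] = {}
    for size, m, crmsd in scored_pairs:
        by_size.setdefault(int(size), []).append((float(m), tp_rule.is_tp(int(size), crmsd)))

    thresholds: dict[int, float] = {}
    undefined: list[int] = []
    for size, pairs in sorted(by_size.items()):
        if len(pairs) < min_pairs or not any(tp for _, tp in pairs):
            undefined.append(size)
            continue
        arr = np.array([(m, tp) for m, tp in pairs])
        order = np.argsort(arr[:, 0], kind="stable")
        m_sorted = arr[order, 0]
        tp_cum = np.cumsum(arr[order, 1])
        prec_cum = tp_cum / np.arange(1, len(pairs) + 1)
        # precision of the prefix mjs <= t, evaluated at grid points up to
        # the largest observed value rounded up
        top_bin = int(np.ceil(m_sorted[-1] / MJS_BIN_WIDTH))
        best = None
        for b in range(top_bin, -1, -1):
            t = b * MJS_BIN_WIDTH
            idx = np.searchsorted(m_sorted, t, side="right") - 1
            if idx < 0:
                break
            if prec_cum[idx] >= target_precision:
                best = t
                break
        if best is None or best <= 0:
            undefined.append(size)
        else:
            thresholds[size] = float(best)

    if not thresholds and undefined:
        raise ValueError("no size could be calibrated")
    own = set(thresholds)
    for size in undefined:  # nearest-neighbor fallback across sizes
        nearest = min(own, key=lambda s: (abs(s - size), s))
        thresholds[size] = thresholds[nearest]
    out = dict(sorted(thresholds.items()))
    if with_provenance:
        return out, own
    return out


# ---------------------------------------------------------------------------
# (MJS, W) expected-precision grid
# ---------------------------------------------------------------------------

@dataclass
class PrecisionGrid:
    """Cumulative observed precision of clusters, per fragment size.

    ``raw_precision`` at cell (x, y) is the precision over all calibration
    clusters with centroid mjs <= x and weight W >= y (MJS binned at 0.001,
    W at 1).  ``precision`` is its monotone lower envelope — the largest
    surface that is non-increasing in MJS and non-decreasing in W while
    never exceeding any raw cell it summarizes — so lookups never
    overestimate the evidence of a low score or high weight.  Cells whose
    cumulative support falls under ``min_support`` are undefined (NaN).
    """

    fragment_size: int
    precision: np.ndarray  # (N_MJS_BINS, w_max) monotone envelope, NaN undefined
    raw_precision: np.ndarray  # cumulative observed precision before envelope
    support: np.ndarray  # (N_MJS_BINS, w_max) cumulative cluster counts
    min_support: int

    @property
    def w_max(self) -> int:
        return self.precision.shape[1]


def _monotone_envelope(prec: np.ndarray) -> np.ndarray:
    """Pessimistic envelope env(x, y) = min over {x' <= x, y' >= y} of the
    defined raw cells: non-increasing in x, non-decreasing in y, <= raw."""
    env = np.where(np.isnan(prec), np.inf, prec)
    env = np.minimum.accumulate(env, axis=0)  # over mjs <= x
    env = np.minimum.accumulate(env[:, ::-1], axis=1)[:, ::-1]  # over W >= y
    out = np.where(np.isinf(env), np.nan, env)
    out = np.where(np.isnan(prec), np.nan, out)  # undefined cells stay undefined
    return out


def calibrate_precision_grid(
    clusters,
    min_support: int = 10,
) -> dict[int, PrecisionGrid]:
    """Build one PrecisionGrid per fragment size from labeled calibration
    clusters (size, centroid_mjs, W, is_tp)."""
    by_size: dict[int, list[tuple[float, int, bool]]] = {}
    for size, m, w, tp in clusters:
        if w < 1:
            raise ValueError("cluster weight must be >= 1")
        by_size.setdefault(int(size), []).append((float(m), int(w), bool(tp)))

    grids: dict[int, PrecisionGrid] = {}
    for size, rows in by_size.items():
        w_max = max(w for _, w, _ in rows)
        counts = np.zeros((N_MJS_BINS, w_max))
        tps = np.zeros((N_MJS_BINS, w_max))
        for m, w, tp in rows:
            b = _mjs_bin(m)
            counts[b, w - 1] += 1
            tps[b, w - 1] += tp
        # cumulative over mjs <= x (ascending) and W >= y (descending)
        counts = np.cumsum(np.cumsum(counts[:, ::-1], axis=0), axis=1)[:, ::-1]
        tps = np.cumsum(np.cumsum(tps[:, ::-1], axis=0), axis=1)[:, ::-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(counts >= min_support, tps / counts, np.nan)
        grids[size] = PrecisionGrid(size, _monotone_envelope(raw), raw, counts, min_support)
    return grids


def expected_precision(grid: PrecisionGrid, mjs: float, w: int, cfg: FilterConfig) -> float:
    """Look up the expected precision of a cluster from its (MJS, W) cell.

    The MJS axis uses half-open bins [x, x + 0.001).  Weights above the
    calibrated range are clipped to the largest calibrated weight (the grid
    is non-decreasing in W, so clipping is conservative).  Undefined cells
    return the configured fallback.
    """
    b = _mjs_bin(mjs)
    wi = min(int(w), grid.w_max) - 1
    if wi < 0:
        raise ValueError("weight must be >= 1")
    val = grid.precision[b, wi]
    return float(val) if np.isfinite(val) else float(cfg.fallback)


def annotate_expected_precision(
    candidates: list[Candidate],
    grids: dict[int, PrecisionGrid],
    cfg: FilterConfig,
) -> list[Candidate]:
    """Fill each candidate's expected_precision from its size's grid
    (fallback when the size has no grid)."""
    for cand in candidates:
        grid = grids.get(cand.hit.query_len_aa)
        if grid is None:
            cand.expected_precision = float(cfg.fallback)
        else:
            cand.expected_precision = expected_precision(
                grid, cand.hit.mjs_score, cand.weight, cfg
            )
    return candidates


# ---------------------------------------------------------------------------
# Calibration data collection
# ---------------------------------------------------------------------------

def collect_scored_pairs(
    query_trace,
    query_profile,
    bank,
    sizes=range(6, 28),
    query_stride: int = 2,
    bank_stride: int = 2,
):
    """Scan a calibration query against the bank and return unfiltered
    (size, mjs, crmsd) triples on a strided sub-grid of window pairs.

    These labelled pairs feed ``calibrate_mjs_thresholds``; striding keeps
    the quadratic pair count manageable without biasing the MJS range.
    """
    from .assess import kabsch_crmsd_many
    from .compare import js_matrix

    pairs = []
    for entry in bank.entries:
        J = js_matrix(query_profile.rows, entry.profile.rows)
        for size in sizes:
            c = size - 3
            nqw = query_profile.n_rows - c + 1
            nbw = entry.profile.n_rows - c + 1
            if nqw <= 0 or nbw <= 0:
                continue
            qmask = query_trace.fragment_valid_mask(size)
            bmask = entry.trace.fragment_valid_mask(size)
            for i in range(0, nqw, query_stride):
                if not qmask[i]:
                    continue
                scores = np.stack([J[i + k, k : k + nbw] for k in range(c)]).max(axis=0)
                js = [j for j in range(0, nbw, bank_stride) if bmask[j]]
                if not js:
                    continue
                qfrag = query_trace.coords[i : i + size]
                crmsds = kabsch_crmsd_many(
                    np.broadcast_to(qfrag, (len(js), size, 3)),
                    np.stack([entry.trace.coords[j : j + size] for j in js]),
                )
                pairs.extend(
                    (size, float(scores[j]), float(r)) for j, r in zip(js, crmsds)
                )
    return pairs


def collect_labeled_clusters(query_trace, query_profile, bank, cfg, tp_rule: TPRule):
    """Run the scan -> cluster protocol for one calibration query and label
    every cluster (not only the selected one) by whether its representative
    superposes onto the true query fragment within the TP cutoff.

    Returns (size, centroid_mjs, W, is_tp) tuples for
    ``calibrate_precision_grid``.
    """
    from .assess import kabsch_crmsd
    from .search import search_all

    _, cells = search_all(query_profile, bank, cfg, query_trace=query_trace, collect_cells=True)
    labeled = []
    for cell in cells:
        qfrag = query_trace.coords[cell.query_start : cell.query_start + cell.size_aa]
        for cl in cell.clusters:
            rep = cl.representative
            crmsd = kabsch_crmsd(rep.coords, qfrag)
            labeled.append(
                (cell.size_aa, rep.mjs_score, cl.weight, tp_rule.is_tp(cell.size_aa, crmsd))
            )
    return labeled


def calibrate_protocol(
    bank,
    queries,
    k: float = 2.0,
    min_support: int = 10,
    background_samples: int = 300,
    seed: int = 0,
    query_stride: int = 2,
    bank_stride: int = 2,
    top_n: int = 500,
    sizes=range(6, 28),
):
    """End-to-end calibration against a bank of known structures.

    ``queries`` is a list of (CaTrace, SAProfile) calibration queries with
    known structure.  Computes the size-dependent background cRMSD
    statistics (hence the TP rule), the per-size 0.95-precision MJS
    thresholds, and the (MJS, W) expected-precision grids.

    Returns (tp_rule, search_config, grids).
    """
    from .assess import background_stats
    from .search import SearchConfig

    bg = background_stats(bank, sizes=sizes, n_samples=background_samples, seed=seed)
    rule = TPRule(mu={s: v[0] for s, v in bg.items()}, sigma={s: v[1] for s, v in bg.items()})
    pairs = []
    for trace, profile in queries:
        pairs.extend(
            collect_scored_pairs(
                trace, profile, bank, sizes=sizes,
                query_stride=query_stride, bank_stride=bank_stride,
            )
        )
    thresholds = calibrate_mjs_thresholds(pairs, rule)
    cfg = SearchConfig(
        mjs_thresholds=thresholds, min_len=min(sizes), max_len=max(sizes), top_n=top_n
    )
    clusters = []
    for trace, profile in queries:
        clusters.extend(collect_labeled_clusters(trace, profile, bank, cfg, rule))
    grids = calibrate_precision_grid(clusters, min_support=min_support)
    return rule, cfg, grids


# ---------------------------------------------------------------------------
# Redundancy elimination
# ---------------------------------------------------------------------------

def _span(c: Candidate) -> tuple[int, int]:
    return (c.hit.query_start, c.hit.query_start + c.hit.query_len_aa)


def _nested(inner: Candidate, outer: Candidate) -> bool:
    """True when inner's query span and bank span both lie inside outer's
    spans and the two hits come from the same bank protein."""
    if inner.hit.bank_id != outer.hit.bank_id:
        return False
    qi, qo = _span(inner), _span(outer)
    if not (qo[0] <= qi[0] and qi[1] <= qo[1]):
        return False
    bi = (inner.hit.bank_start, inner.hit.bank_start + inner.hit.bank_len_aa)
    bo = (outer.hit.bank_start, outer.hit.bank_start + outer.hit.bank_len_aa)
    return bo[0] <= bi[0] and bi[1] <= bo[1]


def redundancy_eliminate(
    candidates: list[Candidate],
    query_len: int,
    cfg: FilterConfig,
) -> list[Candidate]:
    """Final two-threshold filtering of annotated candidates.

    1. keep every candidate with expected precision >= upper;
    2. discard every candidate with expected precision < lower;
    3. sort the mid-band by expected precision descending (ties: lower MJS,
       longer fragment, then lexicographic span) and greedily keep any
       candidate covering at least one query residue not yet covered;
    4. drop nested hits: a kept candidate whose query span and bank span
       both lie inside another kept candidate's spans from the same bank
       protein is removed (the shorter of the two).

    Candidates lacking an expected precision raise.  Sets ``kept`` flags on
    the input and returns the kept sublist.
    """
    for c in candidates:
        if c.expected_precision is None:
            raise ValueError("candidates must carry expected_precision")
        c.kept = False

    surely = [c for c in candidates if c.expected_precision >= cfg.upper_precision]
    midband = [
        c
        for c in candidates
        if cfg.lower_precision <= c.expected_precision < cfg.upper_precision
    ]

    covered = np.zeros(query_len, dtype=bool)
    kept: list[Candidate] = list(surely)
    for c in surely:
        s, e = _span(c)
        covered[s:e] = True

    midband.sort(
        key=lambda c: (
            -c.expected_precision,
            c.hit.mjs_score,
            -c.hit.query_len_aa,
            c.hit.query_start,
            c.hit.bank_id,
            c.hit.bank_start,
        )
    )
    for c in midband:
        s, e = _span(c)
        if not covered[s:e].all():
            kept.append(c)
            covered[s:e] = True

    # nested-hit removal among kept candidates, longest first
    kept.sort(
        key=lambda c: (
            -c.hit.query_len_aa,
            c.hit.mjs_score,
            c.hit.query_start,
            c.hit.bank_id,
            c.hit.bank_start,
        )
    )
    final: list[Candidate] = []
    for c in kept:
        if any(_nested(c, k) for k in final):
            continue
        final.append(c)

    for c in final:
        c.kept = True
    final.sort(key=lambda c: (c.hit.query_start, c.hit.query_len_aa, c.hit.bank_id))
    return final
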
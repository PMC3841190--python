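"""Synthetic structures, banks and planted-query scenarios.

Toy Cα geometry stands in for real structure banks: ideal α-helices
(radius 2.3 Å, 1.5 Å rise and 100° twist per residue), zig-zag β-strands
(~3.46 Å axial rise), β-hairpins (two antiparallel strands joined by a
4-residue turn) and smooth random coil, all with 3.8 Å (±) consecutive
Cα-Cα spacing and optional isotropic Gaussian coordinate noise.  Banks
concatenate such motifs into chains, encode them into posterior profiles
with a structural-alphabet model, and optionally degrade the profiles with
the Dirichlet pseudo-predictor so that profile uncertainty mirrors the
smoothing of sequence-based prediction.  ``plant_fragment`` copies a query
fragment into a bank protein for recall experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import pseudo_predict
from .sa_alphabet import CaTrace, SAModel, posterior_profile
from .search import Bank, BankEntry

__all__ = ["BankSpec", "make_motif", "build_chain", "build_bank", "plant_fragment", "MOTIF_KINDS"]

MOTIF_KINDS = ("helix", "strand", "hairpin", "coil")

CA_STEP = 3.8  # Å, canonical consecutive Cα-Cα distance

# ideal α-helix Cα parameters
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0

# zig-zag strand: axial rise, right-handed twist per residue, and lateral
# half-amplitude chosen so the consecutive step is CA_STEP.  The twist makes
# the strand a proper screw (as in real beta structure) rather than a planar,
# mirror-symmetric zig-zag whose phase shift distance-based descriptors
# cannot see.
STRAND_RISE = 3.46
STRAND_TWIST_DEG = -15.0


@dataclass
class BankSpec:
    """Conditions for one synthetic bank.

    composition weights order: (helix, strand, hairpin, coil), summing
    to 1.  ``noise_sd`` is the isotropic coordinate noise in Å applied to
    every motif before profile encoding; ``prediction_concentration`` (None
    disables) degrades profiles with the Dirichlet pseudo-predictor.
    """

    n_proteins: int = 10
    min_len: int = 30
    max_len: int = 60
    composition: tuple[float, float, float, float] = (0.4, 0.25, 0.2, 0.15)
    noise_sd: float = 0.3
    prediction_concentration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_len < 6 or self.max_len < self.min_len:
            raise ValueError("invalid length range")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition weights must sum to 1")


def _helix(n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Ideal helix, with mild per-motif variation of rise and twist (real
    helices are not all canonical); the radius is solved so the consecutive
    Cα-Cα step stays exactly CA_STEP."""
    rise, twist_deg = HELIX_RISE, HELIX_TWIST_DEG
    if rng is not None:
        rise = rng.uniform(1.40, 1.60)
        twist_deg = rng.uniform(96.0, 104.0)
    t = np.arange(n) * np.deg2rad(twist_deg)
    radius = np.sqrt(CA_STEP**2 - rise**2) / (2.0 * np.sin(np.deg2rad(twist_deg) / 2.0))
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)])


def _strand(n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    rise, twist_deg = STRAND_RISE, STRAND_TWIST_DEG
    if rng is not None:
        rise = rng.uniform(3.35, 3.55)
        twist_deg = rng.uniform(-25.0, -5.0)
    tau = np.deg2rad(twist_deg)
    lateral = 0.5 * np.sqrt(CA_STEP**2 - rise**2) / np.cos(tau / 2.0)
    k = np.arange(n)
    amp = lateral * np.where(k % 2 == 0, 1.0, -1.0)
    return np.column_stack([rise * k, amp * np.cos(tau * k), amp * np.sin(tau * k)])


def _hairpin(n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Two antiparallel strands joined by a 4-residue turn.

    The turn samples a half-circle of diameter ``sep`` (the inter-strand
    separation) in the xy-plane at equal angles, adding an out-of-plane
    zig-zag in z sized so that every consecutive step is exactly CA_STEP.
    """
    n_turn = 4
    n_strand1 = (n - n_turn) // 2
    n_strand2 = n - n_turn - n_strand1
    sep = 4.8 if rng is None else float(rng.uniform(4.5, 5.1))  # strand separation, Å
    pts = list(_strand(max(n_strand1, 1), rng))
    A = pts[-1]
    # arc from A (angle 0) to the strand-2 anchor B (angle pi): n_turn
    # intermediate residues, n_turn + 1 equal segments
    r = sep / 2.0
    n_seg = n_turn + 1
    chord = 2 * r * np.sin(np.pi / (2 * n_seg))
    dz = np.sqrt(max(CA_STEP**2 - chord**2, 0.0))
    for k in range(1, n_seg + 1):  # k = n_seg lands on B itself
        th = np.pi * k / n_seg
        pts.append(A + np.array([r * np.sin(th), r * (1 - np.cos(th)), dz * (k % 2)]))
    B = pts[-1]
    # second strand: a twisted strand rotated 180 deg about z, anchored at B
    # and running back along -x
    s2 = _strand(max(n_strand2, 1), rng) * np.array([-1.0, -1.0, 1.0])
    for k in range(1, n_strand2):
        pts.append(B + s2[k] - s2[0])
    return np.array(pts[:n])


def _coil(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random walk with fixed CA_STEP bond length and a per-motif stiffness:
    each coil stretch draws its own turning amplitude, so coil geometry is
    heterogeneous across motifs (as in real irregular regions) rather than a
    single canonical curve."""
    stiffness = rng.uniform(0.4, 1.6)
    pts = [np.zeros(3)]
    d = np.array([1.0, 0.0, 0.0])
    for _ in range(n - 1):
        d = d + stiffness * rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + CA_STEP * d)
    return np.array(pts)


def make_motif(
    kind: str,
    n_res: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    vary_shape: bool = True,
) -> CaTrace:
    """An idealized Cα motif with optional isotropic Gaussian noise.

    With ``vary_shape`` (default) each motif draws mild per-motif shape
    parameters (helix rise/twist, strand twist, hairpin separation, coil
    stiffness) so repeated motifs are similar but not congruent, as in real
    structures; ``vary_shape=False`` gives the canonical geometry.  At zero
    noise, consecutive Cα-Cα distances lie in [3.6, 4.0] Å for all motif
    kinds, and output is deterministic for fixed parameters.
    """
    if n_res < 4:
        raise ValueError("motifs need at least 4 residues")
    rng = np.random.default_rng(seed)
    shape_rng = rng if vary_shape else None
    if kind == "helix":
        X = _helix(n_res, shape_rng)
    elif kind == "strand":
        X = _strand(n_res, shape_rng)
    elif kind == "hairpin":
        X = _hairpin(n_res, shape_rng)
    elif kind == "coil":
        X = _coil(n_res, rng)
    else:
        raise ValueError(f"unknown motif kind {kind!r}")
    if noise_sd > 0:
        X = X + rng.normal(scale=noise_sd, size=X.shape)
    return CaTrace(kind, list(range(1, n_res + 1)), X)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _append_motif(chain: list[np.ndarray], X: np.ndarray, rng: np.random.Generator) -> None:
    """Rigidly place X so its first residue continues the chain at CA_STEP."""
    if not chain:
        chain.extend(X)
        return
    R = _random_rotation(rng)
    Xr = (X - X[0]) @ R.T
    prev = chain[-1]
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    chain.extend(Xr + prev + CA_STEP * d)


def build_chain(
    target_len: int,
    composition: tuple[float, float, float, float],
    noise_sd: float,
    rng: np.random.Generator,
    chain_id: str = "chain",
) -> CaTrace:
    """Concatenate randomly drawn motifs into one continuous Cα chain of at
    least ``target_len`` residues (each motif rigidly appended at CA_STEP
    from the previous one, in a random orientation)."""
    chain: list[np.ndarray] = []
    while len(chain) < target_len:
        kind = MOTIF_KINDS[rng.choice(4, p=np.array(composition))]
        n = int(rng.integers(6, 15)) if kind != "hairpin" else int(rng.integers(10, 17))
        n = min(n, target_len - len(chain)) if target_len - len(chain) >= 4 else 4
        motif = make_motif(kind, max(n, 4), noise_sd, seed=int(rng.integers(2**31)))
        _append_motif(chain, motif.coords, rng)
    return CaTrace(chain_id, list(range(1, len(chain) + 1)), np.array(chain))


def build_bank(spec: BankSpec, model: SAModel) -> Bank:
    """Assemble a synthetic bank: motif chains encoded into posterior
    profiles (optionally degraded by the pseudo-predictor).  Deterministic
    for a fixed spec seed."""
    rng = np.random.default_rng(spec.seed)
    entries: list[BankEntry] = []
    for p in range(spec.n_proteins):
        target_len = int(rng.integers(spec.min_len, spec.max_len + 1))
        trace = build_chain(
            target_len, spec.composition, spec.noise_sd, rng, chain_id=f"syn{p:03d}"
        )
        profile = posterior_profile(trace, model)
        if spec.prediction_concentration is not None:
            profile = pseudo_predict(
                profile, spec.prediction_concentration, seed=int(rng.integers(2**31))
            )
        entries.append(BankEntry(trace.chain_id, trace, profile))
    return Bank(entries)


def plant_fragment(
    bank: Bank,
    query_trace: CaTrace,
    at: tuple[int, int],
    model: SAModel | None = None,
    prediction_concentration: float | None = None,
    seed: int = 0,
    detach: bool = True,
) -> Bank:
    """Copy of the bank with the query fragment rigidly planted at
    (protein index, position).

    With ``detach=True`` (default) the placed fragment is offset from the
    rest of the host chain so that both junctions register as chain breaks:
    the fragment then forms its own break-free segment whose posterior
    profile is exactly the fragment's standalone profile (a planted copy is
    recovered at MJS 0 under zero prediction noise).  With ``detach=False``
    the fragment is superposed onto the span it replaces, keeping the chain
    roughly continuous; forward-backward context from the host then bleeds
    into the edge profile columns.  The host profile is re-encoded (which
    requires the model) and optionally re-degraded with the
    pseudo-predictor.
    """
    p_idx, pos = at
    frag = query_trace.coords
    entry = bank.entries[p_idx]
    n = len(frag)
    if pos < 0 or pos + n > len(entry.trace):
        raise ValueError("planted span exceeds target protein")
    target = entry.trace.coords[pos : pos + n]
    # Kabsch superposition of the fragment onto the span it replaces
    Xc = frag - frag.mean(axis=0)
    Yc = target - target.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc.T @ Yc)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    R = U @ D @ Vt
    placed = Xc @ R + target.mean(axis=0)
    if detach:
        placed = placed + np.array([0.0, 0.0, 50.0])  # guarantees junction breaks

    coords = entry.trace.coords.copy()
    coords[pos : pos + n] = placed
    trace = CaTrace(entry.trace.chain_id, list(entry.trace.residue_ids), coords)
    if model is None:
        raise ValueError("an SAModel is required to re-encode the host profile")
    profile = posterior_profile(trace, model)
    if prediction_concentration is not None:
        profile = pseudo_predict(profile, prediction_concentration, seed=seed)
    entries = list(bank.entries)
    entries[p_idx] = BankEntry(entry.id, trace, profile)
    return Bank(entries)
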
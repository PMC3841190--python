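# Methods

## Model

A structural alphabet is a hidden Markov model over local backbone
conformations.  Hidden states ("letters", 27 by default) emit multivariate
Gaussians over four geometric descriptors of one 4-residue Cα fragment:
the non-consecutive distances d₁₃ = |C₁−C₃|, d₁₄ = |C₁−C₄|, d₂₄ = |C₂−C₄|
(Å) and the signed volume of the Cα tetrahedron (Å³), whose sign flips
under reflection and therefore separates mirror-image conformations.
Successive fragments overlap by three residues, so an N-residue chain is a
length N−3 observation sequence.  Decoding a structure gives either the
optimal letter string (Viterbi) or the posterior profile (forward–
backward): an (N−3)×27 row-stochastic matrix.  All recursions run in
natural-log space and are exact for chains up to at least 10⁴ residues.

Chains are split at any consecutive Cα–Cα distance outside [2.0, 4.5] Å;
each break-free segment is decoded independently, letter strings carry a
`-` at positions whose fragment would span a break, posterior rows there
are uniform placeholders, and no search window ever crosses a break.

## Profile comparison

Columns are compared with the Jensen–Shannon divergence in log base 2
(symmetric, finite because the mixture dominates both arguments, bounded
in [0, 1]; the divergence itself is used, no square root).  Conventions:
0·log(0/q) = 0; no pseudocounts are added at comparison time.  Fragments
are compared ungapped by the maximum column divergence (MJS).  The
pairwise form D_JS = H(M) − (H(P)+H(Q))/2 lets the search compute one
column-pair JS matrix per bank entry and derive every window score as a
running diagonal maximum, so scores are shared across all fragment sizes.

## Search, clustering, selection

For each query cell (start position, size n ∈ [6, 27]) every same-length
bank window is scored; windows with MJS ≤ threshold(n) become hits, sorted
ascending by (MJS, bank id, bank start) and capped at the 500 best.  Hits
are clustered in one pass in MJS order: a hit joins the first cluster
whose representative it superposes onto within a size-dependent cRMSD
radius, else founds a new cluster; the founder (lowest MJS) is the
representative and the member count is the weight W.  Default radius
0.5 + 0.04·(n − 6) Å capped at 1.5 Å, configurable.  Per cell only the
largest-W cluster survives (ties: lowest representative MJS, then bank id
and start).  All tie-breaks are lexicographic, making the whole pipeline
deterministic.

Superposition uses the determinant-corrected Kabsch SVD solution
restricted to proper rotations.  The RMSD is evaluated from the explicit
residual after applying the optimal rotation rather than from the
closed-form trace identity; the latter loses ~7 digits to cancellation
near zero RMSD, the residual form is exact there.

## Calibration

Two empirical calibrations are learned from scored (size, MJS, cRMSD)
pairs and labeled clusters collected by scanning calibration queries with
known structures against the bank:

* **Per-size MJS thresholds** — the largest grid value t (0.001 steps) at
  which the precision among pairs with MJS ≤ t is still ≥ 0.95; sizes
  without enough pairs or without true positives borrow the nearest
  calibrated size's value.
* **Expected-precision grids** — clusters are binned by representative MJS
  (0.001) and weight (1); cell (x, y) stores the cumulative observed
  precision over clusters with MJS ≤ x and W ≥ y, undefined below 10
  supporting clusters.  The raw cumulative precision is not mathematically
  monotone (adding a band of true positives can raise it; removing low-W
  clusters can lower it), so lookups use its *monotone lower envelope*
  env(x, y) = min over {x′ ≤ x, y′ ≥ y} of the defined raw cells:
  non-increasing in MJS, non-decreasing in W, and never above any raw
  value it summarizes — a conservative estimate that cannot reward a
  candidate beyond its least favorable dominating evidence.  Weights above
  the calibrated range clip to the largest calibrated weight; undefined
  cells fall back to just under the lower filtering threshold (unknown
  evidence is treated as unreliable).

The true-positive rule is cutoff(n) = max(μₙ − k·σₙ, 0.5 Å) with k = 2 by
default, where μₙ and σₙ are the mean and SD of the cRMSD of random
same-size fragment pairs drawn from the bank; the 0.5 Å floor keeps the
rule meaningful for very tight backgrounds.

## Redundancy elimination

Candidates with expected precision ≥ 0.99 are kept, < 0.82 discarded
(a 0.995/0.65 preset is provided for redundant banks).  The mid band is
sorted by expected precision (ties: lower MJS, longer fragment,
lexicographic span) and greedily kept only where it covers at least one
still-uncovered query residue.  Finally a kept candidate whose query span
and bank span both lie inside another kept candidate's spans from the same
bank protein is dropped (the shorter one).

## Stage accounting

The pipeline is monitored at four stages: raw hits → cluster
representatives → best cluster per cell → final candidates.  Quality at
each stage is measured with *hit-mass* weighting: a representative counts
for the W raw hits of its cluster, so every stage averages over the same
population of original matches.  Unweighted per-representative averages
would be dominated, after clustering, by the long tail of weight-1 noise
clusters that the subsequent stages exist to remove, and would misstate
the filtering as a loss of quality.

## Synthetic data

The generator emulates a structure bank with four motif families assembled
into continuous chains: α-helices (rise and twist drawn per motif in
[1.40, 1.60] Å and [96°, 104°], radius solved so the Cα step is exactly
3.8 Å), β-strands (zig-zag with a right-handed twist drawn in [−25°, −5°];
the twist makes the strand a proper screw, as in real β structure — a
planar zig-zag is mirror-symmetric and its phase shift is invisible to
distance-based descriptors while being ~2 Å in cRMSD), β-hairpins (two
antiparallel strands joined by a 4-residue turn with separation drawn in
[4.5, 5.1] Å) and coil (fixed-step random walks with per-motif stiffness in
[0.4, 1.6]).  Isotropic Gaussian coordinate noise (default 0.3 Å, a typical
backbone variability scale) is applied before encoding, so profile
uncertainty is geometric.  Sequence-based profile prediction is emulated by
resampling each posterior row from Dirichlet(50·p + 0.01); this reproduces
prediction *noise* but not the strong smoothing of a real sequence
predictor — synthetic profiles remain sharper than predicted ones, which
makes the synthetic raw hit lists cleaner than real ones.  Passing tests
therefore demonstrate the correctness and internal consistency of the
machinery, not attainable accuracy on real structures.

`plant_fragment` inserts a copy of a query fragment into a bank protein.
By default the copy is detached (its junctions register as chain breaks),
so the planted span forms its own segment whose posterior profile is
exactly the fragment's standalone profile and an exact copy is recovered
at MJS = 0; continuous splicing (`detach=False`) is available but lets
forward–backward context from the host bleed into the edge columns.

## Fitting the bundled toy alphabet

The shipped 27-letter model is fitted by Baum–Welch (hmmlearn) on 80
fixed-seed synthetic chains with three regularizations, all exposed as
fitting parameters:

* **Sticky transition prior** (Dirichlet pseudocounts 20 on the diagonal).
  With many states and few underlying conformations, plain EM splits one
  conformation across phase-alternating state pairs; which twin wins on a
  given chain is an arbitrary symmetry break, so identical geometries
  would encode to mismatched profiles.
* **Covariance floor** 1e-3 Å² during EM (numerical stability); the
  generic degeneracy ridge is 1e-6 Å².
* **Covariance eigenvalue cap** 0.5 Å².  EM otherwise parks catch-all
  states with very large covariances over heterogeneous coil; a run of
  such a letter then scores as a low-MJS match between structurally
  unrelated fragments, which destroys the precision-vs-MJS relationship
  the threshold calibration relies on.  Letters of a structural alphabet
  are meant to be specific local shapes; the cap enforces that.

Multiple EM restarts (`n_init`) are supported and keep the
highest-likelihood solution; fitting is deterministic given the seed.

## Study conditions and problem sizes

The bundled thresholds and the benchmark in `scripts/acceptance.py` use a
bank of 20–25 proteins of 30–60 residues (composition 40 % helix, 25 %
strand, 20 % hairpin, 15 % coil), 8–12 calibration queries and 3 held-out
evaluation queries of 70–80 residues, prediction concentration 50, and
300 background pairs per size — a desk-scale stand-in for the thousands of
proteins and queries of a real calibration.  Planted-fragment recall uses
a 12-residue coil fragment: recall probes whether the search finds an
exact structural copy, so the planted fragment must be identifiable — a
generic helix cell is legitimately won by the (equally correct) denser
cluster of bank helices.

## Known limitations

* The toy alphabet is a synthetic stand-in: its letters describe idealized
  motif geometry, not the conformational inventory of real proteins, and
  no published letter parameterization is reproduced.
* The Dirichlet pseudo-predictor cannot smooth sharp posterior rows, so
  calibrated MJS thresholds vary more between sizes than a real,
  smoother predictor would produce; sizes without calibratable pairs
  borrow neighbors' thresholds.
* Letter-equivalence-aware comparison (substitution matrices between
  letters) and gapped alignment are out of scope by design.
* Small calibration sets leave expected-precision grids sparsely
  supported; unsupported cells deliberately read as unreliable, which
  trades coverage for precision.
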
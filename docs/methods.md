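# Methods

## Model and assumptions

The package rests on one empirical regularity: the spatial proximity of two
residues in folded proteins is predictable, on average, from their amino-acid
types and their separation along the chain.  Pooling Cα–Cα distances per
(type pair, separation range) gives a table of average distances; a
sequence whose residue pairs have short table averages is expected to form
contacts, and a map of such "expected contacts" (the average distance map,
ADM) behaves like a structure-free contact map.  Dense clusters on it mark
compact regions; stretches that fail to accumulate plots behave like
intrinsically disordered regions.  The method uses no evolutionary profiles,
no secondary-structure prediction and no learned model — the statistics
table plus one density law carry all the structural knowledge.

Assumptions worth keeping in mind:

* the table is built from *folded* structures, so "average distance" means
  "average distance when the pair is in a folded context";
* pooling is per separation range, not per exact separation, so within-range
  distance variation is averaged away by design;
* the whole-map density of a real 15-Å contact map follows rho_av = C/N
  with a universal C.  The package treats C as a configurable constant
  (default 36.12) and never refits it per protein.

## Separation ranges and the statistics table

Ranges partition k = |i − j|: M = 1 covers 1–8, M = 2 covers 9–20, M ≥ 3
covers decades 10M−9..10M, up to `max_M` (default 9, i.e. k ≤ 90; longer
pairs carry no statistics and are never plotted).  Table cells with fewer
than `min_count` = 10 observations are insignificant: they are excluded
from the plottable-pair count P(M) and can never be plotted, whatever their
mean.  Both defaults are configurable; 10 observations is the smallest
count at which a pooled mean of distances with ~Å-scale spread is stable
enough to rank pairs within a range.

Structure parsing keeps the first model, one chain (first by default), the
' '/'A' alternate location, and drops non-standard residues, residues with
insertion codes, and residues lacking a Cα, each with a logged warning.

## Map construction

The target plot count is round(C·(N−1)/2), i.e. density rho_av = C/N over
the N(N−1)/2 upper-triangle cells — the denominator that makes the density
law equivalent to a fixed per-residue contact count, matching the 15-Å
contact-map analogy.  Per-range counts obey P(M)_C = (D/M)·P(M) with one
global D shared by all ranges (the 1/M factor already encodes the range
dependence).  D solves the piecewise-linear equation
Σ_M min((D/M)P(M), P(M)) = target exactly (the kinks sit at the saturation
points D = M); per-range counts are then rounded half-away-from-zero and
capped at P(M).  If even full saturation cannot reach the target, every
significant pair is plotted.

Within a range, the P(M)_C pairs with the smallest table means are plotted;
equal means are broken by ascending (i, j), so construction is bit-for-bit
deterministic.  The recorded per-range threshold is the midpoint between
the largest plotted mean and the next strictly larger candidate (+0.5 Å
when the range is exhausted), so "mean < threshold" reproduces the
selection except for index-tie-broken pairs exactly at the boundary —
candidates of the same type pair share one table mean, so such ties are
common and the tie-break rule, not the threshold, is authoritative.

## Density-difference scanning

At division index i the upper triangle splits into a triangular part and a
trapezoidal part; densities use the discrete cell counts of each part, with
cross pairs assigned to the trapezoid.  Two directions are kept: the
horizontal scan's triangle holds pairs with both residues ≥ i (a compact
block [m, n] peaks it at m), the vertical scan's triangle holds pairs with
both residues ≤ i (peak at n).  Divisions where either part has zero cells
are NaN-flagged, never zero-filled.  Peaks are strict interior local maxima
above `min_height` (default 0.01 density units), plateaus resolve to their
leftmost index, and candidate regions pair each horizontal peak m with each
vertical peak n ≥ m + `min_span` (default 20 residues, a minimal domain
size), scored by η = Δρ^h_m + Δρ^v_n with greedy η-descending overlap
resolution.  The defaults were chosen so that a two-block map at ≥ 3×
background density is recovered exactly while pure-noise maps at N ≤ 219
yield no calls; both properties are asserted in the test suite.

## Disorder calibration and prediction

Per-residue counts take plots with separations in the band 9 ≤ k ≤ 29 —
long-range pairs (k > 8), restricted to below 30 where the
ordered/disordered contrast concentrates; the band is configurable.
Counts are smoothed by a truncated 11-residue window (half-width 5).

Calibration pools annotated proteins whose disordered *and* ordered
fractions both reach `min_coverage` = 10% of the chain (nearly one-class
proteins say nothing about the count→class boundary and would bias the
pooled fractions).  Residues are binned by the integer-rounded smoothed
count; each bin records its residue count and disordered fraction; a cubic
polynomial is fitted to the bin fractions by least squares with weights
√(bin occupancy), the lowest degree that tracks the sigmoid-shaped empirical
profile without oscillating through it.

Curve evaluation clips to [0, 1], clamps to the observed count domain, and
additionally clamps to the fitted cubic's central monotone branch (the
interval between consecutive stationary points with the largest total
change).  The last rule exists because an unconstrained cubic fitted to a
sigmoid rises again in the sparse tails — measured on synthetic data, up to
probability 0.66 at counts where every observed residue was ordered — while
the disorder probability is, by construction of the method, monotone
non-increasing in the plot count.  Holding the fit flat past its own
turning points is the smallest correction with that property.

Thresholding labels residue i disordered when probability ≥ θ; presets
`accw` = 0.62 (default) and `accp` = 0.53.  Segments are maximal label
runs; no minimum segment length is imposed, since segments as short as 4
residues are meaningful predictions.  Tandem mode concatenates the sequence
with itself (no linker) and reports the 2N-residue prediction plus per-copy
views.

## Evaluation

Residue-level confusion counts are taken over annotated residues only;
residues in neither interval set are excluded rather than assumed ordered.
Pooling across proteins is micro-averaged (counts summed before metrics).
ACCw is undefined (raised, not silently 0) when a class is absent.

## Synthetic data: what it emulates, what it does not

The generators provide the statistical contrasts the method consumes,
nothing more:

* **chains** — straight (closed-form distances for exact oracles), ideal
  α-helix (rise 1.5 Å, 100° twist, radius 2.3 Å), and collapsed (a seeded
  3.8-Å random walk rescaled into a sphere of radius 3·N^⅓ Å).  The
  collapsed chain is compact but not sterically realistic; rescaling can
  shrink local distances below physical bond lengths.
* **tables** — `uniform` (every cell significant; a deterministic seeded
  spread of means, for density-calibration and selection oracles) and
  `two-class` (pairs of hydrophobic "order-prone" residues A C F I L M V W Y
  get short means, everything else long, emulating the abundance of
  hydrophilic residues and scarcity of hydrophobic ones in disordered
  regions).
* **annotated sets** — sequences alternate order-prone and disorder-prone
  compositional segments of 30–60 residues (the length scale of common
  IDRs) at 95% pool purity; per-residue disordered labels are Bernoulli
  draws from a known monotone law applied to the realized smoothed counts
  (logistic, midpoint 12 — between the realized count modes of the two
  segment kinds, giving ≈ balanced classes — steepness 2, a transition
  width the cubic fit family can represent), and annotations store the
  label runs as intervals.

Because labels are generated *from* realized counts, passing the
calibration-recovery and accuracy tests shows the estimator recovers a
known count→probability law and converts it into accurate labels — it does
not show that real disordered regions follow such a law, that real
statistics tables separate classes this cleanly, or anything about
performance on curated annotations, which require external data.

## Problem sizes and numerical choices

Test and acceptance runs use 150-residue sequences for density calibration,
100 random (sequence, table) instances for the selection oracle, 200 maps
of N = 60 for the null-scan check, 64-residue two-block maps for region
recovery, and 40 training + 15 held-out proteins of 100–199 residues
(≈ 6,000 pooled residues) for calibration recovery — sizes at which every
quantity under test is already stable.  Rounding is half-away-from-zero
throughout; merged tables use count-weighted means (exact to 1e-9 in
tests); all generators take explicit seeds and no global random state is
touched.

## Known limitations

* The density law and its constant C = 36.12 are taken as given; no
  re-derivation from a structure survey is attempted.
* Only monomeric, ≤ 2-domain behaviour is modelled by the scanning
  defaults; nested or discontinuous domains are out of scope.
* The counting band conjunction (9 ≤ k ≤ 29) is one of several defensible
  readings of "long-range, below 30"; it is a configuration parameter.
* X residues are accepted as unplottable placeholders; other non-standard
  letters are rejected.
* A sequence with *no* significant table pair raises a no-statistics error
  rather than returning an empty prediction.
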
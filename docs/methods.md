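# Methods

## The model

A chromatin segment is represented as a chain of beads. At the finest
genomic resolution (one bead per matrix bin, typically 100 kbp) a bead is
a sphere: its centroid, start and end points coincide. At every coarser
resolution a bead summarizes a previously reconstructed subchain through
three points — its start point, its geometric centroid and its end point —
plus an effective radius. The two arm lengths and the arm angle of such a
triple are frozen at construction: whatever happens to the chain
afterwards, the subchain it stands for moves as a rigid body.

Consecutive beads are joined by an explicit bond from one bead's end
anchor to the next bead's start anchor. Bond lengths vary inside a range
derived from the flanking radii (default 0.8–1.2 × (r_i + r_j)), so
neighbours can neither interpenetrate nor drift apart; the often-stated
idealization that the end point of one bead *coincides* with the start
point of the next is recovered in the zero-bond limit. We use explicit
bonds because they are the only representation under which all three
sampler moves (bond, planar, dihedral) are well defined at every
resolution.

Internally a chain is a single polyline. Each bead contributes one point
(degenerate) or three (start, centroid, end). The internal coordinates of
the polyline — segment lengths, planar angles ψ, signed dihedrals φ —
split into *frozen* entries (inside a rigid bead) and *free* entries (the
degrees of freedom). This chart makes the topology-preservation property
of the moves exact rather than approximate.

## Chain evolution by quaternions

Rotations are stored as unit quaternions (4 scalars; composition by the
Hamilton product costs 16 multiplications and 12 additions, against 27
and 18 for 3×3 matrices — both counts are asserted by instrumented
arithmetic in the test suite). The three moves are pivots:

- **planar**: the tail beyond a hinge vertex rotates about the normal of
  the flanking plane, through the vertex;
- **dihedral**: the tail beyond a bond rotates about the bond direction;
- **bond**: the tail translates along the bond.

Because each rotation maps the plane (or axis) defining the targeted
coordinate onto itself, exactly one free internal coordinate changes, by
exactly the requested delta; all other segment lengths, planar angles and
dihedrals are untouched, and bead triples ride rigidly. A planar angle
lives on the open chart (0°, 180°); a proposal that would push it through
either end (a collinear configuration, where the plane normal inverts and
adjacent dihedral signs would flip by 180°) is signalled as degenerate and
the sampler simply retries, exactly as it does for an already-collinear
hinge.

## Data fit

The objective is Φ(C) = Σ_{(i,j)∈L} n_ij · d_ij over a pair set L: each
listed pair pulls its beads together with strength proportional to the
observed contact count. No conversion of counts into target distances is
performed; zero counts carry no information and never enter L. At the
finest level L holds the k largest strictly-upper-triangle counts of the
block (default k = 20), excluding the diagonal always and |i−j| = 1 pairs
by default (bonds already hold those together; configurable).

At coarser levels (default k = 40) two refinements apply, both following
from the same asymmetry — high counts imply proximity, low counts imply
nothing:

- adjacent block pairs are *included*: on a realistic binned matrix the
  largest entries sit near the diagonal, and coarse centroids are not
  meaningfully restrained by the single seam bond;
- a block pair enters L only if its count per cross pair,
  n_kl / (s_k · s_l), reaches 20 % of the median within-block per-pair
  rate n_kk / s_k² (s = number of finest bins per block). Background
  rates in contact data sit one to two orders of magnitude below
  within-domain rates, so this floor removes noise-level pairs — which
  would otherwise actively pull two unrelated domains together — without
  touching genuine interfaces.

## Constraints

All structures must satisfy, at the finest resolution:

| constraint | default | meaning |
|---|---|---|
| steric floor | 120 nm (or r_i + r_j if larger) | non-adjacent beads may not interfere |
| span bound | 10 µm | no two beads farther apart than a nucleus |
| curvature | 100° | maximum bending (180° − ψ) at any free hinge |
| bond range | 0.8–1.2 × (r_i + r_j) | neighbours neither overlap nor separate |

The curvature figure is interpreted as a bound on the *bending* angle
180° − ψ (a straight chain bends by 0°); bounding ψ itself would forbid
near-straight chains. Both conventions are selectable
(`curvature_convention="bend" | "psi"`).

Constraint handling is hard rejection: a proposal violating any bound
never enters the chain, and no penalty terms touch Φ.

## Bead sizing

Many contacts inside a locus mean compact (small) chromatin, few mean
open (large). The concrete surrogate is a cube-root law,

    r = r_ref · (L / L_ref)^(1/3) · (c_ref / max(c, c_floor))^(1/3),

with L the genomic span, c the internal contact density (mean
off-diagonal count per pair inside the block; the diagonal entry itself
for a single-bin block), c_ref the median density across blocks at that
level, r_ref = 60 nm at L_ref = one bin. Volume scales with genomic
content, compaction with contact density; the law is strictly monotone in
both arguments, which is all the downstream procedure relies on.

A summarized subchain's radius is half its radius of gyration plus the
mean child radius.

## Annealing

Classical simulated annealing: uniform choice among applicable move types,
uniform site, delta uniform in ±15° (planar), ±30° (dihedral), ±5 % of the
bond length; Metropolis acceptance with geometric cooling T ← 0.98 T per
sweep. T0 is auto-calibrated by a short pilot so that ~80 % of initial
uphill moves would be accepted; the run stops at T0/1000, after 400
sweeps (the default cooling reaches T0/1000 after ~342), or after 50
sweeps without an acceptance. Each sweep proposes 10 moves per polyline
point. The sampler is deliberately not a global optimiser: independent
seeded runs are the ensemble mechanism, and distinct configurations with
similar low Φ are all plausible solutions.

Initial configurations are grown self-avoiding with bond lengths uniform
in their range and bend angles half-normal (σ = 30°, capped at the
curvature bound), i.e. randomized but not pre-folded. Drawing bends
uniformly up to the 100° cap would pre-collapse the chain into a blob
whose Φ is already within a factor ~2 of the steric floor, confounding
initializer compactness with data-driven compaction; with the moderate
default, compactness in the result is attributable to the fit term.

## Multiscale recursion

1. Extract the diagonal blocks (TADs) of the matrix and anneal each
   independently (block anneals are embarrassingly parallel; per-block
   seeds are spawned from the master seed, so serial and parallel
   execution agree).
2. Summarize each reconstructed block as a rigid bead; bin the matrix so
   each block becomes one entry.
3. Recurse on the binned matrix; when one block remains, compose
   hierarchically and return.

Composition maps each child's summary triple onto its placed bead's
triple by a rigid transform (Kabsch on the three points; for collinear
triples the free roll is fixed deterministically by aligning the child's
least-squares plane normal as close to the lab z-axis as possible). The
rigid placement preserves every intra-child distance exactly — the
method's central structural assumption, asserted to 1e-9 in the tests.

Coarse-level feasibility is evaluated on the *composed* structure: since
children ride rigidly on their beads, a coarse configuration fully
determines the finest-level one, so the finest-level constraint set is
checked directly during coarse sampling (O(N²) per proposal, negligible
at the problem sizes used). Every structure the reconstruction emits
therefore satisfies the full constraint set at the data's resolution.

The initial coarse configuration chains the children seam-aligned: each
child is oriented so its first finest-level bond continues the incoming
seam bond (seam bending starts near zero), with a random roll and a small
random tilt, and the outgoing seam follows the placed child's last bond.
This is purely a feasibility device; the anneal moves away from it.

The headline Φ of a run is the data fit at the data's own resolution
(the level-0 fit sets), reported before and after annealing. Coarser
levels optimise binned objectives whose weights aggregate many
finest-level counts; mixing levels into one number would double-count
contacts across scales. Per-level traces are kept for inspection.

Recursion depth is driven by the supplied partitions (the notion of a
"lowest significant resolution" is data-set specific); the default call
with a single TAD partition performs the two-level procedure.

## Synthetic data

The generator emulates the regime the method assumes: a chain organised
into consecutive compact domains with many internal and few external
contacts. Ground-truth chains are grown with deliberately folded
statistics (bends uniform up to the curvature cap, bonds in the lower 40 %
of their range, candidate steps biased toward per-domain anchors laid out
on a coarse random walk). Counts follow a hard-threshold Poisson model:
Poisson(λ_contact) for pairs closer than the contact threshold,
Poisson(λ_bg) otherwise, the diagonal included with d = 0. The indicator
(not a smooth decay in distance) mirrors the method's own stance that
high counts imply proximity while low counts imply nothing, and keeps
recovery tests interpretable.

Defaults: 24 bins of 100 kbp in three 8-bin domains, λ_contact = 50,
λ_bg = 0.5, 60 nm beads, 300 nm contact threshold — the scale at which
two 60 nm beads inside a compact domain blob are plausibly cross-linked.
What the generator does *not* emulate: protocol biases (fragment length,
GC, mappability), cell-to-cell structural variability beyond Poisson
noise, distance-dependent background decay, inter-chromosomal contacts.
Passing recovery tests therefore demonstrate internal consistency of the
pipeline under the method's own assumptions, not performance on real
Hi-C libraries.

## Numerical choices

- Symmetry: matrices are symmetrized as (M + Mᵀ)/2 on load; asymmetry
  beyond 1e-9 relative warns rather than fails (real pipelines emit
  near-symmetric matrices).
- Fit-set ties are broken by ascending (i, j), making selection
  deterministic.
- Quaternions are renormalized when drift exceeds 1e-12 after composition
  chains; the rotation itself is applied in matrix form for vectorized
  tails (identical to conjugation, tested to 1e-12).
- Degenerate geometry (collinear hinges, chart-crossing planar moves,
  zero-length bonds) is signalled and resampled, never silently patched.
- The dihedral sign convention follows the right-hand rule about the
  axis bond; only internal consistency matters to the sampler.
- All randomness flows from one master seed through `numpy`
  SeedSequence spawning; manifests record the seeds, so runs are
  reproducible bit for bit.

## Problem sizes

The default test and acceptance workloads use the three-domain 24-bin
fixture with five independent seeds, 8-to-30-bead chains for the
geometry audits, 10⁴ random moves for the topology audit and 10⁵ draws
for the Metropolis check. These sizes give stable statistics for every
quantity reported while keeping a full run in the minutes range on one
CPU; the pipeline itself is size-agnostic and the per-proposal cost is
O(|L| + N²) at the finest level.

## Known limitations

- Partitions are user-supplied; no TAD caller is included (block
  detection from the matrix is deliberately out of scope).
- No treatment of experimental biases in the counts; raw counts are used
  as weights directly.
- The bead-size law and the summary radius are monotone surrogates, not
  fitted physical models.
- The ensemble across seeds explores the constraint-compatible minimisers
  of Φ; it is not a posterior distribution and carries no noise model.
- With very small fit sets the coarse placement of mutually non-
  interacting domains is decided by the constraints and the initial
  state, i.e. only weakly by data — by design, since low counts are
  treated as uninformative.
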
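# Methods

## Problem and representation

A carbon HSQC spectrum reports one peak per directly bonded ¹H–¹³C pair,
at coordinates (¹H ppm, ¹³C ppm). Two compounds with similar structures
have similar peak patterns, so a distance between peak lists is a proxy
for structural similarity that needs no structure drawing and no
fingerprint. Peak intensities are deliberately ignored: they depend on
acquisition parameters and are rarely comparable across datasets.

Peaks are mapped to dimensionless coordinates by min–max normalization
over *fixed* ppm windows: x = (δC − c_min)/(c_max − c_min) with the
default window 0–200 ppm for ¹³C, and y likewise over 0–10 ppm for ¹H.
Fixed windows (rather than per-spectrum scaling) keep distances
comparable across a library; per-spectrum min–max would rescale every
pair differently and make scores incomparable. Shifts outside the window
are allowed (coordinates leave [0, 1]) but logged, since they usually
indicate a referencing problem. The pairwise peak metric is the
Euclidean norm in these normalized coordinates. Because the score scale
depends on this convention, the category cut-offs below are meaningful
only under the default windows; the windows are configurable but were
not tuned.

## Nearest-neighbour (NN) score

Each peak of **p** is matched to its nearest peak of **q** and vice
versa (many-to-one allowed); the score is the mean of all N+M directed
nearest distances. The denominator N+M makes the score an exact per-peak
mean and makes symmetry exact by construction. Ties between equidistant
target peaks are broken toward the lowest index — the distance, and
hence the score, is unaffected. NN is deterministic and O(N·M); it
describes peak *neighbourhoods* rather than a one-to-one correspondence,
so it cannot be dominated by a single long match but also cannot
distinguish clustered from uniquely-pairable peaks.

## Unique matching and the raw cost

A matching is an injective index vector j of length N over slots
0..max(N,M)−1: peak n of p pairs with peak j[n] of q when j[n] < M;
entries ≥ M (possible only when N > M) mark unmatched peaks. All peaks
of the smaller spectrum are always matched and the |N−M| surplus peaks
of the larger one are left unmatched. The raw cost ε_S is the sum of
matched pair distances; unmatched peaks cost nothing at this level.
`optimal_assignment` solves this exactly as a rectangular linear
assignment problem (scipy's Hungarian-style solver) and serves as the
deterministic optimum the genetic algorithm is benchmarked against; the
test suite additionally checks the solver against brute-force
enumeration over all injections at small sizes.

## Three-level similarity metric

The score reported for a unique matching refines the plain mean in
three steps:

1. **Matched pairs** contribute their distances (ε_S terms).
2. **Outlier rejection.** Over the matched distances, mean and
   population (divide-by-n) standard deviation σ are computed once; any
   pair with distance > mean + S·σ is flagged (single pass, one-sided —
   short distances are good matches). Default S = 2.5, exposed as a
   user parameter. Each flagged pair is dropped and *both* endpoint
   peaks are rematched to their nearest neighbour in the opposite
   spectrum, replacing one long contribution with two short ones. With
   fewer than 3 matched pairs the statistics are meaningless and
   nothing is flagged.
3. **Unmatched-peak penalty.** Each of the |N−M| unmatched peaks
   contributes its nearest-neighbour distance to the opposite spectrum.

final score = (sum of contributions) / n_contributions, with
n_contributions = kept pairs + 2·(flagged pairs) + |N−M|. The growing
denominator keeps the score a per-contribution mean. Rationale for
rejecting outliers at all: when two near-identical compounds differ by
one substituent, any unique matching is forced to contain one long
cross-region pair whose distance otherwise dominates the mean and
misclassifies the pair as dissimilar.

Design choices that were genuinely open, and how they were resolved:
rematching **both** endpoints of a flagged pair (the dropped target peak
would otherwise vanish from the score entirely); population rather than
sample σ (stable for the 5–25 pair counts involved); the refined
denominator above (keeps the reduction to ε_S/N exact when levels 2–3
are vacuous). Each is covered by a test so a change would be visible.

## Discrete genetic algorithm

The GA searches injective vectors directly, in the style of discrete
travelling-salesman GAs.

* **Population**: K members, each initialized as a uniformly random
  injection (partial Fisher–Yates).
* **Mutations**, chosen uniformly among those applicable per mutant:
  EXC swaps the values at two random positions; L3O/L4O apply a
  uniformly chosen derangement to the values at three/four random
  positions (2 and 9 derangements respectively); EXON (only when N < M)
  moves one position onto a uniformly chosen unused target slot. EXC
  alone spans all permutations at N = M; with EXON it spans all
  injections (verified by BFS in the tests), so the search is ergodic.
* **Crossover masks**: RX draws iid fair bits; BURSTRAND draws the
  first bit fair then flips each successive bit with probability 2/N
  (Gilbert–Elliott bursty noise); SINGLEBURST places a single cyclic
  block of ones of length uniform in [3, N] (needs N ≥ 3).
  The child copies parent a's values where the mask is 1 and fills the
  rest left-to-right from parent b's sequence, skipping values already
  present — the standard validity-preserving fill for unique-integer
  encodings.
* **Generations**: G_max = multiplier × max(N, M). Each generation runs
  5 mutation sweeps (every member spawns one mutant, accepted iff
  strictly cheaper) followed by one crossover step (K children from
  random distinct parent pairs and a uniformly chosen mask kind, each
  replacing the current worst member iff strictly cheaper). Greedy
  replacement suits the small K regime and gives elitism for free: the
  best member can never be lost, so the best cost is monotonically
  non-increasing. Early exit when the best cost hits 0 (identical
  spectra).
* **Presets**: small (K=2, ×5), medium (K=5, ×10), large (K=20, ×50).
  NFE — the hardware-independent effort measure — counts raw-cost
  evaluations only: K at initialization plus (5K + K) per generation,
  and is reported exactly.

The evolved matching is then scored with the three-level metric. A
fixed seed makes the whole run bit-reproducible; library-scale runs
derive an independent seed per ordered pair from one master seed, so
the two orientations of a pair are independent runs. The hot loop is
compiled with numba; the public operator functions wrap the same jitted
primitives, so there is exactly one implementation of each operator.

## Fingerprint comparator

Tanimoto similarity T_c = |A∩B|/|A∪B| over externally supplied
fixed-length bit strings (FPS-like text, hex, MSB first). Fingerprints
are consumed, not computed; two identical all-zero strings score 1 by
convention (the case never arises in practice). The usual screening
threshold is T_c ≥ 0.7.

## Library-scale machinery

All C·(C−1) ordered pairs are scored into a C×C matrix (upper triangle
p→q, lower q→p; diagonal stored for reference, excluded from all
statistics). For the stochastic DGA the upper/lower discrepancy measures
convergence: the **symmetry error rate** is the percentage of the
C·(C−1)/2 unordered pairs whose two orientations differ by more than a
tolerance (default 1e-9, i.e. exact up to float noise; configurable
because integer-category comparisons motivate coarser tolerances).
At C = 51 this gives the bookkeeping 2601 grid entries, 2550 ordered and
1275 unordered pairs, so 32 and 6 discordant pairs are 2.5% and 0.5%.

Scores bin into six categories (1 = most similar): MFP at 0.9/0.8/0.7/
0.6/0.5 (top bin closed, [0.9, 1.0]); NN at 0.0076/0.0152/0.0228/
0.0304/0.0380 and DGA at 0.0098/0.0196/0.0294/0.0392/0.0490, half-open
[lo, hi) with category 6 unbounded. The first three categories span the
"similar" range at regular intervals; these cut-offs assume the default
normalization windows.

For ranking, an unordered pair's score is the **worse** of its two
orientations (max for distances, min for MFP) — conservative, so one
lucky orientation cannot promote a pair; `mean` and `better` reductions
are available. `top_k_pairs` returns the k best pairs plus the k-th
score as the operating threshold, including all pairs tied with it.
Consensus intersects per-method hit lists into the 7 Venn regions;
pairs found by at least two methods are "significant". The recommended
protocol: fix the MFP threshold (usually 0.7), size the NN and DGA hit
lists to match the MFP hit count, and review single-method hits case by
case.

## Synthetic libraries

No public peak-list collection accompanies this kind of screening
study, so the generator fabricates one with the structure the analysis
assumes: combinatorial **families** share a scaffold peak set and
members differ by Gaussian chemical-shift jitter (default 0.02 ppm ¹H,
0.2 ppm ¹³C — typical solvent/concentration variation) plus occasional
peak addition/deletion (p = 0.05 each, the substituent-swap case);
**singletons** are drawn fresh. Chemical shifts come from region boxes
(aromatic ¹H 6–9/¹³C 110–160, aliphatic 0.5–4.5/10–80, methoxy
3.6–4.0/54–57, weighted 45/45/10) so cross-region matches are genuinely
long. Defaults: 51 compounds, 5–25 peaks each, 4 families of 6.
Fabricated fingerprints give family members a shared random bit core
with a few per-member flips, so within-family Tanimoto (~0.85) well
exceeds between-family (~0.2). A truth table records family membership
as clustering ground truth. `make_outlier_pair` builds the canonical
two-spectra outlier scenario: 11 peaks each, 10 coincident, one
displaced diagonally by 80 ppm ¹³C-equivalent across regions.

What the generator does *not* emulate: real chemical-shift
distributions conditioned on structure, peak overlap/multiplicity
artefacts, missing peaks from exchange broadening, or fingerprints
derived from actual structures. Passing tests therefore demonstrate the
algorithms' internal correctness and relative behaviour (family
separation, preset trends), not absolute category boundaries on real
compound collections.

## Numerical and scale choices

* Exact (bit-level) equality is asserted where the algorithm guarantees
  it (NN symmetry, determinism under a fixed seed); float tolerances of
  1e-12 for sums/oracles and 1e-9 for order-invariance of the refined
  score.
* Degenerate inputs: empty spectra are rejected at construction;
  single-peak pairs have one legal matching and return it immediately;
  duplicate peak coordinates are legal and tie-break deterministically.
* The preset convergence trend is evaluated on a 25-compound library
  (300 unordered pairs, 5 master seeds, all three presets) — the
  smallest scale at which the small/medium/large ordering is stable.
  Absolute symmetry error rates on random synthetic libraries are much
  higher than on a curated compound collection, because uniformly drawn
  peak sets produce many near-degenerate assignments; the *ordering*
  across presets, not the absolute rate, is the meaningful output.
* Mean NFE grows as K·N per generation and G_max as multiplier·N, so a
  full library matrix costs O(C²·K·sweeps·multiplier·N²) distance sums;
  the medium preset is the practical default.

## Known limitations

* Scores depend on the normalization windows; comparing scores across
  windows, or against published cut-offs under unknown conventions, is
  only meaningful up to that choice.
* The outlier rule assumes one or few long matches among many short
  ones; with very small spectra (< 3 matched pairs) it is disabled.
* NN and DGA can both produce false positives (NN through clustering,
  DGA through forced unique matches); the consensus step exists
  precisely because no single comparator is sufficient.
* The self-adaptive differential-evolution comparator that preceded the
  DGA is out of scope, as is fingerprint generation from structures.
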
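# Methods

This note records the models, numerical choices and open design decisions
behind `shapealign`, in the order a user meets them: scoring, alignment,
evaluation statistics, the synthetic-data generator, the folding pipeline,
and parameter optimization.

## SHAPE comparison scoring

The per-column score for reactivities `ri`, `rj` is

    s(ri, rj) = max( m·|ri − rj| + b ,  m + b )        m < 0 < b

a line of slope `m` through intercept `b`, clipped at the value it attains at
|Δ| = 1. With the default parameters (m = −2, b = 2) the score is +2 at equal
reactivity, falls linearly, and floors at 0 for |Δ| ≥ 1.

**Why this clip level.** The clip can also be written max(−m̂·|Δ| + b, −m̂ + b)
with a positive magnitude m̂ = |m|; both readings give the identical function.
A floor of −m + b with *signed* m (= +4 with the defaults) would sit above
the line's maximum b = 2 and make the function constant, which contradicts
its purpose — rewarding small reactivity differences — so that reading is
rejected. This choice affects every downstream benchmark number and is
therefore stated prominently here.

**Missing data.** SHAPE-MaP leaves some positions unquantified. A comparison
involving a missing value scores exactly 0 — between the floor and the
intercept — so alignment through unprobed regions is neither rewarded nor
penalized. Missing values are `NaN` in memory and `-999` on disk.

**Negative reactivities** (an artifact of background subtraction in
normalization) are used as-is: the score depends only on |Δ| and no transform
is applied.

**Base identity.** In combined mode, MATCH (+2) is added for identical bases
and MISMATCH (−2) otherwise; `N` never matches. Default parameter sets:
SHAPE-only m = −2, b = 2, GOP = −5, GEP = −0.25; combined keeps m, b and uses
GOP = −6, GEP = −1, MATCH = 2, MISMATCH = −2.

## Alignment

Global alignment with affine gaps (gap of length L costs GOP + L·GEP) via the
three-matrix Gotoh recursion; see the `align` module docstring for the exact
recurrences and initialization. Specific choices:

* **Sentinel, not −∞**: forbidden states (`P[0, j]`, `Q[i, 0]`) hold a finite
  value 4× larger in magnitude than any achievable score, keeping all
  arithmetic finite.
* **Traceback determinism**: the traceback tracks which matrix the current
  cell was reached through. Ties are broken diagonal ≻ gap-in-y ≻ gap-in-x,
  and within a gap run closing the gap is preferred over extending it. Any
  tie branch is optimal; fixing the order makes outputs bit-reproducible.
* **Terminal gaps** are penalized exactly like internal ones (this follows
  from the boundary initialization `D[i, 0] = GOP + i·GEP`). A free-end-gap
  mode is deliberately not the default.
* **Boundary accumulation**: `D[i, 0]` is filled by sequential addition of
  GEP rather than by the closed form `GOP + i·GEP`; the two differ only in
  floating-point association, and the sequential form keeps the DP score
  bit-identical to a left-to-right re-summation of the traceback, which the
  oracle tests exploit for exact equality.
* **P/Q semantics**: `P` consumes x against a gap in y (it advances i), `Q`
  the converse — the convention fixed by the recursion itself.
* The inner DP loop is JIT-compiled (numba); a 1,500 × 1,500 alignment takes
  well under a second, and the ~2,900-nt large-subunit scale is a few seconds
  including matrix allocation.

**Oracle.** `exhaustive_align` enumerates *every* global alignment of
instances with len(x) + len(y) ≤ 16 and scores them by direct summation with
affine gap costing. The DP must match its optimum exactly and return a member
of its optimal set; this is checked over hundreds of randomized instances
(profiles, parameters, both modes) in the test suite and the acceptance
script.

## Evaluation statistics

* **Alignment sensitivity**: 100 · |test ∩ reference| / |reference| over
  matched-position pairs, exact identity, no allowance. Reference pairs come
  from columns of a curated alignment where both rows are non-gap.
* **Structure sensitivity/PPV**: pseudoknotted and non-canonical pairs (G-U
  wobble excepted) are filtered from *both* structures (the symmetric choice;
  the convention for reference-only or prediction-only filtering is not
  established, and symmetry preserves sens(A,B) = ppv(B,A)). A reference pair
  (x, y) matches a predicted (x′, y′) when `x = x′ and |y − y′| ≤ a` or
  `y = y′ and |x − x′| ≤ a`, allowance a = 5 nt by default — tolerating
  helix register shifts while requiring one anchored end. Allowance 0 is
  exact matching.
* **Reactivity-difference distribution**: |Δ| histogram (default bin width
  0.1 SHAPE units, configurable; the natural resolution of normalized SHAPE
  scales) over pairs with both reactivities present. The randomized control
  permutes one side's reactivities across the paired positions — the minimal
  null that destroys pairing while conserving the reactivity multiset —
  repeated 8 times by default; separation is tested with a Welch (unequal
  variance) two-sample t-test of related vs pooled randomized |Δ|. Welch is
  used because the related distribution is sharply concentrated near 0 while
  the randomized one is not; equal variances cannot be assumed. When both
  samples are identical constants the t-statistic is undefined and p = 1 is
  reported (no evidence of separation).
* The distribution report carries both the count of pairs with reactivity on
  both sides and the total aligned-pair count, since conventions differ on
  which to quote.

## Synthetic data generator

The generator produces homolog pairs with a known true alignment so that
recovery is measurable without any external dataset. It emulates exactly the
features the method relies on:

* **Two-component reactivities**: paired positions draw Exp(mean 0.1),
  unpaired Exp(mean 1.0) — the simplest model consistent with the SHAPE
  convention that paired nucleotides are lowly reactive. A random mask marks
  55% of positions as paired (ribosomal-RNA-like pairing density).
* **Related-position coupling**: a retained position's reactivity is the
  ancestor's value ± an Exp(λ) magnitude (λ = 4 by default, i.e. mean |Δ| =
  0.25 SHAPE units), so the related |Δ| distribution is exponential by
  construction. The sign is random except where subtraction would go below
  zero, where it is forced positive: this keeps reactivities non-negative
  *without* clipping, so |Δ| remains exactly Exp(λ) (verified by a
  Kolmogorov–Smirnov property test at n = 10,000).
* **Sequence divergence**: substitutions at 0.25 per site (≈75% identity,
  the divergence scale of distant eubacterial rRNAs) and indel events at 0.02
  per site with geometric lengths (mean 3 nt), split evenly between
  insertions and deletions. Missing data at 5% per position.
* Default length 1,500 nt (small-subunit rRNA scale).

What it does *not* emulate: covariation structure (compensatory mutations),
position-dependent substitution rates, reactivity errors correlated along the
sequence, and multi-taxon phylogeny. Passing recovery tests on this generator
therefore demonstrates that the aligner exploits reactivity similarity and
base identity as designed — not that any particular accuracy carries over to
real rRNA data, where the published benchmark (see README) is the relevant
check.

All generator functions are deterministic under a seed; the default
configuration (including seed) is frozen and used as-is by the recovery
tests. Under these conditions SHAPE-only alignment recovers 88% of true pairs
and combined mode 97% (the acceptance script recomputes both for any seed).

## Consensus folding pipeline

Folding is delegated to ViennaRNA (`RNAalifold`, `RNAfold`); this package
never reimplements the partition function, the SHAPE pseudo-energy
conversion, or ribosum scoring.

* Step 1: `RNAalifold -p -r --maxBPspan=600 --shape=…` on the alignment, with
  per-sequence SHAPE files in the engine's 3-column dialect (missing written
  as −999, which the engine ignores). Pair probabilities are parsed from
  `alifold.out`; consensus pairs with probability **strictly greater** than
  0.95 are retained. Probabilities are taken at the consensus level (not
  averaged per sequence).
* Mapping to a sequence: a consensus column pair is dropped for a sequence if
  either column is a gap in that row, or the mapped bases cannot form a
  Watson-Crick/G-U pair (the engine would reject such a constraint).
* Step 2: `RNAfold -C --enforceConstraint --maxBPspan=600 [--shape=…]` per
  sequence; the output is verified to contain every constraint pair and an
  error listing offenders is raised otherwise. With no constraints and no
  SHAPE file this reduces to the engine's plain MFE prediction.
* Engine version and full command lines are logged on every invocation.
  Because consensus pairs above probability 0.5 are mutually compatible,
  the >0.95 constraint set is always nested and acceptable to the engine.
* Engine outputs are version-dependent; pipeline tests therefore assert
  *contracts* (constraints present, strict thresholding, determinism) on a
  designed 20-nt hairpin whose 8-bp GC-rich stem folds unambiguously, rather
  than exact energies.

## Parameter grid search

`grid_search` evaluates every point of a finite grid by aligning every
training pair and averaging sensitivity; ties break toward the earlier grid
point, making the search fully deterministic. Default ranges (m: −4…−0.5 by
0.5; b: 0.5…4 by 0.5; GOP: −10…−1 by 1; GEP: {−2, −1.5, −1, −0.5, −0.25,
−0.1}) bracket the default optima; the true granularity used to derive the
published values is unknown, so those values are shipped as configuration
defaults rather than re-derived truths. Following the published protocol, a
combined-mode search freezes m and b at the SHAPE-only optimum (pass
single-element tuples) and re-optimizes only the gap penalties and
match/mismatch terms.

## Known limitations

* Alignment memory is O(m·n) for three float64 matrices (~200 MB at the
  ~2,900-nt large-subunit scale); no linear-memory or banded variant.
* Local alignment, heuristic seeding and probabilistic (log-odds) reactivity
  scoring are out of scope.
* Multiple sequence alignment is not performed here: pairwise alignments are
  written as aligned FASTA consumable by consistency-based MSA tools.
* Reference structures in CT form must contain a consistent pairing table;
  crossing pairs are flagged pseudoknots by a greedy 5′-first nesting rule,
  which may differ from curated pseudoknot annotations in pathological cases.
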
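# Methods

This note documents the models and procedures implemented in
`axialtrends`, the defaults and numerical choices behind them, what
the synthetic-data generator does and does not emulate, and the known
limitations a user should weigh before interpreting output.

## Complexity indices

The vertebral column is treated as a fully enumerated collection of
*N* elements in *k* regions.  The Brillouin index
H_R = (1/N)·ln(N!/∏nᵢ!) is the appropriate information measure for
such collections (as opposed to Shannon entropy, which presumes a
random sample), and the evenness index H′_R divides H_R by its
maximum over the most even partition of N into k parts.  Numerical
choices:

* **Natural logarithm.**  The log base is in principle free; every
  reference value this package reproduces is consistent only with
  base e, so natural log is fixed.
* **Log-gamma, never raw factorials.**  ln n! = lgamma(n+1), exact to
  double precision for any anatomically meaningful N (and far beyond,
  to N ≈ 10⁴).  0! = 1 falls out of the same convention, so zero
  counts — accepted only behind an explicit flag — contribute nothing.
* **Truncation for display.**  Reference values are printed truncated
  (floored) at the fourth decimal, not rounded; `truncate()`
  reproduces that convention for comparisons while full precision is
  kept internally.
* **Exact unity on even splits.**  A maximally even partition (every
  count in {c, c+1}, d counts at c+1) is detected structurally and
  returns 1.0 without dividing, so the H′_R ≤ 1 bound holds to the
  last bit regardless of floating-point summation order.
* **Logit T:L.**  Implemented as ln(T/L), the logit of the thoracic
  proportion T/(T+L).  Some statistical libraries rescale
  ratio-valued input to percentages before applying the logit, which
  changes magnitudes (not orderings or signs); ln(T/L) is the
  mathematically coherent choice and is antisymmetric under swapping
  T and L.

## Trees

Trees are rooted, with branch lengths in Myr.  Newick/NEXUS parsing
(including translate tables) is delegated to dendropy with
underscores preserved verbatim; a tree explicitly flagged unrooted or
missing a branch length is rejected.  Internally a flat
parent-pointer array keeps every traversal iterative, so ~1,000-tip
trees cannot overflow the interpreter stack.

**Branch score distance (BSD)** is the square root of summed squared
branch-length differences over the union of the two trees'
bipartitions (an absent bipartition contributes length 0).
Bipartitions are canonicalized against a fixed tip ordering, and the
two child edges of a bifurcating root — which describe the same split
— are merged with summed length.  This matches the convention of the
standard unrooted implementation (phangorn's `KF.dist`, against which
the hand cases were cross-checked): swapping length between the two
root edges leaves the distance at 0, and the 4-tip opposite-topology
case gives √8.  A `merge_root_edges=False` flag keys edges by their
raw subtree tip set instead, for users who want rooted behaviour.

**Centroid tree**: the full pairwise BSD matrix is computed once (one
bipartition map per tree), column-summed, and the minimizing index
returned with ties broken deterministically by lowest index.

**Node ages** are measured back from the present, defined as the
maximum root-to-tip depth; non-ultrametric input is accepted with a
warning (shallow tips get positive ages).  **Pruning** builds the
induced subtree on the kept tips, suppressing degree-2 nodes with
summed lengths, so all retained tip-to-tip path lengths are preserved
exactly; the new root is the MRCA of the kept tips.

## Ancestral states under Brownian motion

The ML state at an internal node under BM equals the GLS prediction
given the tips.  It is computed by Gaussian message passing: an
upward pass combines each node's children by precision weighting
(variances = branch length + downstream variance), a downward pass
propagates the complement of each subtree, and the estimate at a node
fuses all incident messages.  This is linear in tree size,
equivalent to re-rooting at every node, and agrees with the explicit
dense GLS solve to ~1e-14 (tested to 1e-8 on 100 random trees).
Estimates are convex combinations of tip values, hence bounded by the
observed range, and independent of σ²; σ̂² itself is reported from the
summed squared standardized contrasts with ML (denominator n)
normalization.  Zero-length internal branches are collapsed with a
warning (ancestor and descendant share an estimate); a zero-length
terminal branch is an error, as it pins the estimate to the tip and
indicates a malformed time tree.

Trend tests default to internal→internal branches only, so both
members of each pair are node estimates; `include_tips` adds terminal
branches with the observed tip values, and the choice is echoed in
the run report.

## Descendant–ancestor trend battery

Pairing each branch's ancestor estimate X with its descendant
estimate Y, the corrected differences are D = r·(X−X̄) − (Y−Ȳ) when a
two-sided variance-ratio F-test (α = 0.05; Levene behind a flag) does
not reject var X = var Y, else D1 = adj·(X−X̄) − (Y−Ȳ) with
adj = 2·r·sX·sY/(varX+varY); the result is negated so positive means
increase.  Both formulas have exactly zero mean — asserted to 1e-10 —
so count imbalance reflects distributional asymmetry, not offset.
Tests applied: exact two-sided binomial sign test (zeros excluded),
two-sided one-sample Wilcoxon signed-rank (exact null for small
tie-free samples, normal approximation with continuity correction
otherwise), and a two-sample Wilcoxon rank-sum comparing positive
values against magnitudes of negative values (exact by enumeration
for ≤25 pooled observations, asymptotic beyond).  Robust regressions
use the Huber M-estimator (tuning constant 1.345, MAD scale,
coefficient tolerance 1e-8, cap 200 iterations — the canonical
defaults) with coefficient Wald F-tests from an HC3-type sandwich
covariance evaluated on the final weighted fit.  Per-group reruns
require at least 10 branches (configurable); smaller groups are
skipped, not errored.  No multiple-testing correction is applied
across indices; users comparing many indices should account for that
themselves.

**Calibration and a documented limitation.**  On driftless simulated
histories (200 tips) the sign test on RTM-adjusted true branch
changes rejects at the nominal 5% level in ≈1% of replicates —
conservative, because phylogenetically correlated branches violate
the test's independence assumption in the safe direction.  With
Gaussian drift of 0.5·σ per Myr it rejects in ≈95% of replicates, but
note the direction: mean-centering removes the uniform shift, so the
imbalance the test detects comes from the right skew that
heterogeneous (Yule-exponential) branch durations impose on the
centred differences, producing an excess of *decreases* under a
uniformly *positive* trend.  The direction of a trend should be read
from the node-estimate-vs-age regression, not from the sign counts
alone.  Further: when the same battery is run on ML ancestral
*estimates* rather than true values, BM smoothing shrinks
descendant–ancestor differences toward zero and a uniform Gaussian
drift becomes statistically invisible to the count tests (power ≈
the nominal level).  Detectable signal in estimate-based runs
therefore reflects asymmetry structure in the data beyond a uniform
mean shift.  Calibration tests accordingly use the generator's true
node values, which is what they are designed to certify: the test
battery itself, isolated from reconstruction error.

## Subclade skewness partition

With weights wᵢ = nᵢ/N, group means mᵢ, grand mean M, group
population variances vᵢ and third central moments tᵢ:

    SCW = Σ wᵢ tᵢ
    SCH = 3 Σ wᵢ vᵢ (mᵢ − M)
    SCB = Σ wᵢ (mᵢ − M)³

This is the exact mixture identity for the pooled third central
moment — the only decomposition in which the three components sum to
the total, which is the module's correctness oracle (machine
precision on arbitrary inputs).  All moments use population
(denominator n) normalization for the same reason; the reported
standardized `total_skewness` is the population moment ratio μ₃/σ³.
Percentages are taken against the *signed* total: a component opposing
the overall skew is negative and others may exceed 100, and they
always sum to 100.  Because the partition's directional reading
presupposes right skew, left-skewed inputs (most complexity indices)
are negative-log transformed automatically (override with
`transform='force'|'none'`); the decision is recorded in the output.
The verdict label is deliberately coarse — "driven-leaning" only when
SCW is strictly largest, ties counted as passive — and carries the raw
percentages for the user's own judgement.

## Synthetic data

The generator emulates a desk-scale mammalian clade:

| parameter | default | rationale |
|---|---|---|
| n_tips | 200 | desk-scale stand-in for ~1,100-species trees |
| birth_rate | 0.03 /Myr | Yule expected crown age ≈ Σ₂ⁿ 1/(kλ) ≈ 175 Myr |
| sigma2 | 5e-4 trait²/Myr | keeps an index-like trait with sd ≈ 0.3 over the tree height |
| root_value | 0.6 | mid-range of presacral Brillouin values |
| drift | 0 | driven regime uses 0.5·σ per Myr |
| lower_bound | none | bounded regime reflects at root − σ |
| n_groups | 10 | named higher taxa of unequal size |

Trees are pure-birth (no extinction), ultrametric by construction.
Traits evolve by exact Gaussian increments per branch; with a lower
bound, branches are subdivided into 10 substeps with reflection
(v ← 2·bound − v) after each — reflection rather than truncation or
absorption, to mimic diffusion away from a hard bound without
distorting increments elsewhere.  Formula tables fix C = 7 (cervical
counts are nearly invariant in mammals), map the latent trait to
T ∈ [9, 24] and a correlated second latent (ρ = 0.5) to L ∈ [2, 31].
The latent is centred on the root value and mapped to the middle of
each count range, so the root formula sits mid-range rather than at
the range floor — without this, clamping would pin roughly half the
species to the minimum count and destroy the latent signal.  Groups
are assigned by repeatedly splitting the largest clade until the
requested number of monophyletic groups exists, so groups are clades,
as real higher taxa are.

What the generator does **not** emulate: extinction and fossil
sampling; homoeotic variation in cervical counts; discreteness
effects of real count data on the indices' error structure beyond the
clamped rounding used here; correlated evolution between T and L
beyond a single latent correlation; rate heterogeneity across clades.
Passing calibration tests on this generator therefore certifies the
statistical machinery under idealized BM-with-drift conditions, not
the biological fidelity of any particular empirical conclusion.

All randomness derives from one integer seed through independent
substreams (tree, trait, formula), making every dataset and report
bit-reproducible; pipeline reports echo the seed and every
data-dependent decision (D vs D1, transform applied, tip inclusion).

## Degenerate inputs and tie-breaks

* Constant X and Y: degenerate-input error in the RTM step; all-zero
  adjusted differences likewise (no signal to test).
* All-equal trait values: the skewness partition reports zero
  components and null percentages with an explanatory reason.
* Centroid ties: lowest index wins, deterministically.
* Sign-test zeros are excluded from the count; Wilcoxon ties fall
  back to mid-ranks with the normal approximation.
* Robust regression on a constant response returns slope 0 exactly;
  a constant predictor is a domain error.

## Problem sizes used in the shipped tests

Unit and property tests run on trees of 4–30 tips; the calibration
suite uses 500 driftless and 100 drifted 200-tip histories; the
mixture-identity check uses 1,000 random grouped datasets; the GLS
cross-check uses 100 trees of ≤10 tips.  These sizes were chosen so
the full suite completes in well under a minute on one core while
keeping Monte-Carlo error far from every asserted bound.
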
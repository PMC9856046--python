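# Methods

This note records the models implemented in `pollencrp`, the numerical
and design choices behind them, what the synthetic-data generators do and
do not emulate, and the problem sizes used by the test suite and the
reproducibility script.

## Cysteine-spacing grammars

A CRP family pattern is an ordered list of conserved cysteines separated
by bounded runs of non-cysteine residues.  The parser reads the compact
notation (`C`, `X`, `X(a)`, `X(a-b)`); each inter-cysteine region
accumulates its tokens, so `CXXC` and `CX(2)C` denote the same spacer.
Two decisions were genuinely open and are resolved as follows:

* **`X` excludes cysteine.**  A match anchors on consecutive cysteines of
  the sequence's cysteine skeleton, so spacers are cysteine-free by
  construction.  Allowing cysteines inside `X` would let a pattern skip
  over skeleton positions and make the family grammars degenerate —
  they describe conserved-cysteine spacing, not arbitrary subsequences.
* **Notation repair.**  A bracketed range must follow an `X`; the one
  published row that reads `...CXC(1-8)C` is repaired to `...CXCX(1-8)C`
  (restoring the eighth cysteine in line with the sister rows) and the
  repair is logged at parse time.

Matching is position-free (no signal-peptide model: how mature peptides
were delimited upstream is unknown), extra cysteines outside the matched
span are ignored, and a configurable precursor size filter (default
≤ 300 residues) is applied before matching.  The per-family *envelope*
takes, per spacer, the min of mins and max of maxes over the per-species
rows; it provably accepts everything any row accepts.  When a sequence
matches several families, the primary label is chosen by (1) more
matched cysteines, (2) smaller total spacer slack (the more specific
grammar), (3) a fixed precedence (PCP-B, SCRL, GASA, nsLTP,
PCP-A/DEFL/LCR).  On the published patterns the four 8-cysteine
envelopes are pairwise disjoint (no gap vector satisfies two), so the
tie rule is exercised only by engineered inputs.  Coordinates are 0-based
half-open internally and 1-based in reports.

## Codon site models

Substitution follows the standard codon model on the 61 sense codons:
the instantaneous rate i→j is zero unless the codons differ at exactly
one nucleotide, and otherwise proportional to π_j · κ^[transition] ·
ω^[nonsynonymous].  Codon frequencies π default to F3x4 (position-
specific nucleotide frequencies estimated from the alignment,
renormalized over sense codons); equal and user-supplied frequencies are
options.  Site models place a mixture over ω:

| model | ω distribution | free parameters (besides κ) |
|-------|----------------|------------------------------|
| M0  | one ω | ω |
| M1a | ω0 < 1 (p0), ω = 1 (1−p0) | p0, ω0 |
| M2a | M1a + ω_s ≥ 1 (p2) | p0, p1, ω0, ω_s |
| M7  | Beta(p, q) in K = 10 equal-probability classes | p, q |
| M8  | Beta(p, q) with weight p0, plus ω_s ≥ 1 with weight 1−p0 | p0, p, q, ω_s |

Beta classes are represented by their conditional means within each
quantile decile (computed by the incomplete-beta identity; a median rule
is available).  K = 10 follows the conventional setting; the
representative-value rule is our choice and is tested against numerical
quadrature.

**Rate normalization.**  All category matrices of a mixture share one
scale: the class-weight-weighted average equilibrium rate.  This makes a
branch length the expected number of substitutions per codon averaged
over site classes, and — importantly — makes zero-weight classes inert,
so lnL(M8 with p1 = 0) equals lnL(M7) exactly.  The simulator uses the
identical convention.

**Likelihood.**  Felsenstein pruning over compressed site patterns,
batched across ω categories, with per-pattern rescaling against
underflow.  Gaps, ambiguity codes and (optionally) masked in-frame stop
codons are marginalized as missing data at the leaf; alignments with
in-frame stops are rejected by default.  The tree is rooted arbitrarily;
reversibility makes the likelihood independent of that choice (tested).
A vectorized exhaustive enumeration over internal-node states serves as
the correctness oracle on ≤ 4-taxon trees (agreement < 1e-8 per site).

**Fitting.**  Bounded quasi-Newton (L-BFGS-B) on the natural scale with
restarts: candidate starts are, in priority order, a warm start (M8 from
the M7 optimum with p1 → 0; M2a from M1a), a fixed default, then seeded
random draws; `n_restarts` (default 3) starts are used.  Branch lengths
and κ are optimized jointly under M0 and then held fixed for the mixture
models (re-optimization is switchable) — a deliberate trade of a small
amount of likelihood for a large amount of speed at desk scale.
Convergence tolerance is 1e-6 on lnL.  When line searches terminate
abnormally on finite-difference noise, a derivative-free (Nelder–Mead)
polish verifies or completes the optimum before the fit is declared
converged.  Because the null optimum is an admissible point of the
alternative, `fit_site_models` additionally pins M8 (M2a) at the M7
(M1a) optimum whenever the optimizer lands below it; LRT statistics are
therefore nonnegative by construction.  Alignments with no variable
sites are flagged unidentifiable.

**LRT.**  2ΔlnL is compared to χ² with df = 2 for M7 vs M8 and M1a vs
M2a (the extra-parameter count); the statistic is clamped at zero.  At
the boundary (p1 = 0, ω_s = 1) the χ² reference is known to be
conservative, which the null-calibration test quantifies.  Significance
tiers are annotated * p < 0.05, ** p < 0.001, *** p < 0.0001.

**BEB.**  Site posteriors for the ω_s class integrate over (p0, p, q,
ω_s) on a uniform grid of 10 interval midpoints per dimension — p0 over
(0, 1), p and q over (0, 2), ω_s over (1, 11) — with grid weights
proportional to the data likelihood.  κ, branch lengths, codon
frequencies *and the rate normalization constant* stay fixed at the M8
MLE; fixing the scale is what lets the per-ω site likelihoods be cached
across the 10⁴ grid points, and it perturbs only the (already
approximate) prior geometry, not the per-grid-point likelihoods'
internal consistency.  The naive empirical-Bayes variant (posteriors at
the MLE only) is provided for comparison.  Site reports are keyed to a
reference taxon's residues (`23E` style) and mark cysteine columns so
the expected conservation of the disulphide skeleton can be inspected —
it is a property to look at, not a test assertion.

## Proteomic post-processing

Target–decoy FDR at threshold s is (#decoys ≥ s)/(#targets ≥ s), 1.0
when no target passes; a score threshold accepts whole tied groups, so
every PSM takes the FDR of its score group, and q-values are the running
minimum over lower thresholds (non-increasing in score).  Tiers: q ≤ 1%
high, 1% < q ≤ 5% medium, else excluded; the published wording gives
strict inequalities on both sides of 1%, so the boundary is assigned to
the high tier (logged choice).  The +1-pseudocount numerator variant is
available and off by default.  Replicate merging is a union with
per-protein replicate counts and relative abundance as percent of total
peptide area; molecular weight falls back to 110 Da per residue when no
measured mass is supplied.  Size profiles use bins <20, 20–40, 40–60,
≥60 kDa by default.

## Enrichment and expression

Enrichment is a one-sided hypergeometric upper tail per term (over-
representation only), fold = (k/n)/(K/N), with Benjamini–Hochberg
adjustment across the tested terms — the standard reading of "FDR
correction" here; terms are flat labels without ontology propagation.
The reporting filter keeps fold > 3 (strict) and p < 0.05.

Counts are normalized by median-of-ratios: per-gene geometric means over
samples restricted to genes nonzero in every sample (a pseudo-reference
fallback uses positive entries only); the per-sample factor is the
median count/reference ratio taken in ratio space.  Specificity
categories quantify "very little to no expression" as reference tissues
≤ max(5% of the target peak, 5 normalized counts), with an expressed
floor of 10 normalized counts — the source analyses give no numbers, so
these defaults are our calibration and are configurable.  Categories:
mature-anther-specific, young-anther/bud-enriched (auxiliary peak
exceeds target and references stay below the same leakage bound),
broadly-expressed, not-expressed.

## Synthetic data: what it does and does not emulate

Generators are deterministic in their seed and emit truth tables.
Sequences draw spacer lengths uniformly within pattern ranges and spacer
residues uniformly over the 19 non-cysteine amino acids; negatives are
single-cysteine knockouts.  Codon alignments evolve gap-free along a
given tree (no indels, no alignment error, no recombination).  PSM
scores are Gaussian mixtures (true matches N(4, 1) with proportion 0.6
against a N(0, 1) null shared with the decoys) — simplest forms with the
needed structure, not spectral realism.  Counts are negative-binomial
(dispersion 0.3) with log-normal gene effects, 2× library-size
variation, and planted target-only genes with exactly zero reference
signal.  Annotation tables plant term enrichment by resampling sample
memberships at an elevated rate.  Passing tests therefore demonstrate
correctness of the algorithms under their own assumptions; they do not
certify performance on real proteomes, real alignments (whose
construction — orthology calls, aligner, masking — is upstream of this
package), or real RNA-seq noise.

## Problem sizes and limitations

The test suite and `scripts/acceptance.py` run at desk scale, chosen as
the package's own verification budget: grammar round trips use 500
sequences per family; the pruning oracle uses 4 taxa × 20 codons; M0
recovery uses 20 replicates of 8 taxa × 300 codons (ω = 0.3, κ = 2);
nesting uses 20 replicates of 5 taxa × 50 codons; null calibration uses
100 replicates of 6 taxa × 60 codons with single warm-started fits; BEB
precision uses 8 taxa × 200 codons with 20% of sites at ω = 4; the
tabular statistics are checked against brute-force oracles on 100 random
inputs each.  Known limitations: branch lengths are not re-optimized per
mixture model by default; the BEB grid is the conventional 10-point
one (finer grids are a config change); branch models, branch-site
models, clade models, tree search and synonymous-rate variation are out
of scope; published selection results on real orthologue sets are not
bit-reproducible in principle, since they depend on retrieval and
alignment choices outside this package.
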
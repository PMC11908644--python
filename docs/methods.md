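# Methods

## Model and assumptions

`panselect` scores genome conservation on a single-chromosome pangenome
variation graph. The working assumptions are:

- each haplotype is a complete walk over the chromosome's graph (GFA
  P-line or W-line; partial W-line walks of one sample are concatenated
  in file order);
- homology is expressed by segment sharing: two haplotypes that traverse
  the same segment carry homologous sequence there, so similarity can be
  measured from graph topology and segment lengths alone, without a
  base-level alignment;
- enough segments are universal (traversed exactly once by every
  haplotype) to serve as window anchors — true for graphs of haplotypes
  at roughly ≥ 98% identity; and
- translocations are absent (one GFA = one chromosome). Inversions are
  tolerated: a globally reverse-complemented haplotype keeps its
  anchors, and an inverted sub-region is extracted, re-oriented and
  compared by content.

## Binning geometry

Boundary candidates are segments with exactly one occurrence in every
path whose orientation matches the path's *dominant* orientation (the
majority orientation of its universal single-copy segments relative to
the reference). The dominant-orientation rule keeps anchors on fully
inverted haplotypes while discarding anchors that lie inside a local
inversion, where sub-path extraction would be ambiguous; a
`--strict-forward` flag restricts candidates to all-forward occurrences
instead. Candidates are thinned greedily left to right: keep the first,
then the next candidate starting at least `s` bases after the end of the
last kept one. Greedy selection is deterministic and linear; it does not
try to optimise bin-size uniformity.

Bin *reference intervals* place their edges at the **ends** of the
selected boundary segments (leading bin from 0, trailing bin to the
reference length), so the intervals tile the reference exactly — a
property the bedGraph/BED outputs rely on. Bin *sub-paths* are the steps
strictly between the two boundary occurrences: the anchors themselves
are excluded from comparison because mass shared by construction can
only push every Jaccard value toward 1 and compress the score's dynamic
range (the test suite demonstrates this monotonicity). When a haplotype
traverses a bin in reverse, its sub-path is reversed with orientations
flipped before storage; when no anchor exists at all, the whole
chromosome becomes one bin and a warning is logged.

## Similarity score

Sub-paths are reduced to orientation-blind multisets of segment
traversal counts; the weighted Jaccard index is the ratio of
length-weighted multiset intersection to union. Conventions:

- two empty sub-paths score J = 1 — haplotypes that both deleted a
  region are identical there, and scoring 0 would flag shared deletions
  as divergent;
- the bin score averages the pairwise J values arithmetically over all
  unordered pairs (the length weighting lives inside the index, not in
  the average);
- the score is x = −ln(max(J̄, ε)). The natural log is a convention
  only; a different base rescales every score and leaves the mixture
  fit's classifications unchanged. The floor ε handles J̄ = 0 (disjoint
  walks): by default ε = 1/(1 + W) with W the largest pairwise union
  weight over all bins, i.e. just below the smallest non-zero Jaccard
  the data could produce, so floored scores stay on the scale of real
  ones instead of breaking the tail fit at +∞. ε is overridable
  (`--jaccard-floor`) and echoed in the TSV header and model dump.

## Mixture null and significance

Scores are modelled as π·N(μ, σ²) + (1−π)·logN(μ_L, σ_L²), fitted in
stages rather than by joint likelihood so that each component is
estimated where it is identifiable:

1. **Gaussian bulk** (μ, σ): iterative left-anchored robust fit.
   Starting from the global median, repeat: σ ← median(μ − x | x ≤ μ) /
   Φ⁻¹(0.75) (a half-sample MAD using only the left flank, which the
   divergent tail never contaminates), then μ ← median of scores within
   μ ± 3σ. The iteration is a fixed point at the true (μ, σ) when the
   left flank is Gaussian, and converges in a handful of steps; 25
   iterations are allowed, with a relative tolerance of 1e−10 on μ.
   All-equal scores (e.g. a fully conserved test chromosome) get a
   machine-epsilon σ and a warning; scores of exactly 0 are kept — they
   are the most conserved observations, not artifacts. Below 30 scores
   a noisy-fit warning is issued.
2. **Log-normal tail** (μ_L, σ_L): maximum likelihood (mean and SD of
   ln x) on the tail subset {x > μ + k·σ}, k = 2 by default
   (`--tail-k`). Because a Gaussian bulk of any size spills a few points
   past μ + 2σ, one model-based trimming pass follows: tail points whose
   density under the fitted Gaussian exceeds their density under the
   initial log-normal are discarded and the log-normal refitted — this
   removes bulk spill-over almost exactly while leaving a genuine tail
   untouched. An empty tail subset marks the model *tail-free* (π = 1,
   divergence calls disabled); a tail of fewer than 10 points falls back
   to fitting all positive scores, with a warning.
3. **Combination**: π = 0.5 — the null is the average of the two fitted
   densities. `--estimate-weight` instead runs EM on π alone (component
   parameters frozen, ≤ 200 iterations, stop at |Δπ| < 1e−6).

p-values are two one-sided tail probabilities under the full mixture
CDF: p_cons = F(x), p_div = 1 − F(x); they sum to 1, so conserved and
divergent calls are mutually exclusive for α < 0.5. A
`--null gaussian` option uses the Gaussian component alone instead. No
multiple-testing correction is applied by default; `--fdr` switches to
per-tail Benjamini–Hochberg. Adjacent significant bins of the same
class merge into regions annotated with their smallest p-value
(BED score = −10·log10 min p, capped at 1000).

## Synthetic graphs and what they do (not) show

The generator builds the structure the pipeline assumes: universal
anchor segments alternating with variable regions. Each region's
reference allele is cut into ~25 bp segments (the granularity of
small-variant bubbles in real graphs); each non-reference haplotype
replaces each segment independently with a same-length private segment
with probability equal to the region's divergence parameter — so that
parameter is exactly the expected private fraction of region sequence —
and may additionally delete or tandem-duplicate its whole allele with
probability `sv_probability`. The first haplotype always carries the
reference alleles, fixing anchor coordinates. All randomness flows from
one integer seed; equal parameters give byte-identical GFA.

Default parameters define the standard benchmark: 4 haplotypes, 20
regions of 1 kb, anchors of 100 bp, divergence linearly spaced 0 → 0.9,
no structural variants. These sizes make every property checkable in
seconds while leaving enough segments per region (~40) that realised
divergence concentrates around its parameter.

Deliberately not emulated: base-level mutation followed by graph
construction (the method never reads nucleotide identity, only sharing
and lengths, so simulating topology directly keeps ground truth exact),
length-changing small indels within alleles, nested bubbles, coalescent
haplotype correlation, and translocations. Passing tests therefore
demonstrate the pipeline's correctness on graphs matching its structural
assumptions, not robustness to graph-builder artifacts such as
spuriously collapsed repeats.

## Numerical and interface choices

- Coordinates are 0-based half-open everywhere, matching BED/bedGraph.
- P-line overlap fields must be `*` or all-match CIGARs (blunt
  concatenation is assumed); L-lines are parsed but only used by the
  optional `--validate-links` diagnostic.
- The reference path defaults to the first in file order (overridable
  with `--reference`); there is no principled way to pick one haplotype
  over another, and the choice only fixes the coordinate system.
- Boundary-candidate ties never arise: selection is a deterministic scan
  in reference order. Region merging breaks at any neutral bin or class
  change; single-bin regions are reported as such.
- One process handles one chromosome; bins are scored independently, so
  parallelism across chromosomes is left to the caller.

## Problem sizes

The test suite and the acceptance script run on simulated chromosomes of
about 2.5–22 kb (5–30 regions, 2–6 haplotypes) and on simulated score
sets of 10 000 bins, with 8–50 replicate seeds per property; the full
suite completes in well under a minute. These sizes were chosen as the
smallest at which each statistical check is decisive (e.g. recovery
tolerances of 3 standard errors at n = 10 000).

## Known limitations

- Regions whose haplotype walks differ only in segment orientation
  (pure inversions over the same segments) score J = 1: the index is
  content-based by design, matching segment-level path similarity as
  used in graph toolkits.
- Sparse anchors (highly divergent graphs) produce bins much larger
  than `s`; bin sizes are reported in the TSV so downstream analyses
  can filter.
- The staged mixture fit presumes the conserved bulk is the *low* mode
  and is the majority left of the global median; a chromosome that is
  mostly divergent would invert that geometry and the fit would anchor
  on the wrong component.
- p-values are per-bin; with many bins the default α = 0.05 calls ~5%
  of null bins per tail (use `--fdr` when that matters).
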
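# Methods

## GAD scoring

A gene-body-associated domain (GAD) is read off a symmetric, binned,
intra-chromosomal contact matrix at fixed resolution (default 10 kb). A
gene maps to the half-open range of bins it overlaps by at least one base.
Eligibility requires gene length strictly greater than 30 kb *and* at
least 3 gene-body bins; at 10 kb resolution the length condition is the
binding one (a > 30 kb gene always spans ≥ 4 bins), but both are checked
so that coarser resolutions behave sensibly. Ineligible genes are reported
with reason `too_short`, never silently dropped.

`G` is the mean over the off-diagonal upper triangle of the gene-body
block; `Gu` and `Gd` are the same statistic over the square flank blocks
of `n_bins` bins immediately upstream (lower coordinates) and downstream.
`Gs = 2G/(Gu+Gd)`. Design choices where the definition is genuinely open:

- **Diagonal exclusion.** Self-bin entries are dominated by self-ligation
  signal; including them compresses Gs toward 1. An `include_diagonal`
  flag restores them.
- **Flank geometry.** Flanks are measured in bins, not bases, so the three
  blocks are size-matched in matrix space. The default compares
  within-region means (square flank blocks); `flank_mode="rectangle"`
  instead averages the gene-vs-flank rectangles for users who read
  "upstream interaction" as gene-to-flank contact.
- **Edges.** A gene whose flank would leave the matrix is undefined
  (`edge`) rather than truncated: truncated flanks would bias the mean
  asymmetrically. `Gu + Gd = 0` yields `zero_flanks`.
- **Strand is ignored**; "upstream" always means lower genomic
  coordinates. Overlapping genes are scored independently.

Invariants relied on downstream: Gs is scale-invariant (it is a ratio, so
any global rescaling of the matrix — including the balancing rescale —
cancels), symmetric in the two flanks, strictly increasing in uniform
body-block enrichment, and exactly 1 on a uniform matrix.

## ICE balancing

Iterative correction equalises bin marginals: each iteration divides every
entry by the product of its row and column marginal ratios (relative to
the mean unmasked marginal), accumulating per-bin biases, until the
largest relative bias change drops below `tol` (default 1e-5, cap 200
iterations; non-convergence is flagged, not raised). Low-coverage bins
are masked up front — marginal at or below the 2% quantile of nonzero
marginals *and* below half the median nonzero marginal. The second guard
restricts masking to genuinely starved bins; without it, re-balancing an
already-balanced matrix (whose marginals are equal to within `tol`) would
mask bins on floating-point noise, and balancing would not be idempotent.
The output is rescaled so the mean unmasked off-diagonal intensity matches
the input; because Gs is a ratio this rescale is a no-op for scoring and
exists only to keep balanced matrices on an interpretable scale.

## Sig-GAD calling

Defined scores are sorted ascending (ties broken by gene id so the call is
order-invariant), rank and score are each min-max rescaled to [0, 1], and
the cutoff rank is the argmin of (rescaled score − rescaled rank) — the
tangent point where the curve's slope passes 1, the standard
operationalisation used for super-enhancer rank curves. A gene is
significant iff its rank exceeds the cutoff *and* `Gs > 1` (strict). The
rescaled axes make the rule unit-free; on a raw-axis curve "slope = 1"
would depend on the score units. With fewer than `min_genes` (10) defined
scores only the floor rule is applied (logged); a flat curve calls
nothing. A known property of the tangent rule on noisy data: when the
decoy (non-domain) score distribution has a steepening empirical tail, the
cutoff can admit the top one or two background genes — visible in the
synthetic benchmark as precision slightly below 1 at perfect recall.

## Statistics

Both procedures are implemented in `gadpipe.stats` so every reported
p-value comes from one auditable code path; SciPy supplies only
distribution functions (t and normal CDFs).

- **Pearson correlation**: product-moment r; two-sided p from
  `t = r·sqrt(n−2)/sqrt(1−r²)` against Student-t with n−2 df; `|r| = 1`
  returns p = 0; constant vectors are an error, not r = 0.
- **Wilcoxon rank-sum**: exact two-sided p (2·min(P(W≤w), P(W≥w)), capped
  at 1) via a dynamic program over the smaller group's rank-sum
  distribution when min(n) ≤ 8 and there are no ties — equivalent to
  enumerating all C(n₁+n₂, n₁) assignments; otherwise a normal
  approximation on midranks with tie-corrected variance and a 0.5
  continuity correction. The method used is recorded in every result.

No multiple-testing correction is applied anywhere; all downstream
thresholds are on raw p-values, and users screening many hypotheses should
correct externally.

## TF screen

Candidates must pass all four strict criteria: `log2FC > 1` with
`p < 0.05` upward in the development series and downward in the activation
series, and Pearson `r > 0.3` with `p < 0.05` against the target in both
expression series. Correlations are one-sided by design — the screen looks
for positive regulators — with a `two_sided_r` flag for |r|. Expression
values are used as provided; a TF absent from either dataset cannot be a
candidate; the target gene is removed from the TF list. Raising any
threshold can only shrink the candidate set.

## Single-cell stage

QC boundary semantics are strict by wording: "fewer than 400 genes"
removes ≤ 399 and keeps 400; "more than 10%" mitochondrial removes
> 0.10 and keeps exactly 0.10. Log-normalisation is
`ln(1 + count/total × 10000)` per entry. The module score bins genes by
mean normalised expression into 24 equal-frequency bins (ties broken by
gene id), draws up to 100 control genes per set gene without replacement
from the same bin (set genes excluded), pools the draws with multiplicity
and reports mean(set) − mean(controls) per cell. Defaults (24 bins, 100
controls) follow the reference implementation of this scoring scheme; both
are parameters. The score is deterministic for a fixed seed, invariant to
gene row order (everything is sorted before drawing) and exactly invariant
to constant shifts of the normalised matrix (bin ranks and both means
shift together). Cells with score exactly 0 are excluded from the
high/low split because the groups are defined by strict inequalities.
Batch correction, clustering and embedding are deliberately out of scope;
the split is defined purely on the module score.

## Synthetic data

The generators define the conditions under which the pipeline is
validated; what they emulate and what they do not:

- **Hi-C**: expected intensity `base · (1+|i−j|)^(−α)` (the +1 offset
  avoids the distance-0 singularity), default α = 1 and base 100 counts —
  a deep-coverage 10 kb map. Planted genes multiply the *off-diagonal*
  entries of their body block by an enrichment factor (default benchmark
  3): domain formation enriches contacts between distinct loci, not
  self-ligation, and planting the diagonal would also distort balancing
  biases. Optional Poisson noise on the upper triangle, mirrored for exact
  symmetry. Decoy genes (40 kb) and one 20 kb gene are auto-placed with
  full flank room; truth labels are returned. Not emulated: translocations,
  copy-number effects, inter-chromosomal contacts, read-level artefacts —
  so passing benchmarks demonstrate correctness of the scoring machinery,
  not robustness to structural variation.
- **Expression series**: a driver TF trending up across the development
  series and down across activation (amplitude 2 on a baseline of 5),
  target = driver + trend + Gaussian noise (sd 0.5), 20 samples per
  series, 49 decoy TFs with unit-variance independent variation. The
  companion DE tables plant the driver (and optionally confounders that
  must be rejected by the correlation filter) directionally; all other
  rows are constructed to fail at least one DEG criterion. With zero
  noise, zero slope and zero trend the target would be constant and
  correlation undefined, so independence of decoys is validated at small
  noise instead.
- **Single cell**: negative-binomial counts (dispersion 2) with per-gene
  lognormal mean variation around 1, 2000 genes, 200 cells per population
  by default; markers (and optional co-upregulated query genes) get a
  4-fold mean increase in the exhausted population. Per-cell mitochondrial
  fractions are drawn uniformly (default 1–8%) and realised exactly by a
  multinomial over 10 `MT-` genes. Cells violating exactly one QC
  criterion each can be appended on request. Not emulated: doublets,
  batch effects, ambient RNA.

All generators are bit-reproducible for a fixed seed.

## Problem sizes

The recovery benchmark uses a 600-bin matrix with 20 planted domains among
100 genes over 10 seeds; the screen benchmark 100 seeds of 50 TFs × 20
samples; the single-cell null 100 seeds at 100 cells per population and
600 genes, with the signal arm at the full 200 cells per population and
2000 genes. These sizes give stable Monte-Carlo estimates (binomial SE
≤ ~2 percentage points on the rates tested) while keeping the whole suite
fast on a laptop.

## Known limitations

- Only single-chromosome, single-resolution matrices; KR balancing and
  `.hic`/`.cool` binary formats are out of scope (plain-text COO/dense
  matrices plus bin tables are the interchange format).
- The sig-GAD tangent rule is heuristic; its behaviour on multi-modal
  score distributions is not characterised here.
- The exact rank-sum branch is limited to min(n) ≤ 8 without ties;
  mid-sized tied samples always use the normal approximation.
- The screen reports raw p-values; with thousands of TFs the intersection
  of two datasets controls false positives only informally.
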
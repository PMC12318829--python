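# gadpipe

Multi-omics analysis toolkit for studying how chromatin architecture and
transcription-factor programmes control a target gene, built around three
quantitative procedures:

1. **Gene-body-associated-domain (GAD) scoring** of Hi-C contact matrices.
   Some genes sit inside a self-interacting chromatin domain that coincides
   with their gene body; `gadpipe` quantifies this from ICE-balanced
   intra-chromosomal contact matrices and calls the significantly
   domain-forming genes.
2. **A two-dataset transcription-factor screen** that nominates candidate
   regulators of a target gene by intersecting directional
   differential-expression filters with Pearson-correlation screens across
   two independent sample series (e.g. a developmental and an activation
   time course).
3. **Single-cell exhaustion module scoring**: QC filtering, depth
   log-normalisation and bin-matched control scoring of a T-cell exhaustion
   marker set (*PDCD1*, *TNFRSF9*, *LAG3*, *HAVCR2*, *TOX*, *CTLA4*),
   followed by comparison of any query gene between high- and low-scoring
   cells.

A bundled synthetic-data generator emulates all three input modalities
(distance-decaying contact matrices with planted domains, correlated
expression series with a planted driver TF, negative-binomial single-cell
counts with an exhausted subpopulation), so the entire pipeline is testable
without any downloads.

## The GAD score

For each gene longer than 30 kb (spanning ≥ 3 bins at 10 kb resolution),
let `G` be the mean contact intensity of the gene-body block of the
balanced matrix, and `Gu`, `Gd` the same statistic for upstream and
downstream flanking blocks of equal length. The GAD score is

```
Gs = 2 G / (Gu + Gd)
```

Block means are taken over the off-diagonal upper triangle of each square
block (the main diagonal is self-ligation signal). On a uniform matrix
every eligible gene scores exactly 1; true GADs score above 1. Significant
GADs are genes with `Gs > 1` lying past the point where the slope of the
min-max-rescaled ranked score curve passes 1 (the tangent-point rule used
for super-enhancer rank curves).

The TF screen applies strict thresholds `r > 0.3` and `p < 0.05` in *both*
series (Pearson p from the t transform `t = r·sqrt(n−2)/sqrt(1−r²)`),
intersected with TFs that are upregulated (`log2FC > 1`, `p < 0.05`) in
the development series and downregulated in the activation series. Cell QC
removes cells with fewer than 400 detected genes, fewer than 1000 UMIs or
more than 10% mitochondrial counts; the exhaustion score is the Tirosh-style
mean over marker genes minus the mean over expression-bin-matched control
genes. All group comparisons use a self-contained two-sided Wilcoxon
rank-sum test (exact enumeration for small tie-free samples, tie-corrected
normal approximation otherwise).

## Worked example

Run the full synthetic-to-report pipeline:

```
gadpipe all --seed 7 --out run1
```

This simulates a 400-bin contact matrix with 8 planted gene-body domains,
ICE-balances it, scores and calls GADs; simulates two expression series
with one planted driver TF among 50 and screens for it; and simulates
two T-cell populations (one exhausted), scores the exhaustion module and
compares the co-upregulated query gene *INPP4B* between score groups.
`run1/summary.json` then reads (abridged):

```json
{
  "gad":    {"n_planted": 8, "planted_recovered": 8, "n_sig": 11,
             "cutoff": 1.119},
  "screen": {"candidates": ["TF001"], "driver": "TF001"},
  "cells":  {"mean_high": 2.508, "mean_low": 1.416,
             "n_high": 143, "n_low": 157, "p": 1.69e-16}
}
```

All 8 planted domains are recovered among the 11 called sig-GADs (the
rank-curve cutoff landed at Gs ≈ 1.12); the screen returns exactly the
planted driver; and cells with a positive exhaustion score express the
query gene much more highly (normalised mean 2.51 vs 1.42, rank-sum
p ≈ 2 × 10⁻¹⁶). Every stage writes inspectable TSVs plus a JSON manifest
recording parameters, seed and input checksums; rerunning with the same
seed reproduces every output byte for byte.

Individual stages are available as `gadpipe simulate hic|expr|sc|deg`,
`gadpipe balance`, `gadpipe gad score|call|compare`, `gadpipe screen` and
`gadpipe cells qc|score|compare`; the same functionality is importable
from the `gadpipe` package.

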
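# Methods

This note records the models the package implements, the defaults it ships,
the choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Coordinates and units

All intervals are 0-based half-open; BED files round-trip unchanged. Peak
summits come from an optional 7th BED column as an offset from the interval
start (narrowPeak convention) and default to the interval midpoint.
Tag signal is expressed in tags per 10⁷ library tags throughout, so the
activity floor of 16 normalized H3K27ac tags is well-defined regardless of
sequencing depth. Peak-to-gene distance is measured summit-to-TSS,
strand-ignored; equidistant TSSs break to the lexicographically smaller gene
id. Distal means strictly more than `distal_bp` (default 3,000) bases from
the nearest TSS.

## Replicate reproducibility

Full irreproducible-discovery-rate modelling (a copula mixture) is not
implemented; the filter is a deterministic surrogate with the same contract:
a peak counts as reproducible only if every other replicate has a peak whose
summit lies within `summit_dist` (default 100 bp) and all partners sit in
the top `rank_fraction` (default 0.9) of their replicate by signal. To make
the result invariant to replicate ordering, supported peaks from all
replicates are clustered by summit proximity (single linkage at
`summit_dist`) and each cluster merges into one peak: union interval,
score-weighted mean summit, mean score. With more than two replicates this
requires support against every other replicate, the stricter reading of
merging "all pairwise comparisons". Merged peak sets keep the maximum
constituent score (most-confident-call semantics).

## Differential count model

Counts at peak windows (or genes) are modelled as negative binomial with
Var = μ + αμ². The test is a Wald z on the log₂ ratio of condition means:

- size factors by median-of-ratios over features with all-positive counts
  (falling back to total-count ratios for degenerate matrices);
- per-feature method-of-moments dispersion from within-condition variance,
  averaged 50/50 with a fitted mean–dispersion trend α(μ) = a₀ + a₁/μ
  (the averaging is arithmetic: floor-free, so near-zero raw estimates are
  pulled up to at least half the trend rather than collapsing the variance);
- delta-method standard error of the log₂ fold change with a 0.5
  normalized-count pseudocount guarding empty conditions;
- BH correction after an independent filter that drops features with mean
  normalized count below 1 from adjustment (padj reported as missing).

This is deliberately not a DESeq2 reimplementation; the contract is
calibration and power, which the suite asserts (null rejection 0.05 ± 0.02
at n = 3 vs 3, ≥ 90% power on 4-fold effects at dispersion 0.05) alongside a
cross-check against the DESeq2 reference implementation (log₂FC correlation
> 0.99 on planted data). Verdicts use strict inequalities: up means
log₂FC > log₂(fc) and padj < α; fold-change thresholds apply to the raw
(unshrunken) estimate.

## Enhancer classification

Active enhancers are distal peaks whose mean normalized H3K27ac (±500 bp,
window 1,000) exceeds the floor in **at least one** condition — the
condition logic mirrors the expression-floor phrasing "in at least one
group". Classification is the truth table over (TF overlap ≥ 1 bp,
differential verdict); unchanged peaks are retained as `unclassified` so the
partition is exhaustive and exclusive. The stage order is fixed: distal
filter → activity floor → differential test → TF overlap.

## Super-enhancers

ROSE-style: peaks within `stitch_bp` (default 12,500; gap measured end to
start, stitched when ≤ the threshold) are stitched, stitched signal is the
sum of constituent scores, and regions rank by descending signal. The elbow
scales both axes of the ascending rank-signal curve to [0, 1] and takes the
point where a slope-1 line is tangent from below (argmin of y − x), i.e.
where the curve's slope passes 1; regions strictly above that signal are
super-enhancers. Fewer than three stitched regions, or an all-equal curve,
leaves the elbow undefined and flags nothing (with a warning). TSS exclusion
defaults to 0 and is available via gene annotations.

## Expression

TPM_g = 10⁶ · (count_g/length_g) / Σ_j (count_j/length_j) per sample. DEGs
require padj < α, |FC| > fc and group-mean log₂(TPM+1) above the floor in at
least one of the contrasted groups (floor 2 by default; 4 is appropriate for
stricter contrasts and is a parameter). Signature genes satisfy
focal mean TPM > fold × (mean of per-group mean TPMs across comparison
groups + 0.01); the 0.01 TPM pseudocount keeps genes silent elsewhere
well-defined (they are included, which is the intended marker-gene
behaviour). The comparison-group average uses per-group means, not pooled
samples, and no TPM floor is applied in the focal group. Gene-set overlap
p-values are hypergeometric upper tails against an explicitly supplied
universe — there is no default universe, which prevents silently
irreproducible p-values.

## Motifs

PWM scores are log₂ odds against the background composition; a 0.001
pseudocount is mixed into each probability cell (then renormalized) before
the log, and ambiguous bases contribute 0 bits. Log base 2 is forced by the
match-threshold semantics: 4 bits ⇔ 2⁴ = 16-fold likelihood ratio. Scanning
reports all windows on both strands strictly above threshold; per-sequence
"best score" is the maximum over windows and strands.

Known-motif enrichment compares the fraction of target sequences with ≥ 1
match to the same fraction in a background resampled to match the targets'
GC decile profile (seeded; bins with no background fall back to the
nearest-GC sequences), with a one-sided binomial upper-tail p.

Conservation: a match projects through an alignment map (strictly
increasing aligned column pairs); it is conserved iff at least half of its
positions are aligned and the partner sequence has a same-PWM match within
`tolerance` (default 3, exposed as a parameter — the width of "homologous
position" is a judgement call) of the projected start, on either strand. A
convenience local aligner (match +1, mismatch −2, gap open 5, gap extend 2)
is provided for building fixtures; real cross-species alignments are
expected as input.

Mutation association: per locus d = bestScore(positive) − bestScore
(negative); zeros are uninformative and dropped; two-sided Wilcoxon
signed-rank per motif — exact for n ≤ 25 via the signed-rank distribution
computed by convolution (identical to enumerating all 2ⁿ sign assignments;
tied midranks are doubled to stay on integers), normal approximation with
continuity and tie corrections beyond; BH across motifs. The signed summary
is sign(median d) · (−log₁₀ p): averaging on the log scale preserves
significance ordering, which is why clusters average signed log p rather
than signed raw p. Motif clusters are connected components of the graph
with edges at Pearson r > 0.6 between score-difference vectors (single
linkage — "maximum correlation larger than 0.6" read as any-pair linkage);
constant vectors have undefined correlation and become singletons with a
warning. A cluster is biologically relevant when at least one member's
cognate TF exceeds 2 TPM in the focal group; fewer than 6 informative loci
flags a motif underpowered.

## Synthetic data

Generators are pure functions of (seed, parameters) and regenerate
bit-identically. One NB noise family serves all assays, with dispersion
0.05 for ChIP/ATAC counts and 0.1 for RNA, 2-fold planted log₂ effects
(4-fold ratios), log-normal library sizes around 10⁷, and a default scale of
2 chromosomes × 10 Mb, 2,000 peaks, 5,000 genes (full pipeline well under a
minute). Peaks sit on a regular grid with one gene each, placed so that the
distal fraction is exact by construction. Signature genes are planted at a
low baseline outside the focal cell type (marker-gene regime) so the 50-fold
elevation survives TPM renormalization. The super-enhancer landscape uses
bounded typical signals below well-separated planted clusters, making exact
elbow recovery the correct answer. Strain pairs plant the causal consensus
in every positive sequence and disrupt its most informative positions in the
negative homolog with the stated mutation probability; decoy consensi are
planted identically in both homologs. Background SNPs are applied to the
negative sequence only — a simplification of real strain divergence.

What the synthetic data do **not** emulate: fragment-level read structure,
sequence-composition realism beyond GC control, peak-width and signal-shape
heterogeneity, linked variants, batch effects, or any coupling between
chromatin and expression noise. Passing the planted-recovery suites
therefore demonstrates the correctness of the decision rules and the
calibration of the tests under the stated model, not performance on real
sequencing data.

## Suite and problem sizes

The calibration suites use 2,000 features at n = 3 vs 3 for the count test
and 40 replicates × 20 motifs × 150 loci (background SNP rate 0.05, 150 bp
sequences, so most motifs have ≥ 20 informative loci and the exact test's
discreteness does not deflate the rejection rate) for the association test;
recovery suites use the default 2,000-peak / 5,000-gene scale and 100 loci
with 20 decoys. These sizes keep the whole suite fast while leaving
Monte-Carlo error comfortably inside the asserted bands. `scripts/
acceptance.py` recomputes the same quantities from scratch at a
caller-supplied seed.

## Known limitations

- The reproducibility surrogate is not an IDR estimate; its `rank_fraction`
  has no direct correspondence to an IDR cutoff.
- The Wald test is mildly anti-conservative at very small replicate numbers
  (rates up to ~0.07 at n = 3 observed), as plug-in dispersion tests are.
- Nearest-gene assignment ignores chromatin loops; peak-gene links from
  proximity ligation data would reassign a minority of enhancers.
- The enrichment binomial treats the background fraction as known; with few
  background sequences its p-values are coarse (a warning is emitted when
  the background is smaller than the target set).
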
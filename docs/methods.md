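# Methods

This note documents the models and procedures implemented in saccpop,
the defaults chosen where the design was open, and what the synthetic
cohorts do and do not establish about real data.

## Synthetic cohorts

The generator (`saccpop.synthgen`) emulates the statistical structure
of a wild/domesticated yeast resequencing panel, not its biology in
mechanistic detail. A cohort is built on a compact 8-chromosome genome
(206 kb by default, scalable) whose three smallest chromosomes are
genuinely small relative to the rest, echoing the uneven size spectrum
of a yeast karyotype; two ORFs per chromosome (≤ 1.5 kb, capped at 1/8
of the chromosome so that gene-level copy changes cannot dominate a
chromosome median) stand in for the annotated gene set.

- **Wild lineages** are haplotypes evolved from a common random
  ancestor by uniform substitution at a per-lineage rate drawn from
  U(0.001, 0.0085) per site, so pairwise divergences span up to ~1.7%
  — the maximum inter-lineage divergence scale of the species. Wild
  isolates are homozygous diploids (two copies of the lineage
  haplotype).
- **Domesticated isolates** are outcrossed F1s: two parental haplotypes
  each evolved a further d/2 from one wild lineage haplotype, with the
  target heterozygosity d ~ U(0.0005, 0.005) — matching the reported
  0.0024–0.508% range of heterozygous-site ratios. The true
  heterozygous sites are exactly the positions at which the parents
  differ.
- **Aneuploidy** affects ~30% of isolates (1–2 chromosomes each);
  the affected chromosome is drawn with probability ∝ 1/length,
  reproducing the observed enrichment of extra copies on the smallest
  chromosomes; duplication dominates (+1 at 0.80, +2 at 0.15, −1 at
  0.05), as chromosome loss is rare in real aneuploids.
- **Gene CNVs** are tandem copy factors (0, 2, or 3×) applied to the
  expected read depth over the ORF, concentrated in the domesticated
  group as in real panels.
- **Alien fragments** (2–6 kb) are copied from donor genomes evolved
  from the same ancestor at 8–35% divergence, onto both haplotypes of
  ≥ 2 carrier isolates. Donors carry taxonomy tags (congeneric vs
  outside-genus) so that classification can be scored. Sharing the
  ancestor's coordinates keeps fragments homologous to the conspecific
  reference at a known identity, which is what the scan must detect.
- **Observation model**: per-site depth ~ Poisson(mean depth × local
  copy number / basal ploidy); each read picks a haplotype uniformly
  and reports its base, with probability *e* (default 0.002) replaced
  by a base uniform over all four. Flow-cytometry D is the isolate's
  effective ploidy (copy-weighted genome size over basal) plus
  truncated Gaussian noise (sd 0.05). Depth defaults to 50×, a reduced
  but calling-adequate stand-in for the 68–439× coverages of real
  panels.

All randomness flows from one integer seed through named substreams;
identical seed and spec give byte-identical cohorts.

What the generator deliberately omits: indels and rearrangements,
read-level errors and mapping artefacts, GC and positional coverage
bias ("smiley" patterns), recombination/LOH mosaics, and allele
imbalance at heterozygous sites on aneuploid chromosomes (reads are
drawn half-and-half from the two haplotypes regardless of copy
number). Tests passing on these cohorts therefore establish the
correctness and calibration of the *procedures* under clean sampling
noise, not robustness to alignment or library artefacts.

## Genotype calling

The filter stack is applied per site: N when depth < `min_depth` (15)
or depth > `max_depth_factor` (4) × the isolate's median depth;
homozygous top allele at fraction ≥ `hom_fraction` (0.80) of reads;
heterozygous IUPAC code of the top two alleles when the second allele
reaches ≥ `het_fraction` (0.20); otherwise N. Rule order matters at the
exact 80/20 boundary: the homozygous rule fires first. Three alleles
each ≥ 20% at adequate depth indicate artefact and yield N. A 50/50
tie is heterozygous; ties in count break towards the alphabetically
earlier base, which only affects which of two equivalent IUPAC
encodings is reached (the code itself is unordered). The matrix keeps
variant sites (≥ 1 non-N call differing from the reference) with
missing fraction ≤ 10%.

Heterozygosity uses the number of callable (non-N) sites as its
denominator — the computable analogue of a consensus genome size at
desk scale.

## Diversity statistics

π and θ treat a diploid call as two allele copies (heterozygous = one
of each). A site enters a group's statistics when ≥ 80% of the group's
isolates are non-missing; the per-site sums are divided by qualifying
variant sites plus the invariant callable sites supplied by the
caller, giving genome-scale per-site quantities from a variant-only
matrix. θ uses S and the harmonic number a_{k−1} with k = 2 × group
size. Both are checked against brute-force double loops in the tests.

The polymorphism partition retains sites with ≥ 75% non-missing pooled
data, removes sites whose variant allele is carried by exactly one
isolate of the pooled pair (singletons), and classifies the rest:
shared (polymorphic in both groups), fixed (each group monomorphic for
different alleles), private (polymorphic in exactly one). `ambiguity`
mode accepts IUPAC het codes as valid data and allows > 2 alleles;
`biallelic` mode treats het codes as missing and drops multi-allelic
sites. The shared fraction is reported over all classified sites of
the pair — the denominator is this package's convention, declared
rather than inherited, since published percentages rarely state one.

## RRHS consensus phylogenetics

Each replicate resolves every heterozygous call independently and
uniformly to one of its two alleles (replicate r uses substream
(seed, r)), computes pairwise p-distances with pairwise deletion of
missing sites, and builds a neighbor-joining tree. NJ is implemented
in-package for deterministic tie-breaking (first minimum in taxon
order) and clamps negative branch lengths to zero; the replicate trees
are summarised by dendropy's split-distribution machinery — the same
summarisation as the SumTrees program — into a majority-rule (> 50%)
consensus with supports as percentages and branch lengths as means
over the replicates containing each split. The protocol accepts any
per-replicate tree builder over the same taxa; NJ was chosen because
the contribution being reproduced is the sampling-plus-consensus
protocol, not a likelihood search. Distance-matrix pathologies
(asymmetry, triangle violations) are reported by a diagnostic, never
silently repaired.

## Karyotype and gene CNV

Frame values are mean depth per 1000-bp non-overlapping frame divided
by the genome-wide median frame depth (trailing partial frames average
over their own length), making every downstream call invariant to
global depth scaling. Vo is the median frame value of a chromosome;
Va = D × (Vo − 1) with D the flow-cytometry relative DNA content
(falls back to the basal ploidy when no measurement exists).
Classification bins follow the printed rule; values in the unprinted
gaps (e.g. 0.5 < Va < 0.6) snap to the nearest boundary with an
`ambiguous` flag, and Va > 2.6 is +2 with the flag set. A chromosome
that is euploid overall but contains a run of ≥ 50 frames whose
per-frame and run-median Va reach a nonzero bin receives a partial
call of ±0.5 — the run-length criterion is this package's convention
for a case the printed rules illustrate but do not define.

Gene values are per-base medians over the ORF (each base inherits its
frame's value; even counts take the midpoint of the central pair).
Cohort tails are either the printed defaults (0.34, 0.73, 1.2, 1.74)
or fitted as the empirical 1/5/95/99 percentiles of the pooled cohort
values (`--tails fit`); fitting requires ≥ 100 values and a
non-degenerate distribution. Group differences use the Wilcoxon
rank-sum test by default (Student's t optionally) at α = 0.01; fully
tied data return P = 1.

Known limitation: median normalisation assumes most of the genome is
at basal copy number. When aneuploidy or amplification covers a large
genome fraction (possible at desk scale, rare at genome scale), the
median shifts and Vo compresses toward 1; the flow adjustment
compensates only partially.

## Introgression/HGT scan

Windows of 1000 bp slide by 500 bp (tail windows ≥ 200 bp allowed).
The identity engine anchors each window to each reference taxon by
exact 15-mer seeds (matches capped at 4 subject positions per seed,
median diagonal anchors the subject slice) and extends with edlib's
banded edit-distance alignment; identity = matched columns / aligned
columns, gaps counting as non-matches. A window with identity < 65%
and seed coverage < 30% carries no alignment signal and its identity
is set to 0 (the deletion rule). Stage 1 merges runs of windows below
95% conspecific identity into candidates spanning ≥ 1 kb; candidate
boundaries are refined below window resolution by linear interpolation
of the edge-window identity deficit against the run's deepest window —
this keeps boundary error well under one window step. Stage 2 keeps
fragments with mean conspecific identity < 93% (mean over
non-deletion windows) and length ≥ 1.5 kb, merges fragments
overlapping by ≥ 50% of the shorter across isolates into one cohort
fragment with a carrier list, and drops fragments carried by a single
isolate when shorter than 2 × 1.5 kb — the operationalisation of
removing "short" single-isolate fragments. Donor = non-conspecific
taxon with the highest mean window identity if ≥ 65%;
congeneric → introgression, outside-genus → HGT, none → unknown. The
93% cut applies to the fragment mean, not per window.

## Pipeline

`run_pipeline` composes simulate → call → stats → phylo → karyotype →
scan. The configuration is a flat structure of every named threshold
with its default; unknown keys are rejected, and the resolved
configuration, package versions and SHA-256 checksums of all outputs
are echoed into `manifest.json`, so a manifest suffices to reproduce a
run bit for bit. Problem sizes in the test suite (206 kb genomes at
depth 50, cohorts of 5–16 isolates, 10–100 RRHS replicates, 40–60 kb
scan cohorts) were chosen as the smallest scales at which the planted
effects are statistically unambiguous under the generator's noise
model.
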
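# Methods

## Scope and design

`circsponge` reimplements, at desk scale, the analysis chain that links
circular RNA expression to miRNA sponging in docetaxel-resistant breast
cancer cell models.  The package is organised as an analysis project:
numbered drivers under `analysis/` narrate the study over the library in
`src/circsponge/`, where every computation lives and is unit-tested.  All
stages operate on plain-text files (FASTA, refFlat, BED, TSV, GMT,
cytoband) and are deterministic under a fixed seed.

## Back-splice detection

A full spliced aligner is out of scope.  Detection is exact-match split
alignment: for every split point leaving ≥ `anchor_min` (default 10) nt on
each side, both segments are looked up in a k-mer-indexed genome (both
strands); a junction is called when the left read-segment maps strictly
downstream of the right one on the same chromosome and strand — the
out-of-order signature of back-splicing — and both breakpoints fall inside
one annotated gene span.  This is adequate for synthetic genomes up to a
few Mb; for real data, junction BEDs from genome-scale callers are ingested
instead (`detect.ingest_junctions`).

Decisions worth knowing:

- **"Unique" reads** are distinct read sequences per sample; duplicates
  count once.  This is the conservative reading of unique junction support.
- **Exonic-only rule:** a junction is kept iff its acceptor matches an exon
  start and its donor an exon end of the *same* transcript, within
  `boundary_tol` (default 0; the synthetic reads are exact).  Matched
  junctions are snapped to the annotated boundaries.  When several
  transcripts match, the one with the fewest exons in the run is chosen,
  ties broken by transcript id — a deterministic minimal structure.
- The raw split-alignment definition admits off-by-a-few "shifted"
  junctions when an intronic base happens to equal the exon-boundary base;
  these carry no exon-boundary match and are removed by the exonic rule, so
  the emitted call set on clean synthetic reads equals the planted set
  exactly (asserted in tests).
- An optional interval exclusion list models the rRNA pre-filter; off by
  default for synthetic data.

**SRPBM.** The normalization constant for "spliced reads per billion
mappings" is reads per billion mapped *bases*:
`SRPBM = count / (total_mapped_reads × read_length) × 1e9`.  It is
depth-invariant (scaling reads and totals together leaves it fixed) and
configurable in the reporting layer.

## Group-specific signatures

"Specifically expressed" is presence/absence at the detection level: a
circRNA is detected in a sample when it has ≥ 1 unique junction read, and
specific to a group when detection is confined to that group's 6 samples.
No abundance threshold is added.  Abundance ranking uses total SRPBM with
detection frequency (denominator: the 6 samples of the circRNA's specific
group) breaking ties, then circ id — a total order, so ranking is stable
under permutation.  The cross-background shared fraction is
`|both| / |either|` over the two backgrounds' detection sets.  The qPCR
layer implements 2^-ΔΔCt with the replicate standard error of ΔCt
propagated onto the fold-change scale.

## MRE prediction and consensus

Two deliberately independent predictors are implemented natively; the
thermodynamics engines of accessibility- or MFE-based tools are not
reimplemented — their outputs enter via TSV ingestion.

- **Seed scanner:** canonical classes against miRNA positions 2–8.  The
  site layout on the target (5'→3') is `[m8][core 7..2][A1]`; the 6mer core
  is the reverse complement of positions 2–7, extension to position 8 gives
  7mer-m8, an adenine opposite position 1 gives 7mer-A1, both give 8mer.
- **Complementarity aligner:** Smith–Waterman-style local duplex alignment
  (match +5, G:U wobble +1, mismatch −3, gap −8, seed positions 2–8 doubled
  in weight), reported above a score threshold (default 80, which admits a
  few percent background hits; ~120 is effectively background-free on
  random 21-mers).  These constants are module defaults and are not claimed
  to equal any published tool's.  The target dimension of the DP is
  vectorized with a prefix-max scan over the vertical-gap recurrence, which
  is exact (verified against a reference triple-loop implementation).

Circularity is handled by scanning the doubled sequence and deduplicating
positions modulo the length; this equals brute-force scanning of every
rotation (property-tested on sequences ≤ 200 nt).  The consensus vote is
pair-level: votes count distinct predictors reporting ≥ 1 site for a
(circRNA, miRNA) pair regardless of site positions, and pairs with
≥ `min_votes` (default 2) are kept, with tiers (=2, =3, =4) preserved for
network rendering.

## miRNA differential expression

The NB Wald pipeline is reimplemented without empirical-Bayes shrinkage:

1. **Size factors:** median-of-ratios — for features with a nonzero
   geometric mean across samples, a sample's factor is the median of
   count/geometric-mean ratios (linear-space median).
2. **Dispersion:** method of moments on normalized counts,
   `α = max(1e-8, (pooled within-group variance − mean)/mean²)`; zero-mean
   features are flagged untestable.
3. **Wald test:** `log2FC = log2(μ̂_R/μ̂_S)` with a 0.5 pseudo-count applied
   only when a group mean is exactly zero; the standard error comes from
   the NB variance `μ + αμ²` of each group mean.  The statistic is referred
   to a **t distribution with n₁+n₂−2 df** rather than the normal: with
   6-vs-6 designs the plug-in variance is noisy and the normal reference
   rejects ~8% at nominal 5%, while the t reference is calibrated (the
   acceptance suite re-measures type-I error within [0.03, 0.07] over
   200 × 500 null features).
4. **Multiplicity:** in-house BH step-up (equal to brute force and to
   statsmodels within 1e-12); all-zero features are excluded from the BH
   family.

The SDE gate is `|log2FC| > 1` and **raw** `P < 0.05` (the stated selection
rule); Q is emitted alongside for users who prefer an FDR gate.  The
comparison pools both cell backgrounds (6 resistant vs 6 sensitive); a
blocking covariate is not fitted.  Because dispersions and fold-changes are
unshrunk, agreement with shrinkage-based packages is approximate, not
exact.

## Evidence integration and enrichment

miRNA ids are matched exact-string after lowercasing and trimming the
`hsa-` prefix; arm suffixes (`-5p`/`-3p`) are always significant.  The
three-way Venn is computed over SDE, Reported (a file input; literature
mining is out of scope) and Predicted (consensus pairs); eligible is the
triple intersection, and the eligible table cross-checks each row against
the DE table (missing or non-SDE rows are integrity errors).  Pathway
enrichment uses the upper-tail hypergeometric P with k = 0 assigned P = 1;
the universe defaults to all genes in the gene-set collection (the original
analysis environment's universe is unknown), and BH runs across the tested
sets.

## CNV / multi-RNA co-location

Features (mRNA, lncRNA, circRNA, miRNA loci with up/down/group-specific
direction — DE of mRNA/lncRNA and CNV segments are input tables) are
assigned every cytoband they overlap (half-open interval arithmetic,
interval trees, equal to a quadratic oracle in tests).  A band's score is
the number of RNA classes with ≥ 1 concordantly-up feature, counted only
when the band overlaps an amplification in ≥ 1 cell line; runs of adjacent
qualifying bands merge into one region call, ranked by score then feature
count.  No formal criterion exists for a region "dominated by amplification
and overexpression"; this score is an explicit, configurable
operationalization.

## Synthetic data generator

The generator emulates the 12-sample study design (2 backgrounds × 2 groups
× 3 replicates) on a 2-chromosome, 20-gene, 300 kb genome:

| parameter | default | rationale |
|---|---|---|
| exons per gene | 4–8, 100–400 nt | circle lengths concentrate in the few-hundred-nt range typical of exonic circRNAs |
| planted circRNAs | 12 (4 resistant-specific, 4 sensitive-specific, 4 shared; ≥ 1 single-exon) | covers the specificity classes and the single-exon circle case |
| junction depth | 3–8 unique reads/sample, 15% sample dropout | clears the ≥2-reads/≥2-samples filter with realistic sparsity |
| read length / anchor | 100 nt / 10 nt | each junction read carries both anchors |
| linear background | 300 reads/sample | exercises the negative path of the detector; the real libraries' linear fraction is unknown, so this is a free parameter, not a calibration |
| miRNAs | 300, NB counts, dispersion 0.05, means 100–2000 | small-RNA-seq-like overdispersion |
| planted DE | 30 miRNAs at log2FC ±2 | strong but realistic effects |
| planted MREs | 12 sites cycling all four canonical types | full complement of miRNA positions 2..L so both native predictors fire (vote = 2) |
| eligible set | 8 miRNAs (DE ∩ Reported ∩ MRE-planted) | closed-loop recovery of the funnel's endpoint |

One global seed fans out to independent named streams (genome, circles,
reads, miRNA, MRE, fixtures), so changing one generator's request does not
shift another's draws.  Junction reads are emitted at distinct split
positions, making every read unique within its sample; a top-up pass
guarantees each planted circle is recoverable (≥ 2 samples with ≥ 2 reads)
and expressed in every group it belongs to, so dropout can never flip a
shared circle to group-specific.  After planting MRE sites, a repair pass
destroys accidental seed cores of all reported/planted miRNAs outside
planted windows; accidental cores *inside* another miRNA's planted window
are left (they yield a single-predictor vote, which the ≥2 consensus
ignores).

What the generator does **not** emulate: sequencing errors and quality
scores, paired-end reads, isoform-level linear quantification, GC or
mappability biases, and library-size imbalance beyond what read planting
induces.  Passing tests therefore demonstrate correctness of the
algorithms' logic and calibration of the statistics under clean NB/exact-
match assumptions — not robustness to alignment noise in real libraries.

## Problem sizes and runtime

The default study (300 kb genome, ~4,000 reads/sample-set, 300 miRNAs,
8 candidate circRNA sequences) runs end to end in a few seconds; the DE
calibration in the acceptance script uses 200 null replicates × 500
features (100,000 feature-tests) and 20 replicates × 20 planted-effect
features.  These sizes were chosen so the whole evidence chain, including
Monte-Carlo calibration, reruns comfortably on a laptop-class single core.

## Known limitations

- The split aligner assumes exact matches and flanking exons ≥ read length;
  it is not a general-purpose circRNA caller.
- DE statistics are unshrunk; with very few replicates or very low counts
  the MoM dispersion is noisy (the t reference compensates on average, not
  per feature).
- The aligner's scoring constants are heuristic; its default threshold
  trades a few percent background hits for sensitivity.
- Consensus is pair-level by design; site-level co-location of predictor
  hits is not required.
- The hotspot score is an operationalization; ranking near-tied regions
  depends on the configured `min_classes` and the cytoband resolution.
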
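# Methods

This note documents the statistical model, the synthetic study generator
and the numerical/design choices behind `loopscape`.

## Coordinate conventions

All internal coordinates are 0-based half-open, the BED/BEDPE native
convention; GFF3 (1-based inclusive) is converted on read so interval
length is preserved. All distances — PET spans, loop distances — are
measured midpoint-to-midpoint, which makes them independent of read
length and anchor width. Overlap anywhere in the package means ≥ 1 bp of
shared half-open span.

## PET processing

Replicates are pooled and deduplicated by exact coordinate identity of
both ends after canonical ordering (the two ends sorted by chromosome
then start); multiplicity is kept on the record. A PET whose ends lie on
one chromosome less than `min_span` = 10 kb apart is classified as
self-ligation (a fragment circularising on itself) and excluded from
loop calling; the boundary is strict, so a span of exactly 10,000 bp is
retained. Inter-chromosomal PETs are kept in a separate stratum and can
be scored for inter-chromosomal candidates, but never enter the
intra-only statistics (distances, class bins).

The window peak caller (`call_pet_peaks_simple`) exists so synthetic
end-to-end runs need no external peak caller: fixed windows (default
500 bp), per-window PET-end counts tested against a Poisson with the
genome-wide mean rate, adjacent significant windows merged, peak signal
= −log10 of the best window's p. Real-data workflows are expected to
supply peaks from a dedicated ChIP/PET peak caller through `read_peaks`.

## Loop significance model

Candidates are all peak pairs linked by ≥ 1 PET. The urn is the set of
PETs whose both ends fall inside (merged, non-overlapping) peaks:
`n_tot` counts those PETs, and `n_A` / `n_B` count PET ends assigned to
each anchor within that population — a PET with both ends in one peak
contributes two ends there and links nothing. The tail probability
`P[X ≥ x]` for `X ~ Hypergeom(n_tot, n_A, n_B)` is computed as the
survival function at `x − 1` (scipy); `x = 0` returns 1 exactly.
Benjamini–Hochberg runs genome-wide across all candidates of a
(tissue, mark) run, before mark merging. High-confidence loops satisfy
`pet_count ≥ 3` and `fdr < 0.01`.

Choices the underlying model leaves open, fixed here and configurable
where sensible:

- `n_A`/`n_B` count PET *ends*, the urn population counts PETs. Ends are
  capped at `n_tot` to keep the urn well defined in degenerate cases.
- BH is applied genome-wide, not per chromosome.
- Two mark-specific loop sets from one tissue merge when both anchor
  pairs overlap ≥ 1 bp (A-vs-A and B-vs-B); the merged record keeps the
  minimum FDR, maximum PET count and the union of mark provenance. The
  same both-anchor rule defines loop identity everywhere (mark merging,
  tissue comparison, network overlap, truth matching).
- The model is deliberately distance-free; the distance-decay background
  in the generator exists precisely to stress that assumption.

## Anchor annotation

A peak is proximal when its interval overlaps `[tss − w, tss + w)` of
any gene (`w` = 2 kb), listing all such genes; otherwise distal. DRs are
H3K27ac peaks with no TSS-window overlap. DR genomic locations follow
the precedence geneBody > downstream2kb (strand-aware 2 kb past the
TTS) > TE > intergenic; precedence between overlapping categories is a
package decision, not something the underlying classification scheme
fixes. Skipped genes of a P–D loop are genes whose TSS lies strictly
between the anchor midpoints with a TSS window clear of both anchors;
"typically expressed" means mean FPKM ≥ 1, the same threshold as the
activity call.

## Expression integration

Shannon entropy uses the relative profile `p_t = w_t / Σ w` over the
sample panel with `0·log₂0 := 0`; all-zero genes are excluded (logged),
and entropy is scale-invariant by construction. The co-expression test
takes P–P loops whose anchors each contain exactly one gene promoter
(two distinct genes), computes Pearson r across the panel, and compares
against shifted controls: each loop is shifted along its chromosome by a
uniform offset preserving anchor distance and chromosome bounds,
`n_shifts` = 100 times; a shifted loop is retained when both anchors
land on promoter windows of two different genes and both overlap a peak
whose signal reaches the 25th percentile of signals at the real anchors
(a quantitative stand-in for "similar mark level"; quantile
configurable). Observed and control r distributions are compared with a
two-sided Welch t test — the unequal-variance form, since group sizes
and spreads differ by construction.

Entropy-by-context groups genes by their distal-anchor relationships:
(i) promoters looping to gene-body (genic) distal anchors, (ii) to
intergenic distal anchors — with strata by the number of distinct
intergenic partners (1, 2, ≥ 3) — (iii) genes carrying a distal anchor
inside their own body regardless of loops, and (iv) a control of
peak-overlapped genes without intergenic-distal loops. Groups are not
exclusive; a gene may appear in several.

## Tissue comparison

Per-tissue FPKM is the mean over that tissue's replicate samples. A gene
is B-specific iff its A mean is exactly 0 and its B mean ≥ 2 (strict, as
a noise guard); the two specific sets are disjoint by construction. Loop
specificity uses the both-anchor overlap rule against the other tissue's
combined-mark set; each tissue's set partitions exactly into specific +
common. Class enrichment among specific vs common loops is tested with a
two-sided Fisher exact test on the 2×2 table.

## Networks

Anchors are nodes (peak ids), loops are edges (parallel edges allowed);
connected components with ≥ 3 edges are reported as ChINs, largest
first. Cross-tissue conservation of P–P components is the fraction of a
component's edges matched in the other tissue (both-anchor rule), with
`> 0.65` counting as conserved; a node-interval-overlap variant is
exposed as an option since the conservation metric itself is a design
choice. Term enrichment reuses the hypergeometric tail (population =
gene universe, successes = genome-wide term carriers, draws = component
genes) with BH across the terms tested per component.

## Synthetic study generator

The generator emulates the *shape* of a two-tissue histone-mark ChIA-PET
study at desk scale; defaults are the standard scenario used throughout
the tests:

| parameter | default | meaning |
|---|---|---|
| `n_chroms` × `chrom_length` | 2 × 20 Mb | genome |
| `n_genes` | 300 | genes, ≥ 10 kb apart, bodies 2.5–6 kb |
| `n_distal_peaks` | 120 | distal peaks, ≥ 2 kb from every TSS |
| `dr_location_mix` | .15/.10/.30/.45 | geneBody/downstream/TE/intergenic |
| `n_loops` | 200 | planted loops |
| `loop_class_mix` | .60/.35/.05 | P–P / P–D / D–D |
| `loop_pet_mean` | 10 | Poisson mean PETs per planted loop |
| `background_pets` | 50,000 | background budget |
| `decay_exponent` | 1.0 | background distance density ∝ d^−α |
| `self_lig_fraction` | 0.20 | short-span (< 10 kb) contamination |
| `inter_fraction` | 0.05 | cross-chromosome contamination |
| `n_samples` | 78 (53 + 25) | expression panel shape |
| `coexpression_rho` | 0.6 | planted pair correlation |
| `shared_loop_fraction` | 0.55 | within-tissue common-loop fraction |

Peak widths are log-normal around 1.5 kb (proximal) and ~1–1.2 kb
(distal), typical of histone-mark peaks and proportionate on a genome
50× smaller than a large plant genome; peaks never overlap, so peak
identity is stable through merging. Background PETs start inside a
random peak (mark enrichment) and reach a partner at a distance drawn
with density ∝ d^−α on [1 kb, chrom_length/2] in a random direction —
a deliberately adversarial background for a distance-free test, since
decay concentrates spurious links between nearby peaks. Planted loop
partners are drawn with weight ∝ 1/d among same-chromosome peaks
≥ 10 kb apart, so planted distances also decay. Self-ligation and
inter-chromosomal strata take their fractions out of the background
budget.

Expression: background genes are i.i.d. log-normal; co-expressed pairs
(gene-disjoint, from P–P loops) share a latent factor on the raw FPKM
scale, `w = 50 + 10(√ρ f + √(1−ρ) ε)`, so the expected pairwise Pearson
r equals ρ without transform distortion; tissue-specific genes are
exactly 0 in one sample group and ≥ 2 mean in the other, and every
other profile keeps a small positive floor so the strict FPKM = 0 rule
identifies exactly the planted set. The entropy contrast is planted
through distal context: own-body-distal genes get near-uniform profiles
(H ≈ log₂ 78), genic-distal partners intermediate support, intergenic
partners concentrated support that shrinks with the number of distinct
intergenic partners (hence the 1 / 2 / ≥ 3 strata trend). Genes carrying
a context profile are excluded from co-expression and tissue-specific
planting so the planted structures never overwrite one another; P–P
loops avoid own-body-gene promoters for the same reason.

In two-tissue mode, `shared_loop_fraction` is the expected fraction of
*one tissue's* loops that are common to both (matching how
tissue-specific percentages are usually reported); the share of all
planted loops that are shared is therefore s/(2−s). PET sets are drawn
independently per tissue from the same landscape.

Everything is a deterministic function of (config, seed) via one
`numpy` Generator; identical seeds give identical files byte for byte.

### What the generator does not emulate

Read-level sequence artefacts (mappability, linker chimeras, duplicate
towers), overdispersed loop counts (Poisson by default), peak-calling
uncertainty (anchors are known intervals), genome-scale interval sizes
and polyploid repeat content. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated
generative model — not that any particular biological dataset will meet
the model's assumptions.

## Problem sizes and numerical notes

The standard scenario (2 × 20 Mb, 300 genes, 200 loops, 50k background
PETs) runs the whole pipeline in a couple of seconds per seed; the
recovery check uses seeds 1–10 pooled, and the co-expression
calibration 500 null panels over a fixed loop geometry with fresh
expression and shift draws each time — sizes chosen so the whole suite
runs comfortably on a laptop. The hypergeometric tail is validated to
1e−12 against exact rational arithmetic for all populations ≤ 30 (and
against literal subset enumeration for populations ≤ 8); BH against a
textbook step-up on 1,000 random vectors; entropy bounds, closed forms
and scale invariance on 10,000 random profiles. Median loop distances in
the synthetic landscape (hundreds of kb) are larger than in dense real
genomes because peaks sit ~90 kb apart on average; distance *statistics*
are reported as computed and carry no calibration role.

## Known limitations

- The hypergeometric model ignores genomic distance; under strong decay
  backgrounds it admits some near-pair false positives (the generator's
  empirical-FDR check bounds these at the study scale but a genome-scale
  guarantee would need a distance-aware background).
- DR location precedence and the component-conservation metric are
  documented package decisions among defensible alternatives.
- The strict FPKM = 0 specificity rule is noise-sensitive on real
  quantifications; it is implemented as stated, not softened.
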
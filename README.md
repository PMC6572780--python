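# loopscape

Chromatin-interaction analysis for histone-mark ChIA-PET studies: from
mapped paired-end tags (PETs) and peak/gene annotations to high-confidence
chromatin loops, enhancer–promoter annotation, expression integration and
chromatin interaction networks (ChINs). A fully synthetic study generator
with a ground-truth manifest makes every pipeline stage testable without
any sequencing data.

## The problem

ChIA-PET enriches proximity-ligation read pairs for a chromatin mark
(e.g. H3K4me3 at active promoters, H3K27ac at putative enhancers), so
each PET is evidence that two genomic loci touch in the nucleus. Turning
raw PETs into biology requires:

1. **Loop calling.** After removing self-ligation pairs (genomic span
   < 10 kb), a peak pair (A, B) linked by `x` PETs is scored with a
   hypergeometric tail over the population of peak-assigned PETs:

   `P[X ≥ x],  X ~ Hypergeom(N = n_tot, K = n_A, n = n_B)`

   where `n_A`, `n_B` count PET ends in each anchor and `n_tot` is the
   number of PETs with both ends inside peaks. P-values are adjusted
   genome-wide with Benjamini–Hochberg; high-confidence loops require
   **≥ 3 PETs and FDR < 0.01**.
2. **Anchor annotation.** An anchor within 2 kb of a TSS is proximal (P),
   otherwise distal (D); loops fall into P–P, P–D or D–D. H3K27ac peaks
   ≥ 2 kb from every TSS are distal regulatory regions (DRs, the
   putative-enhancer class), located in gene bodies, downstream 2 kb
   windows, transposable elements or intergenic space.
3. **Expression integration.** Gene activity (FPKM ≥ 1), co-expression of
   P–P-linked promoter pairs (Pearson r against distance-preserving
   shifted control loops, two-sided Welch t test), and tissue specificity
   by Shannon entropy of the relative expression profile
   `p_t = w_t / Σ w`, `H = Σ −p_t log₂ p_t ∈ [0, log₂ N]`.
4. **Tissue comparison.** A gene is tissue-specific under a strict
   FPKM = 0 vs ≥ 2 rule; a loop is tissue-specific when no loop in the
   other tissue matches it on both anchors (≥ 1 bp reciprocal overlap).
5. **Networks.** Anchors and loops form a graph; connected components
   with ≥ 3 loops are ChINs, whose gene sets can be tested for
   annotation-term enrichment (hypergeometric + BH).

## Worked example

```python
import loopscape as ls
from loopscape.anchor_annotation import add_dr_locations
from loopscape.synthetic_data import evaluate_recovery

cfg = ls.SimConfig()                       # 2 x 20 Mb, 300 genes, 200 loops
data = ls.simulate_dataset(cfg, seed=1)

petset = ls.classify_pets(ls.pool_and_dedup([data.pets]))
print(petset.stats)

peaks = data.genome.all_peaks()
loops = ls.call_interactions(petset, peaks, mark="combined")
ann = ls.annotate_peaks(peaks, data.genome.genes)
ann = add_dr_locations(ann, peaks, data.genome.genes, data.genome.tes)
loops = ls.classify_interactions(loops, ann)
print(len(loops), {c: sum(1 for it in loops if it.cls == c)
                   for c in ("PP", "PD", "DD")})
print(evaluate_recovery(loops, data.genome, data.truth))
```

prints

```
{'total': 52112, 'unique': 52108, 'selfLigation': 19301, 'intra': 30307, 'inter': 2500}
206 {'PP': 122, 'PD': 74, 'DD': 10}
{'n_called': 206.0, 'n_planted': 200.0, 'recall': 1.0, 'empirical_fdr': 0.0291...}
```

Of 52,108 deduplicated PETs, short-span pairs are set aside as
self-ligation noise and the 30,307 intra-chromosomal PETs drive loop
calling. The caller reports 206 high-confidence loops — every one of the
200 planted loops is recovered (recall 1.0) with 6 background pairs
slipping through (empirical FDR ≈ 2.9 %, inside the 5 % the pipeline is
designed to hold). Classes split roughly 60/36/5 % across P–P/P–D/D–D,
matching the generator's planted mix.

The same objects feed the downstream analyses: `ls.coexpression_test`
(P–P co-expression vs shifted controls), `ls.entropy_by_context` (tissue
specificity by distal-anchor context), `ls.tissue_specific_interactions`
(two-tissue comparison) and `ls.build_chins` (network components).

A `loopscape` command exposes the same pipeline on files
(`simulate`, `preprocess`, `call`, `merge`, `annotate`, `expression`,
`compare`, `network`); see `loopscape --help`.

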
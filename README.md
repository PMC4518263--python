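# ernakit

Tools for genome-wide analysis of enhancer RNAs (eRNAs) and their
relationship to target-gene expression across tissues.

Enhancers are distal regulatory elements, many of which are themselves
transcribed into noncoding eRNAs. Given per-tissue enhancer–target-gene
maps, strand-aware RNA-seq contigs, gene models and expression tables,
`ernakit`:

1. **Calls enhancer transcription states.** An intergenic enhancer
   (≥ 3 kb from any gene transcript boundary) is *transcribing*
   (`eRNA`) in a tissue when some gene-free RNA contig's 5′ end falls in
   the window `[start − 3 kb, end + 3 kb)` around the enhancer locus;
   otherwise it is `no-eRNA`.
2. **Correlates eRNA and target-gene expression.** Expression is BPKM
   (bases per kilobase of region per million mapped bases). Each eRNA's
   BPKM is paired with the BPKM of a length-matched region at the target
   gene's TSS and compared, via Pearson *r*, against 1-kb flanking bins
   and two negative backgrounds (upstream of random non-target genes;
   random intergenic intervals).
3. **Compares target-gene expression by state across tissues.**
   Same-positioned enhancers (midpoints within 1 kb) targeting the same
   gene in different tissues are grouped; groups containing both states
   isolate the eRNA's presence. Per-tissue z-scores of target-gene BPKM
   are averaged by state within groups and tested with a one-sided
   paired *t*-test (and a one-sided Wilcoxon rank-sum test per tissue).
4. **Tests ncRNA-family annotation enrichment.** Covariance-model hit
   tables for eRNAs are compared per family against length-matched
   random intergenic controls with a one-sided pooled two-proportion
   z-test (significance at p < 0.001), and miRNA families are compared
   against all other families at the class level.
5. **Finds miRNA-like promoter target sites.** eRNAs carrying an exact
   miRNA mature/seed copy are scanned against sense and antisense
   promoter sequences of their target genes for canonical seed sites
   (8mer, 7mer-m8, 7mer-A1) and complementarity-scored alignment sites;
   matches with promoter sites but no 3′UTR site are retained, and
   per-eRNA significance comes from a shuffle bootstrap
   (p = (1 + #{shuffles ≥ observed}) / (1 + B)).

A synthetic-data generator (`ernakit.simulate`) produces complete
multi-tissue worlds with planted, recorded effects — transcription
states, an eRNA–target correlation ρ, a state-dependent expression shift
δ, promoter seed sites and an enriched ncRNA family — so every stage is
testable against ground truth without any external download.

## Worked example

```python
from ernakit.simulate import SimConfig
from ernakit.pipeline import run_pipeline

result = run_pipeline(SimConfig(rng_seed=1))

print(result.proportions.head(3))
#           n_eRNA  n_no_eRNA  fraction_eRNA
# tissue
# tissue00      51         77       0.398438
# tissue01      49         77       0.388889
# tissue02      58         69       0.456693

print(result.correlations.query("tissue == 'tissue00'")[["label", "n", "r"]])
#                 label    n         r
# 0         target_gene   59  0.389292
# 1          flank_0_1k  102 -0.254038
# 2          flank_1_2k  102 -0.090327
# 3          flank_2_3k  102  0.091124
# 4       gene_upstream   59  0.122074
# 5   random_intergenic   59  0.137049

print(result.paired_t)
# TestResult(statistic=8.6816..., p=1.21e-14, alternative='greater', n=120)
```

About 40 % of enhancers are called transcribing (the generator's planted
fraction). The eRNA–target-gene correlation clearly exceeds every flank
and background class (the planted ρ = 0.6 on the log scale appears
attenuated on the BPKM scale; per-tissue estimates at n ≈ 59 fluctuate
around ≈ 0.57). The paired *t*-test over the 120 cross-tissue enhancer
groups detects the planted half-standard-deviation expression shift of
genes targeted by transcribing enhancers.

The same stages are available from the shell:

```bash
ernakit simulate --seed 1 --out world/
ernakit call-erna --enhancers world/enhancers.tsv \
    --contigs world/contigs.tissue00.bed --genes world/genes.tsv --out calls.tsv
ernakit run-all --seed 1 --out results/ --plots
```

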
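# Methods

This note documents the models, rules and numerical choices behind
`ernakit`, the parameters that matter, and what the synthetic test bed
does and does not establish.

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open (BED-native); readers for
1-based dialects must convert at the boundary. A single convention
everywhere prevents off-by-one drift between stages. Gene "start or
end" always means transcript boundaries, not CDS. Sequences are stored
as DNA; RNA `U` is converted to `T` on input, so miRNA tables (RNA) and
promoters (DNA) interoperate.

## Enhancer state calling

An enhancer enters the analysis only if it is intergenic: its gap to
every gene transcript boundary is at least `margin` (default 3000 bp)
and it overlaps no gene. The boundary case is inclusive — a gap of
exactly 3000 bp qualifies; 2999 bp does not. Contigs overlapping any
gene are removed before calling, so transcription read through from
genes is never attributed to enhancers.

A contig's transcript start (5′ end) is `start` on the plus strand and
`end − 1` on the minus strand; unstranded contigs are rejected rather
than guessed, because a 5′ end is undefined without strand. The calling
window is the enhancer's boundaries extended by ±`window` (default
3000 bp), half-open like every other interval. When several contigs
qualify, the highest-BPKM contig is attached as *the* eRNA (ties broken
by leftmost 5′ start, then plus strand) — downstream correlation needs
one eRNA per enhancer — while the full qualifying list is retained. A
contig may serve several enhancers. Note the calling rule cannot
distinguish transcriptionally silent enhancers from ones expressed below
detection; `no-eRNA` means only "no qualifying contig observed".

## Expression and correlation

BPKM = covered bases / (region length / 10³) / (library size / 10⁶).
The target-gene region is matched in length to the paired eRNA, starting
at the strand-aware TSS and truncated at the transcript end. Flanking
controls are three 1-kb bins per side starting at the window boundary —
or at the eRNA's far end when the eRNA extends past the boundary — with
any gene-overlapping bin discarded. Two background classes are
constructed per eRNA–gene pair: a region of the eRNA's length
immediately 5′ of a random non-target gene's TSS, and a length-matched
interval drawn uniformly from intergenic space (genes padded by the
same 3-kb margin as enhancer filtering, for consistency). Background
sampling is seeded and iterates pairs in sorted order, so a fixed seed
reproduces the regions exactly.

Pearson *r* is tested one-sided (positive alternative) via the
*t*-transform with n − 2 degrees of freedom, matching the directional
claim that eRNA expression tracks its target gene; the two-sided test is
available by flag. Each (eRNA, target gene) pair contributes one point;
when an enhancer targets several genes each pair enters separately — a
multiplicity choice, recorded here. Pairs whose region lacks an
expression entry are dropped listwise within a class, and the per-class
n is always reported; classes with fewer than three usable pairs are
flagged undefined rather than imputed.

## Cross-tissue grouped comparison

Candidate groups are single-linkage clusters of enhancer midpoints
(link threshold 1000 bp) among all tissues' enhancers targeting one
gene. Midpoints are used because they are symmetric and insensitive to
unequal enhancer lengths; single-linkage is one defensible reading of
"within a 1000 bp window" and is recorded as a package choice, with the
group validator checking exactly this connectivity. Groups must contain
at least one transcribing and one non-transcribing member. When
surviving groups share an enhancer (via multi-target enhancers), the
largest is kept, ties resolved by a seeded uniform choice; enhancer-
disjoint groups all survive. The implementation is greedy
keep-largest-first, which is equivalent to repeatedly selecting a
maximum-size compatible group.

Expression is standardised per tissue — z-scores over the tissue's full
set of enhancer-target-gene BPKMs, sample (n − 1) standard deviation
throughout — and averaged within groups by state. The paired *t*-test is
one-sided in the direction eRNA > no-eRNA (two-sided by flag); the
per-tissue pooled comparison uses a one-sided Wilcoxon rank-sum test
with each (gene, state) counted once per tissue (configurable). The
rank-sum test uses exact enumeration for small tie-free samples (both
n ≤ 20) and the tie-corrected normal approximation otherwise. Figure
trend lines use least-rectangles (geometric-mean) regression,
slope = sign(r)·sd(y)/sd(x), which treats the two mean-z axes
symmetrically.

## Family-annotation enrichment

The covariance-model scan itself is out of scope; the module consumes a
TSV hit table (query_id, family_id, family_class, score). Each query
counts at most once per family; totals n₁/n₂ are the full numbers of
eRNAs and controls (not only annotated ones — configurable). Controls
match the eRNA count exactly and draw lengths with replacement from the
eRNA length multiset, placed uniformly in intergenic space. The
per-family test is the one-sided pooled two-proportion z-test with
significance at p < 0.001; a pooled proportion of 0 or 1 makes the
statistic undefined and is reported as degenerate with p = 0.5 (the
equality convention). The class-level comparison aggregates significant
families' hit counts and tests miRNA-class real-vs-control composition
against the other-class composition with the same z-test.

## miRNA-like target sites

A family is considered carried by an eRNA when the eRNA contains an
exact (100 % identity) copy of a mature sequence or of the 7-nt seed
(mature positions 2–8), in either orientation. Promoters are
TSS − 1000 to TSS + 200 (strand-aware) minus all other genes' transcript
spans; the 3′UTR runs from the coding end to the transcript end.

Canonical seed sites follow target-site nomenclature: 8mer = reverse
complement of the seed followed by `A`; 7mer-m8 = the same 7-mer without
the `A`; 7mer-A1 = reverse complement of seed positions 2–7 followed by
`A`, reported only when not the tail of an 8mer. The `A` is required in
the target regardless of the miRNA's first base. Antisense scanning
applies the same rules to the reverse complement with positions mapped
back; duplicate (position, type) records are collapsed. The alignment
scanner is a deliberately simple ungapped complementarity score standing
in for heuristic aligner output: +5 Watson–Crick, +1 G:U wobble, −3
mismatch, miRNA positions 2–8 weighted ×2, reported above a threshold
(default 80). The constants are declared, not claimed to match any
external program. A perfect 22-nt complement scores 145.

A (eRNA, gene, family) triple is retained iff the promoter has ≥ 1 site
and the 3′UTR has none. The bootstrap statistic is the retained-triple
count; shuffling is a uniform character permutation (a
dinucleotide-preserving Altschul–Erickson shuffle is available by
flag), and p = (1 + k)/(1 + B) with B = 100 — the add-one estimator
never returns zero and is conservative (null p-values are stochastically
≥ uniform).

## Synthetic worlds

`SimConfig` defaults define the study conditions: 12 tissues, 200
intergenic enhancer templates, erna_fraction 0.4, planted latent
correlation ρ = 0.6, planted shift δ = 0.5 (z-score units), seed-site
rate 0.3 per promoter, one enriched miRNA family class (+0.15 hit
probability) plus mildly enriched other families (+0.05) so the
class-level comparison has both classes populated.

Geometry guarantees exact recovery of planted states: genes on a regular
grid (slot = chrom_length / n_genes, minimum 18 kb) with ≥ 7 kb gaps;
one enhancer template per gap, placed so that margins, calling windows
and 3 kb of flank room never touch a gene and adjacent windows never
overlap; planted contigs (5′ start uniform in the window, lognormal
length, median ≈ 500 bp) are clipped to the gene-free gap so the
gene-overlap filter cannot remove them. Decoy contigs inside gene bodies
exercise the filters. Enhancer instances shared across tissues are
jittered ±400 bp so grouped midpoints stay within 1 kb.

Expression is bivariate lognormal on the (eRNA, target-region) pairs:
latent normals with correlation ρ, σ = 0.5, exponentiated because the
correlation stage works on raw BPKM. Exponentiation attenuates the
BPKM-scale correlation (ρ = 0.6 → r ≈ 0.57); the truth record stores
both latent and realized values. Gene-level BPKM for the cross-tissue
stage is normal (mean 10, sd 1, truncated at 0.01) with +δ·sd added
when any transcribing enhancer targets the gene in that tissue — the
planted shift is defined on the z-score scale. Flanks and backgrounds
receive independent lognormal values.

What the generator does *not* emulate: read-level noise and coverage
estimation (BPKM values are drawn, not computed from alignments),
realistic gene density or enhancer clustering, sequence composition
biases (promoters are uniform random, so canonical 7-mers occur at the
uniform background rate), and real covariance-model score
distributions. Passing tests therefore demonstrate correctness of the
rules and statistics and recoverability of planted effects under
idealised geometry — not performance on real genomes.

## Problem sizes and tolerances

The test suite uses single-tissue worlds of 200–625 enhancers for the
oracle-equivalence and recovery studies (1000 worlds for state calling;
200 replicates at ≈ 500 pairs for correlation recovery; 100 replicates
at ≈ 300 pairs for the profile-ordering property), 2000 simulated group
sets for t-test calibration and 100 × 200-family null runs for the
enrichment false-positive rate; these sizes give the stated Monte-Carlo
bounds comfortable margins while keeping the default run fast. Numerical
agreement with closed forms is asserted at 1e-12 (relative) for BPKM and
1e-9 for the pooled z-statistic; scanner oracles are exact. All
randomness flows from explicit integer seeds; identical seeds give
byte-identical outputs end to end.

## Known limitations

- The calling rule is purely positional; it cannot separate silent from
  lowly expressed enhancers, and contig reuse across enhancers is
  allowed.
- Single-linkage grouping can, in principle, chain midpoints beyond
  1 kb diameter; on realistic (and generated) data clusters are tight,
  but the behaviour is a definitional choice, not the only one.
- The alignment scorer is ungapped with fixed weights; no
  thermodynamics, conservation or context scores.
- The mononucleotide shuffle ignores dinucleotide composition unless
  the preserving shuffle is requested; for uniform-random synthetic
  sequences the two coincide in distribution.
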
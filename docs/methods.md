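# Methods

## The measurement model

A pooled complementation screen measures, per barcoded fragment, read
counts in a t0 (post-transformation, pre-selection) sample and in one
or more selected samples.  Fitness is the normalized log2 change in
relative abundance,

    f = log2((n_sel + p)/(N_sel + pB)) − log2((n_t0 + p)/(N_t0 + pB)),

with pseudocount p = 0.5 reads per barcode and pB added to the totals
(B = number of barcodes).  This keeps f finite at zero counts while
converging to exact scaling invariance as counts grow; at p = 0 the
statistic is exactly invariant to rescaling either sample.
Normalization is by total reads, not median centering: after a
selection that kills most of the library, the median barcode is dead
and median-centering would be degenerate.

The accompanying statistic is a delta-method z under Poisson count
noise on the log2 scale,

    z = f / se,   se = (1/ln 2) · sqrt(1/(n_sel + p) + 1/(n_t0 + p)).

No closed-form z is canonical for this assay; we chose the simplest
form that is (i) monotone in the evidence, (ii) approximately standard
normal under the null at moderate counts, and (iii) cheap.  Calibration
is by simulation: with no enrichment at depth 1e5 over 1e5 barcodes,
the joint rate P(f > 5 and z > 4) is far below 1e-3 per barcode
(`tests/test_acceptance.py`), and for paired Poisson(50) counts
P(z > 4) ≤ 1e-3.

## Hit calling

A fragment is significant in an experiment when f > 5 **and** z > 4
(strict inequalities).  Magnitude alone is not enough because scraping
plates collects a small amount of mass from "faint colonies" that grow
on agar impurities; the joint cutoff is what makes that background
ignorable.  Significant fragments become high-confidence hits when
either (1) an overlapping fragment (same source genome, ≥ 1 shared bp)
was significant in the same experiment, or (2) the same fragment was
significant in a second experiment of the same mutant background —
different inducer levels count as different experiments.  Overlap and
merging are background-specific: hits in different knockouts never
merge.

High-confidence inserts are merged into regions as connected components
of the interval-overlap graph (sort-and-sweep; verified against a
transitive-closure oracle).  Each region is associated with the genes
fully contained in its best insert — the member with the highest mean
fitness across that background's experiments, ties broken by longer
insert then lexicographic barcode (determinism; the choice is otherwise
arbitrary).  Genes covered ≥ 90% including the position of the start
codon are reported in a separate "nearly full length" column and do not
enter the one-ORF/multi-ORF/no-full-ORF classification; 90% is our
choice for "nearly".

## Expected-hit recovery

Recovery statuses are always computed, never supplied: a protein is
recovered when a high-confidence insert of the right background fully
(or nearly, as above) contains its gene.  Orientation analysis is per
insert, not per gene, since one gene can ride many inserts; success
rates carry exact central Clopper–Pearson intervals (90% by default —
the conservative reading of an unspecified "binomial" interval).
Covariates: GC content of the insert sequence; the codon adaptation
index as the geometric mean of per-codon relative adaptiveness w
against the Sharp–Li table of codon usage in highly expressed *E. coli*
genes (shipped as `data/ecoli_sharp_li_w.tsv`; stop codons and the
single-codon families ATG/TGG excluded; a terminal stop ignored;
internal stops skipped with a warning; w floored at 0.01 only for
codons absent from the reference); and the fraction of codons from the
eight classically rare *E. coli* codons (ATA, CGG, CGA, CTA, AGA, AGG,
GGA, CCC) among non-stop codons.  Group comparisons use the two-sided
Wilcoxon rank-sum test; per-library RBS-strength means additionally get
a Welch t test with Bonferroni correction for the number of libraries.
RBS strength itself is an optional external input column, never
computed here.

## BarSeq counting

Barcodes are the 20-mers between exact matches of the primer-defined
flanks (`...CGTACG` upstream, `AGAGACCTCGTGGACATC` downstream).  Reads
are rejected — and tallied, so reads are conserved — for missing
flanks, wrong barcode length, an N, or any barcode base below the
quality floor (0 when counting for fitness, 30 when estimating library
diversity).  Under Q ≥ 30 the per-base error ceiling is 1e-3, so a
barcode is wrong with probability at most 20 × 0.001 = 2% (union
bound); the read simulator reproduces the exact value 1 − 0.999^20 ≈
1.98%.  Barcodes at Hamming distance 1 from a strictly more common
barcode are eliminated and their reads discarded, not reassigned
(reassignment would inflate the neighbour); ties keep both.  Decisions
are taken against the input counts, which makes the operation
idempotent and order-independent.

## The synthetic screen

The generator emulates the data-generating process the analysis
assumes, with defaults encoding the study conditions:

| parameter | default | meaning |
|---|---|---|
| fragment_mean / sd | 3000 / 800 nt | sonication target |
| fragment_window | 1500–5000 nt | gel excision window (truncated normal) |
| t0_lognormal_sigma | 1.0 | spread of starting abundances |
| t0_dropout | 0.13 | fraction lost at transformation (≈ 20/152) |
| p_sense / p_antisense | 0.66 / 0.35 | colony-success probability by orientation |
| enrichment_log2 | 10 | winner mass multiplier |
| background_mass | 1e-4 | "faint colony" share of post-selection mass |
| read_error_rate | 0.001 | per-base substitution rate |

Genomes are random sequence at a configurable GC fraction with
non-overlapping genes written as proper ORFs (ATG, stop-free body with
GC-biased codons, terminal stop), so CDS covariates are well defined.
Selection is all-or-nothing per clone: a barcode whose fragment carries
a full-length complementing gene and that survives to t0 wins a
Bernoulli draw at p_sense or p_antisense depending on its orientation
to the synthetic promoter; winners then hold 1 − background_mass of the
post-selection mass in proportion to their t0 abundance, and all
non-winners share background_mass.  Reads are multinomial at the
configured depth.  Antisense expression (internal promoters) has no
quantitative model; p_antisense is a phenomenological constant.

A consequence of winner-take-mass selection worth knowing: once any
winner exists, a winner's fitness is ≈ log2((1 − bg)/W) where W is the
winners' collective share of t0 mass — the enrichment multiplier
cancels.  Fitness magnitudes therefore reflect how rare complementing
fragments are in the library, exactly as in a real screen; the test
suite checks this closed form rather than the multiplier.  Liquid
-culture jackpot dynamics, cross-feeding, and PacBio read simulation are
out of scope.

One RNG stream per operation, seeded from (seed, fixed offset), keeps
partial re-runs reproducible.

## Problem sizes

Analysis scripts and whole-pipeline tests run desk-scale screens chosen
to keep every regime well populated: 400 kb genomes with 60 genes,
2,000-fragment libraries for exactness checks (winner t0 share ≈ 0.5%,
winner fitness ≈ 7–8, comfortably above the cutoff), 25,000-fragment
libraries with 6 complementing genes (≥ 500 carrier fragments) for
orientation-rate recovery, and 1e5 barcodes at depth 1e5 for null
calibration.  These sizes are the package's own choices for stable
statistics at interactive runtimes.

## What passing tests do and do not show

The generator reproduces the statistical structure the analysis relies
on — log-normal abundances, dropout, all-or-nothing enrichment,
orientation asymmetry, background mass, sequencing error — but not
genome-scale gene density, multi-genome mixed libraries, homologous
regions across genomes, PCR jackpots, or index hopping.  Exact recovery
under noise-free settings and calibrated rates under the defaults
validate the pipeline's logic and thresholds, not the biology of any
particular screen.  Known limitations: origin-spanning fragments of
circular genomes are rejected on input; overlap confirmation requires
the same source genome, so homologous inserts from different genomes
never confirm each other; no gene-level fitness aggregation or
empirical-Bayes shrinkage.
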
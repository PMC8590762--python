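# Methods

This note documents the models, parameters, and design choices behind
`asmeval`, and what the built-in simulation benchmark does and does not
demonstrate.

## Error model and detection

### Structural errors (≥ 50 bp)

Read-to-contig alignments carry four signal types:

| signal | alignment feature | interpretation |
|---|---|---|
| expansion | ≥ 50 bp deletion op in a read's CIGAR, or a contig-coordinate gap between consecutive same-strand split segments | contig contains sequence absent from the genome |
| collapse | ≥ 50 bp insertion op, or a read-coordinate surplus between split segments | contig is missing genome sequence |
| inversion | strand-flipped block among a read's split segments | contig segment is reverse-complemented |
| haplotype switch | expansion cluster overlapping a collapse cluster | contig matches neither haplotype at a heterozygous SV |

Signals are clustered greedily per type along each contig. A signal joins
the open cluster when it lies within `max(base_window, repeat_tolerance_factor ×
cluster median size)` of the cluster's rightmost member (`base_window` 500 bp,
factor 2.0). The adaptive term is our instantiation of repeat-tolerant
clustering: breakpoint scatter caused by repeats grows with event size, so
the tolerance scales with the cluster's size estimate while unambiguous
loci keep the tight 500 bp window. Each read contributes at most once to a
cluster's support.

Filtering retains clusters with

* `n_support ≥ 3` distinct reads;
* error-supporting read ratio `n_support / local_depth ≥ 0.75`, where
  `local_depth` is mean coverage over the cluster ± 50 bp. Heterozygous
  variants are supported by one haplotype (ratio ≈ 0.5) while true errors
  approach 1.0. The 0.75 default is chosen from the binomial tail of the
  heterozygous case at typical 50× coverage: P(Binom(n≈50, ½) ≥ 0.75·n) ≈
  3·10⁻⁴ per heterozygous SV, small enough that a tenfold excess of SVs
  over true errors costs well under 1% precision, while measured support
  ratios of genuine spiked errors stay above 0.85. The cutoff is an
  exposed flag (`--ratio-cutoff`).
* `local_depth ≤ 3 ×` assembly mean depth (collapsed-repeat pileups are
  unreliable);
* mean mapping quality ≥ 20.

Haplotype-switch merging runs *before* the ratio filter: each side alone
looks heterozygous (≈ 50% support), but the union of the expansion-side and
collapse-side reads approaches 100%, which is exactly what distinguishes a
switch from an ordinary heterozygous SV. The switch's support ratio uses
the union of both sides' reads.

### Small-scale errors (< 50 bp)

A whole-contig pileup counts, per position: spanning reads (`n_reads`,
including reads whose alignment deletes the column), mismatch counts per
alternative base, insertion events per anchor (attributed to the position
preceding the inserted sequence, grouped by inserted allele), and deleting
reads per column. Only spanning reads are binomial trials; clipped-out
reads carry no evidence. Positions with fewer than 5 spanning reads are
uncallable. The most-supported alternative event per column becomes a
candidate when its support reaches 20% of spanning reads (boundary
inclusive). The one-tailed binomial p-value `P(X ≥ n_supp | n_reads, p)`
is computed exactly (regularised incomplete beta); candidates pass at
`p = 0.5, α = 0.01` for HiFi and `p = 0.4, α = 0.05` for CLR/Nanopore —
the lower null probability absorbs the chance that a 15–20% per-base error
rate destroys an error-supporting observation. Runs of adjacent
deletion-supported columns merge into a single expansion record spanning
the run. Small-scale calls inside reported structural error spans are
suppressed (same underlying event at base resolution).

The pileup accumulator is a compiled (numba) CIGAR walk — a 50× CLR
alignment of a 5-Mb assembly contains ~70 M CIGAR operations — and is
verified base-for-base against a plain-Python pileup in the test suite.

### Quality value

`N_Err = N_Exp + N_Col + N_Her + N_Small + n_Inv` where expansions and
collapses contribute their size, a haplotype switch contributes the larger
of its two affected spans (its two-sided nature makes a single "affected
bases" number ambiguous; we take the conservative maximum and record both
sides), small-scale errors contribute their affected bases, and each
inversion contributes exactly 1 (its bases are present, only their
orientation is wrong). `E = N_Err / N_asm`, `QV = −10·log10 E`. A
zero-error evaluation reports a lower bound computed from a pseudo-count
of 0.5 errors and is printed with a `≥` marker rather than an infinite QV.

## Correction

Small-scale errors are corrected by substituting the majority read allele
(insertions after the anchor column, deletions by removing the flagged
span); conflicting calls at one position keep the lower p-value. Each
structural error is corrected by local reassembly: reads anchored across
the locus ± 5 kb flank are collected (for haplotype switches, only reads
carrying the majority side's signal, so the consensus reconstructs a
single haplotype; reads must span both flanks, which keeps the read set
inside the current repeat unit), clipped to the window, and collapsed to a
consensus. The built-in engine is a greedy star alignment: the longest
read is the backbone, every other read is infix-aligned to it with edlib,
and a column-majority vote (including insertion junctions) yields the
consensus. Any callable can be plugged in instead, e.g. an external
assembler adapter. The consensus must anchor on both 500 bp flank anchors
of the original contig (≤ 25% anchor divergence) or the error is declared
uncorrectable and retained in the report — never silently dropped.
The 5 kb flank anchors the consensus uniquely outside most repeat
contexts while keeping the local read set small; it is an exposed flag.

## Reference-based mode

Contigs are aligned to a user-supplied reference with minimap2's `asm5`
preset. Aligned blocks give NA50 (N50 over aligned block lengths with the
half-total taken from the *full* assembly length, so NA50 ≤ N50), contig
mapping rate (union of aligned contig bases / assembly bases), and genome
coverage (reference bases covered ≥ 1×). Error coordinates are projected
through match columns only; positions inside alignment indels inherit the
nearest match to the left and are flagged approximate, and errors in
unaligned regions are flagged unprojectable. Contig-to-reference
differences conflate assembly errors with genetic variants, so this mode
projects and summarises — it never calls errors.

## Simulation benchmark

The generator emulates a realistic diploid evaluation scenario at desk
scale. Defaults (one replicate):

| parameter | default | rationale |
|---|---|---|
| genome | 5 Mb uniform-random diploid | desk-scale replica |
| SNPs | 1,600 (3.2·10⁻⁴/bp) | human-scale SNP heterozygosity (~1 variant per 3 kb) |
| SVs | 200 insertions/deletions, geometric-like sizes ≥ 50 bp (mean ≈ 300, cap 5 kb) | keeps SVs ~10× more abundant than true structural errors — the regime a variant-aware detector must survive |
| het fraction | 0.67 (exactly round(0.67·n) het, assigned by seeded shuffle; het alleles on one haplotype) | typical het/hom split of an outbred diploid genome |
| structural errors | 9 expansions + 9 collapses + 2 haplotype switches (+0 inversions), ≥ 2 kb apart | an expansion/collapse-dominated mix with a minority of switches; a strict per-bp scaling of genome-wide error counts (≈6.5·10⁻⁷/bp) would yield ~3 events per replicate, too few to estimate recall or represent the composition |
| small-scale errors | 950 (1.9·10⁻⁴/bp): 50% substitutions, 25% 1-bp expansions, 25% 1-bp collapses | consensus-error load typical of a long-read assembly before polishing |
| haplotype switches | spiked at heterozygous insertions ≥ 120 bp carried by haplotype 1: the assembly keeps only half the inserted allele, so it matches neither haplotype | co-placement is required by the definition of a switch |
| reads | 50×, lengths ~N(15000, 3000²) truncated at 1 kb, split evenly across haplotypes, random strand | typical long-read library profile |
| read errors | i.i.d. per base; HiFi 2% (60/20/20 sub/ins/del), CLR 15% (10/60/30) | fixed per-read rate by design; the CLR mix follows the indel-rich PacBio profile, HiFi leans to substitutions |

A haploid benchmark uses a single haplotype with homozygous-only variants.
Scoring matches calls to truth one-to-one, greedily by distance:
structural pairs must agree in kind (haplotype switches match expansions,
collapses and switches at their locus), lie within 500 bp, and agree in
size within a 0.5 reciprocal tolerance (waived for switches); small-scale
pairs must agree in kind within ±5 bp — the window absorbs aligner
left-shifting of 1-bp indels inside homopolymer runs, where the spiked
coordinate and the alignment-normalised coordinate legitimately differ.
Both windows are exposed flags and are echoed in the benchmark output.

### What the benchmark does and does not show

The simulation captures the statistical structure that the detectors rely
on — diploid support ratios, sequencing-noise floors, indel-rich vs
substitution-rich error profiles, SVs outnumbering true errors ten to
one — so passing it demonstrates correct signal extraction, clustering,
haplotype-aware filtering and binomial testing at realistic depths.
It does **not** emulate: long tandem/segmental repeats of real genomes
(uniform-random sequence is essentially repeat-free, so mapping-quality
and adaptive-window behaviour in repeats is exercised only lightly),
PBSIM-style context-dependent error clustering and per-read quality
variation (our i.i.d. error model makes read support for true small
errors slightly cleaner than real CLR data, so measured CLR small-scale
recall in the high 80s should be read as an upper end for such data),
GC bias, chimeric reads, and coverage waves. Conclusions about real-data
recall should be calibrated accordingly.

### Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the scaled benchmark at
5 Mb × 50× with three seeds per diploid read class plus one haploid
replicate, and a correction round on a 2-Mb replicate — sizes chosen so a
full validation completes in minutes on a single CPU while keeping ≥ 60
structural and ~2,850 small-scale truth events per read class behind the
aggregate metrics.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; writers convert (VCF is
  1-based).
* N50 uses an inclusive half-total boundary (ties report the smaller
  contig at exactly 50%).
* The binomial tail uses `scipy`'s regularised incomplete beta, exact to
  ~1e-15 and verified against enumeration for n ≤ 12.
* `n_supp = 0` returns p-value 1.0; empty call sets give NaN precision and
  F1 = 0.
* Contigs with zero coverage produce no calls; positions below 5 spanning
  reads are uncallable rather than trusted.
* Clustering ties (a signal exactly at the window edge) join the open
  cluster; candidate-event ties prefer substitution, then insertion, then
  deletion; haplotype-switch merging consumes the nearest collapse by
  midpoint; switch-side ties during correction pick the expansion side.
* Secondary alignments are excluded everywhere; supplementary alignments
  count for depth, splitting rate and structural signals but a read is
  counted once however many segments it has.
* Simulation is a pure function of (config, seed): identical seeds give
  byte-identical genomes, assemblies and read files.

## Known limitations

* Inversion signal attribution assumes the inverted block is shorter than
  the read-level flanking evidence; inversions much longer than the read
  length are reported from breakpoint pairs with less precise spans.
* Small-scale insertion alleles longer than 1 bp are reconstructed from
  the majority first base and mean length, an approximation that is exact
  for the dominant 1-bp case.
* Ploidy > 2 is out of scope; the support-ratio filter assumes at most
  two haplotypes.
* The built-in star-alignment consensus is adequate for ≤ ~20 kb loci at
  moderate depth; very large or highly repetitive loci are better served
  by plugging in a dedicated local assembler.
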
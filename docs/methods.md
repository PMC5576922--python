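# Methods

This note documents the models, rules and numerical choices behind
spacerscope, what the synthetic-data generators do and do not emulate, and
the design decisions taken where the underlying procedures left room.

## Coordinates, randomness, matching

All internal coordinates are 0-based half-open; GFF3 and the VCF-like
variant tables convert to 1-based inclusive at the file boundary. Every
stochastic stage draws from a generator derived from the run seed and the
stage name (`stage_rng`), so results are reproducible regardless of stage
execution order, and two runs with the same config are byte-identical.

Spacer/protospacer matching is Hamming-only: every described match is a
length-preserving 32-mer, so indel-tolerant alignment would only add
ambiguity. `N` never matches any base, including another `N` — mismatch
counts are conservative. Ties in best-hit selection resolve to the fewest
mismatches, then the + strand, then the leftmost coordinate; each acquired
spacer has one true source, so one best hit is reported and multi-mapping
is only logged.

## Strand-bias statistic

A mapped spacer is sense when its strand equals that of the overlapping
gene, antisense when opposite, and unassigned when no gene covers at least
50% of the spacer (the partial-overlap threshold is a package choice; the
boundary sits at exactly half the spacer length). The sense fraction is
computed over **all** spacers, unassigned included: that denominator is
what makes the no-bias expectation (1 − d)/2 = 44.3% at intergenic
fraction d = 0.114, rather than 50%. Group comparison uses Welch's
(unequal-variance) two-sided t-test on per-sample sense fractions; SEM is
the across-sample standard error.

## SUS expression null

`sus_sample` implements stochastic universal sampling: one uniform offset
in [0, W/n) and n pointers spaced W/n apart over the cumulative weight
line. Each gene's count is the floor or ceiling of n·w_i/W, hence exact
counts for integer expectations and per-gene variance strictly below the
multinomial equivalent. The null envelope draws `sus_trials` (default
1000) samples of `sus_sample_size` (default 500) spacers weighted by gene
length, accumulates cumulative spacer fractions along the
descending-expression gene order (expression ties broken by gene id), and
takes the pointwise min/max — an exact range; a quantile band is available
via the `quantile` argument. Whether the x-axis is gene rank or cumulative
expression mass is presentation only; the per-rank table supports both.

Because SUS is deliberately low-variance, a *single* observed sample of a
few hundred spacers fluctuates more than the envelope is wide; envelope
comparisons are meaningful for observed profiles pooled to a few thousand
spacers, which is how the tests exercise them.

## Small-RNA read classification

The trimming rule follows the assay: the anchor is the first (leftmost)
exact occurrence of the repeat's first 5 bases; the read prefix before it
is the trimmed read. An empty trimmed prefix counts as a repeat substring
(pure-repeat reads carry no spacer evidence). Trimmed reads shorter than
12 nt are accepted only if their last 5 nt equal the last 5 nt of a
genomic spacer. Matching is exact throughout — anchors, repeat substrings
and the 5-nt junction — and reads are searched on the given strand only,
because the library protocol preserves strand. Only literal repeat
substrings are accepted; rotations spanning the spacer–repeat junction are
not.

The dominant 3′-end offset is the modal (trimmed length − spacer length)
over trimmed reads whose last 5 nt match a spacer 3′ end; with the 8-nt
repeat-derived handle this is 8, i.e. cleavage 8 nt upstream of the repeat
3′ end. Histogram counts are normalized to the most abundant tRNA
reference (reads counting toward a tRNA when they are exact substrings of
it). `processing_detected` calls processing when the modal bin is ≥ 5-fold
enriched (tRNA-normalized) over the matched control — the assay's
"efficient processing" is not quantified anywhere, so the threshold is a
config default, and identical or jointly processed profiles yield False.

## Protospacer annotation and competence

The PAM is read as the 2 bases immediately 5′ of the protospacer on the
protospacer-carrying strand (`five_prime_of_protospacer`, the default; the
convention is explicit and switchable because the underlying figures show
PAM positions only graphically). Mismatch positions are 1-based from the
PAM-proximal end; the seed region is positions 1–8, following the type
I-F seed literature, and is configurable. The self/non-self check compares
the `handle_len` (8) bases adjacent to the crRNA 5′-handle position —
immediately 5′ of the protospacer on its strand — with the repeat's last 8
bases; full identity is required for "self" by default, since the
repeat-flanked constructs that motivated the rule used complete repeats.
Whether partial flank complementarity (< 8/8) still suppresses type III-B
targeting is untested; the threshold is exposed.

Competence rules: type I-F fires iff the PAM is canonical (GG), no seed
mismatch, and total mismatches ≤ 5 — transcription-independent, so
orientation-invariant. Type III-B fires iff the protospacer is antisense
to the overlapping transcript (crRNA complementary to mRNA) and the flank
is non-self — PAM-irrelevant, so reversing the orientation abolishes it.
Phage genomes without annotation fall back to a minimal 6-frame ATG-to-stop
ORF caller (≥ 150 nt).

## Variant calling and escape classes

`diff_genomes` assumes collinear assemblies. K-mers unique in both genomes
(k = 21) are chained by longest increasing subsequence; out-of-order
anchors raise a rearrangement flag with partial results. Chained anchors
merge into contiguously covered constant-offset blocks; inter-anchor gaps
are resolved by global (Needleman–Wunsch) alignment via edlib, with pure
insertions/deletions called directly. Indels are left-normalized to their
canonical leftmost placement (the generators normalize their truth tables
identically, so representations are comparable), a multi-base contiguous
event counts as one site, and deletions ≥ 50 bp are reported as structural
(the 50-bp indel/structural cutoff is a package choice; the source data
distinguish the classes without defining one).

Escape classification is priority-ordered per protospacer: deletion
spanning the whole protospacer, PAM mutation, seed substitution, seed
frameshift (indel at seed positions), other in-protospacer change, none.
PAM positions are included although the upstream tabulation lists
protospacer-region mutations, because PAM escape is the central mechanism
under study. When the reference sequence is supplied, an indel inside
repeated sequence is tested against *every* equivalent placement, not just
its left-aligned one — otherwise a seed-adjacent homopolymer insertion
could be misfiled.

In-silico PCR uses exact primer matching (the diagnostic primers are exact
sequences); both primer orientations are tried and product length includes
both primers. Protein comparison uses a BLOSUM62 global alignment with
free end gaps (open −11 / extend −1); identity and similarity are over
alignment columns, and C-terminal loss is the count of reference residues
beyond the last one aligned to a non-gap.

## Assay quantification

MPN titers maximize the Poisson single-hit likelihood directly (bounded
1-D search on log10 c, tolerance 1e-10) rather than using historical
lookup tables. All-negative series return 0 censored at the detection
limit; all-positive series return a lower bound — the concentration at
which an all-positive outcome at the most dilute level has probability
one half. Censoring (including the TMTC plate sentinel) is carried as
explicit flags, never dropped. The log-ratio transcript metric
log10(RNA)/log10(DNA) requires both counts ≥ 10 (the floor guards the log
of small counts; no floor is stated upstream) and is documented as
scale-dependent: it compares constructs within an experiment and is not a
per-cell transcript-to-template ratio.

## Synthetic data: what it emulates, what it does not

`generate_host` builds a genome whose annotated-gene fraction matches the
request exactly by construction (default 88.6%), with non-overlapping
genes on both strands, log-normal expression (μ = 2, σ = 1 in natural-log
units — a broad right-skewed distribution typical of bacterial
transcriptomes), and repeat–spacer arrays embedded in intergenic space.
The two array repeats are random sequences constrained to < 60% mutual
identity, mirroring the sparse similarity of type I-F and type III-B
repeats. Spacers are additionally constrained so the repeat's 5-base
anchor prefix cannot occur upstream of its true position in a mature read
— on clean reads the trimming rule is then exact, which is what "noiseless"
means here.

`simulate_acquired_spacers` draws intergenic spacers with probability
equal to the intergenic base fraction (strandless, unassignable) — the
modeling choice that makes the 44.3% null emerge naturally — and otherwise
picks a source gene weighted by length × expression^α (RNA, α = 1 default)
or length alone (DNA), emitting the spacer antisense with probability
`antisense_bias` (RNA) or 0.5 (DNA). The pipeline's default antisense bias
is 0.65, a moderate bias; active type III-B interference is modeled as
post-hoc purging of antisense host-derived spacers with survival
probability 0.05 — the simplest mechanism reproducing the autoimmune
selection signal, a model rather than a measured rate.

`simulate_crrna_reads` emits mature reads as handle(8) + spacer +
next-repeat prefix stub. The stub length is uniform on 5..8 nt by default:
the 3′-end heterogeneity of mature crRNAs is not quantified anywhere, and
stubs shorter than the 5-nt anchor are unclassifiable by the trimming rule,
so the default keeps every mature read classifiable; the range is
configurable down to 1. Background reads are tRNA fragments (the first
tRNA given is the designated most-abundant species) plus random fragments.

`generate_phage` plants each protospacer inside its own +-strand ORF with
the requested orientation, PAM, mismatch load (seed mismatches forced into
positions 1–8), and flank mode; `repeat` flanks copy the repeat's last 8
bases (making the planted PAM the repeat's last 2 bases). `mutate_phage`
applies non-overlapping SNVs, short indels and large deletions and returns
left-normalized truth calls.

Not emulated: sequencing errors, quality scores, paired-end structure,
PCR bias, realistic phage gene content, codon structure in host genes.
Passing tests therefore demonstrate correctness of the statistics and
classification rules on clean data with known truth — not robustness to
platform noise, which real libraries would add on top.

The susceptibility simulation in the escape study converts competence
calls into log10 titer reductions (type I-F 1.7, type III-B 3.0 when at
least one protospacer is competent for that system) and estimates titers
through simulated MPN series. These constants echo the reported ~50-fold
and >1000-fold magnitudes but are model parameters; only the qualitative
ordering WT < ΔI-F Cas123 < ΔIII-B < ΔI-FΔIII-B is asserted, since
plaque-level magnitudes are not reproducible from desk-scale simulation.

## Problem sizes

Defaults used by the tests and the acceptance script: 100-kb hosts with
100 genes and two 8-spacer arrays; 40-kb phages; 500-spacer samples (100
samples for the null self-consistency check); SUS envelopes of 1000 trials
(reduced to 100–200 in pipeline tests); 500 mature reads for the
classifier check; 20 random 5-kb genomes for the scan oracle; 500
simulated 3×3 dilution series for the MPN bias. These sizes keep every
check well-powered while the full suite runs in well under a minute.

## Known limitations

- `diff_genomes` targets near-identical collinear genomes; rearrangements
  are flagged, not resolved, and highly repetitive genomes starve the
  unique-k-mer anchoring.
- The ORF caller is deliberately minimal (no RBS model, no overlapping
  gene resolution) — supply a GFF3 when real annotation exists.
- Exact-match classification (anchors, junctions, primers, tRNA counting)
  is faithful to the described assays but brittle to sequencing errors; a
  mismatch allowance exists in config but is off by default.
- The MPN lower bound for all-positive series is a convention (50%
  all-positive probability at the most dilute level), not an ML estimate,
  which does not exist in that case.
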
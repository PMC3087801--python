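# Methods

## Scope and model

`gbskit` works with reduced-representation libraries built by digesting
genomic DNA with ApeKI (recognition GCWGC, cut G^CWGC, 3-base 5′
overhang CWG) and ligating a barcoded adapter and a common adapter to
the sticky ends.  Sequencing 86 bp off the barcode adapter yields reads
of the form

    barcode (4–8 bp) · CWGC remnant · fragment sequence · [CWG · common adapter …]

where the bracketed part appears only when the fragment is shorter than
the read.  The marker unit is the *64-base tag*: the read content after
barcode removal, truncated/filled to exactly 64 bases.  Tags are exact
strings — no alignment, clustering or mismatch tolerance anywhere in the
pipeline — which is what makes the method tractable in high-diversity
genomes where reference alignment is unreliable.

## Coordinate and tag conventions

Coordinates are 0-based, half-open.  A cut at recognition start `s`
splits at `s + 1`; digest fragments tile their source exactly.  For an
internal fragment between sites `s1` and `s2`, the maximal sequence a
read can observe is `genome[s1+1 : s2+4]` — the fragment plus the far
CWG remnant, because adapter ligation regenerates exactly those three
genomic bases.  Tags are therefore defined symmetrically from that
window: the left-flank tag is its first 64 bases, the right-flank tag
the first 64 bases of its reverse complement (which again begins with a
C[AT]GC remnant), each polyA-filled to 64 when shorter.

The read trimmer uses the same convention: at an internal full site
GC[AT]GC it keeps through the site's fourth base (the near-side cut
product *including* its regenerated CWG), and at the common-adapter
start AGATCGGA it keeps everything before the adapter (the three
preceding bases being the far CWG).  With this single convention a
partially digested read, a completed-digest read-through read, and the
in-silico tag of the same locus collapse onto one identical 64-mer; any
convention that drops the CWG on one path but not another breaks that
round trip.  Truncation signatures are honoured when they *start* inside
the 64-base window even if they extend past it, again so that observed
and in-silico real lengths agree at the window edge.  Terminal
(sequence-end) fragments carry only one cut, cannot acquire both
adapters, and emit no tags.

## Barcode design

"Mutational steps" is implemented as Levenshtein distance (via edlib):
barcode lengths differ, and both substitutions and indels are realistic
synthesis/sequencing failure modes.  The run rule applies only to
barcodes longer than 5 bases; containment is checked in both directions
as contiguous substring; the enzyme-site rule is checked on
barcode+remnant so that no read prefix can mimic an internal cut.
Generation is a seeded greedy randomized search: per-length candidate
pools are pre-filtered, shuffled, and consumed round-robin across
lengths (so the output spans the requested range); at each step a small
tournament of constraint-compatible candidates is resolved in favour of
the one keeping per-position base composition most uniform.  A 96-plex
set generates in about a second with worst position skew < 0.15.  One
non-obvious consequence of the constraint interaction, verified by
exhaustive clique search: among 4-mers alone, pairwise distance 4 admits
a quadruple on distance grounds ({AAAA, CCCC, GGGG, TTTT}) but only a
triple once the enzyme-junction rule removes GGGG-type codes — the
generator reports exhaustion rather than returning an invalid set.

## Filtering and tabulation

Reads are classified in a fixed order — (1) barcode + exact C[AT]GC
remnant, else rejected; (2) dimer signature C[AT]GAGATCGG after the
barcode; (3) any N in the first 72 bases — so each read has exactly one
status and counts conserve.  qseq input deliberately ignores the
instrument's pass-filter flag (the chastity filter is known to discard
reads that match real segregating tags); '.' decodes as N; quality
offsets default to 64 for qseq and 33 for FASTQ.  `min_q72` is the
minimum quality over the raw read's first 72 bases, barcode included.

The reference tag set keeps tags carried by Q ≥ 10 reads occurring at
least twice *across all samples* (pooling across samples maximizes
recovery of low-depth tags; per-sample thresholds would discard real
tags at depth 1 per line).  The second pass counts exact matches
regardless of quality.  The sample-occurrence screen honours both
printed phrasings: "maize" mode keeps tags in strictly more than
`min_samples` samples (default 10), "barley" mode keeps tags in at least
`min_samples` lines (default 5).

## Mapping statistics

The co-segregation score is the exact binomial upper tail
P(X ≥ k | n, p) (scipy's `binom.sf`), one-sided because co-segregation
is an excess-of-success alternative.  Heterozygous and missing framework
calls shrink `n`, never the success count; `n = 0` is an undefined-test
signal, not p = 1.  All threshold comparisons are strict (<).  Ties
among passing markers resolve by smallest p, then largest n, then map
order.  The maize directed and global scans run sequentially — directed
first against the physically closest SNP (p < 10⁻³, n ≥ 10), global
fallback over all markers and both parents (p < 10⁻⁴).  Tags without a
unique physical position (e.g. private to the non-reference parent, or
repeated 64-mers) get the global scan only.  Fisher's exact test uses
the two-sided minimum-likelihood convention, matching full hypergeometric
enumeration; both exact tests are verified against enumeration oracles
for every configuration with margins ≤ 12.  Cross-validation of a
held-out line compares each mapped tag's presumed parent with the
parent of the line's chromosome segment at the tag's map position; tags
falling between two framework markers whose calls disagree lie inside a
recombination breakpoint window, cannot be assigned, and leave the
denominator.

## Simulator

The generator emulates a biparental homozygous population at desk
scale.  Defaults: 200 kb genome over 2 chromosomes, cut-site density
1/1000 bp (the ApeKI-like regime), 15% of sites polymorphic between
parents (presence/absence, half private to each parent), 15% of shared
sites carrying a SNP inside a tag footprint (biallelic tag pairs), 17%
of fragments shorter than 64 bases (realized by placing companion sites
20–59 bp downstream of a host site), 43 DH lines (the studied DH
population size; RILs double the effective crossover count), Poisson
crossovers with mean 2 per chromosome, 25 framework markers per
chromosome with error-free calls, mean tag depth 5, substitution error
rate 0.002, adapter-dimer rate 5×10⁻⁴ of reads, and 2% of reads given
one sub-Q10 base in their first 72.  All randomness flows from one seed;
seeded runs are byte-identical.

Two deliberate simplifications keep ground truth exact.  Substitution
errors only (no indels): with exact 64-mer matching an indel read is
indistinguishable from a singleton error tag, which the error-rate knob
already produces.  Crossover breakpoints are re-sampled away from any
position within 68 bp of a cut site, so no tag footprint straddles a
parental junction and each line's expected tag complement is a pure
function of which parent owns each cut site; truth is derived from the
parental digests plus the mosaics, never by digesting line genomes, so
digest-based checks remain independent.  The simulator does not model
quality-by-cycle error profiles, PCR duplicates, coverage bias, or
residual heterozygosity — so passing recovery tests demonstrates the
pipeline's logic and statistics, not robustness to those artefacts of
real flow cells.  Repeated 64-mers (multi-locus tags) are excluded from
truth and receive no reads; in real genomes such tags exist and are
dropped at the unique-position stage instead.

## Problem sizes and determinism

The shipped tests run the full pipeline on a 40-line DH population
(~74k reads, ~800 reference tags), a scale chosen so the entire suite
completes in well under a minute while every stage still sees hundreds
of segregating markers; the headline genome-scale counts of a real maize
flow cell depend on real data and a full reference genome and are not
reproducible at this scale.  Recovery at these settings: ≥ 95% of
segregating truth tags present in ≥ 10 lines map, with ≥ 99%
parent-of-origin agreement and zero accepted dimer reads.  The type-I
check scans 1,000 unlinked tags against a 50-marker map and bounds the
mapped fraction by the Bonferroni expectation plus three binomial
standard errors; linkage between markers makes the realized rate fall
below that bound.

## Known limitations

Exact-match demultiplexing only: the distance-3 code would support
single-error barcode rescue, but rescue is not implemented (a flag is
reserved).  Methylation sensitivity is available only as a static
masked-site fraction in the simulator.  Physical positions for real data
must be supplied as an input table (or computed by exact 64-mer match
against a provided reference); read alignment itself is out of scope.
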
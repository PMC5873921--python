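# Methods

`bacfinish` implements the computational finishing workflow for targeted
long-read sequencing of a single large genomic locus cloned into a BAC:
circularisation of the draft assembly, replicate-assembly error-rate
estimation, short-read consensus indel correction, S-locus gene
annotation, and windowed conservation profiling.  This note records the
models, conventions and numerical choices behind each stage, what the
synthetic data generator does and does not emulate, and the known
limitations.

## The setting

A BAC clone is a circular molecule: a large (~150 kb) genomic insert
ligated into a cloning vector (~8 kb).  A long-read assembler that does
not split reads produces, from such a circle, a single **linear** contig
in which the sequence around the (arbitrary) assembly origin appears
twice — once at each end — at reduced coverage.  Finishing therefore
means: find and trim that duplicated end-overlap, locate and excise the
vector, and report the insert as a linear sequence.  Because long-read
consensus sequences retain short-indel errors at rates around
10⁻⁵–10⁻⁴ per bp while being essentially free of substitution and
structural errors, the pipeline also quantifies those error classes, by
two routes: comparing two independent assemblies of the same clone, and
comparing one assembly against the consensus of accurate short reads
mapped to it.

## Alignment kernels

All scored alignment is done by in-package kernels (numba-compiled):

* **Global**: affine-gap Needleman–Wunsch (Gotoh three-state recurrence)
  with match +1, mismatch −2, gap open −4, gap extend −1; a gap of
  length *g* costs 4 + *g*.  `N` matches nothing — every column pairing
  an `N` scores as a mismatch, and such columns are excluded from SNP
  and conservation counting downstream.
* **Local**: Smith–Waterman with linear gaps (match +1, mismatch −1,
  gap −2), used for identity screening of annotation candidates.
  Identity is matches over alignment columns of the best-scoring local
  alignment, so gaps count against identity.

Contig-scale global alignment does not run the quadratic DP over 150 kb.
Instead, 21-mers that are unique in both sequences are matched, merged
into maximal runs, and chained by a length-weighted longest-increasing-
subsequence; the short segments between chained anchors are then aligned
with the full DP (segments over 6 kb fall back to an edit-distance path
from edlib — at the near-identity divergences this pipeline compares,
the two are equivalent in practice).  Pairs up to 3 kb skip anchoring
and run the full DP directly; the test suite verifies that both routes
reach the brute-force optimum computed by an independent pure-Python
oracle.  If two sequences share no collinear anchor chain the aligner
refuses with a structural-divergence signal rather than forcing a
meaningless global alignment.

## Circularisation

`detect_end_overlap` seeds 15-mer matches between the head and tail
windows of the contig, reads candidate overlap lengths off the dominant
diagonals (an end-duplication of length ℓ puts all its matches on the
diagonal L−ℓ), and verifies the top candidates by globally aligning the
putative 5′ and 3′ copies, allowing ±5 bp of terminal slack for
consensus noise at contig ends.  The head/tail window is
min(max(4·min_len, L/4), L/2): wide enough to contain an end-overlap an
order of magnitude longer than the minimum detectable one, since a
non-split assembly of a circle typically duplicates ~10% of the contig.
A hit must be end-anchored and meet the identity threshold (default
0.95); trimming removes the terminal copy and marks the contig circular.

`find_and_trim_vector` searches both strands for the vector, allowing
the match to wrap the origin (the circle is extended by |vector|+50 bp
for the search), requires ≥90% of the vector length at the identity
threshold, and returns the linear insert starting at the base following
the vector's 3′ end on the contig's forward strand.  That start point is
the package's canonical origin convention; when no acceptable match
exists the input is returned unchanged with a warning flag.  The output
for a reverse-strand input is the reverse complement of the forward
result, so recovered inserts are compared up to rotation and strand
(`circular_equal`).

## Replicate-assembly comparison

Differences are read off the global alignment column by column:

* each maximal gap run in one row is **one** indel of length equal to
  the run (a 2-column gap is one 2 bp indel, not two 1 bp events);
* each mismatch column is one SNP; adjacent SNPs stay separate;
* a gap run adjacent to a mismatch column is one indel plus one SNP —
  no re-alignment normalisation is applied, matching a naive columnwise
  reading of the alignment;
* indels are left-aligned within equal-base context before positions
  are reported, so positions do not depend on aligner tie-breaking;
* `N`-containing columns are excluded from both match and SNP counting
  and tallied separately.

Rates divide counts by a stated denominator.  For assembly-vs-assembly
comparison the default denominator is the alignment length (columns);
for read-consensus polishing it is the assembly sequence length.  The
report always records which convention was used, and rates are
serialised both at full precision and at 2 significant figures.  The
single:double ratio is count(length 1)/count(length 2) and is undefined
(None) when no 2 bp indels exist.

The structural screen is independent of base-level comparison: maximal
exact matches of unique 100-mers (both strands) are merged into anchor
blocks, trimmed to be non-overlapping on both sequences (longest block
wins; a junction k-mer can extend a block a base past a boundary, so
small overlaps are trimmed rather than discarding the block), and
chained by weighted LIS.  Reverse-strand blocks become inversion
breakpoints, off-chain forward blocks become translocations (adjacent
off-chain blocks merge into one event), and inter-anchor length
discrepancies above 50 bp become large-indel breakpoints — unless an
inversion/translocation block already occupies that gap, which would
otherwise double-report every rearrangement.  An empty breakpoint list
is the collinearity verdict.

## Short-read consensus indel correction

`build_pileup` consumes SAM records (via pysam; path, open file, or
record iterable) and accumulates per-position base counts, deletion
counts, and insertion counts keyed to the draft position **preceding**
the inserted bases.  Records that are unmapped or below mapping quality
20 are skipped; soft/hard clips contribute nothing; CIGAR ops outside
M/I/D/S/H are rejected loudly, as is any record whose CIGAR disagrees
with its sequence length.  The column invariant is
depth = Σ base counts + deletion count (insertions do not add depth).

Targets are called in one pass (the correction is applied once, not
iterated): a deletion where the deleting fraction reaches the support
threshold at sufficient depth, with consecutive deletion columns merged
into one multi-bp target; an insertion where the modal inserted string
reaches the same support (ties broken lexicographically for
determinism).  Positions inside called deletions are masked from
further calling.  Defaults are min_depth = 10 and min_fraction = 0.7 —
at the deep pileups this workflow sees (tens to thousands-fold) a true
consensus indel is essentially unanimous, so the threshold's job is
only to reject noise; 0.7 keeps calling decisive while remaining
testable at 50× with 1% read error.  Whether a support-fraction or a
bare majority rule better matches historical practice is not decidable,
so the fraction is configuration, not contract.  Base-level
disagreements (SNP-like) are reported on a side channel and never
become targets: this correction fixes indels only.

Corrections are applied right-to-left so stored coordinates stay valid;
the output length always changes by the signed sum of targets, and a
coordinate map translates old positions of unedited bases (deleted
positions raise).  The intended fixpoint — reads re-mapped to the
corrected draft yield zero targets — is exercised by the tests at full
scale.

## Annotation

**Primer sites.** The SRK exon-1 primer pair is matched by Hamming
distance only (no indels — a 20-mer primer hit with an indel was not
part of the historical procedure), both strands, with IUPAC degeneracy
in the primer matching its base set at zero cost and `N` in the subject
matching nothing; default max_mismatch 3.  The reverse primer is
expected on the − strand (it is given 5′→3′ on its own strand).

**Candidates.** Each compatible forward/reverse pair — opposite
orientations in amplicon geometry, within 5 kb — yields one region
spanning both primers inclusive (inclusive so downstream identity
comparisons see the full amplicon); each unpaired hit yields 1 kb of
flank on both sides of the primer, clamped at contig ends.

**Classification.** Candidates are accepted as SRK or rejected as the
paralogous flanking kinase ARK3 by best local-alignment identity
against each reference set, both strands, with verdict `srk` iff
identity ≥ 0.90 (inclusive) and strictly greater than the ARK3 best.
Alignments shorter than 100 columns are ignored: the best-scoring local
alignment to an *unrelated* reference is typically a ~20 bp chance
match with near-perfect identity, which would otherwise defeat the
threshold entirely.

**SCR.** The pollen-side gene evades homology search; its exon 2 is
recognised by translation signature instead.  All six frames are
scanned for ATG→stop ORFs of ≥50 aa; within each translation a window
of 90 residues slides at 1-residue steps, and an ORF is reported when
some window placement contains exactly 8 cysteines — i.e. a group of 8
consecutive cysteines whose first-to-last span fits the window and for
which a placement exists that excludes the neighbouring cysteines on
both sides.  Overlapping qualifying groups within one ORF merge to the
smallest-span group.  Window length and ORF minimum reflect the known
size of the mature SCR domain (~50–90 aa); no inter-cysteine spacing
pattern is enforced because none is established across haplotypes.

## Conservation

Pairwise conservation is the proportion of conserved bases per fixed
250 bp window laid along the **first** sequence's ungapped coordinates
(insertions in the second sequence therefore never shrink a window);
step defaults to the window size (non-overlapping tiling) and can be
reduced for a true sliding window.  Conventions, stated because tools
differ: comparison is case-insensitive; a position aligned to a gap in
the other sequence is non-conserved; `N` never matches; spans between
AXT blocks are unaligned, count as non-conserved, and are tallied
separately as excluded columns.  The final partial window is reported
with its true length as denominator.  AXT blocks must be non-overlapping
on the target and are concatenated in target order from target base 1;
sequence beyond the last block is unknowable from AXT alone and is not
fabricated.

## The synthetic-data generator

The generator is the study-conditions definition for every test.  It
builds a circular construct of a 148,000 bp insert plus an 8,100 bp
vector (both i.i.d. uniform random DNA), with planted features in
order: a 2 kb flanking-gene analogue, tandem-repeat blocks (6 blocks of
a 400 bp unit × 5 copies, generic because no repeat-family composition
is established for the locus), an SRK-exon-1 analogue (1.3 kb core
bracketed by exact 20-mer primer sites, the reverse one as its reverse
complement), an SCR-like ORF (110 codons whose translation carries
exactly 8 cysteines within a 70-residue span, preceded by an in-frame
stop so the ORF cannot extend upstream), more repeat blocks, and a
second 2 kb flank.  The shipped primer 20-mers are configurable
stand-ins: the real primer sequences are literature-cited runtime
inputs, not constants of this package.

The draft-assembly step rotates the circle to a uniform random origin,
appends the first 15,000 bases again at the end (the duplicated
end-overlap), and injects errors i.i.d. uniformly: SNPs and 1–2 bp
indels at configurable rates (defaults 0 and 5.7×10⁻⁵ per bp), indel
lengths drawn to a 2:1 single:double mix, insertions and deletions
equiprobable, edits kept ≥5 bp apart so they do not interact, and
primer/SRK/SCR intervals protected so annotation oracles stay exact.
Real consensus errors are not specifically enriched in homopolymers for
this technology, so no homopolymer bias is modelled.  Short reads are
250 bp proper pairs from normal fragments (600 ± 60 bp), substitution
errors only, constant Q37 qualities (emulating quality-filtered data;
no trimming stage exists downstream), emitted as FASTQ plus a truth SAM
against the template.  Because read mapping is out of scope, reads are
placed onto a *different* reference (e.g. the error-bearing draft) by
`realign_reads`, a synthetic stand-in that edlib-aligns each read to
the reference window around its known placement — valid only because
reference and template differ by a handful of short edits, which is
exactly the regime the pipeline operates in.

Replicate-assembly pairs for error-rate studies put all injected error
into the second copy at the full configured rate, so the measured
inter-assembly difference rate estimates that rate directly.  (In a
real replicate comparison both assemblies contribute errors and the
difference rate is the sum of two per-assembly rates; the pipeline
measures the difference rate either way and makes no attempt to
apportion it.)

What the generator does **not** emulate — and hence what passing tests
do not show about real data: nonuniform base composition and real
repeat families (anchoring is easier on synthetic data than on a
genuinely repeat-rich locus), coverage fluctuation and the reduced
coverage across assembly ends, mapping ambiguity and chimeric reads,
indel errors in reads, and clustered or homopolymer-biased consensus
errors.

## Determinism and problem sizes

Every stochastic step flows from one integer seed through
`numpy.random.default_rng([seed, stage])`, with a distinct stage tag
per operation, so identical parameters give byte-identical FASTA,
FASTQ, SAM and ledger output; the pipeline manifest records a SHA-256
checksum of every artifact and a re-run reproduces all of them.

Test problem sizes: worked error-rate values and the recovery studies
that state a length run at the printed dimensions (156,644 bp
replicate pairs; a 153,563 bp polish cycle at 100×; 178,980 →
156,636 bp circularisation; full 156 kb constructs for rotation/strand
recovery).  Where no length is stated, loops over 100 seeds use 40 kb
structural pairs and 20 kb-insert constructs, which exercise the same
code paths at desk scale.

## Known limitations

* The aligner is built for near-identical sequences; diverged haplotype
  pairs (the conservation use case) should be aligned externally and
  ingested as AXT or aligned FASTA.
* The structural screen reports "collinear" for two sequences sharing
  *no* anchors at all; it is a screen for rearrangements between
  assemblies of the same molecule, not a homology detector.
* Coverage is not used as evidence anywhere: the reduced-coverage
  signature of end-overlaps is not modelled or checked.
* One correction pass only; pathological mutual-overlap target sets are
  rejected, not resolved.
* `BAM` input is not parsed from disk by the tests (text SAM only),
  though any pysam-readable source works through the same reader.
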
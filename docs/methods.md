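# Methods

## K-mer model

A k-mer is a 32-base window. Only two of its fields are stored and
compared: the PREFIX (first `n` bases, `1 ≤ n ≤ 16`, default 14) and the
SUFFIX (last 16 bases). Packing is 2 bits/base with A=0, C=1, G=2, T=3,
leftmost base most significant; the constant is exported so serialized
databases are portable across platforms.

When `n < 16` the middle `32 − n − 16` bases are neither stored nor
compared. Two consequences are deliberate and documented:

* mismatches in the middle region are invisible, granting free error
  tolerance there (2 bases at the default n = 14);
* **k-mer identity during database construction is the stored
  (group, suffix) projection.** Any finer identity could leave duplicate
  (group, suffix) pairs in the serialized database; with the projection
  as identity, the "no duplicate pair, one taxid per k-mer" invariant of
  the on-disk format holds by construction.

The SUFFIX splits into QM (first `m` bases, default 6) and DP (the
remaining `16 − m`). QM is compared under `m` seed masks, each wildcarding
one base, which accepts exactly Hamming distance ≤ 1. DP is compared by a
banded edit distance with budget 2.

### Band geometry

The banded dynamic program uses 4 off-main diagonals — offsets
−2…+2 around the main diagonal — so the alignment's net length shift is
limited to ±2. A symmetric band is required for the stated error budget:
two *insertions* in the DP region shift the query frame by +2, and a band
truncated on that side would reject a corruption the budget promises to
tolerate. Within the band the result equals the unbanded Levenshtein
distance whenever that distance is ≤ 2, because an optimal path of cost
c never strays more than c diagonals off-center; the test suite verifies
this against an independent full-matrix aligner (edlib).

Because an indel shifts the read frame, the query side of the DP
comparison may consume up to two read bases beyond the window's nominal
end, and query bases beyond the optimal path are free. This is what lets
a window containing a deletion still match its source k-mer.

A matched window therefore tolerates ≤ 1 substitution in QM plus ≤ 2
edits (including indels) in DP — at most 3 errors outside the PREFIX.

## Database construction

Collision resolution proceeds species → genus → whole database:

1. all strain sequences of a species are pooled; each k-mer is kept once;
2. within a genus, a k-mer occurring in ≥ 2 species is re-assigned to the
   genus taxid; k-mers unique to one species keep the species taxid;
3. after merging all genera, any k-mer carrying two distinct taxids is
   deleted outright (no promotion to a higher ancestor — deletion keeps
   only k-mers that characterize exactly one taxon).

Subsampling: species-unique k-mers are kept when any source window start
position satisfies `pos mod round(100/X) == 0` (X = 15% → every 7th
position ≈ 14.3%). The stride rule is deterministic, spreads retained
k-mers uniformly over each genome, and is nested across the commonly used
X values (10/20/50/100), so smaller databases are subsets of larger ones.
Genus-shared k-mers are always retained regardless of X, giving the
shared signal priority over the thinning.

Open design points resolved as follows (the published description is
silent on each):

* X% selection is applied **after** genus resolution, so thinning can
  never demote a shared k-mer back to species status;
* reverse-complement k-mers are added at **build** time (both strands of
  every reference are k-merized) and query reads are scanned forward
  only; the alternative — query-time RC scanning — would halve the
  database at twice the query cost and is configurable via
  `BuildParams(include_rc=False)` only for diagnostic builds;
* each query window stops probing its group at the first matching entry
  (entries are discriminative, one taxid each), counting one hit per
  window; exhaustive probing is available as a diagnostic flag.

Serialization is a directory: a JSON text header (magic, version, n, m,
X, base order, entry count), `size.bin` (4·4ⁿ bytes of little-endian
uint32 group sizes), `suffix.bin` and `taxid.bin` (uint32 each). Reads
validate magic/version and all cross-file count consistency. Builds are
byte-deterministic: species are processed in sorted-taxid order and
groups keep insertion order. Note the dense group-size table costs
4·4ⁿ bytes in memory and on disk (1 GiB at n = 14; 4 MiB at n = 10), the
price of O(1) group lookup without hashing.

## Classification

Windows slide at stride 1; windows containing ambiguous bases are
skipped (IUPAC codes are treated like N). A read is assigned to the
taxid with the maximal matched-window count when that count reaches
`min_hits` (default 1), else unclassified. Ties break to the deepest
taxon; a residual tie reports the LCA of the tied taxa — deterministic
and conservative. A copy of the taxonomy is embedded in the database
directory so tie-breaking and downstream evaluation need no extra input.

## Read simulation

Reads are fixed-length source spans drawn uniformly from a genome, with
per-base errors at a uniform total rate. The default error mix is
(substitution, insertion, deletion) = (0.5, 0.25, 0.25), loosely
Nanopore-like; all accuracy properties in the test suite are insensitive
to the mix. Substitutions always change the base; insertions add a
uniform random base after the current position; deletions drop the
current base. The nominal read length refers to the source span, so the
emitted sequence drifts by the net indel count; truth records (taxid,
genome, span, per-type error counts) accompany every read.

Synthetic communities: genomes are i.i.d.-uniform over {A,C,G,T}, and
every species of a genus carries a planted copy of a genus-common
segment (`shared_fraction` of the genome length) so genus-level collision
assignment and clade-exclusion behaviour are actually exercised. What
this emulates — and what it does not: uniform random genomes have no
repeat structure, no compositional bias, no low-complexity regions, and
the error model has no homopolymer bias. Passing tests therefore show
the *algorithmic* machinery is correct at realistic error rates, not
that accuracy figures transfer to real genomes, where inter-species
homology is far richer.

## Problem sizes used in the test suite

Scaled-down study conditions, chosen once: the end-to-end recovery check
uses a 20-genome community (10 genera × 2 species, 5 kb genomes, 20%
within-genus sharing), reads of nominal length 1000 at 10% uniform
error, built at n = 10, m = 6, X = 15; the clade-exclusion check holds
out 30% of species (6 of 18) and simulates 15% error reads. The
simulation-protocol checks generate the full 342,360 = 20 × 17,118 and
400,000 = 10,000 × 40 read counts on 1.1 kb genomes. Matcher/oracle
equivalence uses 10⁵ random window/entry pairs plus exhaustive QM
enumeration for m ≤ 4.

## Known limitations

* Single-threaded; no parallel classification.
* No canonical-k-mer folding: strand symmetry comes from build-time RC
  indexing only.
* No abundance re-estimation; assignment is per-read argmax.
* Cross-taxa deletion (rather than LCA promotion) discards signal from
  conserved regions spanning genera; reads from such regions go
  unclassified rather than to a family-level call.
* The dense 4ⁿ group table makes n > 14 memory-hungry (4 GiB at n = 15).
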
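# Methods

## Gene models and intron phase

Genes are represented in transcript orientation with 0-based half-open
internal coordinates; GFF3's 1-based inclusive convention is converted at
the I/O boundary. The phase of an intron is the number of coding
nucleotides upstream of it modulo 3; an intron that does not interrupt the
CDS (both boundaries inside UTR) carries a sentinel phase `NC` rather than
0, so UTR introns can never satisfy a phase-conservation test. A total CDS
length not divisible by 3 flags the model (`incomplete_orf`) without
rejecting it, since partial annotations and pseudogenes are expected
inputs. Translation stops at the first in-frame stop codon and flags it as
premature when it precedes the final codon — the pseudogene signature —
and must be given the CDS extent so a 3'-UTR is not mistaken for
read-through. Exon numbering follows annotation order in transcript
orientation; homology-based renumbering across species is the caller's
responsibility via an explicit ID map, because no tie-breaking rule exists
when exon counts differ between species.

## Junction queries and perfect-match counting

A junction query is the last `flank` nt of the upstream exon joined to the
first `flank` nt of the downstream exon, with `flank = 15` (30-nt queries).
This length is long enough to make random 30/30 matches vanishingly rare in
a brain-scale library yet short enough not to lose reads whose remainder
diverges. Matching is exact substring search on both strands by default
(library strandedness is generally unknown); there is deliberately no
mismatch or gap tolerance, as the perfect-match criterion is what makes
counts comparable across species without alignment-score tuning. Counting
is read-level: a read increments a query at most once, counts over read
batches are additive, and reads shorter than 30 nt contribute zero. The
production scan hashes every query 30-mer (and its reverse complement) and
slides one window over each read; a naive per-read, per-query substring
scan is kept as the in-test oracle and the two must agree byte for byte.

## Identity QC of matched reads

A 30-nt match confirms only 30 nt. Classification aligns the read to the
expected transcript ungapped at the junction anchor and finds the widest
read interval containing the 30-mer explainable with at most `max_subs`
substitutions (two-pointer search over mismatch positions; positions
mapping outside the transcript are never explained). A fully explained
read is `clean`; `max_subs` defaults to 5, and raising it can only move
reads into the clean class. Otherwise the longer unexplained flank is the
leftover: below `min_leftover` (20 nt, roughly the shortest stretch
identifiable by sequence search) the read is `unidentified_short`;
otherwise exact seeds of `seed_len = 16` nt (both strands, spaced half a
seed apart) are searched against the reference sets in the fixed
precedence **vector > rearranged same-gene > same-species > foreign**,
most specific contamination source first. A leftover hitting the expected
gene itself is by construction a rearrangement (wrong strand or
non-contiguous region — a contiguous continuation would have been
explained by extension). Reads hitting several reference sets are labelled
by precedence and flagged ambiguous in the evidence.

## Expression report

Counts are subtotalled into L (cassette-containing junctions) and S
(cassette-skipping junctions); the subtotals conserve the grand total by
construction. Normalised expression is log10(count / Actb count) from the
same library; a zero numerator is reported as absent rather than −∞, and a
zero Actb count is a hard error because the control doubles as the
library-quality gauge. Presence is operational: `min_reads` perfect
junction reads, default 1 — a deliberate choice documented alongside raw
counts so stricter thresholds can be applied downstream, since "expressed
at substantial levels" has no natural cutoff. The depth report associates
per-species Actb totals with short-isoform presence using the
rank-biserial correlation `2·(mean rank of present − mean rank of
absent)/n`, which is exactly 0 under constant depth and exactly 1 when
presence coincides with the deepest half — the confound the diagnostic
exists to expose. It is a descriptive magnitude; no hypothesis test is
attached.

## Intron anchors and the exon-deletion signature

An intron is projected protein-side as an anchor `(alignment column,
phase)`: the column of the residue immediately following the splice for
phase 0, or of the residue whose codon is split for phases 1–2. Anchors
are invariant under insertion of all-gap columns elsewhere in the
alignment. Conserved introns require identical column *and* identical
phase; a configurable ±k column slack exists but defaults to 0 (strict
positional identity, no intron-sliding allowance). Qualitative
domain-equivalence evidence is carried as annotation only, never used as a
filter. The deletion signature requires: in the retaining gene, two
phase-0 anchors flanking the cassette exon; in the other gene, the exon's
projected columns gapped (default threshold 100%, relaxable for ragged
alignments) and exactly one phase-0 anchor at the fused position. Anything
else is `retained` (exon columns gap-free in both rows and both flanks
pairing) or `no_signature`.

## Conservation scan

Column score: over all unordered sequence pairs, identity 2, conservative
substitution 1, anything else (including any gap) 0; every pair is
elevated to 3 iff the column is identical and gap-free across *all* rows;
the net score is the pairwise mean, bounded in [0, 3]. Conservative
groups are not intrinsic to the scoring rule, so the common strong classes
`{ILMV} {FWY} {DENQ} {HKR} {AGPST} {C}` are the default and alternative
schemes can be passed in. Windows are 30 columns, advance one column, and
only fully contained windows are scored; the centre of a window starting
at 1-based column *s* is reported as *s* + 15, fixed so plots reproduce
bit for bit. Profiles run in alignment columns (gap columns participate,
scoring 0 in their pairs); an option maps centres onto a reference row's
residue numbering for plotting against structural annotations, since both
coordinate conventions are defensible. Note the pairwise mean is not
monotone under row duplication (duplicating a divergent row adds
zero-scoring pairs faster than identity pairs), so no such monotonicity is
asserted. Integer percent identity rounds half away from zero.

## Parsimony

Small parsimony for the binary character uses Sankoff's dynamic program,
which handles multifurcations directly and equals Fitch's count on binary
trees. The gains-only scenario forbids present→absent transitions
(infinite loss cost); its count equals the number of maximal all-present
clades, with a present root itself counting as one ancestral gain. The
single-gain scenario fixes the trait present at a chosen gain node
(default the root), forbids further gains, and counts losses — the number
of maximal all-absent clades below the gain node; a present tip outside
that clade is a hard error. Only event counts are contracted: optimal
ancestral reconstructions may be non-unique, the counts are not. The
bundled 20-tip survey tree carries 12 present tips and yields 4 gains-only
events versus 6 losses under a root gain, with an unconstrained minimum of
4; users can rerun the counts on alternative topologies, which can only
raise the loss count.

## Synthetic data

The generator is the test bed for every stage and defines the study
conditions. Target genes have 7 exons with a cassette exon of 24–33 codons
at position 6, flanked by phase-0 introns (both configurable, including
frame-breaking phases for negative controls); exon CDS lengths are drawn
from 90–240 nt and adjusted to realise the requested phases; a 6-exon
Actb-like control gene accompanies each target. Read lengths are normal
with mean 108 and sd 20, truncated to [30, transcript length]; starts are
uniform (no positional bias is modelled); errors are iid substitutions at
rate 0.005 by default (the exact-match criterion is gap-free, so indels
would only deflate counts and are off by default). Half of each library
comes from the control gene, and 30% of a skipping-positive species'
target transcripts skip the exon (a typical minority-isoform level).
Artifact reads are constructed around an intact junction 30-mer plus
20–50 nt of clean flank, with a category-specific tail: a
reverse-complemented distant region of the same transcript, a 40-nt
segment of the control gene or of a foreign pool sequence, a 40-nt vector
prefix, or a 10-nt tail built base-wise different from the transcript
continuation (so "too short to identify" is unambiguous even at zero error
rate). The artifact count is drawn so that the *retrieved* read set is a
3%-artifact mixture by default, mirroring how chimera rates are observed —
among reads a junction query pulls back. Everything is deterministic given
one seed (byte-identical FASTQ), with per-species substreams spawned from
it.

What the simulator does not emulate: quality-score structure, GC/coverage
bias, paired ends, positional fragmentation bias, allelic polymorphism, or
cross-species contamination at realistic phylogenetic distances. Passing
tests therefore demonstrate correctness of the counting, classification
and reporting logic under the stated error model, not robustness to every
real-library pathology.

## Pipeline and problem sizes

The orchestrated run (simulate → design → count → qc → report) writes
tab-separated tables with one header line plus JSON summaries, and a
manifest with a SHA-256 digest per output; identical configuration and
seed reproduce the digests exactly. The bundled study design is 29 species
(12 skipping-positive) at 5,000–12,000 reads per library — about 240,000
reads in total, which a single core processes in a few seconds and which
puts dozens of reads on every expressed junction, ample for presence
calling at `min_reads = 1`. The parameter-recovery check uses a single
50,000-read library; the counting-oracle equivalence check uses a
10,000-read instance; brute-force parsimony enumeration is vectorised over
all 2^19 internal assignments of the 20-tip tree.

## Known limitations

Exact-substring counting cannot see junction reads with sequencing errors
inside the 30-mer (a known, uniform sensitivity cost of the perfect-match
criterion, ~0.5%/base); QC leftover identification is seed-and-verify, not
local alignment, so heavily mutated leftovers can fall back to
`unidentified_short`; the exon-deletion signature assumes the alignment is
correct around the cassette span; presence calls at `min_reads = 1`
inherit the false-negative behaviour of shallow libraries — which is
exactly what the depth report is for.
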
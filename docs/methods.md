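# Methods

`mirkit` re-implements, as a reusable library, the classic Solexa-era
workflow for cataloguing microRNA genes from small-RNA sequencing: raw
35-nt reads are reduced to unique counted tags, mapped perfectly to a
genome, sorted into annotation categories, and candidate precursors are
excised around read pileups, folded, and filtered on hairpin geometry
before known/novel gene calls and downstream catalogue analyses
(isomiRs, clusters, paralogs, conservation tiers, sense/antisense
pairs). A ground-truthed read simulator generates data with the
statistical structure this workflow assumes, so every stage can be
tested against a manifest of planted outcomes.

## Preprocessing

Reads are accepted or rejected whole: a read passes when its mean Phred
score is at least `min_mean_q` (default 20) and it contains at most
`max_n` (default 0) ambiguous bases. The original low-quality criterion
used by such pipelines is typically an unpublished in-house script, so
the threshold here is explicit, configurable, and shared with the
simulator's definition of a "failing" read — the filter and the
generator agree on what low quality means.

The 3' adapter is clipped by ungapped semi-global alignment of the
adapter prefix against every read suffix (match/mismatch only, no gaps:
for a ~21-nt adapter inside a 35-nt read, gaps add complexity without
benefit). The leftmost cut point whose alignment spans at least
`min_overlap` = 6 bases with a mismatch fraction ≤ 0.1 wins. Reads with
no acceptable adapter occurrence are discarded — without the adapter
boundary the insert length is indeterminate — and tallied separately.
Inserts whose 5' end matches a suffix of the 5' adapter over ≥ 8 bases
(≤ 1 mismatch) are removed as ligation contaminants. Surviving inserts
are collapsed into unique tags with per-library counts; tags shorter
than 18 nt (the conventional mapping floor) or longer than 30 nt (the
gel size-selection ceiling) are excluded. Every stage conserves counts:
raw = low-quality + no-adapter + contaminant + length-failed + clean.

## Mapping

Tags are mapped by exact full-length match on both strands using a
k-mer seed (k = 12) with verification — adequate and fast at the scale
this package targets, and exhaustively checked against a brute-force
string-search oracle in the tests. Mismatched or gapped placements are
not alignments here. Tags with more than `max_hits` = 20 genomic
placements are flagged hyper-repetitive and excluded from hairpin
discovery (their placement is uninformative) while remaining visible to
the repeat-category tally. Retained multi-mappers contribute their full
count at every placement, with the hit count recorded so reports can
note the ambiguity.

## Annotation categories

Each mapped tag receives exactly one category by ≥ 1 bp overlap at any
of its placements, resolved by a fixed priority: known miRNA hairpin >
structural ncRNA (rRNA/tRNA/snRNA/snoRNA — discarded from discovery) >
repeat > exon (sense/antisense by strand) > intron > intergenic.
Repeat-overlapping tags stay eligible for discovery: repeat-derived
miRNA genes are a substantial, real catalogue class. Sense-exon tags
are eligible only if their precursor later shows a significant fold
p-value (< 0.01), guarding against mRNA degradation fragments;
antisense-exon tags are eligible unconditionally, since antisense
hairpins cannot be mRNA breakdown products. Percentages in category
tables are rounded half-up to two decimals, the convention of printed
library-statistics tables.

## Hairpin discovery

Same-strand overlapping alignments merge into pileup loci by a linear
sweep; loci longer than 200 nt are split recursively at the deepest
(leftmost) coverage minimum. The locus's most abundant tag is the
mature guess (ties: 5'-most on the locus strand, then lexicographic).
Two candidate precursors are excised around it in transcript
orientation — 10 nt upstream/70 nt downstream, and the converse —
clipped at chromosome ends, and folded at their MFE with ViennaRNA
(Turner parameters, 37 °C, no pseudoknots). The engine sits behind a
one-function contract (`seq -> (dot_bracket, mfe)`) and is replaceable.
Candidates shorter than 40 nt auto-fail.

The mature/star duplex is read off the MFE structure. The star span is
the mature's pairing-partner interval shifted to leave 2-nt 3'
overhangs on both strands — the Dicer signature; when star-arm reads
exist, the observed star span (most abundant opposite-arm tag)
replaces the inferred one, so geometry is measured from data wherever
data exist. Metrics: `unpaired_mature`/`unpaired_star` count unpaired
bases inside each span; `max_bulge` is the longest unpaired run
strictly interior to either span (terminal overhangs are not bulges);
`asymmetry` is |unpaired_mature − unpaired_star| (an alternative
definition summing per-loop size differences could be slotted in, but
the absolute-difference form is the documented default). The 3'-overhang
flag measures positional protrusion of each strand's 3' end past the
partner of the other strand's outermost paired base, rather than raw
unpairedness of terminal bases: when the MFE fold extends the stem into
flanking sequence, a genuine Dicer duplex would otherwise fail the test
on an artifact of the fold.

A candidate passes when, jointly: MFE ≤ −25.0 kcal/mol; mature and star
on different arms (a loop-spanning mature is rejected outright); each
arm ≤ 6 unpaired bases; largest bulge ≤ 4 nt; asymmetry ≤ 3; and the
duplex shows 3' overhangs at both ends — this last only when star reads
were actually sequenced, because without an observed star the overhang
is a convention, not a measurement. All bounds are inclusive. Both
windows are always evaluated; if both pass, the lower MFE wins (ties
prefer the 10-up/70-down window).

Because one gene's mature-arm and star-arm reads are separated by the
loop, they frequently form two disjoint pileups; accepted candidates
whose precursor windows overlap on one strand are therefore unioned and
re-evaluated as a single locus, so read-support thresholds see the
whole gene. This union-by-overlap also merges per-library candidate
sets into one catalogue.

Fold significance (used for sense-exon candidates) is a permutation
p-value against dinucleotide-preserving shuffles (Altschul–Erickson
Eulerian-walk algorithm; dinucleotide rather than mononucleotide
shuffling, since stacking energies make MFE strongly
dinucleotide-dependent): p = (1 + #{shuffle MFE ≤ observed}) / (n + 1),
with n = 100 shuffles by default — the 0.01 decision threshold is
exactly resolvable at n ≥ 99. On null sequences the p-values are
uniform (verified by KS test in the acceptance suite).

## Catalogue

A candidate is a **known** gene when its mature matches a silkworm
reference mature within ≤ 2 mismatches and ≤ 3 nt end shift, or its
precursor overlaps an annotated hairpin locus, with ≥ 2 mature-arm
reads. The shift/mismatch tolerance reflects that reference annotations
themselves often differ from the dominant sequenced isoform. A
candidate is **novel** when it is not known, not structural ncRNA, has
≥ 5 reads within a single library (the strict per-library reading;
pooled mode by flag), an accepted hairpin, and — if sense-exonic — fold
p < 0.01. Novel loci are named `nov-mir-<n>` in chromosome order;
duplicated names get `-1`, `-2` suffixes.

Per arm (5p/3p, split at the loop midpoint), the dominant isoform is
the highest-count tag (ties: longest, then 5'-most), with 5'/3'
end-offset histograms relative to it; arm dominance is the 5p/3p read
ratio, and a known gene is flagged `arm_switch` when its annotated arm
is not the max-read arm. Clusters chain loci on one chromosome and
strand with inter-precursor gaps strictly below 2,500 nt
(single-linkage; singletons are not clusters; clusters require one
strand because a polycistronic transcript has one, with a
strand-agnostic mode by flag). Paralogs are the union-find closure over
pairs whose mature-vs-mature or mature-vs-star distance is ≤ 2
mismatches. Conservation tiers classify each locus by which reference
species match its mature within ≤ 2 mismatches: `inv-ver` (an
invertebrate and a vertebrate), `inv` (a non-insect invertebrate),
`ins` (a non-silkworm insect), else `sw` (species-specific).
Sense/antisense pairs are precursor intervals overlapping reciprocally
≥ 50% on opposite strands. Genomic context is assigned by precursor
overlap with priority TE > exonic > intronic > intergenic (TE
membership dominates, as repeat-derived genes are reported as such even
when intronic).

## The simulator

The generator builds the study conditions the pipeline is tested under;
its defaults are fixed and are not tuning knobs. Two 100-kb
chromosomes of uniform random sequence receive: 30 true miRNA hairpins
and 10 more inside annotated transposable elements; 20 rRNA/tRNA decoy
loci; 8 gene models with exon/intron structure; 5 intergenic noise
regions; and optionally planted sense/antisense hairpin pairs.

A planted hairpin is `mature + loop(8–15 nt) + star`, where
`star = revcomp(mature[:-2]) + 2-nt tail` — the mature's last two bases
stay unpaired against the loop and the star tail protrudes at the stem
base, building the 2-nt 3'-overhang duplex geometry directly into the
sequence — with up to two engineered substitutions in the star interior
as realistic mismatches, and GC ≥ 50% so the −25 kcal/mol bar is
reachable at ~22 bp. Each design is verified with the pipeline's own
folding engine *in its genomic context* (the 10/70 excision window
around the mature must pass the structural filter, with and without an
observed star) and redesigned on failure: a planted "true miRNA" that
does not exhibit the duplex geometry of a true miRNA would be mislabeled
truth, not a harder test. Planting also verifies that every read the
locus will emit maps full-length only to its own strand; junction
coincidences can otherwise give a star read an exact antisense match
and conjure a phantom opposite-strand locus. Antisense-pair loci are
verified on both strands; the mirrored duplex carries 5' overhangs, so
the antisense partner is simulated without star reads.

Per library, each miRNA locus draws a negative-binomial total read
count (mean 40, dispersion 0.5 — a heavily skewed abundance spectrum:
few dominant genes, many rare ones). Reads split into loop reads
(rate 0.01, emitted as loop ± 5 nt fragments so they survive the length
filter, as real loop reads do), star reads (fraction 0.05, reflecting
the strong biological depletion of the passenger strand), and mature
isoforms with independent 5'/3' end shifts in {−2..+2}; the 3'
distribution (0.60 at offset 0) is deliberately more dispersed than
the 5' (0.90 at 0), encoding the observed asymmetric end
heterogeneity. Decoy/exon/noise loci emit uniformly positioned 16–28 nt
fragments (NB mean 30). Each insert is 3'-extended with the adapter and
truncated to 35 nt; 10% of reads get failing quality strings
(mean Phred ≈ 12 vs ≈ 36; Phred+33), 2% get a 5'-adapter prefix, and
substitution errors occur at 0.005/base (substitutions only — no
indels or quality-by-cycle realism). The manifest records, per locus
and library, planted and *recoverable* read counts (error-free, good
quality, uncontaminated) and the expected pipeline call: `known`
(reference-listed, ≥ 2 recoverable reads), `novel` (≥ 5 recoverable
reads in one library), else `rejected`.

What passing tests on these data do **not** show: robustness to indels
or position-dependent error profiles, to fragmented or repetitive real
genomes beyond the planted TEs, to cross-mapping between genuine
paralog families, or to adapter variants; the simulator's loci are
well-separated by construction, so locus-merging behaviour on densely
overlapping real transcriptomes is exercised only lightly.

## Numerical and procedural choices

* Coordinates are 0-based half-open on the + strand throughout; minus
  strand features store the + interval and a strand flag; precursor
  sequences are emitted 5'→3' in transcript orientation as RNA.
* Folding is deterministic; tests pin it at 0.01 kcal/mol tolerance.
* Problem sizes in tests and the acceptance script (100-kb
  chromosomes, 200 p-value calibration sequences × 99 shuffles) were
  chosen so the whole suite exercises every stage end-to-end in a few
  minutes on one CPU; all scale linearly if enlarged.
* Randomness: a single integer seed drives genome construction, read
  simulation (seed + offset) and shuffle draws; identical config and
  seed reproduce byte-identical outputs.
* Degenerate inputs: empty catalogues produce all-zero tables; windows
  are clipped and flagged at chromosome ends; homopolymers are
  shuffle-invariant (p = 1); candidates < 40 nt auto-fail.

## Known limitations

* The mature-guess heuristic ("most abundant tag") stands in for an
  explicit Drosha/Dicer processing-site model; deeply covered
  degradation regions can present plausible guesses that only the
  structural filter removes.
* `asymmetry` has no single field-standard definition; the
  absolute-difference form used here is simple and monotone but blind
  to compensating loop placements.
* Known-gene matching trusts the reference FASTA's species prefixes;
  a malformed header species not present in the taxon map is a
  configuration error by design.
* Target-site prediction, inter-library expression normalization and
  differential-expression statistics are out of scope.
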
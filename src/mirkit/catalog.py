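"""Catalogue construction: known/novel calls, isoform refinement,
clusters, paralogs, conservation tiers, sense/antisense pairs and
genomic context.

Read-support thresholds follow the discovery rules of Solexa-era miRNA
surveys: a candidate matching an annotated silkworm mature sequence (or
overlapping an annotated hairpin locus) counts as a known gene with as
few as 2 mature reads; a novel gene needs at least 5 reads within a
single library, an accepted hairpin, no structural-ncRNA annotation,
and - when it lies sense to an exon - a precursor fold p-value < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._seq import back_transcribe, transcribe
from .annotate import AnnotationSet, CategoryAssignment
from .hairpin import HairpinCandidate, PileupLocus

KNOWN_MIN_MATURE_READS = 2
NOVEL_MIN_READS = 5
CLUSTER_MAX_GAP = 2500
PARALOG_MAX_MISMATCH = 2
KNOWN_MAX_MISMATCH = 2
KNOWN_MAX_SHIFT = 3

#: conservation tiers, from widest to narrowest distribution
TIERS = ("inv-ver", "inv", "ins", "sw")

#: species prefix -> coarse taxon, for miRBase-style reference headers
DEFAULT_TAXON_MAP = {
    "bmo": "silkworm",
    "dme": "insect",
    "aga": "insect",
    "tca": "insect",
    "ame": "insect",
    "cel": "invertebrate",
    "lgi": "invertebrate",
    "cte": "invertebrate",
    "hsa": "vertebrate",
    "mmu": "vertebrate",
    "gga": "vertebrate",
    "dre": "vertebrate",
}


@dataclass
class CandidateLocus:
    """A pileup locus that survived hairpin filtering, pre-cataloguing."""

    locus: PileupLocus
    hairpin: HairpinCandidate
    category: str
    requires_fold_pvalue: bool = False
    fold_pvalue: float | None = None


@dataclass
class MiRNALocus:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    status: str  # known | novel
    context: str = "intergenic"  # exonic | intronic | intergenic | te
    mature_seq: str = ""  # RNA
    star_seq: str | None = None
    mature_counts: dict[str, int] = field(default_factory=dict)
    star_counts: dict[str, int] = field(default_factory=dict)
    loop_counts: dict[str, int] = field(default_factory=dict)
    dominant_isoform: dict[str, str] = field(default_factory=dict)  # arm -> seq
    arm_switch: bool = False
    matched_reference: list[str] = field(default_factory=list)
    hairpin: HairpinCandidate | None = None


@dataclass
class Cluster:
    members: list[str]
    chrom: str
    start: int
    end: int
    strand: str
    max_gap: int


@dataclass
class ParalogGroup:
    members: list[str]
    representative_mature: str


@dataclass
class ConservationCall:
    name: str
    tier: str
    matched_reference: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sequence similarity with end-shift tolerance


def seq_match(
    a: str,
    b: str,
    max_mismatch: int = KNOWN_MAX_MISMATCH,
    max_shift: int = KNOWN_MAX_SHIFT,
) -> bool:
    """Ungapped best-overlap comparison with end-shift tolerance.

    True when some relative shift of at most max_shift nt aligns the two
    sequences over at least min(len)-max_shift bases with at most
    max_mismatch mismatches.
    """
    a, b = a.upper().replace("T", "U"), b.upper().replace("T", "U")
    min_overlap = max(min(len(a), len(b)) - max_shift, 1)
    for shift in range(-max_shift, max_shift + 1):
        # b starts at position `shift` relative to a
        lo = max(0, shift)
        hi = min(len(a), len(b) + shift)
        if hi - lo < min_overlap:
            continue
        mism = sum(1 for i in range(lo, hi) if a[i] != b[i - shift])
        if mism <= max_mismatch:
            return True
    return False


def reference_species(header: str) -> str:
    """Species prefix of a miRBase-style identifier (``dme-miR-1`` -> dme)."""
    return header.split("-", 1)[0].lower()


# ---------------------------------------------------------------------------
# known / novel calls


def locus_read_counts(cand: CandidateLocus) -> dict[str, dict[str, int]]:
    """Per-library read counts split by arm: mature / star / loop / other.

    A member tag is assigned to the arm its span overlaps most (mature
    span, star span, loop span of the accepted hairpin).
    """
    hp = cand.hairpin
    spans = {"mature": hp.mature_span, "star": hp.star_span, "loop": hp.loop_span}
    out: dict[str, dict[str, int]] = {k: {} for k in ("mature", "star", "loop")}
    for m in cand.locus.members:
        if hp.strand == "+":
            lo, hi = m.start - hp.g_start, m.end - hp.g_start
        else:
            lo, hi = hp.g_end - m.end, hp.g_end - m.start
        best_arm, best_overlap = "loop", 0
        for arm, span in spans.items():
            if span is None:
                continue
            overlap = min(hi, span[1]) - max(lo, span[0])
            if overlap > best_overlap:
                best_arm, best_overlap = arm, overlap
        if best_overlap <= 0:
            continue
        for lib, n in m.counts.items():
            out[best_arm][lib] = out[best_arm].get(lib, 0) + n
    return out


def match_known(
    candidates: Sequence[CandidateLocus],
    reference_matures: Sequence[tuple[str, str]],
    annotations: AnnotationSet | None = None,
    min_mature_reads: int = KNOWN_MIN_MATURE_READS,
) -> dict[int, list[str]]:
    """Known calls: index of candidate -> matched reference names.

    A candidate is known when its mature matches a silkworm (bmo)
    reference mature within the mismatch/shift tolerance, or its
    precursor overlaps an annotated known-miRNA hairpin locus, and its
    mature arm carries at least min_mature_reads reads in total.
    """
    bmo_refs = [
        (name, seq)
        for name, seq in reference_matures
        if reference_species(name) == "bmo"
    ]
    out: dict[int, list[str]] = {}
    for i, cand in enumerate(candidates):
        counts = locus_read_counts(cand)
        if sum(counts["mature"].values()) < min_mature_reads:
            continue
        matched = [
            name for name, seq in bmo_refs if seq_match(cand.hairpin.mature_seq, seq)
        ]
        if not matched and annotations is not None:
            hp = cand.hairpin
            matched = [
                a.feature_id
                for a in annotations.overlapping(hp.chrom, hp.g_start, hp.g_end)
                if a.feature_class == "known_mirna" and a.strand == hp.strand
            ]
        if matched:
            out[i] = matched
    return out


def call_novel(
    candidates: Sequence[CandidateLocus],
    known: dict[int, list[str]],
    min_reads: int = NOVEL_MIN_READS,
    pooled: bool = False,
    fold_p_threshold: float = 0.01,
) -> list[int]:
    """Novel calls (candidate indices): not known, not structural ncRNA,
    >= min_reads in at least one library (or pooled across libraries
    when pooled=True), hairpin already accepted, and fold p-value below
    threshold for sense-exon candidates."""
    out = []
    for i, cand in enumerate(candidates):
        if i in known:
            continue
        if cand.category in ("ncrna_discard", "known_mirna"):
            continue
        per_lib: dict[str, int] = {}
        for m in cand.locus.members:
            for lib, n in m.counts.items():
                per_lib[lib] = per_lib.get(lib, 0) + n
        enough = (
            sum(per_lib.values()) >= min_reads
            if pooled
            else any(n >= min_reads for n in per_lib.values())
        )
        if not enough:
            continue
        if cand.requires_fold_pvalue:
            if cand.fold_pvalue is None or not cand.fold_pvalue < fold_p_threshold:
                continue
        out.append(i)
    return out


# ---------------------------------------------------------------------------
# isoforms


def refine_isoforms(cand: CandidateLocus, tag_seqs: dict[str, str]) -> dict:
    """Dominant isoform per arm, end-offset histograms, arm dominance.

    The dominant isoform per arm is the highest-count member tag (ties:
    longest, then 5'-most); offsets are member 5'/3' end positions
    relative to the dominant isoform in transcript orientation.
    """
    hp = cand.hairpin
    loop_mid = sum(hp.loop_span) / 2 if hp.loop_span else len(hp.precursor_seq) / 2

    arms: dict[str, list] = {"5p": [], "3p": []}
    for m in cand.locus.members:
        if hp.strand == "+":
            lo, hi = m.start - hp.g_start, m.end - hp.g_start
        else:
            lo, hi = hp.g_end - m.end, hp.g_end - m.start
        arm = "5p" if (lo + hi) / 2 < loop_mid else "3p"
        arms[arm].append((m, lo, hi))

    result: dict = {"dominant": {}, "offsets": {}, "arm_reads": {}}
    for arm, entries in arms.items():
        result["arm_reads"][arm] = sum(m.total for m, _, _ in entries)
        if not entries:
            continue
        dom, dlo, dhi = min(
            entries, key=lambda e: (-e[0].total, -(e[2] - e[1]), e[1])
        )
        result["dominant"][arm] = tag_seqs.get(dom.tag_id, "")
        off5: dict[int, int] = {}
        off3: dict[int, int] = {}
        for m, lo, hi in entries:
            off5[lo - dlo] = off5.get(lo - dlo, 0) + m.total
            off3[hi - dhi] = off3.get(hi - dhi, 0) + m.total
        result["offsets"][arm] = {"5p": off5, "3p": off3}
    r5, r3 = result["arm_reads"]["5p"], result["arm_reads"]["3p"]
    result["arm_dominance_5p_over_3p"] = r5 / r3 if r3 else float("inf")
    return result


def arm_of_span(hp: HairpinCandidate, span: tuple[int, int]) -> str:
    loop_mid = sum(hp.loop_span) / 2 if hp.loop_span else len(hp.precursor_seq) / 2
    return "5p" if sum(span) / 2 < loop_mid else "3p"


# ---------------------------------------------------------------------------
# clusters / paralogs / conservation / antisense / context


def detect_clusters(
    loci: Sequence[MiRNALocus],
    max_gap: int = CLUSTER_MAX_GAP,
    same_strand: bool = True,
) -> list[Cluster]:
    """Single-linkage chaining of loci with inter-precursor gap < max_gap
    (strict) on the same chromosome (and strand, by default); singletons
    are not clusters."""
    keyed = sorted(
        loci, key=lambda l: (l.chrom, l.strand if same_strand else "", l.start)
    )
    clusters: list[Cluster] = []
    chain: list[MiRNALocus] = []

    def flush():
        if len(chain) >= 2:
            gaps = [
                chain[i + 1].start - chain[i].end for i in range(len(chain) - 1)
            ]
            clusters.append(
                Cluster(
                    members=[l.name for l in chain],
                    chrom=chain[0].chrom,
                    start=chain[0].start,
                    end=chain[-1].end,
                    strand=chain[0].strand if same_strand else ".",
                    max_gap=max(gaps),
                )
            )

    for locus in keyed:
        if chain and (
            locus.chrom != chain[-1].chrom
            or (same_strand and locus.strand != chain[-1].strand)
            or locus.start - chain[-1].end >= max_gap
        ):
            flush()
            chain = []
        chain.append(locus)
    flush()
    return clusters


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def group_paralogs(
    loci: Sequence[MiRNALocus],
    max_mismatch: int = PARALOG_MAX_MISMATCH,
) -> list[ParalogGroup]:
    """Union-find over pairs whose mature-vs-mature or mature-vs-star
    best-overlap distance is <= max_mismatch; emits groups of size >= 2."""
    uf = _UnionFind(l.name for l in loci)
    for i, a in enumerate(loci):
        for b in loci[i + 1 :]:
            if _paralogous(a, b, max_mismatch):
                uf.union(a.name, b.name)
    groups: dict[str, list[MiRNALocus]] = {}
    for l in loci:
        groups.setdefault(uf.find(l.name), []).append(l)
    out = []
    for members in groups.values():
        if len(members) < 2:
            continue
        rep = max(members, key=lambda l: sum(l.mature_counts.values()))
        out.append(
            ParalogGroup(
                members=sorted(l.name for l in members),
                representative_mature=rep.mature_seq,
            )
        )
    out.sort(key=lambda g: g.members)
    return out


def _paralogous(a: MiRNALocus, b: MiRNALocus, max_mismatch: int) -> bool:
    pairs = [(a.mature_seq, b.mature_seq)]
    if b.star_seq:
        pairs.append((a.mature_seq, b.star_seq))
    if a.star_seq:
        pairs.append((a.star_seq, b.mature_seq))
    return any(
        x and y and seq_match(x, y, max_mismatch=max_mismatch, max_shift=3)
        for x, y in pairs
    )


def classify_conservation(
    locus: MiRNALocus,
    reference_matures: Sequence[tuple[str, str]],
    taxon_map: dict[str, str] | None = None,
    max_mismatch: int = 2,
) -> ConservationCall:
    """Conservation tier from reference matches within <= max_mismatch.

    inv-ver when matches span an invertebrate (insects included) and a
    vertebrate; inv when a non-insect invertebrate matches; ins when a
    non-silkworm insect matches; otherwise sw (silkworm-only).
    """
    taxa = taxon_map or DEFAULT_TAXON_MAP
    matched: list[str] = []
    groups: set[str] = set()
    for name, seq in reference_matures:
        sp = reference_species(name)
        if sp not in taxa:
            raise ValueError(f"species tag {sp!r} missing from taxon map")
        if seq_match(locus.mature_seq, seq, max_mismatch=max_mismatch, max_shift=3):
            matched.append(name)
            groups.add(taxa[sp])
    invertebrate = bool({"insect", "invertebrate"} & groups)
    if invertebrate and "vertebrate" in groups:
        tier = "inv-ver"
    elif "invertebrate" in groups:
        tier = "inv"
    elif "insect" in groups:
        tier = "ins"
    else:
        tier = "sw"
    return ConservationCall(locus.name, tier, matched)


def detect_sense_antisense(
    loci: Sequence[MiRNALocus], min_reciprocal_overlap: float = 0.5
) -> list[tuple[str, str]]:
    """Pairs of precursor loci overlapping reciprocally >= 50% on
    opposite strands."""
    pairs = []
    for i, a in enumerate(loci):
        for b in loci[i + 1 :]:
            if a.chrom != b.chrom or a.strand == b.strand:
                continue
            overlap = min(a.end, b.end) - max(a.start, b.start)
            if overlap <= 0:
                continue
            if (
                overlap >= min_reciprocal_overlap * (a.end - a.start)
                and overlap >= min_reciprocal_overlap * (b.end - b.start)
            ):
                pairs.append((a.name, b.name))
    return pairs


def genomic_context(
    loci: Sequence[MiRNALocus], annotations: AnnotationSet
) -> None:
    """Set each locus's context by precursor overlap with priority
    te (repeat) > exonic > intronic > intergenic."""
    priority = {"repeat": 0, "exon": 1, "intron": 2}
    label = {"repeat": "te", "exon": "exonic", "intron": "intronic"}
    for locus in loci:
        hits = [
            a.feature_class
            for a in annotations.overlapping(locus.chrom, locus.start, locus.end)
            if a.feature_class in priority
        ]
        locus.context = (
            label[min(hits, key=priority.__getitem__)] if hits else "intergenic"
        )


# ---------------------------------------------------------------------------
# assembly


def build_catalog(
    candidates: Sequence[CandidateLocus],
    reference_matures: Sequence[tuple[str, str]],
    annotations: AnnotationSet,
    tag_seqs: dict[str, str],
    pooled_novel: bool = False,
) -> list[MiRNALocus]:
    """Known/novel calls -> named MiRNALocus records with isoform detail."""
    known = match_known(candidates, reference_matures, annotations)
    novel = call_novel(candidates, known, pooled=pooled_novel)
    accepted = [(i, "known") for i in known] + [(i, "novel") for i in novel]
    accepted.sort(key=lambda t: (candidates[t[0]].hairpin.chrom,
                                 candidates[t[0]].hairpin.g_start))
    loci: list[MiRNALocus] = []
    n_novel = 0
    for i, status in accepted:
        cand = candidates[i]
        hp = cand.hairpin
        if status == "known":
            name = known[i][0]
        else:
            n_novel += 1
            name = f"nov-mir-{n_novel}"
        counts = locus_read_counts(cand)
        iso = refine_isoforms(cand, tag_seqs)
        mature_arm = arm_of_span(hp, hp.mature_span)
        dominant_mature = iso["dominant"].get(mature_arm, "")
        max_arm = max(iso["arm_reads"], key=iso["arm_reads"].__getitem__)
        locus = MiRNALocus(
            name=name,
            chrom=hp.chrom,
            start=hp.g_start,
            end=hp.g_end,
            strand=hp.strand,
            status=status,
            mature_seq=transcribe(dominant_mature) or hp.mature_seq,
            star_seq=hp.star_seq,
            mature_counts=counts["mature"],
            star_counts=counts["star"],
            loop_counts=counts["loop"],
            dominant_isoform={
                arm: transcribe(s) for arm, s in iso["dominant"].items()
            },
            arm_switch=(status == "known" and max_arm != mature_arm
                        and iso["arm_reads"][max_arm] > 0),
            matched_reference=known.get(i, []),
            hairpin=hp,
        )
        loci.append(locus)
    # duplicated names (paralogous loci of one known gene) get -1/-2 suffixes
    seen: dict[str, int] = {}
    for locus in loci:
        seen[locus.name] = seen.get(locus.name, 0) + 1
    counters: dict[str, int] = {}
    for locus in loci:
        if seen[locus.name] > 1:
            counters[locus.name] = counters.get(locus.name, 0) + 1
            locus.name = f"{locus.name}-{counters[locus.name]}"
    genomic_context(loci, annotations)
    return loci
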
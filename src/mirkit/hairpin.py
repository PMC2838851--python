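"""Hairpin discovery core: pileup loci, precursor excision, duplex
geometry, and the structural filter.

Candidate Drosha/Dicer products are taken from read pileups: overlapping
same-strand tag alignments merge into loci, the most abundant member is
the mature guess, and two candidate precursors are excised around it
(10 nt upstream / 70 nt downstream, and the converse), mirroring the
two-sided excision used by mireap-era discovery pipelines.  Each
precursor is folded at its MFE and must satisfy, jointly:

* folding energy <= -25 kcal/mol,
* mature and star on different arms, each with <= 6 unpaired bases,
* largest bulge in the duplex <= 4 nt,
* duplex asymmetry (|unpaired mature - unpaired star|) <= 3,
* 2-nt-style 3' overhangs at both duplex ends - required only when star
  reads were actually sequenced, since without an observed star the
  overhang is inferred by convention rather than measured.

The star span is the pairing partner of the mature under the MFE
structure, shifted to leave 2-nt 3' overhangs on both strands (the Dicer
convention); when star-arm reads exist, the observed star span replaces
the inferred one, so the overhang test measures read geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._seq import revcomp, transcribe
from .fold import FoldEngine, fold, pair_table
from .mapping import TagAlignment
from .preprocess import Tag

MFE_THRESHOLD = -25.0
MAX_UNPAIRED = 6
MAX_BULGE = 4
MAX_ASYMMETRY = 3
MIN_PRECURSOR_LEN = 40
WINDOW_NEAR = 10
WINDOW_FAR = 70
DEFAULT_MAX_LOCUS_SPAN = 200


class DuplexError(ValueError):
    """Raised when no mature/star duplex exists (e.g. loop-spanning mature)."""


@dataclass
class PileupMember:
    tag_id: str
    start: int
    end: int
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class PileupLocus:
    chrom: str
    strand: str
    start: int
    end: int
    members: list[PileupMember]

    @property
    def mature_guess(self) -> PileupMember:
        """Highest-count member; ties break to the 5'-most start on the
        locus strand, then lexicographic tag id."""
        if self.strand == "+":
            key = lambda m: (-m.total, m.start, m.tag_id)
        else:
            key = lambda m: (-m.total, -m.end, m.tag_id)
        return min(self.members, key=key)


@dataclass
class DuplexMetrics:
    unpaired_mature: int
    unpaired_star: int
    max_bulge: int
    asymmetry: int
    overhang_3p_both: bool


@dataclass
class HairpinCandidate:
    chrom: str
    strand: str
    window: str  # "up10_down70" | "up70_down10"
    g_start: int
    g_end: int
    precursor_seq: str  # RNA, 5'->3' transcript orientation
    mature_span: tuple[int, int]  # within precursor
    clipped: bool = False
    structure: str | None = None
    mfe: float | None = None
    star_span: tuple[int, int] | None = None
    loop_span: tuple[int, int] | None = None
    duplex: DuplexMetrics | None = None
    fold_pvalue: float | None = None
    passed: bool | None = None
    reasons: list[str] = field(default_factory=list)

    @property
    def mature_seq(self) -> str:
        return self.precursor_seq[self.mature_span[0] : self.mature_span[1]]

    @property
    def star_seq(self) -> str | None:
        if self.star_span is None:
            return None
        lo, hi = self.star_span
        return self.precursor_seq[max(lo, 0) : hi]


# ---------------------------------------------------------------------------
# pileups


def call_pileups(
    alignments: Sequence[TagAlignment],
    tags: Sequence[Tag],
    max_locus_span: int = DEFAULT_MAX_LOCUS_SPAN,
) -> list[PileupLocus]:
    """Merge overlapping same-strand alignments into loci by one linear
    sweep; loci longer than max_locus_span are split at the deepest
    coverage minimum (recursively)."""
    counts = {t.tag_id: t.counts for t in tags}
    groups: dict[tuple[str, str], list[TagAlignment]] = {}
    for a in alignments:
        groups.setdefault((a.chrom, a.strand), []).append(a)
    loci: list[PileupLocus] = []
    for (chrom, strand), aligns in sorted(groups.items()):
        aligns.sort(key=lambda a: (a.start, a.end))
        block: list[TagAlignment] = []
        block_end = -1
        for a in aligns:
            if block and a.start >= block_end:
                loci.extend(_emit_locus(chrom, strand, block, counts, max_locus_span))
                block = []
            block.append(a)
            block_end = max(block_end, a.end)
        if block:
            loci.extend(_emit_locus(chrom, strand, block, counts, max_locus_span))
    loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
    return loci


def _emit_locus(chrom, strand, block, counts, max_locus_span) -> list[PileupLocus]:
    start = min(a.start for a in block)
    end = max(a.end for a in block)
    if end - start > max_locus_span and len(block) > 1:
        # split at the deepest (leftmost) coverage minimum in the interior
        cov = [0] * (end - start)
        for a in block:
            for i in range(a.start - start, a.end - start):
                cov[i] += 1
        interior = cov[1:-1]
        cut = start + 1 + interior.index(min(interior))
        left = [a for a in block if a.start < cut]
        right = [a for a in block if a.start >= cut]
        if left and right:
            return _emit_locus(
                chrom, strand, left, counts, max_locus_span
            ) + _emit_locus(chrom, strand, right, counts, max_locus_span)
    members = [
        PileupMember(a.tag_id, a.start, a.end, counts.get(a.tag_id, {}))
        for a in block
    ]
    return [PileupLocus(chrom, strand, start, end, members)]


# ---------------------------------------------------------------------------
# excision


def excise(
    locus: PileupLocus,
    genome: dict[str, str],
    near: int = WINDOW_NEAR,
    far: int = WINDOW_FAR,
) -> tuple[HairpinCandidate, HairpinCandidate]:
    """Excise the two candidate precursors around the mature guess:
    near nt upstream/far nt downstream and the converse, in transcript
    orientation; windows are clipped at chromosome ends (flagged)."""
    mature = locus.mature_guess
    chrom_seq = genome[locus.chrom]
    out = []
    for window, (up, down) in (
        ("up10_down70", (near, far)),
        ("up70_down10", (far, near)),
    ):
        if locus.strand == "+":
            g_start, g_end = mature.start - up, mature.end + down
        else:  # upstream is genomic-right on the minus strand
            g_start, g_end = mature.start - down, mature.end + up
        clipped = g_start < 0 or g_end > len(chrom_seq)
        g_start, g_end = max(g_start, 0), min(g_end, len(chrom_seq))
        dna = chrom_seq[g_start:g_end]
        if locus.strand == "-":
            dna = revcomp(dna)
            m_span = (g_end - mature.end, g_end - mature.start)
        else:
            m_span = (mature.start - g_start, mature.end - g_start)
        out.append(
            HairpinCandidate(
                chrom=locus.chrom,
                strand=locus.strand,
                window=window,
                g_start=g_start,
                g_end=g_end,
                precursor_seq=transcribe(dna),
                mature_span=m_span,
                clipped=clipped,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# duplex geometry


def duplex_metrics(
    candidate: HairpinCandidate,
    observed_star_span: tuple[int, int] | None = None,
) -> DuplexMetrics:
    """Compute duplex metrics and set candidate.star_span / loop_span.

    Star span defaults to the mature's pairing-partner interval shifted
    by 2 nt to leave 3' overhangs on both strands; an observed star span
    (from actual star-arm reads, precursor coordinates) overrides it.
    The 3'-overhang flag measures positional protrusion of each 3' end
    past the partner of the other strand's outermost paired base, so it
    reflects duplex geometry even when flanking helices pair the
    terminal bases themselves.
    """
    if candidate.structure is None:
        raise ValueError("candidate must be folded first")
    pt = pair_table(candidate.structure)
    a, b = candidate.mature_span
    a, b = max(a, 0), min(b, len(pt))
    paired = [i for i in range(a, b) if pt[i] >= 0]
    if not paired:
        raise DuplexError("no-duplex")
    partners = [pt[i] for i in paired]
    if any(a <= p < b for p in partners):
        raise DuplexError("loop-spanning")
    if not (all(p >= b for p in partners) or all(p < a for p in partners)):
        raise DuplexError("loop-spanning")
    plo, phi = min(partners), max(partners)
    if observed_star_span is not None:
        s_lo, s_hi = observed_star_span
    else:
        s_lo, s_hi = plo + 2, phi + 3
    s_lo, s_hi = max(s_lo, 0), min(s_hi, len(pt))
    candidate.star_span = (s_lo, s_hi)
    if phi < a:  # star on the 5' arm, mature on the 3' arm
        candidate.loop_span = (phi + 1, min(i for i in paired))
    else:
        candidate.loop_span = (max(i for i in paired) + 1, plo)

    unpaired_m = sum(1 for i in range(a, b) if pt[i] == -1)
    unpaired_s = sum(1 for i in range(s_lo, s_hi) if pt[i] == -1)

    max_bulge = max(
        _longest_interior_gap(pt, a, b), _longest_interior_gap(pt, s_lo, s_hi)
    )
    asymmetry = abs(unpaired_m - unpaired_s)

    # positional 3' protrusion of each strand past the duplex
    m_partners_in_star = [pt[i] for i in range(s_lo, s_hi) if a <= pt[i] < b]
    s_partners_in_mature = [pt[i] for i in range(a, b) if s_lo <= pt[i] < s_hi]
    if m_partners_in_star and s_partners_in_mature:
        m_protrusion = (b - 1) - max(m_partners_in_star)
        s_protrusion = (s_hi - 1) - max(s_partners_in_mature)
        overhang = m_protrusion >= 1 and s_protrusion >= 1
    else:
        overhang = False

    metrics = DuplexMetrics(unpaired_m, unpaired_s, max_bulge, asymmetry, overhang)
    candidate.duplex = metrics
    return metrics


def _longest_interior_gap(pt: list[int], lo: int, hi: int) -> int:
    """Longest run of unpaired bases strictly between paired bases of the
    span (terminal overhangs are not bulges)."""
    best = run = 0
    seen_paired = False
    for i in range(lo, hi):
        if pt[i] == -1:
            run += 1
        else:
            if seen_paired:
                best = max(best, run)
            seen_paired = True
            run = 0
    return best


# ---------------------------------------------------------------------------
# the filter


def structural_filter(
    candidate: HairpinCandidate,
    reads_on_star: bool,
    mfe_threshold: float = MFE_THRESHOLD,
    max_unpaired: int = MAX_UNPAIRED,
    max_bulge: int = MAX_BULGE,
    max_asymmetry: int = MAX_ASYMMETRY,
) -> tuple[bool, list[str]]:
    """Apply the precursor filter; every failed criterion is reported.

    All thresholds are inclusive bounds (mfe <= -25.0; unpaired <= 6;
    bulge <= 4; asymmetry <= 3); the 3'-overhang requirement applies
    only when star reads were sequenced.
    """
    reasons: list[str] = []
    if len(candidate.precursor_seq) < MIN_PRECURSOR_LEN:
        reasons.append("short-precursor")
    if candidate.mfe is None or candidate.mfe > mfe_threshold:
        reasons.append("energy")
    d = candidate.duplex
    if d is None:
        reasons.append("no-duplex")
    else:
        if d.unpaired_mature > max_unpaired or d.unpaired_star > max_unpaired:
            reasons.append("unpaired")
        if d.max_bulge > max_bulge:
            reasons.append("bulge")
        if d.asymmetry > max_asymmetry:
            reasons.append("asymmetry")
        if reads_on_star and not d.overhang_3p_both:
            reasons.append("overhang")
    passed = not reasons
    candidate.passed = passed
    candidate.reasons = reasons
    return passed, reasons


def select_precursor(
    cand_a: HairpinCandidate, cand_b: HairpinCandidate
) -> HairpinCandidate | None:
    """The passing candidate; if both pass, the lower MFE (tie: the
    up10_down70 window); None when both fail (reasons merged onto a)."""
    a_pass, b_pass = bool(cand_a.passed), bool(cand_b.passed)
    if a_pass and b_pass:
        if (cand_b.mfe, cand_b.window != "up10_down70") < (
            cand_a.mfe,
            cand_a.window != "up10_down70",
        ):
            return cand_b
        return cand_a
    if a_pass:
        return cand_a
    if b_pass:
        return cand_b
    cand_a.reasons = sorted(set(cand_a.reasons) | set(cand_b.reasons))
    return None


# ---------------------------------------------------------------------------
# per-locus evaluation


def _member_span_in_precursor(
    member: PileupMember, cand: HairpinCandidate
) -> tuple[int, int]:
    if cand.strand == "+":
        return member.start - cand.g_start, member.end - cand.g_start
    return cand.g_end - member.end, cand.g_end - member.start


def _observed_star(
    locus: PileupLocus, cand: HairpinCandidate
) -> tuple[tuple[int, int] | None, bool]:
    """Best star-arm read span: the highest-count member overlapping the
    inferred star span by >= 50% of its length, excluding the mature."""
    if cand.star_span is None:
        return None, False
    s_lo, s_hi = cand.star_span
    mature = locus.mature_guess
    best = None
    for m in locus.members:
        if m.tag_id == mature.tag_id and m.start == mature.start:
            continue
        lo, hi = _member_span_in_precursor(m, cand)
        overlap = min(hi, s_hi) - max(lo, s_lo)
        if overlap >= 0.5 * (hi - lo):
            if best is None or m.total > best[0].total:
                best = (m, (lo, hi))
    if best is None:
        return None, False
    return best[1], True


def evaluate_locus(
    locus: PileupLocus,
    genome: dict[str, str],
    engine: FoldEngine | None = None,
    mfe_threshold: float = MFE_THRESHOLD,
) -> tuple[HairpinCandidate | None, tuple[HairpinCandidate, HairpinCandidate]]:
    """Excise, fold and filter both candidate precursors for one locus.

    Returns (selected_candidate_or_None, (cand_a, cand_b)).
    """
    cand_a, cand_b = excise(locus, genome)
    for cand in (cand_a, cand_b):
        if len(cand.precursor_seq) < MIN_PRECURSOR_LEN:
            cand.passed = False
            cand.reasons = ["short-precursor"]
            continue
        cand.structure, cand.mfe = fold(cand.precursor_seq, engine=engine)
        try:
            duplex_metrics(cand)  # infer star span from structure
        except DuplexError as err:
            cand.passed = False
            cand.reasons = [str(err)]
            continue
        star_span, reads_on_star = _observed_star(locus, cand)
        if reads_on_star:
            try:
                duplex_metrics(cand, observed_star_span=star_span)
            except DuplexError as err:
                cand.passed = False
                cand.reasons = [str(err)]
                continue
        structural_filter(cand, reads_on_star, mfe_threshold=mfe_threshold)
    return select_precursor(cand_a, cand_b), (cand_a, cand_b)
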
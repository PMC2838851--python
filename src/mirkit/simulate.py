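"""Synthetic small-RNA-seq data with a ground-truth manifest.

The simulator builds a toy genome carrying planted miRNA hairpins
(mature + 8-15 nt loop + near-reverse-complement star arm with a built-in
2-nt 3' overhang geometry and up to 2 engineered mismatches), hairpins
embedded in annotated transposable elements, rRNA/tRNA decoy loci, gene
models with exon/intron structure, and intergenic noise regions.  Reads
emulate a Solexa-style library: 35-nt raw reads consisting of an insert
plus the 3' adapter, negative-binomially distributed per-locus counts
(mean 40, dispersion 0.5 - few dominant loci, many rare ones), 5'/3'
end-shifted mature isoforms with more 3' than 5' heterogeneity, sparse
star and loop reads, uniformly positioned degradation fragments from
decoys, substitution errors, low-quality reads and 5'-adapter ligation
contaminants.

Every planted hairpin is verified with the pipeline's own folding engine
to reach the -25 kcal/mol precursor bar (the loop/mature are redesigned
on failure), so planted loci are discoverable by construction and the
manifest can state each locus's expected pipeline outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import gc_fraction, revcomp, transcribe
from .annotate import Annotation, AnnotationSet
from .fold import FoldEngine, fold
from .hairpin import (
    DuplexError,
    HairpinCandidate,
    duplex_metrics,
    structural_filter,
)

ADAPTER3_DNA = "TCGTATGCCGTCTTCTGCTTG"  # 3' RNA adapter, DNA alphabet
ADAPTER5_DNA = "GTTCAGAGTTCTACAGTCCGACGATC"  # 5' RNA adapter, DNA alphabet

FEATURE_CLASSES = (
    "true_mirna",
    "te_mirna",
    "rrna_decoy",
    "trna_decoy",
    "exon_fragment",
    "intergenic_noise",
)

TIER_CYCLE = ("inv-ver", "inv", "ins", "sw")


class SimSizeError(ValueError):
    """Chromosomes too short to host the requested features."""


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 100_000
    n_true_mirnas: int = 30
    n_te_mirnas: int = 10
    n_decoy_ncrna: int = 20
    n_gene_models: int = 8
    n_noise_loci: int = 5
    n_antisense_pairs: int = 0
    mature_len_range: tuple[int, int] = (20, 23)
    # per-locus per-library total read count ~ NB(mean, dispersion)
    count_mean: float = 40.0
    count_dispersion: float = 0.5
    decoy_count_mean: float = 30.0
    # end-shift offset -> probability; 3' ends are more heterogeneous
    end_shift_probs_5p: dict[int, float] = field(
        default_factory=lambda: {-2: 0.01, -1: 0.04, 0: 0.90, 1: 0.04, 2: 0.01}
    )
    end_shift_probs_3p: dict[int, float] = field(
        default_factory=lambda: {-2: 0.05, -1: 0.15, 0: 0.60, 1: 0.15, 2: 0.05}
    )
    star_fraction: float = 0.05
    loop_read_rate: float = 0.01
    error_rate: float = 0.005
    adapter3: str = ADAPTER3_DNA
    adapter5: str = ADAPTER5_DNA
    raw_read_len: int = 35
    lowq_fraction: float = 0.10
    contaminant5_fraction: float = 0.02
    min_mean_quality: float = 20.0  # shared definition with preprocess
    known_fraction: float = 0.4  # planted true miRNAs entered as bmo references

    def validate(self) -> None:
        for name in (
            "star_fraction",
            "loop_read_rate",
            "error_rate",
            "lowq_fraction",
            "contaminant5_fraction",
            "known_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("end_shift_probs_5p", "end_shift_probs_3p"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1) > 1e-9:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        lo, hi = self.mature_len_range
        if not (18 <= lo <= hi <= 30):
            raise ValueError("mature_len_range must lie within [18, 30]")
        max_insert = hi + 4  # longest end-shifted mature isoform
        if self.raw_read_len < max_insert + 4:
            raise ValueError("raw_read_len must be >= max insert + 4")


@dataclass
class TruthRecord:
    locus_id: str
    chrom: str
    start: int  # precursor/locus interval, 0-based half-open, + strand coords
    end: int
    strand: str
    feature_class: str
    mature_seq: str = ""  # DNA, transcript orientation
    star_seq: str = ""
    expected_call: str = "rejected"  # known | novel | rejected
    tier: str = ""
    known: bool = False
    emit_star: bool = True  # antisense partners do not emit star reads
    mature_start: int = -1  # genomic mature/star spans for read emission
    mature_end: int = -1
    star_start: int = -1
    star_end: int = -1
    reads: dict[str, int] = field(default_factory=dict)
    clean_reads: dict[str, int] = field(default_factory=dict)


@dataclass
class GroundTruth:
    records: list[TruthRecord]

    def by_class(self, *classes: str) -> list[TruthRecord]:
        return [r for r in self.records if r.feature_class in classes]

    def to_tsv(self, path) -> None:
        rows = []
        for r in self.records:
            d = asdict(r)
            d["reads"] = ";".join(f"{k}={v}" for k, v in sorted(r.reads.items()))
            d["clean_reads"] = ";".join(
                f"{k}={v}" for k, v in sorted(r.clean_reads.items())
            )
            rows.append(d)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    quality: list[int]
    locus_id: str
    role: str  # mature | star | loop | fragment
    clean: bool
    insert: str
    chrom: str = ""
    start: int = -1
    end: int = -1
    strand: str = "+"


# ---------------------------------------------------------------------------
# reference construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _design_hairpin(
    rng: np.random.Generator,
    mature_len: int,
    engine: FoldEngine | None,
    mfe_threshold: float = -25.0,
    max_tries: int = 80,
) -> tuple[str, str, str, str]:
    """Design (precursor, mature, loop, star_arm) with MFE <= threshold.

    star_arm = revcomp(mature[:-2]) + 2-nt tail: the mature's last two
    bases stay unpaired against the loop and the star tail protrudes at
    the stem base, so the duplex carries 2-nt 3' overhangs on both
    strands.  Up to 2 engineered substitutions in the star interior add
    realistic mismatches.  The design is re-drawn until the fold engine
    confirms the energy bar.
    """
    for _ in range(max_tries):
        mature = _random_seq(rng, mature_len)
        if gc_fraction(mature) < 0.5:
            continue
        loop = _random_seq(rng, int(rng.integers(8, 16)))
        star = list(revcomp(mature[:-2]))
        for pos in rng.choice(
            range(2, len(star) - 2), size=int(rng.integers(0, 3)), replace=False
        ):
            choices = [c for c in "ACGT" if c != star[pos]]
            star[pos] = choices[int(rng.integers(3))]
        tail = _random_seq(rng, 2)
        star_arm = "".join(star) + tail
        precursor = mature + loop + star_arm
        _, mfe = fold(transcribe(precursor), engine=engine)
        if mfe <= mfe_threshold:
            return precursor, mature, loop, star_arm
    raise RuntimeError("failed to design a hairpin meeting the energy bar")


def _unique_strand(chrom_strs: dict[str, str], q: str, strand: str) -> bool:
    """True when transcript-oriented read q has no full-length match on
    the strand opposite its locus strand anywhere in the genome."""
    probe = revcomp(q) if strand == "+" else q
    return all(probe not in s for s in chrom_strs.values())


def _window_passes(
    context: str,
    p0: int,
    plen: int,
    mature_len: int,
    star_len: int,
    engine: FoldEngine | None,
    require_observed: bool = True,
) -> bool:
    """True when the 10-up/70-down window around the planted mature, in
    its genomic context, passes the structural filter both with the
    inferred star span (arms sequenced separately) and with the planted
    star span observed (3'-overhang test armed).

    ``context`` is transcript-oriented sequence with the precursor at
    [p0, p0+plen) and the mature at its 5' end.
    """
    m0, m1 = p0, p0 + mature_len
    if m0 < 10 or m1 + 70 > len(context):
        return False
    w = context[m0 - 10 : m1 + 70]
    cand = HairpinCandidate(
        "ctx", "+", "up10_down70", 0, len(w), transcribe(w), (10, 10 + mature_len)
    )
    cand.structure, cand.mfe = fold(cand.precursor_seq, engine=engine)
    star_span = (10 + plen - star_len, 10 + plen)
    try:
        duplex_metrics(cand)
        ok_inferred, _ = structural_filter(cand, reads_on_star=False)
        if not require_observed:
            return ok_inferred
        duplex_metrics(cand, observed_star_span=star_span)
        ok_observed, _ = structural_filter(cand, reads_on_star=True)
    except DuplexError:
        return False
    return ok_inferred and ok_observed


class _Placer:
    """Reserves non-overlapping intervals with padding on a toy genome."""

    def __init__(self, rng, chrom_names, chrom_length, pad=150):
        self.rng = rng
        self.chroms = list(chrom_names)
        self.length = chrom_length
        self.pad = pad
        self.used: dict[str, list[tuple[int, int]]] = {c: [] for c in self.chroms}

    def place(self, length: int, max_tries: int = 2000) -> tuple[str, int]:
        if length + 2 * self.pad > self.length:
            raise SimSizeError(
                f"feature of length {length} cannot fit a chromosome of "
                f"{self.length} nt with {self.pad} nt padding"
            )
        for _ in range(max_tries):
            chrom = self.chroms[int(self.rng.integers(len(self.chroms)))]
            start = int(self.rng.integers(self.pad, self.length - length - self.pad))
            lo, hi = start - self.pad, start + length + self.pad
            if all(hi <= s or lo >= e for s, e in self.used[chrom]):
                self.used[chrom].append((lo, hi))
                return chrom, start
        raise SimSizeError(
            f"could not reserve {length} nt after {max_tries} tries; "
            "chromosomes too crowded for the requested feature count"
        )


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    s = list(seq)
    if n_subs == 0:
        return seq
    for pos in rng.choice(len(s), size=n_subs, replace=False):
        choices = [c for c in "ACGT" if c != s[pos]]
        s[pos] = choices[int(rng.integers(3))]
    return "".join(s)


_TIER_SPECIES = {
    # tier -> foreign species entries to plant in the reference
    "inv-ver": ("dme", "hsa"),
    "inv": ("cel",),
    "ins": ("dme", "tca"),
    "sw": (),
}


def build_reference(
    config: SimConfig, engine: FoldEngine | None = None
) -> tuple[dict[str, str], AnnotationSet, list[tuple[str, str]], GroundTruth]:
    """Toy genome + annotations + reference mature FASTA + ground truth.

    Deterministic for a fixed config seed.  Raises SimSizeError when the
    chromosomes cannot host the requested features.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {c: list(_random_seq(rng, config.chrom_length)) for c in chrom_names}
    placer = _Placer(rng, chrom_names, config.chrom_length)
    annotations: list[Annotation] = []
    reference: list[tuple[str, str]] = []
    records: list[TruthRecord] = []

    def plant(chrom: str, start: int, seq: str) -> None:
        genome[chrom][start : start + len(seq)] = list(seq)

    # --- gene models (annotation only; sequence stays random) -------------
    exon_pool: list[tuple[str, int, int, str]] = []
    for g in range(config.n_gene_models):
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(150, 400, size=n_exons)
        intron_lens = rng.integers(300, 800, size=n_exons - 1)
        total = int(exon_lens.sum() + intron_lens.sum())
        chrom, start = placer.place(total)
        strand = "+" if rng.random() < 0.5 else "-"
        pos = start
        for i in range(n_exons):
            e_end = pos + int(exon_lens[i])
            annotations.append(
                Annotation(chrom, pos, e_end, strand, "exon", f"gene{g + 1}.e{i + 1}")
            )
            exon_pool.append((chrom, pos, e_end, strand))
            if i < n_exons - 1:
                i_end = e_end + int(intron_lens[i])
                annotations.append(
                    Annotation(
                        chrom, e_end, i_end, strand, "intron", f"gene{g + 1}.i{i + 1}"
                    )
                )
                pos = i_end

    # --- rRNA/tRNA decoys ---------------------------------------------------
    for d in range(config.n_decoy_ncrna):
        if d % 2 == 0:
            cls, ann_cls, length = "rrna_decoy", "rrna", int(rng.integers(800, 1500))
        else:
            cls, ann_cls, length = "trna_decoy", "trna", int(rng.integers(70, 90))
        chrom, start = placer.place(length)
        strand = "+" if rng.random() < 0.5 else "-"
        annotations.append(
            Annotation(chrom, start, start + length, strand, ann_cls, f"decoy{d + 1}")
        )
        records.append(
            TruthRecord(
                locus_id=f"decoy{d + 1}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand=strand,
                feature_class=cls,
            )
        )

    # --- true / TE-embedded miRNA hairpins ---------------------------------
    n_total_mirna = config.n_true_mirnas + config.n_te_mirnas
    n_known = round(config.known_fraction * config.n_true_mirnas)
    known_flags = [i < n_known for i in range(config.n_true_mirnas)]
    rng.shuffle(known_flags)

    lo_len, hi_len = config.mature_len_range
    reserved = 2 * hi_len + 15 + 2  # longest possible precursor

    def plant_verified(chrom: str, start: int, strand: str) -> tuple[str, str, str]:
        """Design, plant and verify a hairpin at a fixed spot; redesigns
        until the genomic 10/70 window around the mature passes the
        structural filter (planted miRNAs must be discoverable)."""
        for _ in range(60):
            mature_len = int(rng.integers(lo_len, hi_len + 1))
            precursor, mature, loop, star_arm = _design_hairpin(
                rng, mature_len, engine
            )
            plant(chrom, start, _random_seq(rng, reserved))  # fresh background
            written = precursor if strand == "+" else revcomp(precursor)
            plant(chrom, start, written)
            end = start + len(precursor)
            ctx0, ctx1 = max(start - 80, 0), min(end + 80, config.chrom_length)
            context = "".join(genome[chrom][ctx0:ctx1])
            if strand == "-":
                context = revcomp(context)
                p0 = ctx1 - end
            else:
                p0 = start - ctx0
            if not _window_passes(
                context, p0, len(precursor), len(mature), len(star_arm), engine
            ):
                continue
            # every read this locus will emit must map only to its own
            # strand: junction coincidences can otherwise give a star or
            # isoform read a full-length antisense match, conjuring a
            # phantom opposite-strand locus
            plen, mlen, slen = len(precursor), len(mature), len(star_arm)
            queries = [
                context[p0 + o5 : p0 + mlen + o3]
                for o5 in range(-2, 3)
                for o3 in range(-2, 3)
            ]
            queries.append(star_arm)
            queries.append(context[p0 + mlen - 5 : p0 + plen - slen + 5])
            chrom_strs = {c: "".join(s) for c, s in genome.items()}
            if all(_unique_strand(chrom_strs, q, strand) for q in queries):
                return precursor, mature, star_arm
        raise RuntimeError("failed to plant a discoverable hairpin")

    def plant_mirna(idx: int, te: bool, tier: str, known: bool) -> TruthRecord:
        if te:
            te_len = int(rng.integers(500, 1500))
            chrom, te_start = placer.place(te_len)
            offset = int(rng.integers(50, te_len - reserved - 50))
            start = te_start + offset
            annotations.append(
                Annotation(
                    chrom, te_start, te_start + te_len, "+", "repeat", f"TE{idx + 1}"
                )
            )
        else:
            chrom, start = placer.place(reserved)
        strand = "+" if rng.random() < 0.5 else "-"
        precursor, mature, star_arm = plant_verified(chrom, start, strand)
        end = start + len(precursor)
        # genomic spans of mature/star in + strand coordinates
        if strand == "+":
            m_start, m_end = start, start + len(mature)
            s_start, s_end = end - len(star_arm), end
        else:
            m_start, m_end = end - len(mature), end
            s_start, s_end = start, start + len(star_arm)
        locus_id = f"temir{idx + 1}" if te else f"mir{idx + 1}"
        rec = TruthRecord(
            locus_id=locus_id,
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            feature_class="te_mirna" if te else "true_mirna",
            mature_seq=mature,
            star_seq=star_arm,
            tier=tier,
            known=known,
            mature_start=m_start,
            mature_end=m_end,
            star_start=s_start,
            star_end=s_end,
        )
        if known:
            reference.append((f"bmo-miR-sim{idx + 1}", transcribe(mature)))
            annotations.append(
                Annotation(
                    chrom, start, end, strand, "known_mirna", f"bmo-mir-sim{idx + 1}"
                )
            )
        for sp_i, sp in enumerate(_TIER_SPECIES[tier]):
            n_subs = int(rng.integers(0, 3))
            reference.append(
                (
                    f"{sp}-miR-sim{idx + 1}{chr(97 + sp_i)}",
                    transcribe(_mutate(rng, mature, n_subs)),
                )
            )
        return rec

    for i in range(n_total_mirna):
        te = i >= config.n_true_mirnas
        tier = TIER_CYCLE[i % len(TIER_CYCLE)]
        known = known_flags[i] if not te else False
        records.append(plant_mirna(i, te, tier, known))

    # --- planted antisense hairpin pairs ------------------------------------
    for p in range(config.n_antisense_pairs):
        chrom, start = placer.place(reserved)
        for _ in range(200):
            mature_len = int(rng.integers(lo_len, hi_len + 1))
            precursor, mature, loop, star_arm = _design_hairpin(
                rng, mature_len, engine
            )
            plant(chrom, start, _random_seq(rng, reserved))
            plant(chrom, start, precursor)
            end = start + len(precursor)
            ctx0, ctx1 = max(start - 80, 0), min(end + 80, config.chrom_length)
            context = "".join(genome[chrom][ctx0:ctx1])
            sense_ok = _window_passes(
                context, start - ctx0, len(precursor), len(mature),
                len(star_arm), engine,
            )
            # the mirrored duplex carries 5' overhangs, so the antisense
            # locus is verified (and later read-simulated) without star
            # reads; its own mature still must pass the inferred filter
            anti_ok = _window_passes(
                revcomp(context), ctx1 - end, len(precursor), len(star_arm),
                len(mature), engine, require_observed=False,
            )
            if sense_ok and anti_ok:
                break
        else:
            raise RuntimeError("failed to plant a discoverable antisense pair")
        records.append(
            TruthRecord(
                locus_id=f"asp{p + 1}s",
                chrom=chrom,
                start=start,
                end=end,
                strand="+",
                feature_class="true_mirna",
                mature_seq=mature,
                star_seq=star_arm,
                tier="sw",
                mature_start=start,
                mature_end=start + len(mature),
                star_start=end - len(star_arm),
                star_end=end,
            )
        )
        # the antisense locus: the - strand of the same interval also folds
        # into a hairpin whose 5' arm is revcomp(star_arm)
        records.append(
            TruthRecord(
                locus_id=f"asp{p + 1}a",
                chrom=chrom,
                start=start,
                end=end,
                strand="-",
                feature_class="true_mirna",
                emit_star=False,
                mature_seq=revcomp(star_arm),
                star_seq=revcomp(mature),
                tier="sw",
                mature_start=end - len(star_arm),
                mature_end=end,
                star_start=start,
                star_end=start + len(mature),
            )
        )

    # --- exon-fragment and intergenic-noise emitters -------------------------
    rng.shuffle(exon_pool)
    for i, (chrom, e_start, e_end, strand) in enumerate(
        exon_pool[: min(len(exon_pool), config.n_gene_models)]
    ):
        records.append(
            TruthRecord(
                locus_id=f"exfrag{i + 1}",
                chrom=chrom,
                start=e_start,
                end=e_end,
                strand=strand,
                feature_class="exon_fragment",
            )
        )
    for i in range(config.n_noise_loci):
        length = int(rng.integers(100, 300))
        chrom, start = placer.place(length)
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            TruthRecord(
                locus_id=f"noise{i + 1}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand=strand,
                feature_class="intergenic_noise",
            )
        )

    genome_str = {c: "".join(s) for c, s in genome.items()}
    return (
        genome_str,
        AnnotationSet(annotations, source="mirkit-sim"),
        reference,
        GroundTruth(records),
    )


# ---------------------------------------------------------------------------
# read simulation


def _draw_offset(rng, probs: dict[int, float]) -> int:
    offsets = sorted(probs)
    return int(rng.choice(offsets, p=[probs[o] for o in offsets]))


def _insert_from_genome(genome, rec: TruthRecord, lo: int, hi: int) -> str:
    seq = genome[rec.chrom][lo:hi]
    return seq if rec.strand == "+" else revcomp(seq)


def simulate_reads(
    genome: dict[str, str],
    truth: GroundTruth,
    config: SimConfig,
    n_libraries: int = 3,
    library_ids: list[str] | None = None,
) -> tuple[dict[str, list[SimulatedRead]], pd.DataFrame]:
    """Simulate per-library FASTQ-ready reads from the planted loci.

    Also finalizes the manifest: per-library planted and clean
    (error-free, good-quality, uncontaminated) read counts and each
    record's expected_call.  Returns (reads per library, count table).
    """
    if n_libraries < 1:
        raise ValueError("n_libraries must be >= 1")
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    libs = library_ids or [f"lib{i + 1}" for i in range(n_libraries)]
    if len(libs) != n_libraries:
        raise ValueError("library_ids length must equal n_libraries")

    reads: dict[str, list[SimulatedRead]] = {lib: [] for lib in libs}
    tally: dict[tuple, dict[str, int]] = {}
    serial = 0

    def emit(lib, rec, role, lo, hi, key_extra=()):
        nonlocal serial
        insert = _insert_from_genome(genome, rec, lo, hi)
        errored = False
        if config.error_rate > 0:
            s = list(insert)
            for i in range(len(s)):
                if rng.random() < config.error_rate:
                    s[i] = "ACGT"[int(rng.integers(4))]
                    errored = True
            insert = "".join(s)
        contaminated = rng.random() < config.contaminant5_fraction
        emitted = insert
        if contaminated:
            k = int(rng.integers(8, len(config.adapter5) + 1))
            emitted = config.adapter5[-k:] + insert
        raw = (emitted + config.adapter3)[: config.raw_read_len]
        raw = raw + _random_seq(rng, config.raw_read_len - len(raw))
        lowq = rng.random() < config.lowq_fraction
        mu = 12.0 if lowq else 36.0
        quality = np.clip(
            np.rint(rng.normal(mu, 2.0, size=len(raw))), 2, 40
        ).astype(int)
        clean = not (errored or contaminated or lowq)
        serial += 1
        reads[lib].append(
            SimulatedRead(
                read_id=f"{lib}:{serial}",
                sequence=raw,
                quality=list(quality),
                locus_id=rec.locus_id,
                role=role,
                clean=clean,
                insert=insert,
                chrom=rec.chrom,
                start=lo,
                end=hi,
                strand=rec.strand,
            )
        )
        key = (rec.locus_id, lib, role) + tuple(key_extra)
        t = tally.setdefault(key, {"reads": 0, "clean": 0})
        t["reads"] += 1
        t["clean"] += int(clean)
        rec.reads[lib] = rec.reads.get(lib, 0) + 1
        if clean and role in ("mature", "star"):
            rec.clean_reads[lib] = rec.clean_reads.get(lib, 0) + 1

    p_count = config.count_dispersion / (config.count_dispersion + config.count_mean)
    p_decoy = config.count_dispersion / (
        config.count_dispersion + config.decoy_count_mean
    )

    for rec in truth.records:
        for lib in libs:
            if rec.feature_class in ("true_mirna", "te_mirna"):
                n = int(rng.negative_binomial(config.count_dispersion, p_count))
                n_loop = int(rng.binomial(n, config.loop_read_rate)) if n else 0
                n_star = (
                    int(rng.binomial(n - n_loop, config.star_fraction))
                    if n > n_loop and rec.emit_star
                    else 0
                )
                n_mature = n - n_loop - n_star
                for _ in range(n_mature):
                    o5 = _draw_offset(rng, config.end_shift_probs_5p)
                    o3 = _draw_offset(rng, config.end_shift_probs_3p)
                    if rec.strand == "+":
                        lo, hi = rec.mature_start + o5, rec.mature_end + o3
                    else:
                        lo, hi = rec.mature_start - o3, rec.mature_end - o5
                    emit(lib, rec, "mature", lo, hi, (o5, o3))
                for _ in range(n_star):
                    emit(lib, rec, "star", rec.star_start, rec.star_end)
                for _ in range(n_loop):
                    # loop fragments reach a few nt into both arms so they
                    # survive the length filter, as real loop reads do
                    mid_lo = min(rec.mature_end, rec.star_end)
                    mid_hi = max(rec.mature_start, rec.star_start)
                    lo = max(rec.start, mid_lo - 5)
                    hi = min(rec.end, mid_hi + 5)
                    if hi - lo >= 18:
                        emit(lib, rec, "loop", lo, hi)
            else:
                n = int(rng.negative_binomial(config.count_dispersion, p_decoy))
                for _ in range(n):
                    length = int(rng.integers(16, 29))
                    if rec.end - rec.start <= length:
                        continue
                    lo = int(rng.integers(rec.start, rec.end - length))
                    emit(lib, rec, "fragment", lo, lo + length)

    # finalize expected calls
    for rec in truth.records:
        if rec.feature_class in ("true_mirna", "te_mirna"):
            clean_total = sum(rec.clean_reads.values())
            clean_max = max(rec.clean_reads.values(), default=0)
            if rec.known and clean_total >= 2:
                rec.expected_call = "known"
            elif clean_max >= 5:
                rec.expected_call = "novel"
            else:
                rec.expected_call = "rejected"
        else:
            rec.expected_call = "rejected"

    rows = [
        {
            "locus_id": k[0],
            "library": k[1],
            "role": k[2],
            "offset5": k[3] if len(k) > 3 else 0,
            "offset3": k[4] if len(k) > 4 else 0,
            "reads": v["reads"],
            "clean_reads": v["clean"],
        }
        for k, v in sorted(tally.items())
    ]
    return reads, pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "library",
            "role",
            "offset5",
            "offset3",
            "reads",
            "clean_reads",
        ],
    )


# ---------------------------------------------------------------------------
# file output


def write_fasta(entries, path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")


def write_fastq(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quality)
            fh.write(
                f"@{r.read_id} locus={r.locus_id} role={r.role} "
                f"clean={int(r.clean)}\n{r.sequence}\n+\n{qual}\n"
            )


def write_outputs(
    outdir,
    genome: dict[str, str],
    annotations: AnnotationSet,
    reference: list[tuple[str, str]],
    truth: GroundTruth,
    reads: dict[str, list[SimulatedRead]] | None = None,
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(genome.items(), out / "genome.fa")
    write_fasta(reference, out / "reference_matures.fa")
    annotations.to_gff3(out / "annotations.gff3")
    truth.to_tsv(out / "truth.tsv")
    if reads:
        for lib, lib_reads in reads.items():
            write_fastq(lib_reads, out / f"{lib}.fastq")
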
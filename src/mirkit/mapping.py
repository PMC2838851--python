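"""Perfect full-length mapping of tags to both genome strands.

A seed-and-verify exact matcher: k-mer positions (default k=12) are
indexed over the + strand; a tag is located by looking up its first
k-mer (and that of its reverse complement) and verifying the full-length
match.  Only perfect, full-length matches count - mismatched or gapped
placements are not alignments here, matching the mapping contract of
miRNA discovery from short tags.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import NamedTuple

from ._seq import revcomp
from .preprocess import Tag

DEFAULT_SEED_K = 12
DEFAULT_MAX_HITS = 20

_ACGT = set("ACGT")


@dataclass(frozen=True)
class TagAlignment:
    tag_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_genomic_hits: int = 1


class MapResult(NamedTuple):
    alignments: list[TagAlignment]
    unmapped: list[str]
    hyper_repetitive: list[str]


class GenomeIndex:
    """Exact-substring lookup over both strands of a genome."""

    def __init__(self, genome: dict[str, str], k: int = DEFAULT_SEED_K):
        if len(set(genome)) != len(genome):  # dict cannot collide, kept for clarity
            raise ValueError("duplicate chromosome names")
        if k < 1:
            raise ValueError("seed length must be >= 1")
        self.k = k
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self._kmers: dict[str, list[tuple[str, int]]] = collections.defaultdict(list)
        for name, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                # non-ACGT characters (N etc.) are unmatchable: skip their kmers
                if _ACGT.issuperset(kmer):
                    self._kmers[kmer].append((name, i))

    @classmethod
    def from_fasta(cls, path, k: int = DEFAULT_SEED_K) -> "GenomeIndex":
        from Bio import SeqIO

        genome: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in genome:
                raise ValueError(f"duplicate chromosome name {rec.id!r}")
            genome[rec.id] = str(rec.seq).upper()
        return cls(genome, k=k)

    def _find_forward(self, seq: str) -> list[tuple[str, int]]:
        hits = []
        for chrom, pos in self._kmers.get(seq[: self.k], ()):
            if self.genome[chrom][pos : pos + len(seq)] == seq:
                hits.append((chrom, pos))
        return hits

    def find(self, seq: str) -> list[tuple[str, int, int, str]]:
        """All perfect full-length occurrences as (chrom, start, end, strand)."""
        seq = seq.upper()
        if len(seq) < self.k:
            raise ValueError(
                f"query length {len(seq)} below seed length {self.k}"
            )
        out = [
            (chrom, pos, pos + len(seq), "+") for chrom, pos in self._find_forward(seq)
        ]
        out += [
            (chrom, pos, pos + len(seq), "-")
            for chrom, pos in self._find_forward(revcomp(seq))
        ]
        return sorted(out)


def map_tags(
    tags: list[Tag],
    index: GenomeIndex,
    max_hits: int = DEFAULT_MAX_HITS,
) -> MapResult:
    """Map every tag; returns alignments, unmapped tag ids, and tag ids
    exceeding max_hits (hyper-repetitive; excluded from hairpin discovery
    but kept here so the repeat category tally can still see them)."""
    alignments: list[TagAlignment] = []
    unmapped: list[str] = []
    hyper: list[str] = []
    for tag in tags:
        hits = index.find(tag.sequence)
        if not hits:
            unmapped.append(tag.tag_id)
            continue
        if len(hits) > max_hits:
            hyper.append(tag.tag_id)
        alignments.extend(
            TagAlignment(tag.tag_id, chrom, start, end, strand, len(hits))
            for chrom, start, end, strand in hits
        )
    alignments.sort(key=lambda a: (a.chrom, a.start, a.end, a.strand, a.tag_id))
    return MapResult(alignments, unmapped, hyper)


def alignments_to_tsv(result: MapResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("tag_id\tchrom\tstart\tend\tstrand\tn_genomic_hits\n")
        for a in result.alignments:
            fh.write(
                f"{a.tag_id}\t{a.chrom}\t{a.start}\t{a.end}\t{a.strand}\t"
                f"{a.n_genomic_hits}\n"
            )
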
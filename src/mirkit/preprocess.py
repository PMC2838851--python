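"""Raw small-RNA reads -> unique counted tags.

The stage order mirrors a classic Solexa small-RNA workflow: whole-read
quality accept/reject, 3' adapter clipping by ungapped semi-global
alignment, removal of 5'-adapter ligation contaminants, a length window
(default 18-30 nt, matching a 16-30 nt gel size selection with an 18 nt
mapping floor), and collapsing of identical inserts into tags with
per-library counts.

Reads without a detectable 3' adapter are discarded (their insert length
is indeterminate); every discard is tallied so that stage counts are
conserved: raw = low_quality + no_adapter + contaminant_5p + too_short_or_N
+ collapsed insert total.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from ._seq import hamming

DEFAULT_MIN_MEAN_QUALITY = 20.0
DEFAULT_MAX_N = 0
DEFAULT_MIN_OVERLAP = 6
DEFAULT_MAX_ERROR_RATE = 0.1
DEFAULT_MIN_PREFIX = 8
DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30


class MalformedRecordError(ValueError):
    """Sequence/quality length mismatch in a FASTQ record."""


@dataclass
class ReadRecord:
    """A raw sequencing read with Phred quality scores."""

    read_id: str
    sequence: str
    quality: list[int]

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise MalformedRecordError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    @property
    def mean_quality(self) -> float:
        return sum(self.quality) / len(self.quality) if self.quality else 0.0


@dataclass
class Tag:
    """A unique insert sequence with per-library read counts."""

    tag_id: str
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def read_fastq(path, offset: int = 33) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a Phred+33 (default) or +64 FASTQ file."""
    shift = offset - 33  # Bio.SeqIO decodes assuming +33
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        if shift:
            quals = [q - shift for q in quals]
        yield ReadRecord(rec.id, str(rec.seq).upper(), list(quals))


def quality_filter(
    reads: Iterable[ReadRecord],
    min_mean_q: float = DEFAULT_MIN_MEAN_QUALITY,
    max_n: int = DEFAULT_MAX_N,
) -> tuple[list[ReadRecord], int]:
    """Whole-read accept/reject: mean Phred >= min_mean_q and <= max_n Ns."""
    passed: list[ReadRecord] = []
    n_low = 0
    for read in reads:
        if read.mean_quality >= min_mean_q and read.sequence.count("N") <= max_n:
            passed.append(read)
        else:
            n_low += 1
    return passed, n_low


def clip_adapter3(
    sequence: str,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> str | None:
    """Clip the 3' adapter by ungapped semi-global alignment.

    The adapter prefix is aligned against every read suffix; the clip is
    made at the leftmost position whose alignment spans >= min_overlap
    bases with a mismatch fraction <= max_error_rate.  Returns the 5'
    insert, or None when no acceptable adapter occurrence exists (the
    read is then treated as un-ligated and discarded upstream).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n = len(sequence)
    for i in range(0, n - min_overlap + 1):
        overlap = min(n - i, len(adapter))
        mismatches = hamming(sequence[i : i + overlap], adapter[:overlap])
        if mismatches <= max_error_rate * overlap:
            return sequence[:i]
    return None


def drop_5p_contaminants(
    insert: str,
    adapter5: str,
    min_prefix: int = DEFAULT_MIN_PREFIX,
) -> bool:
    """True (keep) unless the insert starts with a >=min_prefix suffix of
    the 5' adapter with at most one mismatch."""
    top = min(len(insert), len(adapter5))
    for k in range(top, min_prefix - 1, -1):
        if hamming(insert[:k], adapter5[-k:]) <= 1:
            return False
    return True


def collapse(
    inserts: Iterable[tuple[str, str]],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[Tag], int]:
    """Merge identical inserts into Tags with per-library counts.

    Inserts outside [min_len, max_len] or containing N are excluded and
    tallied.  Output is sorted by total count descending, then sequence
    ascending, and tag ids are assigned in that order.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    counts: dict[str, collections.Counter] = collections.defaultdict(
        collections.Counter
    )
    n_excluded = 0
    for library_id, seq in inserts:
        if not (min_len <= len(seq) <= max_len) or "N" in seq:
            n_excluded += 1
            continue
        counts[seq][library_id] += 1
    ordered = sorted(counts.items(), key=lambda kv: (-sum(kv[1].values()), kv[0]))
    tags = [
        Tag(tag_id=f"tag{i + 1}", sequence=seq, counts=dict(libs))
        for i, (seq, libs) in enumerate(ordered)
    ]
    return tags, n_excluded


def run_preprocess(
    reads_by_library: dict[str, Iterable[ReadRecord]],
    adapter3: str,
    adapter5: str,
    min_mean_q: float = DEFAULT_MIN_MEAN_QUALITY,
    max_n: int = DEFAULT_MAX_N,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
    min_prefix: int = DEFAULT_MIN_PREFIX,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[Tag], pd.DataFrame]:
    """Run the full preprocessing chain on one or more libraries.

    Returns the collapsed tag list plus a per-library stage summary with
    conserved counts (every raw read lands in exactly one bucket).
    """
    clean_inserts: list[tuple[str, str]] = []
    rows = []
    for library_id, reads in reads_by_library.items():
        reads = list(reads)
        passed, n_low = quality_filter(reads, min_mean_q=min_mean_q, max_n=max_n)
        n_no_adapter = n_contaminant = 0
        lib_inserts: list[str] = []
        for read in passed:
            insert = clip_adapter3(
                read.sequence,
                adapter3,
                min_overlap=min_overlap,
                max_error_rate=max_error_rate,
            )
            if insert is None:
                n_no_adapter += 1
                continue
            if not drop_5p_contaminants(insert, adapter5, min_prefix=min_prefix):
                n_contaminant += 1
                continue
            lib_inserts.append(insert)
        n_len_fail = sum(
            1
            for s in lib_inserts
            if not (min_len <= len(s) <= max_len) or "N" in s
        )
        clean_inserts.extend((library_id, s) for s in lib_inserts)
        rows.append(
            {
                "library": library_id,
                "raw_reads": len(reads),
                "low_quality": n_low,
                "no_adapter": n_no_adapter,
                "contaminant_5p": n_contaminant,
                "too_short_or_N": n_len_fail,
                "clean_inserts": len(lib_inserts) - n_len_fail,
            }
        )
    tags, _ = collapse(clean_inserts, min_len=min_len, max_len=max_len)
    return tags, pd.DataFrame(rows)


def write_tag_fasta(tags: list[Tag], path) -> None:
    """Collapsed tags as FASTA with ``>tagN_x<total>`` headers."""
    with open(path, "w") as fh:
        for tag in tags:
            fh.write(f">{tag.tag_id}_x{tag.total}\n{tag.sequence}\n")


def tag_count_matrix(tags: list[Tag]) -> pd.DataFrame:
    """Per-library tag count matrix (rows: tags, columns: libraries)."""
    df = pd.DataFrame(
        [{"tag_id": t.tag_id, "sequence": t.sequence, **t.counts} for t in tags]
    )
    if not df.empty:
        df = df.fillna(0)
        lib_cols = [c for c in df.columns if c not in ("tag_id", "sequence")]
        df[lib_cols] = df[lib_cols].astype(int)
    return df
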
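"""Genomic-annotation overlap and small-RNA category assignment.

Every mapped tag is assigned exactly one category by overlap (>= 1 bp at
any of its genomic loci) against a strand-aware annotation set, with a
fixed priority: known miRNA hairpins first, then structural ncRNA
(rRNA/tRNA/snRNA/snoRNA, discarded from discovery), then repeats,
exons (split by sense), introns, and finally intergenic for tags that
overlap nothing.  Repeat-associated tags stay eligible for discovery
(repeat-derived miRNAs are a real catalogue class); sense-exon tags are
eligible only with a significant precursor fold p-value downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from intervaltree import IntervalTree

from .mapping import TagAlignment
from .preprocess import Tag
from .report import round_pct

FEATURE_CLASSES = frozenset(
    {"known_mirna", "rrna", "trna", "snrna", "snorna", "repeat", "exon", "intron"}
)
NCRNA_CLASSES = frozenset({"rrna", "trna", "snrna", "snorna"})

#: category labels in priority order (highest first)
CATEGORIES = (
    "known_mirna",
    "ncrna_discard",
    "repeat_associated",
    "exon_sense",
    "exon_antisense",
    "intron",
    "intergenic",
)
_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class Annotation:
    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str
    feature_id: str


class AnnotationSet:
    """Strand-aware genomic intervals with feature classes, indexed for
    overlap queries."""

    def __init__(self, intervals: Iterable[Annotation], source: str = ""):
        self.intervals: list[Annotation] = []
        self.source = source
        self._trees: dict[str, IntervalTree] = {}
        for ann in intervals:
            self.add(ann)

    def add(self, ann: Annotation) -> None:
        if ann.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature_class {ann.feature_class!r}")
        if not ann.start < ann.end:
            raise ValueError(f"empty interval for {ann.feature_id!r}")
        self.intervals.append(ann)
        self._trees.setdefault(ann.chrom, IntervalTree()).addi(
            ann.start, ann.end, ann
        )

    def overlapping(self, chrom: str, start: int, end: int) -> list[Annotation]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start, end)),
            key=lambda a: (a.start, a.end, a.feature_id),
        )

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for a in sorted(self.intervals, key=lambda x: (x.chrom, x.start)):
                fh.write(
                    f"{a.chrom}\t{self.source or 'mirkit'}\t{a.feature_class}\t"
                    f"{a.start + 1}\t{a.end}\t.\t{a.strand}\t.\tID={a.feature_id}\n"
                )

    @classmethod
    def from_gff3(cls, path, class_map: dict[str, str] | None = None):
        """Read annotations from GFF3; the type column (optionally via a
        class mapping) supplies the feature class."""
        anns = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                cls_name = (class_map or {}).get(f[2], f[2]).lower()
                if cls_name not in FEATURE_CLASSES:
                    raise ValueError(f"unknown feature_class {cls_name!r}")
                fid = "."
                for kv in f[8].split(";"):
                    if kv.startswith("ID="):
                        fid = kv[3:]
                anns.append(
                    Annotation(f[0], int(f[3]) - 1, int(f[4]), f[6], cls_name, fid)
                )
        return cls(anns, source=str(path))


@dataclass
class CategoryAssignment:
    tag_id: str
    category: str
    eligible_for_discovery: bool
    requires_fold_pvalue: bool = False
    overlaps: list[str] = field(default_factory=list)


def _category_of(align: TagAlignment, ann: Annotation) -> str:
    if ann.feature_class == "known_mirna":
        return "known_mirna"
    if ann.feature_class in NCRNA_CLASSES:
        return "ncrna_discard"
    if ann.feature_class == "repeat":
        return "repeat_associated"
    if ann.feature_class == "exon":
        return "exon_sense" if align.strand == ann.strand else "exon_antisense"
    return "intron"


def categorize(
    alignments: list[TagAlignment], ann: AnnotationSet
) -> list[CategoryAssignment]:
    """One CategoryAssignment per distinct tag among the alignments.

    A tag's category is the highest-priority class over all overlaps at
    all of its loci; tags overlapping nothing are intergenic.
    """
    by_tag: dict[str, list[TagAlignment]] = {}
    for a in alignments:
        by_tag.setdefault(a.tag_id, []).append(a)
    out = []
    for tag_id, aligns in by_tag.items():
        categories: list[str] = []
        feature_ids: list[str] = []
        for a in aligns:
            for hit in ann.overlapping(a.chrom, a.start, a.end):
                categories.append(_category_of(a, hit))
                feature_ids.append(hit.feature_id)
        category = (
            min(categories, key=_PRIORITY.__getitem__) if categories else "intergenic"
        )
        out.append(
            CategoryAssignment(
                tag_id=tag_id,
                category=category,
                eligible_for_discovery=category != "ncrna_discard",
                requires_fold_pvalue=category == "exon_sense",
                overlaps=sorted(set(feature_ids)),
            )
        )
    return out


def category_table(
    assignments: list[CategoryAssignment], tags: list[Tag]
) -> pd.DataFrame:
    """Per-library total/unique read counts and percentages per category.

    Rows partition each library's clean tag pool: per library, the
    ``reads`` column sums to the library total and percentages to 100
    within rounding.
    """
    tag_by_id = {t.tag_id: t for t in tags}
    cat_of = {}
    for a in assignments:
        if a.tag_id not in tag_by_id:
            raise ValueError(f"assignment for unknown tag {a.tag_id!r}")
        cat_of[a.tag_id] = a.category
    libraries = sorted({lib for t in tags for lib in t.counts})
    rows = []
    for lib in libraries:
        total = sum(t.counts.get(lib, 0) for t in tags)
        unique_total = sum(1 for t in tags if t.counts.get(lib, 0) > 0)
        for cat in CATEGORIES:
            members = [t for t in tags if cat_of.get(t.tag_id) == cat]
            reads = sum(t.counts.get(lib, 0) for t in members)
            unique = sum(1 for t in members if t.counts.get(lib, 0) > 0)
            rows.append(
                {
                    "library": lib,
                    "category": cat,
                    "reads": reads,
                    "unique_tags": unique,
                    "pct_reads": round_pct(reads, total),
                    "pct_unique": round_pct(unique, unique_total),
                }
            )
    return pd.DataFrame(rows)
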
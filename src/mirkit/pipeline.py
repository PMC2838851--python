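"""End-to-end discovery: reads -> tags -> alignments -> categories ->
hairpins -> catalogue -> report."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import annotate, catalog, hairpin, mapping, preprocess, report
from .fold import FoldEngine, fold_pvalue
from .preprocess import ReadRecord, Tag


def _merge_overlapping(
    accepted: list[tuple[hairpin.PileupLocus, hairpin.HairpinCandidate]],
    genome: dict[str, str],
    engine: FoldEngine | None,
) -> list[tuple[hairpin.PileupLocus, hairpin.HairpinCandidate]]:
    """Union candidates whose precursor windows overlap (same chrom and
    strand) and re-evaluate each union as one locus; falls back to the
    group's highest-count member when the union fails the filter."""
    parent = list(range(len(accepted)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (_, hi_) in enumerate(accepted):
        for j in range(i + 1, len(accepted)):
            hj = accepted[j][1]
            if (
                hi_.chrom == hj.chrom
                and hi_.strand == hj.strand
                and min(hi_.g_end, hj.g_end) > max(hi_.g_start, hj.g_start)
            ):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(accepted)):
        groups.setdefault(find(i), []).append(i)

    out = []
    for members in groups.values():
        if len(members) == 1:
            out.append(accepted[members[0]])
            continue
        loci = [accepted[i][0] for i in members]
        seen = set()
        merged_members = []
        for l in loci:
            for m in l.members:
                key = (m.tag_id, m.start, m.end)
                if key not in seen:
                    seen.add(key)
                    merged_members.append(m)
        merged = hairpin.PileupLocus(
            chrom=loci[0].chrom,
            strand=loci[0].strand,
            start=min(l.start for l in loci),
            end=max(l.end for l in loci),
            members=merged_members,
        )
        best, _ = hairpin.evaluate_locus(merged, genome, engine=engine)
        if best is not None:
            out.append((merged, best))
        else:
            rep = max(
                members,
                key=lambda i: sum(m.total for m in accepted[i][0].members),
            )
            out.append(accepted[rep])
    out.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].strand))
    return out


@dataclass
class DiscoveryResult:
    tags: list[Tag]
    stage_summary: pd.DataFrame
    map_result: mapping.MapResult
    assignments: list[annotate.CategoryAssignment]
    category_table: pd.DataFrame
    candidates: list[catalog.CandidateLocus]
    rejected: list[tuple[hairpin.PileupLocus, list[str]]]
    loci: list[catalog.MiRNALocus]
    clusters: list[catalog.Cluster]
    paralogs: list[catalog.ParalogGroup]
    conservation: list[catalog.ConservationCall]
    pairs: list[tuple[str, str]]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def discover(
    reads_by_library: dict[str, Iterable[ReadRecord]],
    genome: dict[str, str],
    annotations: annotate.AnnotationSet,
    reference_matures: list[tuple[str, str]],
    adapter3: str,
    adapter5: str,
    seed: int = 0,
    engine: FoldEngine | None = None,
    n_shuffles: int = 100,
    pooled_novel: bool = False,
    max_hits: int = mapping.DEFAULT_MAX_HITS,
    min_mean_q: float = preprocess.DEFAULT_MIN_MEAN_QUALITY,
) -> DiscoveryResult:
    """Run the whole discovery pipeline on raw reads.

    Fold p-values (needed only for sense-exon candidates) draw their
    shuffles from ``seed``; everything else is deterministic.
    """
    tags, stage_summary = preprocess.run_preprocess(
        reads_by_library, adapter3=adapter3, adapter5=adapter5, min_mean_q=min_mean_q
    )
    index = mapping.GenomeIndex(genome)
    map_result = mapping.map_tags(tags, index, max_hits=max_hits)
    assignments = annotate.categorize(map_result.alignments, annotations)
    mapped_ids = {a.tag_id for a in map_result.alignments}
    mapped_tags = [t for t in tags if t.tag_id in mapped_ids]
    cat_table = annotate.category_table(assignments, mapped_tags)

    category_of = {a.tag_id: a for a in assignments}
    hyper = set(map_result.hyper_repetitive)
    eligible_alignments = [
        a
        for a in map_result.alignments
        if a.tag_id not in hyper
        and category_of[a.tag_id].eligible_for_discovery
    ]
    pileups = hairpin.call_pileups(eligible_alignments, tags)

    rng = np.random.default_rng(seed)
    accepted: list[tuple[hairpin.PileupLocus, hairpin.HairpinCandidate]] = []
    rejected: list[tuple[hairpin.PileupLocus, list[str]]] = []
    for locus in pileups:
        best, (cand_a, _) = hairpin.evaluate_locus(locus, genome, engine=engine)
        if best is None:
            rejected.append((locus, cand_a.reasons))
            continue
        accepted.append((locus, best))

    # One gene often yields separate mature- and star-arm pileups (the
    # loop gap keeps their alignments from overlapping); candidates whose
    # accepted precursor windows overlap on one strand are merged and the
    # union re-evaluated, so read thresholds see the whole gene.
    accepted = _merge_overlapping(accepted, genome, engine)

    candidates: list[catalog.CandidateLocus] = []
    for locus, best in accepted:
        assignment = category_of[locus.mature_guess.tag_id]
        cand = catalog.CandidateLocus(
            locus=locus,
            hairpin=best,
            category=assignment.category,
            requires_fold_pvalue=assignment.requires_fold_pvalue,
        )
        if cand.requires_fold_pvalue:
            cand.fold_pvalue = fold_pvalue(
                best.precursor_seq,
                n_shuffles=n_shuffles,
                seed=rng,
                engine=engine,
            )
            best.fold_pvalue = cand.fold_pvalue
        candidates.append(cand)

    tag_seqs = {t.tag_id: t.sequence for t in tags}
    loci = catalog.build_catalog(
        candidates, reference_matures, annotations, tag_seqs, pooled_novel=pooled_novel
    )
    clusters = catalog.detect_clusters(loci)
    paralogs = catalog.group_paralogs(loci)
    conservation = [
        catalog.classify_conservation(l, reference_matures) for l in loci
    ]
    pairs = catalog.detect_sense_antisense(loci)
    tables = report.build_report(
        loci,
        clusters,
        paralogs,
        conservation,
        pairs,
        category_table=cat_table,
        stage_summary=stage_summary,
    )
    return DiscoveryResult(
        tags=tags,
        stage_summary=stage_summary,
        map_result=map_result,
        assignments=assignments,
        category_table=cat_table,
        candidates=candidates,
        rejected=rejected,
        loci=loci,
        clusters=clusters,
        paralogs=paralogs,
        conservation=conservation,
        pairs=pairs,
        tables=tables,
    )
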
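"""Known/novel thresholds, clusters, paralogs, conservation, antisense
pairs, genomic context and report arithmetic."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mirkit.annotate import Annotation, AnnotationSet
from mirkit.catalog import (
    CandidateLocus,
    Cluster,
    ConservationCall,
    MiRNALocus,
    call_novel,
    classify_conservation,
    detect_clusters,
    detect_sense_antisense,
    genomic_context,
    group_paralogs,
    match_known,
    seq_match,
)
from mirkit.hairpin import HairpinCandidate, PileupLocus, PileupMember
from mirkit.report import build_report


def make_candidate(
    counts_by_lib,
    mature="ACGUACGUACGUACGUACGUAC",
    chrom="chr1",
    start=1000,
    strand="+",
    category="intergenic",
    requires_p=False,
    fold_p=None,
):
    """A minimal accepted candidate whose mature arm holds all reads."""
    mlen = len(mature)
    member = PileupMember("t1", start + 10, start + 10 + mlen, dict(counts_by_lib))
    locus = PileupLocus(chrom, strand, start + 10, start + 10 + mlen, [member])
    seq = mature + "CUUCGG" + "".join(
        {"A": "U", "U": "A", "G": "C", "C": "G"}[c] for c in reversed(mature)
    )
    pad = "A" * 10
    hp = HairpinCandidate(
        chrom, strand, "up10_down70", start, start + len(seq) + 20,
        pad + seq + pad, (10, 10 + mlen),
    )
    hp.structure = "." * len(hp.precursor_seq)
    hp.mfe = -30.0
    hp.star_span = (10 + mlen + 6, 10 + 2 * mlen + 6)
    hp.loop_span = (10 + mlen, 10 + mlen + 6)
    hp.passed = True
    return CandidateLocus(
        locus, hp, category, requires_fold_pvalue=requires_p, fold_pvalue=fold_p
    )


REF = [("bmo-miR-1", "ACGUACGUACGUACGUACGUAC")]


class TestSeqMatch:
    @pytest.mark.parametrize("n_mut,expected", [(0, True), (1, True),
                                                (2, True), (3, False)])
    def test_mismatch_grid(self, n_mut, expected):
        a = "ACGUACGUACGUACGUACGUAC"
        b = list(a)
        for i in range(n_mut):
            b[2 + 3 * i] = "U" if b[2 + 3 * i] != "U" else "G"
        assert seq_match(a, "".join(b)) is expected

    def test_end_shift_tolerated_to_three(self):
        a = "ACGUACGUACGUACGUACGUAC"
        assert seq_match(a, a[3:] + "GGG", max_mismatch=2, max_shift=3)
        assert not seq_match(a, a[4:] + "GGGG", max_mismatch=0, max_shift=3)

    def test_dna_rna_alphabet_insensitive(self):
        assert seq_match("ACGTACGTACGTACGTACGT", "ACGUACGUACGUACGUACGU")


class TestMatchKnown:
    def test_two_reads_suffice(self):
        cands = [make_candidate({"l1": 2})]
        assert 0 in match_known(cands, REF)

    def test_single_read_not_called(self):
        cands = [make_candidate({"l1": 1})]
        assert match_known(cands, REF) == {}

    def test_two_mismatches_known_three_not(self):
        mature = "ACGUACGUACGUACGUACGUAC"
        two = "AAGUACGUACGUACGUACGUAU"  # 2 substitutions
        three = "AAGUACGAACGUACGUACGUAU"  # 3 substitutions
        assert 0 in match_known([make_candidate({"l": 5}, mature=two)], REF)
        assert match_known([make_candidate({"l": 5}, mature=three)], REF) == {}

    def test_hairpin_annotation_overlap_counts(self):
        cands = [make_candidate({"l": 3}, mature="GGGGCCCCGGGGCCCCGGGG")]
        ann = AnnotationSet(
            [Annotation("chr1", 990, 1090, "+", "known_mirna", "bmo-mir-x")]
        )
        assert match_known(cands, [], annotations=ann) == {0: ["bmo-mir-x"]}


class TestCallNovel:
    def test_five_reads_in_one_library(self):
        cands = [make_candidate({"l1": 5}, mature="GGGGCCCCGGGGCCCCGGGG")]
        assert call_novel(cands, known={}) == [0]

    def test_four_reads_per_library_insufficient(self):
        """Three libraries at 4 reads each: no single library reaches 5,
        so the per-library reading rejects the locus (pooled mode would
        accept)."""
        cands = [
            make_candidate({"l1": 4, "l2": 4, "l3": 4},
                           mature="GGGGCCCCGGGGCCCCGGGG")
        ]
        assert call_novel(cands, known={}) == []
        assert call_novel(cands, known={}, pooled=True) == [0]

    def test_exon_sense_needs_significant_fold_pvalue(self):
        kw = dict(mature="GGGGCCCCGGGGCCCCGGGG", category="exon_sense",
                  requires_p=True)
        reject = make_candidate({"l": 9}, fold_p=0.02, **kw)
        accept = make_candidate({"l": 9}, fold_p=0.009, **kw)
        assert call_novel([reject], known={}) == []
        assert call_novel([accept], known={}) == [0]

    def test_known_and_ncrna_excluded(self):
        cand = make_candidate({"l": 9}, category="ncrna_discard",
                              mature="GGGGCCCCGGGGCCCCGGGG")
        assert call_novel([cand], known={}) == []
        cand2 = make_candidate({"l": 9})
        assert call_novel([cand2], known={0: ["bmo-miR-1"]}) == []


def locus(name, chrom="chr1", start=0, end=100, strand="+",
          mature="ACGUACGUACGUACGUACGUAC", star=None, reads=10):
    return MiRNALocus(
        name=name, chrom=chrom, start=start, end=end, strand=strand,
        status="novel", mature_seq=mature, star_seq=star,
        mature_counts={"l": reads},
    )


class TestDetectClusters:
    def test_gap_2400_joins(self):
        loci = [locus("a", end=100), locus("b", start=2500, end=2600)]
        (c,) = detect_clusters(loci)
        assert c.members == ["a", "b"]

    def test_gap_2500_exactly_separates(self):
        loci = [locus("a", end=100), locus("b", start=2600, end=2700)]
        assert detect_clusters(loci) == []

    def test_chain_of_three(self):
        loci = [
            locus("a", end=100),
            locus("b", start=2100, end=2200),
            locus("c", start=4200, end=4300),
        ]
        (c,) = detect_clusters(loci)
        assert c.members == ["a", "b", "c"]

    def test_strands_do_not_chain_by_default(self):
        loci = [locus("a", end=100), locus("b", start=500, end=600, strand="-")]
        assert detect_clusters(loci) == []
        assert len(detect_clusters(loci, same_strand=False)) == 1

    def test_equals_allpairs_chaining_oracle(self):
        """On 50 random loci, single-linkage chaining matches the
        transitive closure of the pairwise gap<2500 relation computed by
        networkx connected components."""
        rng = np.random.default_rng(8)
        loci = []
        pos = 0
        for i in range(50):
            pos += int(rng.integers(100, 4000))
            loci.append(locus(f"m{i}", start=pos, end=pos + 80))
        clusters = detect_clusters(loci)
        g = nx.Graph()
        g.add_nodes_from(l.name for l in loci)
        for a, b in itertools.combinations(loci, 2):
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap < 2500:
                g.add_edge(a.name, b.name)
        oracle = sorted(
            sorted(c) for c in nx.connected_components(g) if len(c) >= 2
        )
        assert sorted(sorted(c.members) for c in clusters) == oracle


class TestGroupParalogs:
    def test_identical_matures_grouped(self):
        loci = [locus("a"), locus("b", start=5000, end=5100)]
        (g,) = group_paralogs(loci)
        assert g.members == ["a", "b"]

    def test_three_mismatches_separate(self):
        m = "ACGUACGUACGUACGUACGUAC"
        other = "AAGUACGAACGUACGUACGUAU"
        loci = [locus("a", mature=m), locus("b", mature=other, start=5000)]
        assert group_paralogs(loci) == []

    def test_mature_vs_star_links(self):
        m1 = "ACGUACGUACGUACGUACGUAC"
        m2 = "GGGGCCCCGGGGCCCCGGGG"
        loci = [
            locus("a", mature=m1),
            locus("b", mature=m2, star=m1, start=5000),
        ]
        (g,) = group_paralogs(loci)
        assert g.members == ["a", "b"]

    def test_transitive_closure_matches_connected_components(self):
        """A~B and B~C force one group even when A and C differ by more
        than the threshold; verified against networkx components on a
        random cohort."""
        base = "ACGUACGUACGUACGUACGUAC"
        ab = base[:10] + "UU" + base[12:]
        bc = ab[:4] + "GG" + ab[6:]
        loci = [
            locus("A", mature=base),
            locus("B", mature=ab, start=3000),
            locus("C", mature=bc, start=6000),
        ]
        (g,) = group_paralogs(loci)
        assert g.members == ["A", "B", "C"]
        rng = np.random.default_rng(9)
        cohort = [
            locus(f"r{i}",
                  mature="".join(rng.choice(list("ACGU"), size=22)),
                  start=i * 1000)
            for i in range(20)
        ]
        groups = group_paralogs(cohort)
        g = nx.Graph()
        g.add_nodes_from(l.name for l in cohort)
        for a, b in itertools.combinations(cohort, 2):
            if seq_match(a.mature_seq, b.mature_seq, max_mismatch=2, max_shift=3):
                g.add_edge(a.name, b.name)
        oracle = sorted(
            sorted(c) for c in nx.connected_components(g) if len(c) >= 2
        )
        assert sorted(g_.members for g_ in groups) == oracle


class TestClassifyConservation:
    REFS = [
        ("dme-miR-x", "ACGUACGUACGUACGUACGUAC"),
        ("hsa-miR-x", "ACGUACGUACGUACGUACGUAC"),
        ("aga-miR-y", "GGGGCCCCGGGGCCCCGGGG"),
        ("tca-miR-y", "GGGGCCCCGGGGCCCCGGGG"),
        ("cel-miR-z", "UUUUGGGGAAAACCCCUUUUGG"),
    ]

    def test_fly_plus_human_is_inv_ver(self):
        call = classify_conservation(locus("a"), self.REFS)
        assert call.tier == "inv-ver"
        assert {"dme-miR-x", "hsa-miR-x"} <= set(call.matched_reference)

    def test_insects_only_is_ins(self):
        call = classify_conservation(
            locus("a", mature="GGGGCCCCGGGGCCCCGGGG"), self.REFS
        )
        assert call.tier == "ins"

    def test_non_insect_invertebrate_is_inv(self):
        call = classify_conservation(
            locus("a", mature="UUUUGGGGAAAACCCCUUUUGG"), self.REFS
        )
        assert call.tier == "inv"

    def test_no_match_is_sw(self):
        call = classify_conservation(
            locus("a", mature="ACACACACUGUGUGUGACAC"), self.REFS
        )
        assert call.tier == "sw" and call.matched_reference == []

    def test_missing_species_tag_is_config_error(self):
        with pytest.raises(ValueError, match="taxon map"):
            classify_conservation(locus("a"), [("zzz-miR-1", "ACGU" * 5)])


class TestSenseAntisense:
    def test_identical_interval_opposite_strands_pair(self):
        loci = [locus("s"), locus("a", strand="-")]
        assert detect_sense_antisense(loci) == [("s", "a")]

    def test_adjacent_non_overlapping_no_pair(self):
        loci = [locus("s", end=100), locus("a", start=100, end=200, strand="-")]
        assert detect_sense_antisense(loci) == []

    def test_same_strand_never_pairs(self):
        loci = [locus("s"), locus("t")]
        assert detect_sense_antisense(loci) == []

    def test_planted_antisense_pair_detected_exactly(self):
        """A simulation planting one sense/antisense hairpin pair yields
        exactly that pair."""
        from conftest import run_discovery

        from mirkit import simulate

        cfg = simulate.SimConfig(
            seed=3, chrom_length=40_000, n_true_mirnas=4, n_te_mirnas=0,
            n_decoy_ncrna=2, n_gene_models=1, n_noise_loci=1,
            n_antisense_pairs=1,
        )
        genome, ann, ref, truth = simulate.build_reference(cfg)
        reads, _ = simulate.simulate_reads(genome, truth, cfg, n_libraries=2)
        result = run_discovery(genome, ann, ref, reads, cfg, seed=3)
        asp = [r for r in truth.records if r.locus_id.startswith("asp")]
        assert len(result.pairs) == 1
        (a, b) = result.pairs[0]
        by_name = {l.name: l for l in result.loci}
        spans = {(by_name[x].chrom, by_name[x].strand) for x in (a, b)}
        assert {(r.chrom, r.strand) for r in asp} == spans


class TestGenomicContext:
    ANN = AnnotationSet(
        [
            Annotation("chr1", 1000, 2000, "+", "intron", "g.i1"),
            Annotation("chr1", 2000, 2400, "+", "exon", "g.e2"),
            Annotation("chr1", 1200, 1400, "+", "repeat", "te1"),
        ]
    )

    def test_intronic(self):
        l = locus("a", start=1500, end=1600)
        genomic_context([l], self.ANN)
        assert l.context == "intronic"

    def test_exon_beats_intron(self):
        l = locus("a", start=1950, end=2050)
        genomic_context([l], self.ANN)
        assert l.context == "exonic"

    def test_te_beats_intron(self):
        l = locus("a", start=1250, end=1350)
        genomic_context([l], self.ANN)
        assert l.context == "te"

    def test_priority_table_exhaustive(self):
        """Context equals the argmax of te > exonic > intronic over every
        subset of overlapping classes."""
        label = {"repeat": "te", "exon": "exonic", "intron": "intronic"}
        order = ["repeat", "exon", "intron"]
        for k in range(0, 4):
            for subset in itertools.combinations(order, k):
                ann = AnnotationSet(
                    [
                        Annotation("chr1", 100, 200, "+", cls, f"{cls}1")
                        for cls in subset
                    ]
                )
                l = locus("a", start=120, end=180)
                genomic_context([l], ann)
                expected = next(
                    (label[c] for c in order if c in subset), "intergenic"
                )
                assert l.context == expected


class TestBuildReport:
    def test_known_plus_novel_totals(self):
        loci = [locus(f"k{i}") for i in range(55)] + [
            locus(f"n{i}") for i in range(202)
        ]
        for l in loci[:55]:
            l.status = "known"
        tables = build_report(loci, [], [], [], [])
        totals = tables["totals"].set_index("class")["genes"]
        assert totals["known"] == 55
        assert totals["novel"] == 202
        assert totals["total"] == 257

    def test_empty_catalogue_no_crash(self):
        tables = build_report([], [], [], [], [])
        assert tables["totals"]["genes"].tolist() == [0, 0, 0]
        assert tables["loci"].empty

    def test_tier_counts_partition_loci(self, default_run):
        *_, result = default_run
        tiers = result.tables["conservation"]
        assert tiers["genes"].sum() == len(result.loci)
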
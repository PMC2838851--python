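# mirkit

Small-RNA-seq miRNA discovery: from raw 35-nt reads to a catalogue of
miRNA genes — with clusters, paralogs, conservation classes,
sense/antisense pairs and isomiR refinement — plus a ground-truthed
simulator for end-to-end validation.

## What it does

Deep-sequenced small-RNA libraries mix genuine miRNAs with degradation
fragments of rRNA/tRNA, mRNA breakage products and repeat-derived
reads. `mirkit` separates them the way Solexa-era discovery pipelines
do, for anyone who wants that workflow as a tested, scriptable library:

1. **preprocess** — whole-read quality filter (mean Phred ≥ 20), 3'
   adapter clipping by ungapped semi-global alignment, 5'-adapter
   contaminant removal, collapse to unique tags (18–30 nt) with
   per-library counts;
2. **map** — perfect full-length matches on both genome strands
   (k-mer seed + verify), multi-mappers capped at 20 placements;
3. **annotate** — one category per tag by overlap priority
   `known miRNA > rRNA/tRNA/snRNA/snoRNA (discard) > repeat > exon >
   intron > intergenic`;
4. **hairpin** — read pileups nominate a mature sequence; two candidate
   precursors (10 nt up/70 nt down and the converse) are folded
   (ViennaRNA MFE) and filtered: ΔG ≤ −25 kcal/mol, mature and star
   (2-nt 3'-overhang convention) on opposite arms, ≤ 6 unpaired bases
   per arm, bulges ≤ 4 nt, duplex asymmetry ≤ 3, and 3' overhangs at
   both duplex ends whenever star reads were sequenced; sense-exonic
   candidates additionally need a dinucleotide-shuffle fold p-value
   < 0.01;
5. **catalog/report** — known genes (reference mature within 2
   mismatches/3 nt shift, ≥ 2 reads) and novel genes (≥ 5 reads in one
   library), isomiR end-offset histograms and arm switching, clusters
   (< 2.5 kb), paralog groups (≤ 2 mismatches), conservation tiers
   (`inv-ver`/`inv`/`ins`/`sw`), sense/antisense pairs, genomic context
   (TE/exonic/intronic/intergenic), and summary tables.

The `simulate` module generates a toy genome with planted hairpins
(verified discoverable with the pipeline's own folding engine),
TE-embedded miRNAs, ncRNA decoys, gene models and noise, then emits
adapter-bearing 35-nt reads with skewed negative-binomial counts,
asymmetric 5'/3' isomiR heterogeneity, rare star/loop reads,
sequencing errors, low-quality reads and 5'-adapter contaminants —
together with a manifest stating each locus's expected call.

See `docs/methods.md` for the model, parameter defaults and their
rationale.

## Worked example

```python
from mirkit import pipeline, simulate
from mirkit.preprocess import ReadRecord

cfg = simulate.SimConfig(seed=1)          # 2 x 100 kb, 30+10 miRNAs, 20 decoys
genome, ann, ref, truth = simulate.build_reference(cfg)
reads, counts = simulate.simulate_reads(genome, truth, cfg, n_libraries=3)

result = pipeline.discover(
    {lib: [ReadRecord(r.read_id, r.sequence, r.quality) for r in rs]
     for lib, rs in reads.items()},
    genome, ann, ref,
    adapter3=cfg.adapter3, adapter5=cfg.adapter5, seed=1,
)
print(result.tables["totals"])
```

prints

```
   class  genes
0  known     12
1  novel     26
2  total     38
```

— 38 miRNA gene loci recovered from the simulated libraries, 12
matching the reference database (known) and 26 newly discovered
(novel); the planted rRNA/tRNA decoys are absent. Per-locus detail,
category percentages, clusters, paralogs, conservation tiers and
sense/antisense pairs sit in the other `result.tables` entries, and
`truth` holds the manifest to compare against.

The same run from a shell:

```bash
mirkit simulate --seed 1 --outdir sim
mirkit discover --fastq sim/lib1.fastq --fastq sim/lib2.fastq --fastq sim/lib3.fastq \
    --genome sim/genome.fa --annotations sim/annotations.gff3 \
    --reference sim/reference_matures.fa --seed 1 --outdir out
```

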
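"""Summary tables for a discovery run.

Percentages are rounded half-up to two decimals, the convention used for
printed library-statistics tables in small-RNA-seq reports (e.g.
2,848,263 low-quality of 5,467,768 raw reads -> 52.09%).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd


def round_pct(count: int, total: int) -> float:
    """100*count/total, rounded half-up to 2 decimals (0.0 when total=0)."""
    if total == 0:
        return 0.0
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def preprocessing_summary(raw_total: int, n_low_quality: int) -> pd.DataFrame:
    """Low/high-quality split of a library with printed-style percentages."""
    n_high = raw_total - n_low_quality
    return pd.DataFrame(
        [
            {"class": "raw", "reads": raw_total, "pct": 100.0 if raw_total else 0.0},
            {
                "class": "low_quality",
                "reads": n_low_quality,
                "pct": round_pct(n_low_quality, raw_total),
            },
            {
                "class": "high_quality",
                "reads": n_high,
                "pct": round_pct(n_high, raw_total),
            },
        ]
    )


def build_report(
    loci,
    clusters,
    paralogs,
    conservation,
    pairs,
    category_table: pd.DataFrame | None = None,
    stage_summary: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the run-summary tables from catalogue outputs.

    Returns a dict of DataFrames: ``totals`` (known/novel/total gene
    counts), ``context`` (genomic-context breakdown), ``conservation``
    (tier counts), ``clusters``, ``paralogs``, ``sense_antisense``,
    ``loci`` (per-locus detail), plus the pass-through category and
    preprocessing-stage tables when given.
    """
    n_known = sum(1 for l in loci if l.status == "known")
    n_novel = sum(1 for l in loci if l.status == "novel")
    totals = pd.DataFrame(
        [
            {"class": "known", "genes": n_known},
            {"class": "novel", "genes": n_novel},
            {"class": "total", "genes": n_known + n_novel},
        ]
    )
    context = (
        pd.Series([l.context for l in loci], dtype=object)
        .value_counts()
        .rename_axis("context")
        .reset_index(name="genes")
    )
    tier_of = {c.name: c.tier for c in conservation}
    tiers = (
        pd.Series([tier_of.get(l.name, "sw") for l in loci], dtype=object)
        .value_counts()
        .rename_axis("tier")
        .reset_index(name="genes")
    )
    cluster_df = pd.DataFrame(
        [
            {
                "cluster_id": i + 1,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "n_members": len(c.members),
                "members": ",".join(c.members),
            }
            for i, c in enumerate(clusters)
        ]
    )
    paralog_df = pd.DataFrame(
        [
            {
                "group_id": i + 1,
                "n_members": len(g.members),
                "members": ",".join(sorted(g.members)),
                "representative_mature": g.representative_mature,
            }
            for i, g in enumerate(paralogs)
        ]
    )
    pair_df = pd.DataFrame(
        [{"locus_a": a, "locus_b": b} for a, b in pairs]
    )
    locus_df = pd.DataFrame(
        [
            {
                "name": l.name,
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "strand": l.strand,
                "status": l.status,
                "context": l.context,
                "tier": tier_of.get(l.name, "sw"),
                "mature_seq": l.mature_seq,
                "star_seq": l.star_seq or "",
                "mature_reads": sum(l.mature_counts.values()),
                "star_reads": sum(l.star_counts.values()),
                "loop_reads": sum(l.loop_counts.values()),
                "arm_switch": l.arm_switch,
            }
            for l in loci
        ]
    )
    report = {
        "totals": totals,
        "context": context,
        "conservation": tiers,
        "clusters": cluster_df,
        "paralogs": paralog_df,
        "sense_antisense": pair_df,
        "loci": locus_df,
    }
    if category_table is not None:
        report["categories"] = category_table
    if stage_summary is not None:
        report["preprocessing"] = stage_summary
    return report


def write_report(report: dict[str, pd.DataFrame], outdir) -> None:
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
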
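"""Genomic feature annotation of peaks.

Each peak is assigned exactly one feature category via a fixed priority
hierarchy over all same-strand features it overlaps: protein-coding
features first (CDS, then 3'UTR, then 5'UTR, then intron), followed by
noncoding exon and intron; a peak overlapping nothing is intergenic.
Annotation is strand-specific because eCLIP libraries are.
"""
from __future__ import annotations

import pandas as pd

from .models import Peak, TranscriptModel

DEFAULT_PRIORITY: tuple[str, ...] = (
    "CDS", "UTR3", "UTR5", "intron", "nc_exon", "nc_intron",
)

CATEGORIES: tuple[str, ...] = DEFAULT_PRIORITY + ("intergenic",)


def build_feature_table(
    transcripts: list[TranscriptModel],
) -> dict[tuple[str, str], list[tuple[int, int, str, str]]]:
    """Flatten transcripts into (chrom, strand) -> [(start, end, category,
    gene_id)], validating models on the way (a malformed CDS raises)."""
    table: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for t in transcripts:
        for cat, s, e in t.features():
            table.setdefault((t.chrom, t.strand), []).append((s, e, cat, t.gene_id))
    for feats in table.values():
        feats.sort()
    return table


def annotate_peak(
    peak: Peak,
    feature_table: dict[tuple[str, str], list[tuple[int, int, str, str]]],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> tuple[str, str]:
    """Highest-priority category among same-strand features overlapping the
    peak by >= 1 bp; gene ties resolve to the lexicographically smallest
    gene_id.  No overlap -> ("intergenic", "")."""
    rank = {cat: i for i, cat in enumerate(priority)}
    hits: list[tuple[int, str, str]] = []
    for s, e, cat, gene_id in feature_table.get((peak.chrom, peak.strand), []):
        if s < peak.end and peak.start < e and cat in rank:
            hits.append((rank[cat], cat, gene_id))
    if not hits:
        return "intergenic", ""
    hits.sort()
    return hits[0][1], hits[0][2]


def annotate_peaks(
    peaks: list[Peak],
    transcripts: list[TranscriptModel],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> list[Peak]:
    """Annotate peaks in place (category + gene_id) and return them."""
    table = build_feature_table(transcripts)
    for p in peaks:
        cat, gene_id = annotate_peak(p, table, priority)
        p.annotation = cat
        p.gene_id = gene_id
    return peaks


def feature_distribution(peaks: list[Peak]) -> pd.DataFrame:
    """Fraction of peaks per category, grouped by sample x peak_type.

    Every category appears in every group (zero counts included);
    fractions sum to 1 within each non-empty group.
    """
    rows = []
    groups: dict[tuple[str, str], list[Peak]] = {}
    for p in peaks:
        groups.setdefault((p.sample, p.peak_type), []).append(p)
    for (sample, peak_type), members in sorted(groups.items()):
        total = len(members)
        for cat in CATEGORIES:
            n = sum(1 for p in members if p.annotation == cat)
            rows.append(
                {
                    "sample": sample,
                    "peak_type": peak_type,
                    "category": cat,
                    "count": n,
                    "fraction": n / total if total else 0.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample", "peak_type", "category", "count", "fraction"]
    )
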
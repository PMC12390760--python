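"""Readers and writers for the pipeline's on-disk interchange.

FASTA/FASTQ go through Biopython.  The annotation travels as standard GTF
(1-based, inclusive).  Mapped fragments travel as BED6 plus a TSV sidecar
carrying UMI/sample/role/miRNA-tag metadata, which keeps every intermediate
diffable and re-runnable.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .models import (
    AlignedFragment,
    CtRecord,
    GenomeBundle,
    MiRNA,
    Peak,
    ReadRecord,
    SiteSpec,
    TranscriptModel,
    TruthRecord,
)

# --------------------------------------------------------------------------- FASTA


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# --------------------------------------------------------------------------- FASTQ


def write_fastq(path: str | Path, reads: Iterable[ReadRecord]) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
            n += 1
    return n


def read_fastq(
    path: str | Path, sample: str = "", role: str = "", replicate: int = 0
) -> list[ReadRecord]:
    out = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            out.append(
                ReadRecord(
                    read_id=title.split()[0],
                    sequence=seq,
                    quality=qual,
                    sample=sample,
                    role=role,
                    replicate=replicate,
                )
            )
    return out


# ----------------------------------------------------------------------------- GTF


def write_gtf(path: str | Path, transcripts: list[TranscriptModel]) -> None:
    """Emit gene/transcript/exon/CDS records, 1-based inclusive."""
    with open(path, "w") as fh:
        for t in transcripts:
            biotype = "protein_coding" if t.biotype == "coding" else "lncRNA"
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{biotype}";'
            )

            def line(feature: str, s: int, e: int) -> str:
                return (
                    f"{t.chrom}\tmirclip\t{feature}\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )

            fh.write(line("gene", t.start, t.end))
            fh.write(line("transcript", t.start, t.end))
            for s, e in t.exons:
                fh.write(line("exon", s, e))
            if t.cds is not None:
                fh.write(line("CDS", t.cds[0], t.cds[1]))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse the GTF dialect written by :func:`write_gtf` back into models."""
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = raw.rstrip("\n").split("\t")
            fields = dict(
                item.strip().split(" ", 1)
                for item in attrs.strip().rstrip(";").split(";")
                if item.strip()
            )
            gene_id = fields["gene_id"].strip('"')
            tx_id = fields["transcript_id"].strip('"')
            biotype = fields.get("gene_biotype", '"protein_coding"').strip('"')
            d = per_tx.setdefault(
                tx_id,
                {"gene_id": gene_id, "chrom": chrom, "strand": strand,
                 "biotype": biotype, "exons": [], "cds": None},
            )
            s, e = int(start) - 1, int(end)
            if feature == "exon":
                d["exons"].append((s, e))
            elif feature == "CDS":
                d["cds"] = (s, e) if d["cds"] is None else (
                    min(d["cds"][0], s), max(d["cds"][1], e))
    out = []
    for tx_id, d in per_tx.items():
        out.append(
            TranscriptModel(
                gene_id=d["gene_id"],
                transcript_id=tx_id,
                chrom=d["chrom"],
                strand=d["strand"],
                exons=tuple(sorted(d["exons"])),
                cds=d["cds"],
                biotype="coding" if d["biotype"] == "protein_coding" else "noncoding",
            )
        )
    return out


# -------------------------------------------------------------- miRNA / family TSV


def write_mirna_fasta(path: str | Path, mirnas: list[MiRNA]) -> None:
    write_fasta(path, {m.name: m.sequence for m in mirnas})


def write_family_tsv(path: str | Path, mirnas: list[MiRNA]) -> None:
    pd.DataFrame(
        [
            {
                "mirna": m.name,
                "family_id": m.family_id or "",
                "seed": m.seed,
                "allowlisted": int(m.allowlisted),
            }
            for m in mirnas
        ]
    ).to_csv(path, sep="\t", index=False)


def read_mirnas(
    fasta_path: str | Path, family_tsv: Optional[str | Path] = None
) -> list[MiRNA]:
    seqs = read_fasta(fasta_path)
    meta: dict[str, dict] = {}
    if family_tsv is not None:
        df = pd.read_csv(family_tsv, sep="\t", dtype=str).fillna("")
        for _, row in df.iterrows():
            meta[row["mirna"]] = {
                "family_id": row["family_id"] or None,
                "allowlisted": row.get("allowlisted", "1") in ("1", "True", "true"),
            }
    return [
        MiRNA(
            name=name,
            sequence=seq,
            family_id=meta.get(name, {}).get("family_id"),
            allowlisted=meta.get(name, {}).get("allowlisted", True),
        )
        for name, seq in seqs.items()
    ]


# ------------------------------------------------------------------- truth / sites


def write_truth_tsv(path: str | Path, truth: list[TruthRecord]) -> None:
    pd.DataFrame(
        [
            {
                "read_id": t.read_id,
                "role": t.role,
                "read_class": t.read_class,
                "mirna_name": t.mirna_name or "",
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "gene_id": t.gene_id or "",
                "region": t.region or "",
                "umi": t.umi,
                "duplicate_of": t.duplicate_of or "",
            }
            for t in truth
        ]
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        TruthRecord(
            read_id=r.read_id,
            role=r.role,
            read_class=r.read_class,
            mirna_name=r.mirna_name or None,
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            gene_id=r.gene_id or None,
            region=r.region or None,
            umi=r.umi,
            duplicate_of=r.duplicate_of or None,
        )
        for r in df.itertuples()
    ]


def write_sites_tsv(path: str | Path, sites: list[SiteSpec]) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "region": s.region,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "mirna": s.mirna or "",
                "weight": s.weight,
            }
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> list[SiteSpec]:
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str}).fillna({"mirna": ""})
    return [
        SiteSpec(
            gene_id=r.gene_id,
            region=r.region,
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            mirna=r.mirna or None,
            weight=float(r.weight),
        )
        for r in df.itertuples()
    ]


# ------------------------------------------------------------- fragments (BED+TSV)

_FRAG_META_COLS = [
    "read_id", "umi", "sample", "role", "replicate", "mirna_tag", "mismatches",
]


def write_fragments(bed_path: str | Path, meta_path: str | Path,
                    fragments: list[AlignedFragment]) -> None:
    with open(bed_path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.read_id}\t{f.mismatches}\t{f.strand}\n")
    pd.DataFrame(
        [
            {
                "read_id": f.read_id,
                "umi": f.umi,
                "sample": f.sample,
                "role": f.role,
                "replicate": f.replicate,
                "mirna_tag": f.mirna_tag or "",
                "mismatches": f.mismatches,
            }
            for f in fragments
        ],
        columns=_FRAG_META_COLS,
    ).to_csv(meta_path, sep="\t", index=False)


def read_fragments(bed_path: str | Path, meta_path: str | Path) -> list[AlignedFragment]:
    meta: dict[str, dict] = {}
    mdf = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    for r in mdf.itertuples():
        meta[r.read_id] = {
            "umi": r.umi,
            "sample": r.sample,
            "role": r.role,
            "replicate": int(r.replicate),
            "mirna_tag": r.mirna_tag or None,
        }
    out = []
    with open(bed_path) as fh:
        for raw in fh:
            chrom, start, end, read_id, score, strand = raw.rstrip("\n").split("\t")
            m = meta[read_id]
            out.append(
                AlignedFragment(
                    chrom=chrom, start=int(start), end=int(end), strand=strand,
                    umi=m["umi"], read_id=read_id, sample=m["sample"],
                    role=m["role"], replicate=m["replicate"],
                    mirna_tag=m["mirna_tag"], mismatches=int(score),
                )
            )
    return out


# ----------------------------------------------------------------------- peaks TSV

_PEAK_COLS = [
    "chrom", "start", "end", "strand", "sample", "replicates", "peak_type",
    "ip_count", "input_count", "ip_rpm", "log2fc", "p_value", "reproducible",
    "annotation", "gene_id", "mirna_counts",
]


def write_peaks(path: str | Path, peaks: list[Peak]) -> None:
    pd.DataFrame(
        [
            {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "strand": p.strand,
                "sample": p.sample,
                "replicates": ",".join(str(r) for r in p.replicates),
                "peak_type": p.peak_type,
                "ip_count": p.ip_count,
                "input_count": p.input_count,
                "ip_rpm": f"{p.ip_rpm:.6g}",
                "log2fc": f"{p.log2fc:.6g}",
                "p_value": f"{p.p_value:.6g}",
                "reproducible": int(p.reproducible),
                "annotation": p.annotation,
                "gene_id": p.gene_id,
                "mirna_counts": ";".join(
                    f"{k}:{v}" for k, v in sorted(p.mirna_counts.items())
                ),
            }
            for p in peaks
        ],
        columns=_PEAK_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_peaks(path: str | Path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for r in df.itertuples():
        counts = {}
        if r.mirna_counts:
            for item in r.mirna_counts.split(";"):
                k, v = item.rsplit(":", 1)
                counts[k] = int(v)
        out.append(
            Peak(
                chrom=r.chrom, start=int(r.start), end=int(r.end), strand=r.strand,
                sample=r.sample,
                replicates=tuple(int(x) for x in r.replicates.split(",") if x),
                peak_type=r.peak_type, ip_count=int(r.ip_count),
                input_count=int(r.input_count), ip_rpm=float(r.ip_rpm),
                log2fc=float(r.log2fc), p_value=float(r.p_value),
                reproducible=r.reproducible in ("1", "True"),
                annotation=r.annotation, gene_id=r.gene_id, mirna_counts=counts,
            )
        )
    return out


# ------------------------------------------------------------------------ Ct / misc


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Ct TSV: sample_id, condition, primer_set, target_role, ct_rep1..ct_repN."""
    df = pd.read_csv(path, sep="\t")
    ct_cols = [c for c in df.columns if c.startswith("ct_rep")]
    out = []
    for r in df.itertuples():
        cts = tuple(
            float(getattr(r, c)) for c in ct_cols if pd.notna(getattr(r, c))
        )
        out.append(
            CtRecord(
                sample_id=str(r.sample_id),
                condition=str(r.condition),
                primer_set=str(r.primer_set),
                target_role=str(r.target_role),
                ct_values=cts,
            )
        )
    return out


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
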
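"""Synthetic miR-eCLIP data with known ground truth.

The generator builds a toy genome (coding and noncoding transcripts,
repeat/rRNA-like intervals, seed-grouped mature miRNAs) and simulates paired
IP / size-matched-input libraries of UMI-bearing single-end reads: planted
AGO2 occupancy sites, rare chimeric reads carrying a full mature miRNA
ligated 5' of a target fragment, transcriptome background, repeat-derived
background, PCR duplicates, and substitution sequencing errors.  Every read
is accounted for in a machine-readable truth table.

The chimera geometry is miRNA-first: the ligation joins the miRNA 3' end to
the target fragment 5' end, so the simulated insert is
``mature miRNA + target fragment`` — the same convention the detector
assumes.
"""
from __future__ import annotations

import string
from dataclasses import replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import io
from .preprocess import _first_adapter_hit
from .models import (
    GenomeBundle,
    MiRNA,
    ReadRecord,
    SimParams,
    SiteSpec,
    TranscriptModel,
    TruthRecord,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


# ------------------------------------------------------------------------- genome


def make_genome(
    n_chroms: int = 2,
    n_genes: int = 20,
    n_mirnas: int = 12,
    n_families: int = 5,
    seed: int = 0,
    chrom_length: Optional[int] = None,
    noncoding_per_chrom: int = 2,
) -> GenomeBundle:
    """Build a deterministic toy genome.

    ``n_genes`` protein-coding genes (each with 5'UTR, multi-exon CDS,
    introns, and a 3'UTR long enough to host binding sites) are laid out
    across ``n_chroms`` chromosomes, interleaved with noncoding genes and
    one repeat/rRNA-like interval per chromosome.  ``n_mirnas`` mature
    miRNAs are grouped into exactly ``n_families`` seed families.

    If ``chrom_length`` is given and too short to host the requested genes,
    a sizing error names the constraint.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (n_mirnas >= n_families >= 1):
        raise ValueError("need n_mirnas >= n_families >= 1")
    rng = np.random.default_rng(seed)

    chromosomes: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    repeats: list[tuple[str, int, int]] = []

    # round-robin gene assignment to chromosomes
    genes_per_chrom = [len(range(c, n_genes, n_chroms)) for c in range(n_chroms)]
    gene_serial = 0
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        parts: list[str] = []
        pos = 0

        def spacer(lo: int = 200, hi: int = 400) -> None:
            nonlocal pos
            n = int(rng.integers(lo, hi))
            parts.append(_random_seq(rng, n))
            pos += n

        spacer()
        # one repeat/rRNA-like region per chromosome: tandem copies of a unit
        unit = _random_seq(rng, 25)
        n_copies = 14
        repeats.append((chrom, pos, pos + n_copies * len(unit)))
        parts.append(unit * n_copies)
        pos += n_copies * len(unit)
        spacer()

        for g in range(genes_per_chrom[c]):
            gene_serial += 1
            strand = "+" if gene_serial % 2 else "-"
            gid = f"gene{gene_serial:03d}"
            utr5 = int(rng.integers(50, 80))
            cds1 = int(rng.integers(90, 140))
            i1 = int(rng.integers(500, 800))
            cds2 = int(rng.integers(90, 140))
            i2 = int(rng.integers(500, 800))
            cds3 = int(rng.integers(60, 100))
            utr3 = int(rng.integers(260, 340))
            if strand == "+":
                e1 = (pos, pos + utr5 + cds1)
                e2 = (e1[1] + i1, e1[1] + i1 + cds2)
                e3 = (e2[1] + i2, e2[1] + i2 + cds3 + utr3)
                cds = (pos + utr5, e3[0] + cds3)
            else:  # mirrored: 3'UTR genomically left
                e1 = (pos, pos + utr3 + cds3)
                e2 = (e1[1] + i2, e1[1] + i2 + cds2)
                e3 = (e2[1] + i1, e2[1] + i1 + cds1 + utr5)
                cds = (pos + utr3, e3[0] + cds1)
            span = e3[1] - pos
            parts.append(_random_seq(rng, span))
            transcripts.append(
                TranscriptModel(
                    gene_id=gid,
                    transcript_id=f"{gid}.t1",
                    chrom=chrom,
                    strand=strand,
                    exons=(e1, e2, e3),
                    cds=cds,
                    biotype="coding",
                )
            )
            pos += span
            spacer()

        for n in range(noncoding_per_chrom):
            gid = f"ncgene{c + 1:02d}{n + 1}"
            x1 = int(rng.integers(100, 160))
            xi = int(rng.integers(80, 130))
            x2 = int(rng.integers(100, 160))
            e1 = (pos, pos + x1)
            e2 = (e1[1] + xi, e1[1] + xi + x2)
            parts.append(_random_seq(rng, e2[1] - pos))
            transcripts.append(
                TranscriptModel(
                    gene_id=gid,
                    transcript_id=f"{gid}.t1",
                    chrom=chrom,
                    strand="+" if n % 2 else "-",
                    exons=(e1, e2),
                    cds=None,
                    biotype="noncoding",
                )
            )
            pos += e2[1] - pos
            spacer()

        seq = "".join(parts)
        if chrom_length is not None:
            if pos > chrom_length:
                raise ValueError(
                    f"chromosome {chrom} needs {pos} bp to host "
                    f"{genes_per_chrom[c]} genes but chrom_length={chrom_length}"
                )
            seq = seq + _random_seq(rng, chrom_length - pos)
        chromosomes[chrom] = seq

    mirnas = _make_mirnas(rng, n_mirnas, n_families)
    return GenomeBundle(
        chromosomes=chromosomes, transcripts=transcripts, repeats=repeats, mirnas=mirnas
    )


def _make_mirnas(rng: np.random.Generator, n_mirnas: int, n_families: int) -> list[MiRNA]:
    seeds: set[str] = set()
    while len(seeds) < n_families:
        seeds.add(_random_seq(rng, 7))
    seed_list = sorted(seeds)
    # every family gets one member, the rest are spread round-robin
    members_of = [1 + len(range(f, n_mirnas - n_families, n_families))
                  for f in range(n_families)]
    mirnas = []
    for f, (sd, k) in enumerate(zip(seed_list, members_of)):
        for j in range(k):
            length = int(rng.integers(20, 23))
            seq = _random_seq(rng, 1) + sd + _random_seq(rng, length - 8)
            name = f"mir-{f + 1}{string.ascii_lowercase[j]}"
            mirnas.append(
                MiRNA(name=name, sequence=seq, family_id=f"fam{f + 1:02d}")
            )
    return mirnas


def write_bundle(bundle: GenomeBundle, outdir: str | Path) -> dict[str, Path]:
    """Persist a bundle as FASTA + GTF + miRNA FASTA + family TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gtf",
        "mirnas": outdir / "mirnas.fa",
        "families": outdir / "families.tsv",
    }
    io.write_fasta(paths["genome"], bundle.chromosomes)
    io.write_gtf(paths["annotation"], bundle.transcripts)
    io.write_mirna_fasta(paths["mirnas"], bundle.mirnas)
    io.write_family_tsv(paths["families"], bundle.mirnas)
    return paths


# -------------------------------------------------------------------------- sites


def default_site_map(
    bundle: GenomeBundle,
    n_genes: Optional[int] = 10,
    sites_per_gene: int = 2,
    region: str = "UTR3",
    site_length: int = 60,
    seed: int = 0,
) -> list[SiteSpec]:
    """Plant miRNA binding sites in the given region of coding genes.

    Sites cycle through the bundle's miRNAs so that every family is
    represented; each site carries equal weight.
    """
    rng = np.random.default_rng(seed)
    coding = [t for t in bundle.transcripts if t.biotype == "coding"]
    if n_genes is not None:
        coding = coding[:n_genes]
    sites: list[SiteSpec] = []
    k = 0
    for t in coding:
        iv = t.region_interval(region)
        if iv is None or iv[1] - iv[0] < site_length:
            raise ValueError(
                f"{t.gene_id}: {region} shorter than site_length={site_length}"
            )
        lo, hi = iv
        # non-overlapping site slots within the region
        slots = (hi - lo) // site_length
        chosen = rng.permutation(slots)[: min(sites_per_gene, slots)]
        for s in sorted(chosen):
            start = lo + int(s) * site_length
            mir = bundle.mirnas[k % len(bundle.mirnas)]
            k += 1
            sites.append(
                SiteSpec(
                    gene_id=t.gene_id,
                    region=region,
                    chrom=t.chrom,
                    start=start,
                    end=start + site_length,
                    strand=t.strand,
                    mirna=mir.name,
                    weight=1.0,
                )
            )
    return sites


def make_expression_table(
    bundle: GenomeBundle,
    site_map: list[SiteSpec],
    seed: int = 0,
    regulated_log2fc: tuple[float, float] = (2.0, 4.0),
):
    """Synthetic WT vs DROSHA-knockout expression comparison.

    Genes carrying planted miRNA sites are de-repressed on miRNA loss
    (positive log2 fold change, significant); other genes fluctuate around
    zero and are not significant.  Returns a DataFrame with columns
    gene_id, log2fc, significant.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    site_genes = {s.gene_id for s in site_map if s.mirna is not None}
    rows = []
    for t in bundle.transcripts:
        if t.biotype != "coding":
            continue
        if t.gene_id in site_genes:
            lfc = float(rng.uniform(*regulated_log2fc))
            sig = 1
        else:
            lfc = float(rng.normal(0.0, 0.3))
            sig = 0
        rows.append({"gene_id": t.gene_id, "log2fc": round(lfc, 4), "significant": sig})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------------ library


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def simulate_libraries(
    bundle: GenomeBundle,
    params: SimParams,
    read_prefix: str = "sim",
) -> tuple[list[ReadRecord], list[ReadRecord], list[TruthRecord]]:
    """Simulate one paired (IP, input) library.

    IP reads are drawn from four classes — chimeric, repeat, background and
    nonchimeric site occupancy — in the proportions given by ``params``;
    the input library is pure transcriptome background with no site
    enrichment.  PCR duplicates re-emit an earlier molecule's UMI+insert
    with independent sequencing errors.  Returns (ip_reads, input_reads,
    truth) with one truth record per read.
    """
    rng = np.random.default_rng(params.seed)
    _validate_sites(bundle, params)
    mir_by_name = {m.name: m for m in bundle.mirnas}
    sites = params.site_map
    mir_sites = [s for s in sites if s.mirna is not None]
    weights = np.array([s.weight for s in sites], dtype=float) if sites else None
    if weights is not None:
        weights = weights / weights.sum()
    mir_weights = (
        np.array([s.weight for s in mir_sites], dtype=float) if mir_sites else None
    )
    if mir_weights is not None:
        mir_weights = mir_weights / mir_weights.sum()
    coding_spans = [
        (t.chrom, t.start, t.end, t.strand, t.gene_id) for t in bundle.transcripts
    ]
    span_weights = np.array([e - s for _, s, e, _, _ in coding_spans], dtype=float)
    span_weights /= span_weights.sum()

    capacity = params.read_length - params.umi_length

    def new_molecule(role: str) -> dict:
        """Draw one original molecule, rejecting adapter-aliased inserts.

        A fragment whose visible 3' end happens to match a prefix of the
        adapter is indistinguishable from adapter read-through for any 3'
        trimmer, so such fragments are resampled (a few percent of draws).
        """
        for _ in range(50):
            mol = _draw_molecule(role)
            visible = mol["insert"][:capacity]
            if _first_adapter_hit(visible, params.adapter, 3, 0.1) is None:
                return mol
        return mol

    def _draw_molecule(role: str) -> dict:
        if role == "input":
            cls = "background"
        else:
            u = rng.random()
            if u < params.chimera_fraction:
                cls = "chimeric"
            elif u < params.chimera_fraction + params.repeat_fraction:
                cls = "repeat"
            elif u < (
                params.chimera_fraction
                + params.repeat_fraction
                + params.background_fraction
            ):
                cls = "background"
            else:
                cls = "nonchimeric_site" if sites else "background"

        frag_len = int(rng.integers(params.min_fragment, params.max_fragment + 1))
        mirna_name = None
        gene_id = region = None
        if cls == "chimeric":
            site = mir_sites[int(rng.choice(len(mir_sites), p=mir_weights))]
            frag_len = min(frag_len, site.end - site.start)
            start = int(rng.integers(site.start, site.end - frag_len + 1))
            chrom, strand = site.chrom, site.strand
            frag = _slice(bundle, chrom, start, start + frag_len, strand)
            mirna_name = site.mirna
            insert = mir_by_name[site.mirna].sequence + frag
            gene_id, region = site.gene_id, site.region
            origin = (chrom, start, start + frag_len, strand)
        elif cls == "nonchimeric_site":
            site = sites[int(rng.choice(len(sites), p=weights))]
            frag_len = min(frag_len, site.end - site.start)
            start = int(rng.integers(site.start, site.end - frag_len + 1))
            chrom, strand = site.chrom, site.strand
            insert = _slice(bundle, chrom, start, start + frag_len, strand)
            gene_id, region = site.gene_id, site.region
            origin = (chrom, start, start + frag_len, strand)
        elif cls == "repeat":
            chrom, rs, re_ = bundle.repeats[int(rng.integers(len(bundle.repeats)))]
            frag_len = min(frag_len, re_ - rs)
            start = int(rng.integers(rs, re_ - frag_len + 1))
            strand = "+"
            insert = _slice(bundle, chrom, start, start + frag_len, strand)
            region = "repeat"
            origin = (chrom, start, start + frag_len, strand)
        else:  # background: uniform over transcript spans (pre-mRNA)
            chrom, ts, te, strand, gene_id = coding_spans[
                int(rng.choice(len(coding_spans), p=span_weights))
            ]
            frag_len = min(frag_len, te - ts)
            start = int(rng.integers(ts, te - frag_len + 1))
            insert = _slice(bundle, chrom, start, start + frag_len, strand)
            origin = (chrom, start, start + frag_len, strand)
        umi = _random_seq(rng, params.umi_length)
        return {
            "class": cls,
            "umi": umi,
            "insert": insert,
            "origin": origin,
            "mirna": mirna_name,
            "gene_id": gene_id,
            "region": region,
        }

    def emit(role: str, n_reads: int, id_prefix: str):
        reads: list[ReadRecord] = []
        truth: list[TruthRecord] = []
        pool: list[tuple[str, dict]] = []  # (read_id, molecule)
        for i in range(n_reads):
            rid = f"{id_prefix}:{i:07d}"
            if pool and rng.random() < params.pcr_duplication_rate:
                orig_id, mol = pool[int(rng.integers(len(pool)))]
                dup_of = orig_id
            else:
                mol = new_molecule(role)
                dup_of = None
                pool.append((rid, mol))
            full = mol["umi"] + mol["insert"] + params.adapter
            seq = _apply_errors(
                rng, full[: params.read_length], params.sequencing_error_rate
            )
            reads.append(
                ReadRecord(read_id=rid, sequence=seq, quality="I" * len(seq), role=role)
            )
            chrom, s, e, strand = mol["origin"]
            truth.append(
                TruthRecord(
                    read_id=rid,
                    role=role,
                    read_class=mol["class"],
                    mirna_name=mol["mirna"],
                    chrom=chrom,
                    start=s,
                    end=e,
                    strand=strand,
                    gene_id=mol["gene_id"],
                    region=mol["region"],
                    umi=mol["umi"],
                    duplicate_of=dup_of,
                )
            )
        return reads, truth

    ip_reads, ip_truth = emit("IP", params.n_reads_ip, f"{read_prefix}:ip")
    in_reads, in_truth = emit("input", params.n_reads_input, f"{read_prefix}:in")
    return ip_reads, in_reads, ip_truth + in_truth


def _slice(bundle: GenomeBundle, chrom: str, start: int, end: int, strand: str) -> str:
    s = bundle.chromosomes[chrom][start:end]
    return s if strand == "+" else revcomp(s)


def _validate_sites(bundle: GenomeBundle, params: SimParams) -> None:
    if params.chimera_fraction > 0 and not any(
        s.mirna is not None for s in params.site_map
    ):
        raise ValueError("chimera_fraction > 0 but no site carries a miRNA assignment")
    for s in params.site_map:
        if s.end - s.start < params.min_fragment:
            raise ValueError(
                f"site {s.gene_id}:{s.start}-{s.end} shorter than minimum "
                f"fragment {params.min_fragment}"
            )
        if s.chrom not in bundle.chromosomes:
            raise ValueError(f"site on unknown chromosome {s.chrom}")
        t = bundle.transcript(s.gene_id)
        iv = t.region_interval(s.region)
        if iv is None or not (iv[0] <= s.start and s.end <= iv[1]):
            raise ValueError(
                f"site {s.start}-{s.end} not inside {s.region} of {s.gene_id}"
            )
        if s.mirna is not None and s.mirna not in {m.name for m in bundle.mirnas}:
            raise ValueError(f"site names unknown miRNA {s.mirna}")
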
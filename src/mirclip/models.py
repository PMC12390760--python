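"""Core data types shared across the miR-eCLIP pipeline.

Coordinates are 0-based, half-open throughout the package; conversion to
1-based inclusive happens only at the GTF boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def extract_seed(sequence: str, window: tuple[int, int] = (2, 8)) -> str:
    """Seed of a mature miRNA: nucleotides `window` (1-based, inclusive).

    The default (2, 8) is the prevailing 7-mer family definition.
    """
    lo, hi = window
    if hi > len(sequence):
        raise ValueError(f"sequence shorter than seed window {window}: {sequence!r}")
    return sequence[lo - 1 : hi]


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA with its seed-derived family membership."""

    name: str
    sequence: str
    family_id: Optional[str] = None
    allowlisted: bool = True

    @property
    def seed(self) -> str:
        return extract_seed(self.sequence)

    def __post_init__(self) -> None:
        if not (18 <= len(self.sequence) <= 24):
            raise ValueError(
                f"mature miRNA {self.name} length {len(self.sequence)} outside 18-24 nt"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """A gene/transcript: strand, exons, optional CDS span, biotype.

    ``exons`` are sorted, pairwise-disjoint 0-based half-open intervals.
    ``cds`` is the genomic (start, end) span of the coding region for
    ``biotype="coding"`` transcripts and None for noncoding ones.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: Optional[tuple[int, int]] = None
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(f"bad biotype {self.biotype!r}")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e
        if self.biotype == "noncoding" and self.cds is not None:
            raise ValueError(f"{self.transcript_id}: noncoding transcript with CDS")
        if self.biotype == "coding":
            if self.cds is None:
                raise ValueError(f"{self.transcript_id}: coding transcript without CDS")
            cs, ce = self.cds
            if not (self._in_exon(cs) and self._in_exon(ce - 1)):
                raise ValueError(
                    f"{self.transcript_id}: CDS ({cs}, {ce}) outside exon union"
                )

    def _in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def features(self) -> list[tuple[str, int, int]]:
        """Decompose the transcript into (category, start, end) intervals.

        Coding transcripts yield UTR5/CDS/UTR3/intron, noncoding ones
        nc_exon/nc_intron.  UTR sidedness is strand-aware: on the minus
        strand the 3'UTR lies genomically left of the CDS.
        """
        out: list[tuple[str, int, int]] = []
        intron_cat = "intron" if self.biotype == "coding" else "nc_intron"
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((intron_cat, e1, s2))
        if self.biotype == "noncoding":
            out.extend(("nc_exon", s, e) for s, e in self.exons)
            return out
        cs, ce = self.cds  # type: ignore[misc]
        left_cat = "UTR5" if self.strand == "+" else "UTR3"
        right_cat = "UTR3" if self.strand == "+" else "UTR5"
        for s, e in self.exons:
            if e <= cs:
                out.append((left_cat, s, e))
                continue
            if s >= ce:
                out.append((right_cat, s, e))
                continue
            if s < cs:
                out.append((left_cat, s, cs))
            out.append(("CDS", max(s, cs), min(e, ce)))
            if e > ce:
                out.append((right_cat, ce, e))
        return out

    def region_interval(self, region: str) -> Optional[tuple[int, int]]:
        """Genomic span of the first/largest interval of a feature category."""
        hits = [(s, e) for cat, s, e in self.features() if cat == region]
        if not hits:
            return None
        return max(hits, key=lambda iv: iv[1] - iv[0])


@dataclass
class GenomeBundle:
    """A toy genome: chromosome sequences, transcripts, repeats, miRNAs."""

    chromosomes: dict[str, str]
    transcripts: list[TranscriptModel]
    repeats: list[tuple[str, int, int]]
    mirnas: list[MiRNA]

    def __post_init__(self) -> None:
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for t in self.transcripts:
            if t.chrom not in self.chromosomes:
                raise ValueError(f"{t.transcript_id}: unknown chromosome {t.chrom}")
            if t.end > len(self.chromosomes[t.chrom]):
                raise ValueError(f"{t.transcript_id}: extends past end of {t.chrom}")
        for chrom, s, e in self.repeats:
            if chrom not in self.chromosomes or e > len(self.chromosomes[chrom]) or s < 0:
                raise ValueError(f"repeat ({chrom}, {s}, {e}) outside genome")
        names = [m.name for m in self.mirnas]
        if len(set(names)) != len(names):
            raise ValueError("duplicate miRNA names")

    def transcript(self, gene_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.gene_id == gene_id:
                return t
        raise KeyError(gene_id)


@dataclass(frozen=True)
class SiteSpec:
    """A planted AGO2 binding site used by the simulator."""

    gene_id: str
    region: str
    chrom: str
    start: int
    end: int
    strand: str
    mirna: Optional[str] = None  # None => nonchimeric-only occupancy site
    weight: float = 1.0


@dataclass
class SimParams:
    """Knobs of the library simulator; defaults are the study conditions."""

    seed: int = 0
    n_reads_ip: int = 50_000
    n_reads_input: int = 50_000
    chimera_fraction: float = 0.02
    repeat_fraction: float = 0.05
    background_fraction: float = 0.01
    umi_length: int = 10
    adapter: str = "AGATCGGAAGAGCACACGTCT"
    read_length: int = 75
    pcr_duplication_rate: float = 0.15
    sequencing_error_rate: float = 0.001
    min_fragment: int = 25
    max_fragment: int = 45
    site_map: list[SiteSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in (
            "chimera_fraction",
            "repeat_fraction",
            "background_fraction",
            "pcr_duplication_rate",
            "sequencing_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.chimera_fraction + self.repeat_fraction + self.background_fraction > 1.0:
            raise ValueError("read-class proportions sum to more than 1")
        if self.read_length <= self.umi_length + self.min_fragment:
            raise ValueError("read_length must exceed umi_length + minimum insert")


@dataclass(frozen=True)
class TruthRecord:
    """Simulator ground truth for one read; the acceptance oracle."""

    read_id: str
    role: str  # IP | input
    read_class: str  # chimeric | nonchimeric_site | background | repeat
    mirna_name: Optional[str]
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: Optional[str]
    region: Optional[str]
    umi: str
    duplicate_of: Optional[str] = None


@dataclass
class ReadRecord:
    """A sequencing read moving through preprocessing."""

    read_id: str
    sequence: str
    quality: str
    umi: str = ""
    sample: str = ""
    role: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class MappingResult:
    status: str  # unique | multi | unmapped
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None
    mismatches: Optional[int] = None


@dataclass(frozen=True)
class AlignedFragment:
    """A deduplicatable mapped read (or chimera target-half)."""

    chrom: str
    start: int
    end: int
    strand: str
    umi: str
    read_id: str
    sample: str = ""
    role: str = ""
    replicate: int = 0
    mirna_tag: Optional[str] = None
    mismatches: int = 0


@dataclass(frozen=True)
class ChimeraCall:
    read_id: str
    mirna_name: str
    match_length: int
    mismatches: int
    target_span: tuple[int, int]
    ambiguous_with: tuple[str, ...] = ()


@dataclass
class Peak:
    """A called cluster with enrichment statistics and annotation."""

    chrom: str
    start: int
    end: int
    strand: str
    sample: str
    replicates: tuple[int, ...]
    peak_type: str  # nonchimeric | chimeric
    ip_count: int
    input_count: int = 0
    ip_rpm: float = 0.0
    log2fc: float = 0.0
    p_value: float = 1.0
    reproducible: bool = False
    annotation: str = ""
    gene_id: str = ""
    mirna_counts: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class FamilySummary:
    family_id: str
    members: tuple[str, ...]
    seed: str
    chimeric_read_count: int
    fraction_of_total: float
    rank: int


@dataclass
class CandidateGene:
    gene_id: str
    peaks_utr3_per_fraction: dict[str, int]
    any_fraction_gt5: bool
    all_fractions_ge1: bool
    expr_log2fc: Optional[float]
    expr_significant: bool
    selected: bool
    expression_known: bool = True


@dataclass(frozen=True)
class CtRecord:
    """qPCR cycle-threshold measurements for one sample x primer set."""

    sample_id: str
    condition: str
    primer_set: str
    target_role: str  # target | reference | inclusion | skipping | full_length
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_values:
            raise ValueError(f"{self.sample_id}/{self.primer_set}: no Ct values")
        if any(c <= 0 for c in self.ct_values):
            raise ValueError(f"{self.sample_id}/{self.primer_set}: nonpositive Ct")

    @property
    def mean_ct(self) -> float:
        return sum(self.ct_values) / len(self.ct_values)
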
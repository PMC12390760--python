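"""A self-contained seeded exact-match aligner for toy genomes.

Reads are mapped by exact k-mer seeding on both strands followed by
ungapped extension counting substitutions.  This is adequate for the
simulator's substitution-only reads; it does no gapped or spliced
alignment and is not meant for real genomes.  Repeat/rRNA filtering runs
against a separate index built from the repeat intervals, before genome
mapping, matching the pipeline's stage order.
"""
from __future__ import annotations

from .models import AlignedFragment, GenomeBundle, MappingResult, ReadRecord, revcomp


class SeedIndex:
    """Exact k-mer position index over a set of named sequences."""

    def __init__(self, sequences: dict[str, str], k: int = 16):
        if k < 4:
            raise ValueError("k must be >= 4")
        if not sequences:
            raise ValueError("no sequences to index")
        shortest = min(len(s) for s in sequences.values())
        if k > shortest:
            raise ValueError(f"k={k} longer than shortest sequence ({shortest} bp)")
        self.k = k
        self.sequences = sequences
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in sequences.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((name, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def build_index(sequences: dict[str, str], k: int = 16) -> SeedIndex:
    return SeedIndex(sequences, k=k)


def _seed_offsets(read_len: int, k: int, max_mismatches: int) -> range:
    """Seed positions along the read.

    When the read is long enough for ``max_mismatches + 1`` disjoint
    k-mers, disjoint seeds suffice (pigeonhole: one must be error-free);
    otherwise every offset is probed for full sensitivity at small cost.
    """
    n = read_len - k + 1
    if read_len >= k * (max_mismatches + 1):
        offsets = list(range(0, n, k))
        if offsets[-1] != n - 1:
            offsets.append(n - 1)
        return offsets  # type: ignore[return-value]
    return range(n)


def _hamming(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def _candidate_hits(
    index: SeedIndex, sequence: str, max_mismatches: int
) -> list[tuple[str, int, str, int]]:
    """All (name, start, strand, mismatches) loci attaining <= max mismatches."""
    k = index.k
    L = len(sequence)
    hits: list[tuple[str, int, str, int]] = []
    for strand, query in (("+", sequence), ("-", revcomp(sequence))):
        seen: set[tuple[str, int]] = set()
        for off in _seed_offsets(L, k, max_mismatches):
            for name, pos in index.lookup(query[off : off + k]):
                start = pos - off
                if start < 0 or start + L > len(index.sequences[name]):
                    continue
                if (name, start) in seen:
                    continue
                seen.add((name, start))
                mm = _hamming(query, index.sequences[name][start : start + L], max_mismatches)
                if mm <= max_mismatches:
                    hits.append((name, start, strand, mm))
    return hits


def map_read(index: SeedIndex, sequence: str, max_mismatches: int = 2) -> MappingResult:
    """Map one read; unique if exactly one best-scoring location exists.

    Reverse-complement hits report the minus strand with the interval on
    the forward coordinate system.
    """
    if len(sequence) < index.k:
        return MappingResult(status="unmapped")
    hits = _candidate_hits(index, sequence, max_mismatches)
    if not hits:
        return MappingResult(status="unmapped")
    best = min(h[3] for h in hits)
    winners = [h for h in hits if h[3] == best]
    if len(winners) > 1:
        return MappingResult(status="multi")
    name, start, strand, mm = winners[0]
    return MappingResult(
        status="unique",
        chrom=name,
        start=start,
        end=start + len(sequence),
        strand=strand,
        mismatches=mm,
    )


def repeat_index_from_bundle(bundle: GenomeBundle, k: int = 16) -> SeedIndex:
    """Index over the repeat/rRNA-like interval sequences of a bundle."""
    seqs = {
        f"repeat_{i}_{chrom}_{s}_{e}": bundle.chromosomes[chrom][s:e]
        for i, (chrom, s, e) in enumerate(bundle.repeats)
    }
    return SeedIndex(seqs, k=k)


def filter_repeats(
    reads: list[ReadRecord], repeat_index: SeedIndex, max_mismatches: int = 2
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Remove reads that align anywhere in the repeat database."""
    kept, removed = [], []
    for r in reads:
        if len(r.sequence) >= repeat_index.k and _candidate_hits(
            repeat_index, r.sequence, max_mismatches
        ):
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


def map_reads(
    reads: list[ReadRecord],
    index: SeedIndex,
    max_mismatches: int = 2,
    umi_from_id: bool = False,
) -> tuple[list[AlignedFragment], list[ReadRecord], dict]:
    """Map a library: unique hits become fragments, unmapped reads are
    returned for chimera detection, multi-mapped reads are discarded.
    """
    from .preprocess import umi_from_read_id

    fragments: list[AlignedFragment] = []
    unmapped: list[ReadRecord] = []
    n_multi = 0
    for r in reads:
        res = map_read(index, r.sequence, max_mismatches=max_mismatches)
        if res.status == "unique":
            umi = r.umi or (umi_from_read_id(r.read_id) if umi_from_id else "")
            fragments.append(
                AlignedFragment(
                    chrom=res.chrom,
                    start=res.start,
                    end=res.end,
                    strand=res.strand,
                    umi=umi,
                    read_id=r.read_id,
                    sample=r.sample,
                    role=r.role,
                    replicate=r.replicate,
                    mismatches=res.mismatches,
                )
            )
        elif res.status == "multi":
            n_multi += 1
        else:
            unmapped.append(r)
    ledger = {
        "n_in": len(reads),
        "n_kept": len(fragments),
        "dropped": {"multi_mapped": n_multi, "unmapped": len(unmapped)},
    }
    return fragments, unmapped, ledger
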
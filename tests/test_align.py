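"""Seeded aligner vs exhaustive brute force, and repeat filtering."""
import numpy as np
import pytest

from mirclip import synthetic
from mirclip.align import (
    SeedIndex,
    build_index,
    filter_repeats,
    map_read,
    map_reads,
    repeat_index_from_bundle,
)
from mirclip.models import ReadRecord, SimParams, revcomp
from mirclip.synthetic import _random_seq


def brute_force_map(genome: dict[str, str], seq: str, max_mm: int):
    """Exhaustive oracle: every position x both strands via numpy windows."""
    hits = []
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        qa = np.frombuffer(q.encode(), dtype="S1")
        for name, chrom in genome.items():
            ca = np.frombuffer(chrom.encode(), dtype="S1")
            if len(ca) < len(qa):
                continue
            win = np.lib.stride_tricks.sliding_window_view(ca, len(qa))
            mm = (win != qa).sum(axis=1)
            for pos in np.nonzero(mm <= max_mm)[0]:
                hits.append((name, int(pos), strand, int(mm[pos])))
    if not hits:
        return ("unmapped", None)
    best = min(h[3] for h in hits)
    winners = [h for h in hits if h[3] == best]
    if len(winners) > 1:
        return ("multi", None)
    return ("unique", winners[0])


def test_index_enumeration_and_absent_kmer():
    idx = SeedIndex({"c": "ACGTACGT"}, k=4)
    assert sorted(idx.lookup("ACGT")) == [("c", 0), ("c", 4)]
    assert idx.lookup("TTTT") == []


def test_index_lookup_equals_naive_scan():
    rng = np.random.default_rng(0)
    seq = _random_seq(rng, 10_000)
    idx = build_index({"c": seq}, k=12)
    for _ in range(100):
        pos = int(rng.integers(0, len(seq) - 12))
        kmer = seq[pos : pos + 12]
        naive = [("c", i) for i in range(len(seq) - 11) if seq[i : i + 12] == kmer]
        assert sorted(idx.lookup(kmer)) == naive


def test_index_rejects_bad_k():
    with pytest.raises(ValueError):
        SeedIndex({"c": "ACGTACGT"}, k=16)  # k longer than shortest sequence
    with pytest.raises(ValueError):
        SeedIndex({"c": "A" * 100}, k=2)


def test_exact_mapping_and_strand_round_trip():
    rng = np.random.default_rng(1)
    genome = {"chr1": _random_seq(rng, 5000)}
    idx = SeedIndex(genome, k=16)
    read = genome["chr1"][100:130]
    res = map_read(idx, read)
    assert (res.status, res.chrom, res.start, res.end, res.strand, res.mismatches) == (
        "unique", "chr1", 100, 130, "+", 0
    )
    rc = map_read(idx, revcomp(read))
    assert (rc.status, rc.start, rc.end, rc.strand) == ("unique", 100, 130, "-")


def test_planted_duplicate_is_multi():
    rng = np.random.default_rng(2)
    core = _random_seq(rng, 30)
    genome = {"chr1": _random_seq(rng, 1000) + core + _random_seq(rng, 500)
              + core + _random_seq(rng, 200)}
    idx = SeedIndex(genome, k=16)
    assert map_read(idx, core).status == "multi"
    assert brute_force_map(genome, core, 2)[0] == "multi"


def test_seeded_aligner_equals_brute_force():
    """1000 random reads (exact copies, reverse complements, error copies,
    and unrelated sequence) agree with the exhaustive aligner."""
    rng = np.random.default_rng(3)
    genome = {"chrA": _random_seq(rng, 6000), "chrB": _random_seq(rng, 4000)}
    k = 16
    idx = SeedIndex(genome, k=k)
    names = list(genome)
    for i in range(1000):
        L = int(rng.integers(20, 64))
        kind = i % 4
        if kind == 3:
            seq = _random_seq(rng, L)
        else:
            name = names[int(rng.integers(2))]
            pos = int(rng.integers(0, len(genome[name]) - L))
            seq = genome[name][pos : pos + L]
            if kind == 1:
                seq = revcomp(seq)
            elif kind == 2:
                # plant substitutions within the seeding sensitivity
                # envelope (full sensitivity for m errors needs
                # L >= (m + 1) * k by pigeonhole)
                n_err = min(L // k - 1, 2)
                for p in rng.integers(0, L, size=n_err):
                    arr = list(seq)
                    arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
                    seq = "".join(arr)
        got = map_read(idx, seq, max_mismatches=2)
        want_status, want_hit = brute_force_map(genome, seq, 2)
        assert got.status == want_status
        if want_status == "unique":
            name, pos, strand, mm = want_hit
            assert (got.chrom, got.start, got.strand, got.mismatches) == (
                name, pos, strand, mm
            )


def test_repeat_filter_removes_exactly_repeat_reads(bundle, sites):
    """On error-free simulated reads the removed set equals the truth records
    of class repeat; site reads pass through."""
    params = SimParams(
        seed=8, n_reads_ip=2000, n_reads_input=0, site_map=sites,
        sequencing_error_rate=0.0, pcr_duplication_rate=0.0,
    )
    ip, _, truth = synthetic.simulate_libraries(bundle, params)
    truth_by_id = {t.read_id: t for t in truth}
    # UMI-extract and adapter-trim as the pipeline would before filtering
    from mirclip.preprocess import preprocess_reads

    reads, _ = preprocess_reads(ip, umi_length=params.umi_length,
                                adapter=params.adapter)
    for r in reads:
        r.read_id = r.read_id.rsplit("_", 1)[0]
    ridx = repeat_index_from_bundle(bundle)
    kept, removed = filter_repeats(reads, ridx)
    removed_classes = {truth_by_id[r.read_id].read_class for r in removed}
    assert removed_classes == {"repeat"}
    n_repeat_truth = sum(1 for t in truth if t.read_class == "repeat")
    assert len(removed) == n_repeat_truth


def test_simulated_reads_map_to_truth_origin(bundle, sites):
    """Error-free nonchimeric reads map uniquely back to their origin."""
    params = SimParams(
        seed=12, n_reads_ip=500, n_reads_input=0, site_map=sites,
        sequencing_error_rate=0.0, pcr_duplication_rate=0.0,
        chimera_fraction=0.0, repeat_fraction=0.0,
    )
    ip, _, truth = synthetic.simulate_libraries(bundle, params)
    truth_by_id = {t.read_id: t for t in truth}
    idx = SeedIndex(bundle.chromosomes, k=16)
    reads = []
    for r in ip:
        t = truth_by_id[r.read_id]
        insert = r.sequence[10 : 10 + (t.end - t.start)]
        reads.append(
            ReadRecord(read_id=r.read_id, sequence=insert,
                       quality="I" * len(insert), umi="X")
        )
    frags, unmapped, ledger = map_reads(reads, idx)
    assert not unmapped and ledger["dropped"]["multi_mapped"] == 0
    for f in frags:
        t = truth_by_id[f.read_id]
        assert (f.chrom, f.start, f.end, f.strand) == (t.chrom, t.start, t.end, t.strand)
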
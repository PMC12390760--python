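"""Deduplication, clustering, enrichment scoring, and peak filtering."""
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mirclip.models import AlignedFragment
from mirclip.quant import (
    Cluster,
    call_clusters,
    deduplicate,
    enrichment_pvalue,
    filter_and_reproduce,
    score_clusters,
    score_peak,
)


def frag(chrom="chr1", start=0, end=35, strand="+", umi="AAAA", read_id="r0",
         tag=None, rep=1):
    return AlignedFragment(chrom=chrom, start=start, end=end, strand=strand,
                          umi=umi, read_id=read_id, replicate=rep, mirna_tag=tag)


# ------------------------------------------------------------------ dedup


def test_dedup_collapses_same_umi_position():
    a = frag(umi="AAAA", read_id="r1")
    b = frag(umi="AAAA", read_id="r2")
    c = frag(umi="CCCC", read_id="r3")
    survivors, removed = deduplicate([a, b, c])
    assert removed == 1 and len(survivors) == 2
    assert {s.read_id for s in survivors} == {"r1", "r3"}  # first by read_id


def test_dedup_requires_umi():
    with pytest.raises(ValueError, match="r0"):
        deduplicate([frag(umi="")])


@given(st.permutations(list(range(6))))
def test_dedup_idempotent_and_order_insensitive(order):
    pool = [
        frag(start=s, umi=u, read_id=f"r{i}")
        for i, (s, u) in enumerate(
            [(0, "AAAA"), (0, "AAAA"), (0, "TTTT"), (5, "AAAA"), (5, "AAAA"), (9, "GGGG")]
        )
    ]
    shuffled = [pool[i] for i in order]
    once, _ = deduplicate(shuffled)
    twice, removed_again = deduplicate(once)
    assert removed_again == 0 and twice == once
    assert {f.read_id for f in once} == {"r0", "r2", "r3", "r5"}


# --------------------------------------------------------------- clusters


def test_cluster_merge_and_strand_separation():
    a = frag(start=100, end=130, umi="A", read_id="a")
    b = frag(start=125, end=155, umi="B", read_id="b")
    merged = call_clusters([a, b])
    assert len(merged) == 1
    assert (merged[0].start, merged[0].end, merged[0].ip_count) == (100, 155, 2)
    c = frag(start=125, end=155, strand="-", umi="C", read_id="c")
    assert len(call_clusters([a, c])) == 2


def _bruteforce_components(frags):
    """O(n^2) oracle: connected components of the pairwise overlap graph."""
    parent = list(range(len(frags)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, f in enumerate(frags):
        for j in range(i + 1, len(frags)):
            g = frags[j]
            if (f.chrom, f.strand) == (g.chrom, g.strand) and f.start < g.end and g.start < f.end:
                parent[find(i)] = find(j)
    comps = {}
    for i, f in enumerate(frags):
        comps.setdefault(find(i), []).append(f)
    return sorted(
        (c[0].chrom, min(f.start for f in c), max(f.end for f in c), c[0].strand,
         len(c))
        for c in comps.values()
    )


def test_clusters_equal_bruteforce_components_on_random_sets():
    rng = np.random.default_rng(0)
    for trial in range(60):
        n = int(rng.integers(5, 120))
        frags = []
        for i in range(n):
            s = int(rng.integers(0, 2000))
            frags.append(
                frag(
                    chrom=f"chr{int(rng.integers(2)) + 1}",
                    start=s,
                    end=s + int(rng.integers(20, 60)),
                    strand="+-"[int(rng.integers(2))],
                    umi=f"U{i}", read_id=f"r{i}",
                )
            )
        got = sorted(
            (c.chrom, c.start, c.end, c.strand, c.ip_count)
            for c in call_clusters(frags)
        )
        assert got == _bruteforce_components(frags)
        # conservation: member counts sum to the fragment count
        assert sum(c[4] for c in got) == n


def test_cluster_mirna_counts_accumulate():
    frags = [
        frag(start=0, end=30, umi="A", read_id="a", tag="mir-1"),
        frag(start=10, end=40, umi="B", read_id="b", tag="mir-1"),
        frag(start=20, end=50, umi="C", read_id="c", tag="mir-2"),
    ]
    (c,) = call_clusters(frags)
    assert c.mirna_counts == {"mir-1": 2, "mir-2": 1}


# ---------------------------------------------------------------- scoring


def test_rpm_and_symmetric_log2fc():
    cl = Cluster("chr1", 0, 60, "+", [frag(umi=f"U{i}", read_id=f"r{i}") for i in range(5)])
    p = score_peak(cl, ip_total=1_000_000, input_fragments=[], input_total=1_000_000)
    assert p.ip_rpm == pytest.approx(5.0)
    cl2 = Cluster("chr1", 0, 60, "+", [frag(umi=f"U{i}", read_id=f"r{i}") for i in range(4)])
    inputs = [frag(start=10, end=40, umi=f"I{i}", read_id=f"i{i}") for i in range(4)]
    p2 = score_peak(cl2, ip_total=5000, input_fragments=inputs, input_total=5000)
    assert p2.input_count == 4 and p2.log2fc == 0.0


def test_zero_totals_error():
    cl = Cluster("chr1", 0, 60, "+", [frag()])
    with pytest.raises(ValueError):
        score_peak(cl, ip_total=0, input_fragments=[], input_total=10)


def _oracle_p(ip, ipt, inp, inpt):
    """Direct hypergeometric tail by exact rational summation."""
    M, n, N = ipt + inpt, ip + inp, ipt
    total = Fraction(0)
    for k in range(ip, min(n, N) + 1):
        if n - k <= M - N:
            total += Fraction(math.comb(N, k) * math.comb(M - N, n - k),
                              math.comb(M, n))
    return float(total)


def test_pvalue_matches_exact_hypergeometric_example():
    assert enrichment_pvalue(8, 1000, 1, 1000) == pytest.approx(
        _oracle_p(8, 1000, 1, 1000), abs=1e-12
    )


# -------------------------------------------------------------- filtering


def test_filters_apply_read_count_and_strict_log2fc(peak_fidelity_fixture):
    rep1, rep2, inputs, totals, expected = peak_fidelity_fixture
    peaks1 = score_clusters(call_clusters(rep1), totals["ip"], inputs[1],
                            totals["input"], replicate=1)
    by_start = {p.start: p for p in peaks1}
    assert by_start[2000].ip_count == 2  # too few reads regardless of log2fc
    assert by_start[3000].log2fc == pytest.approx(3.0)  # boundary: excluded
    peaks2 = score_clusters(call_clusters(rep2), totals["ip"], inputs[2],
                            totals["input"], replicate=2)
    final = filter_and_reproduce(peaks1, peaks2)
    assert [(p.chrom, p.start, p.end, p.strand) for p in final] == expected
    (p,) = final
    assert p.reproducible and p.replicates == (1, 2) and p.ip_count == 17


def test_unreproduced_peak_is_excluded():
    mk = lambda s, rep: score_clusters(
        call_clusters([frag(start=s + i, end=s + 35 + i, umi=f"U{i}",
                            read_id=f"{rep}:{i}", rep=rep) for i in range(8)]),
        1000, [], 1000, replicate=rep,
    )
    assert filter_and_reproduce(mk(100, 1), mk(900, 2)) == []


def test_nonpositive_thresholds_rejected():
    with pytest.raises(ValueError):
        filter_and_reproduce([], [], min_reads=0)


def test_planted_site_found_and_decoy_chromosome_clean():
    """A site at 20x background density yields a reproducible peak over the
    site; a site-free decoy chromosome yields none."""
    rng = np.random.default_rng(4)

    def library(rep):
        frags = []
        for i in range(40):  # site pile on chr1:1000-1060
            s = 1000 + int(rng.integers(0, 26))
            frags.append(frag(start=s, end=s + 35, umi=f"S{rep}{i}",
                              read_id=f"s{rep}:{i}", rep=rep))
        for i in range(20):  # sparse background on the decoy chromosome
            s = int(rng.integers(0, 10_000))
            frags.append(frag(chrom="decoy", start=s, end=s + 35,
                              umi=f"B{rep}{i}", read_id=f"b{rep}:{i}", rep=rep))
        return frags

    def inputs(rep):
        out = []
        for c in ("chr1", "decoy"):
            for i in range(30):
                s = int(rng.integers(0, 10_000))
                out.append(frag(chrom=c, start=s, end=s + 35, umi=f"I{rep}{i}",
                                read_id=f"i{c}{rep}:{i}", rep=rep))
        return out

    finals = filter_and_reproduce(
        score_clusters(call_clusters(library(1)), 60, inputs(1), 60, replicate=1),
        score_clusters(call_clusters(library(2)), 60, inputs(2), 60, replicate=2),
    )
    assert any(p.chrom == "chr1" and p.start <= 1030 <= p.end for p in finals)
    assert not any(p.chrom == "decoy" for p in finals)
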
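"""Shared fixtures: toy genome, hand-derived annotation stack, prioritization
tables, a constructed peak fixture, and one small end-to-end pipeline run."""
from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mirclip import pipeline, synthetic
from mirclip.models import AlignedFragment, TranscriptModel

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle():
    return synthetic.make_genome(seed=11)


@pytest.fixture(scope="session")
def sites(bundle):
    return synthetic.default_site_map(bundle, seed=11)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One full error-free pipeline run at reduced depth, shared read-only."""
    out = tmp_path_factory.mktemp("run")
    cfg = pipeline.resolve_config(
        {
            "seed": 7,
            "simulate": {
                "n_reads_ip": 6000,
                "n_reads_input": 6000,
                "sequencing_error_rate": 0.0,
            },
        }
    )
    report = pipeline.run_all(cfg, out)
    return cfg, out, report


# ------------------------------------------------------- annotation stack


@pytest.fixture(scope="session")
def annotation_case():
    """Six overlapping transcripts exercising every feature class, plus 20
    peaks whose categories were derived by hand from the interval layout."""
    transcripts = [
        TranscriptModel(
            gene_id="geneA", transcript_id="geneA.t1", chrom="chrT", strand="+",
            exons=((100, 400), (500, 800), (900, 1300)), cds=(250, 1050),
        ),
        TranscriptModel(
            gene_id="geneB", transcript_id="geneB.t1", chrom="chrT", strand="+",
            exons=((600, 700), (750, 1500)), biotype="noncoding",
        ),
        TranscriptModel(
            gene_id="geneC", transcript_id="geneC.t1", chrom="chrT", strand="-",
            exons=((2000, 2300), (2400, 2900)), cds=(2150, 2700),
        ),
        TranscriptModel(
            gene_id="geneD", transcript_id="geneD.t1", chrom="chrT", strand="-",
            exons=((3000, 3200),), biotype="noncoding",
        ),
        TranscriptModel(
            gene_id="geneE", transcript_id="geneE.t1", chrom="chrT", strand="+",
            exons=((3500, 3600), (3700, 3800)), biotype="noncoding",
        ),
        TranscriptModel(
            gene_id="geneF", transcript_id="geneF.t1", chrom="chrT", strand="+",
            exons=((950, 1600),), cds=(960, 1040),
        ),
    ]
    # (start, end, strand) -> (category, gene_id), derived by hand
    cases = [
        ((300, 350, "+"), ("CDS", "geneA")),
        ((150, 200, "+"), ("UTR5", "geneA")),
        ((1100, 1150, "+"), ("UTR3", "geneA")),  # UTR3 tie geneA vs geneF
        ((420, 450, "+"), ("intron", "geneA")),
        ((810, 860, "+"), ("intron", "geneA")),  # pc intron beats nc exon
        ((620, 660, "+"), ("CDS", "geneA")),     # CDS beats nc exon
        ((3620, 3660, "+"), ("nc_intron", "geneE")),
        ((3050, 3100, "-"), ("nc_exon", "geneD")),
        ((3050, 3100, "+"), ("intergenic", "")),  # opposite strand only
        ((2050, 2100, "-"), ("UTR3", "geneC")),   # minus strand: UTR3 left
        ((2750, 2800, "-"), ("UTR5", "geneC")),
        ((2320, 2380, "-"), ("intron", "geneC")),
        ((2200, 2250, "-"), ("CDS", "geneC")),
        ((5000, 5100, "+"), ("intergenic", "")),
        ((240, 260, "+"), ("CDS", "geneA")),      # UTR5/CDS boundary
        ((1040, 1060, "+"), ("CDS", "geneA")),    # CDS/UTR3 boundary
        ((380, 520, "+"), ("CDS", "geneA")),      # spans exon-intron-exon
        ((890, 910, "+"), ("CDS", "geneA")),
        ((1350, 1450, "+"), ("UTR3", "geneF")),   # UTR3 beats nc exon
        ((700, 750, "+"), ("CDS", "geneA")),      # CDS beats nc intron
    ]
    return transcripts, cases


# ---------------------------------------------------- prioritization tables


@pytest.fixture(scope="session")
def nine_gene_tables():
    """Nine genes exercising every branch of the two selection criteria."""
    fractions = ("cytoplasm", "nucleus", "chromatin")
    counts = pd.DataFrame(
        [
            {"gene_id": "g1", "cytoplasm": 6, "nucleus": 0, "chromatin": 0},
            {"gene_id": "g2", "cytoplasm": 5, "nucleus": 0, "chromatin": 0},
            {"gene_id": "g3", "cytoplasm": 1, "nucleus": 1, "chromatin": 1},
            {"gene_id": "g4", "cytoplasm": 1, "nucleus": 1, "chromatin": 0},
            {"gene_id": "g5", "cytoplasm": 7, "nucleus": 2, "chromatin": 1},
            {"gene_id": "g6", "cytoplasm": 6, "nucleus": 1, "chromatin": 0},
            {"gene_id": "g7", "cytoplasm": 2, "nucleus": 2, "chromatin": 2},
            {"gene_id": "g8", "cytoplasm": 8, "nucleus": 8, "chromatin": 8},
            {"gene_id": "g9", "cytoplasm": 0, "nucleus": 0, "chromatin": 0},
        ]
    )
    expression = pd.DataFrame(
        [
            {"gene_id": "g1", "log2fc": 3.3, "significant": 1},
            {"gene_id": "g2", "log2fc": 3.0, "significant": 1},
            {"gene_id": "g3", "log2fc": -2.0, "significant": 1},
            {"gene_id": "g4", "log2fc": 2.0, "significant": 1},
            {"gene_id": "g5", "log2fc": 0.5, "significant": 1},
            {"gene_id": "g6", "log2fc": 2.0, "significant": 0},
            # g7 deliberately absent: expression unknown
            {"gene_id": "g8", "log2fc": 1.0, "significant": 1},
            {"gene_id": "g9", "log2fc": 5.0, "significant": 1},
        ]
    )
    expected_selected = {"g1", "g3", "g8"}
    return fractions, counts, expression, expected_selected


# --------------------------------------------------------- peak fixture


def _frags(chrom, start, end, strand, n, tag, rep, role="IP"):
    return [
        AlignedFragment(
            chrom=chrom, start=start + i, end=end + i, strand=strand,
            umi=f"{tag}{i:03d}", read_id=f"{tag}:{i:03d}", sample="cytoplasm",
            role=role, replicate=rep,
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def peak_fidelity_fixture():
    """Replicated fragment piles with hand-computed peak statistics.

    Totals are fixed at 1000/1000 so the fold changes are exact:
    pile A (8 and 9 fragments, no input) passes in both replicates and is
    the only reproducible peak; B has too few reads; C has log2FC exactly
    3.0 (excluded by the strict inequality); D passes in one replicate
    only; E passes in both but on opposite strands; G is input-matched.
    """
    rep1 = (
        _frags("chr1", 1000, 1035, "+", 8, "A1", 1)
        + _frags("chr1", 2000, 2035, "+", 2, "B1", 1)
        + _frags("chr1", 3000, 3035, "+", 7, "C1", 1)
        + _frags("chr1", 4000, 4035, "+", 8, "D1", 1)
        + _frags("chr1", 5000, 5035, "+", 8, "E1", 1)
        + _frags("chr1", 6000, 6035, "+", 10, "G1", 1)
    )
    rep2 = (
        _frags("chr1", 1010, 1045, "+", 9, "A2", 2)
        + _frags("chr1", 5000, 5035, "-", 8, "E2", 2)
        + _frags("chr1", 7000, 7035, "+", 9, "F2", 2)
        + _frags("chr1", 6000, 6035, "+", 10, "G2", 2)
    )
    inputs = {
        1: _frags("chr1", 6000, 6035, "+", 5, "I1", 1, role="input"),
        2: _frags("chr1", 6000, 6035, "+", 5, "I2", 2, role="input"),
    }
    totals = {"ip": 1000, "input": 1000}
    expected_final = [("chr1", 1000, 1053, "+")]  # union of A1 and A2 piles
    return rep1, rep2, inputs, totals, expected_final
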
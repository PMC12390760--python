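"""Generator contracts: genome structure, determinism, truth completeness."""
import numpy as np
import pytest
from scipy.stats import binom

from mirclip import io, synthetic
from mirclip.models import SimParams


def test_genome_structure_and_family_grouping(bundle):
    coding = [t for t in bundle.transcripts if t.biotype == "coding"]
    noncoding = [t for t in bundle.transcripts if t.biotype == "noncoding"]
    assert len(coding) == 20 and len(noncoding) >= 1
    assert len(bundle.repeats) >= 1
    families = {m.family_id for m in bundle.mirnas}
    assert len(families) == 5
    for fam in families:
        seeds = {m.seed for m in bundle.mirnas if m.family_id == fam}
        assert len(seeds) == 1  # one family, one seed


def test_single_family_forces_shared_seed():
    b = synthetic.make_genome(n_genes=2, n_mirnas=4, n_families=1, seed=3)
    assert len({m.seed for m in b.mirnas}) == 1


def test_fixed_seed_gives_byte_identical_fasta(tmp_path):
    for sub in ("a", "b"):
        synthetic.write_bundle(synthetic.make_genome(seed=5), tmp_path / sub)
    assert (tmp_path / "a" / "genome.fa").read_bytes() == (
        tmp_path / "b" / "genome.fa"
    ).read_bytes()
    assert (tmp_path / "a" / "mirnas.fa").read_bytes() == (
        tmp_path / "b" / "mirnas.fa"
    ).read_bytes()


def test_gtf_round_trip_against_independent_parser(tmp_path, bundle):
    """The written annotation, parsed back by gffutils, reproduces the
    in-memory gene models' exon unions."""
    gffutils = pytest.importorskip("gffutils")
    paths = synthetic.write_bundle(bundle, tmp_path)
    db = gffutils.create_db(
        str(paths["annotation"]), ":memory:", keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = {g.id.split(":")[0] for g in db.features_of_type("gene")}
    assert genes == {t.gene_id for t in bundle.transcripts}
    by_gene = {t.gene_id: t for t in bundle.transcripts}
    for tx in db.features_of_type("transcript"):
        gid = tx.attributes["gene_id"][0]
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(tx, featuretype="exon")
        )
        assert tuple(exons) == by_gene[gid].exons


def test_degenerate_chromosome_sizing_error():
    with pytest.raises(ValueError, match="chrom_length"):
        synthetic.make_genome(n_chroms=1, n_genes=8, seed=1, chrom_length=500)


@pytest.fixture(scope="module")
def small_sim(bundle, sites):
    params = SimParams(
        seed=21, n_reads_ip=4000, n_reads_input=1000, site_map=sites,
        sequencing_error_rate=0.0,
    )
    return params, synthetic.simulate_libraries(bundle, params)


def test_truth_table_covers_every_read(small_sim):
    params, (ip, inp, truth) = small_sim
    assert len(truth) == len(ip) + len(inp)
    assert {t.read_id for t in truth} == {r.read_id for r in ip + inp}


def test_read_layout_umi_insert_adapter(small_sim, bundle):
    """Each read is UMI + insert (+ partial adapter); chimeric inserts start
    with the full mature miRNA; repeat reads originate in repeat intervals."""
    params, (ip, inp, truth) = small_sim
    mir = {m.name: m.sequence for m in bundle.mirnas}
    by_id = {r.read_id: r for r in ip + inp}
    for t in truth:
        read = by_id[t.read_id]
        assert read.sequence[: params.umi_length] == t.umi
        insert = read.sequence[params.umi_length :]
        if t.read_class == "chimeric":
            assert insert.startswith(mir[t.mirna_name][: len(insert)])
        if t.read_class == "repeat":
            assert any(
                c == t.chrom and s <= t.start and t.end <= e
                for c, s, e in bundle.repeats
            )
        assert (t.read_class == "chimeric") == (t.mirna_name is not None)


def test_duplicates_share_molecule_identity(small_sim):
    _, (ip, inp, truth) = small_sim
    by_id = {t.read_id: t for t in truth}
    dups = [t for t in truth if t.duplicate_of is not None]
    assert dups, "expected some PCR duplicates at the default rate"
    for t in dups:
        orig = by_id[t.duplicate_of]
        assert orig.duplicate_of is None
        assert (t.umi, t.chrom, t.start, t.end, t.strand) == (
            orig.umi, orig.chrom, orig.start, orig.end, orig.strand
        )


def test_zero_rate_switches(bundle, sites):
    params = SimParams(
        seed=4, n_reads_ip=800, n_reads_input=200, site_map=sites,
        chimera_fraction=0.0, pcr_duplication_rate=0.0,
    )
    _, _, truth = synthetic.simulate_libraries(bundle, params)
    assert not any(t.read_class == "chimeric" for t in truth)
    assert all(t.duplicate_of is None for t in truth)


def test_chimeric_count_within_binomial_interval(bundle, sites):
    """With independent per-read class draws the chimeric read count is
    Binomial(n, chimera_fraction); the observed count must fall in the
    central 99% interval computed from exact binomial quantiles."""
    n = 50_000
    params = SimParams(
        seed=9, n_reads_ip=n, n_reads_input=0, site_map=sites,
        pcr_duplication_rate=0.0, sequencing_error_rate=0.0,
    )
    _, _, truth = synthetic.simulate_libraries(bundle, params)
    observed = sum(1 for t in truth if t.read_class == "chimeric")
    lo = binom.ppf(0.005, n, params.chimera_fraction)
    hi = binom.ppf(0.995, n, params.chimera_fraction)
    assert lo <= observed <= hi


def test_site_validation_errors(bundle, sites):
    tiny = [sites[0].__class__(**{**sites[0].__dict__, "end": sites[0].start + 5})]
    with pytest.raises(ValueError, match="minimum"):
        synthetic.simulate_libraries(bundle, SimParams(seed=1, site_map=tiny))
    no_mir = [sites[0].__class__(**{**sites[0].__dict__, "mirna": None})]
    with pytest.raises(ValueError, match="miRNA"):
        synthetic.simulate_libraries(
            bundle, SimParams(seed=1, site_map=no_mir, chimera_fraction=0.02)
        )


def test_simulation_is_deterministic(bundle, sites):
    params = SimParams(seed=33, n_reads_ip=500, n_reads_input=100, site_map=sites)
    a = synthetic.simulate_libraries(bundle, params)
    b = synthetic.simulate_libraries(bundle, params)
    assert [(r.read_id, r.sequence) for r in a[0]] == [
        (r.read_id, r.sequence) for r in b[0]
    ]
    assert a[2] == b[2]
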
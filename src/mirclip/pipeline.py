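"""Stage orchestration: simulate -> preprocess -> align -> chimera ->
quant -> annotate -> families -> prioritize.

Every stage is a pure function of persisted inputs plus the resolved
configuration, so any stage can be re-run standalone from the previous
stage's on-disk outputs and reproduce the full-run result.  All
randomness flows from the single configured seed; per-library child seeds
are derived arithmetically and stay below 2**31.
"""
from __future__ import annotations

import copy
from pathlib import Path

import pandas as pd
import yaml

from . import align, annotate, chimera, families, io, prioritize, quant, synthetic
from .models import SimParams
from .preprocess import preprocess_reads, umi_from_read_id

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "fractions": ["cytoplasm", "nucleus", "chromatin"],
    "replicates": 2,
    "genome": {
        "n_chroms": 2,
        "n_genes": 10,
        "n_mirnas": 12,
        "n_families": 5,
        "noncoding_per_chrom": 2,
    },
    "sites": {"sites_per_gene": 2, "region": "UTR3", "site_length": 60},
    "simulate": {
        "n_reads_ip": 50_000,
        "n_reads_input": 50_000,
        "chimera_fraction": 0.02,
        "repeat_fraction": 0.05,
        "background_fraction": 0.01,
        "umi_length": 10,
        "adapter": "AGATCGGAAGAGCACACGTCT",
        "read_length": 75,
        "pcr_duplication_rate": 0.15,
        "sequencing_error_rate": 0.001,
        "min_fragment": 25,
        "max_fragment": 45,
    },
    "preprocess": {"min_overlap": 3, "max_mismatch_rate": 0.1, "min_length": 18},
    "align": {"k": 16, "max_mismatches": 2},
    "chimera": {"min_mirna_match": 18, "max_mismatches": 1, "min_target_length": 18},
    "quant": {"min_reads": 3, "min_log2fc": 3.0, "filter_chimeric": True},
    "annotate": {"priority": list(annotate.DEFAULT_PRIORITY)},
    "families": {"top_n": 8, "use_allowlist": True},
    "prioritize": {"min_abs_log2fc": 1.0, "strict_gt": True},
}


def resolve_config(user: dict | None = None) -> dict:
    """Deep-merge a user config over the defaults, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if not user:
        return cfg
    for key, value in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config key: {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key {key!r} must be a mapping")
            for sub, v in value.items():
                if sub not in cfg[key]:
                    raise ValueError(f"unknown config key: {key}.{sub}")
                cfg[key][sub] = v
        else:
            cfg[key] = value
    if cfg["replicates"] != 2:
        raise ValueError("the reproducibility contract requires exactly 2 replicates")
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return resolve_config(yaml.safe_load(fh) or {})


def _lib_seed(base: int, idx: int) -> int:
    return (base * 1_000_003 + 7919 * idx + 1) % 2_147_483_647


def _libraries(cfg: dict):
    for fi, fraction in enumerate(cfg["fractions"]):
        for rep in range(1, cfg["replicates"] + 1):
            yield fi, fraction, rep


def _lib_name(fraction: str, rep: int, role: str) -> str:
    return f"{fraction}_rep{rep}_{role}"


# ------------------------------------------------------------------------- stages


def stage_simulate(cfg: dict, outdir: Path) -> dict:
    ref = outdir / "ref"
    raw = outdir / "raw"
    truth_dir = outdir / "truth"
    for d in (ref, raw, truth_dir):
        d.mkdir(parents=True, exist_ok=True)
    bundle = synthetic.make_genome(seed=cfg["seed"], **cfg["genome"])
    synthetic.write_bundle(bundle, ref)
    with open(ref / "repeats.bed", "w") as fh:
        for chrom, s, e in bundle.repeats:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    sites = synthetic.default_site_map(bundle, seed=cfg["seed"], **cfg["sites"])
    io.write_sites_tsv(ref / "sites.tsv", sites)
    synthetic.make_expression_table(bundle, sites, seed=cfg["seed"]).to_csv(
        ref / "expression.tsv", sep="\t", index=False
    )
    ledger = {}
    for fi, fraction, rep in _libraries(cfg):
        params = SimParams(
            seed=_lib_seed(cfg["seed"], fi * 10 + rep),
            site_map=sites,
            **cfg["simulate"],
        )
        ip, inp, truth = synthetic.simulate_libraries(
            bundle, params, read_prefix=f"{fraction}.r{rep}"
        )
        io.write_fastq(raw / f"{_lib_name(fraction, rep, 'IP')}.fastq", ip)
        io.write_fastq(raw / f"{_lib_name(fraction, rep, 'input')}.fastq", inp)
        io.write_truth_tsv(truth_dir / f"{fraction}_rep{rep}.tsv", truth)
        ledger[f"{fraction}_rep{rep}"] = {
            "n_in": len(ip) + len(inp),
            "n_kept": len(ip) + len(inp),
            "dropped": {},
        }
    return ledger


def stage_preprocess(cfg: dict, outdir: Path) -> dict:
    proc = outdir / "proc"
    proc.mkdir(exist_ok=True)
    ledger = {}
    for _, fraction, rep in _libraries(cfg):
        for role in ("IP", "input"):
            name = _lib_name(fraction, rep, role)
            reads = io.read_fastq(
                outdir / "raw" / f"{name}.fastq",
                sample=fraction, role=role, replicate=rep,
            )
            kept, lg = preprocess_reads(
                reads,
                umi_length=cfg["simulate"]["umi_length"],
                adapter=cfg["simulate"]["adapter"],
                **cfg["preprocess"],
            )
            io.write_fastq(proc / f"{name}.fastq", kept)
            ledger[name] = lg
    return ledger


def _load_ref(outdir: Path, cfg: dict):
    genome = io.read_fasta(outdir / "ref" / "genome.fa")
    repeats = []
    with open(outdir / "ref" / "repeats.bed") as fh:
        for line in fh:
            chrom, s, e = line.split()
            repeats.append((chrom, int(s), int(e)))
    return genome, repeats


def stage_align(cfg: dict, outdir: Path) -> dict:
    frag_dir = outdir / "frags"
    unmapped_dir = outdir / "unmapped"
    frag_dir.mkdir(exist_ok=True)
    unmapped_dir.mkdir(exist_ok=True)
    genome, repeats = _load_ref(outdir, cfg)
    k = cfg["align"]["k"]
    max_mm = cfg["align"]["max_mismatches"]
    genome_index = align.SeedIndex(genome, k=k)
    repeat_seqs = {
        f"repeat_{i}": genome[c][s:e] for i, (c, s, e) in enumerate(repeats)
    }
    repeat_index = align.SeedIndex(repeat_seqs, k=k)
    ledger = {}
    for _, fraction, rep in _libraries(cfg):
        for role in ("IP", "input"):
            name = _lib_name(fraction, rep, role)
            reads = io.read_fastq(
                outdir / "proc" / f"{name}.fastq",
                sample=fraction, role=role, replicate=rep,
            )
            for r in reads:
                r.umi = umi_from_read_id(r.read_id)
            kept, repeat_hits = align.filter_repeats(reads, repeat_index, max_mm)
            frags, unmapped, map_ledger = align.map_reads(
                kept, genome_index, max_mismatches=max_mm
            )
            io.write_fragments(
                frag_dir / f"{name}.bed", frag_dir / f"{name}.meta.tsv", frags
            )
            io.write_fastq(unmapped_dir / f"{name}.fastq", unmapped)
            ledger[name] = {
                "n_in": len(reads),
                "n_kept": len(frags),
                "dropped": {
                    "repeat": len(repeat_hits),
                    **map_ledger["dropped"],
                },
            }
    return ledger


def stage_chimera(cfg: dict, outdir: Path) -> dict:
    chim_dir = outdir / "chimera"
    chim_dir.mkdir(exist_ok=True)
    genome, _ = _load_ref(outdir, cfg)
    genome_index = align.SeedIndex(genome, k=cfg["align"]["k"])
    mirnas = io.read_mirnas(
        outdir / "ref" / "mirnas.fa", outdir / "ref" / "families.tsv"
    )
    ledger = {}
    for _, fraction, rep in _libraries(cfg):
        name = _lib_name(fraction, rep, "IP")
        reads = io.read_fastq(
            outdir / "unmapped" / f"{name}.fastq",
            sample=fraction, role="IP", replicate=rep,
        )
        for r in reads:
            r.umi = umi_from_read_id(r.read_id)
        calls = []
        reasons = {"mirna_only": 0, "no_mirna_match": 0}
        for r in reads:
            call, reason = chimera.classify_unmapped_read(r, mirnas, **cfg["chimera"])
            if call is not None:
                calls.append(call)
            else:
                reasons[reason] += 1
        frags, resolve_ledger = chimera.resolve_chimeras(
            calls, {r.read_id: r for r in reads}, genome_index,
            max_mismatches=cfg["align"]["max_mismatches"],
        )
        pd.DataFrame(
            [
                {
                    "read_id": c.read_id,
                    "mirna": c.mirna_name,
                    "match_length": c.match_length,
                    "mismatches": c.mismatches,
                    "ambiguous_with": ",".join(c.ambiguous_with),
                }
                for c in calls
            ],
            columns=["read_id", "mirna", "match_length", "mismatches", "ambiguous_with"],
        ).to_csv(chim_dir / f"{name}.calls.tsv", sep="\t", index=False)
        io.write_fragments(
            chim_dir / f"{name}.bed", chim_dir / f"{name}.meta.tsv", frags
        )
        ledger[name] = {
            "n_in": len(reads),
            "n_kept": len(frags),
            "dropped": {
                **{k: v for k, v in reasons.items() if v},
                **resolve_ledger["dropped"],
            },
        }
    return ledger


def _load_library_fragments(outdir: Path, fraction: str, rep: int):
    name_ip = _lib_name(fraction, rep, "IP")
    name_in = _lib_name(fraction, rep, "input")
    nonchim = io.read_fragments(
        outdir / "frags" / f"{name_ip}.bed", outdir / "frags" / f"{name_ip}.meta.tsv"
    )
    chim = io.read_fragments(
        outdir / "chimera" / f"{name_ip}.bed", outdir / "chimera" / f"{name_ip}.meta.tsv"
    )
    inp = io.read_fragments(
        outdir / "frags" / f"{name_in}.bed", outdir / "frags" / f"{name_in}.meta.tsv"
    )
    return nonchim, chim, inp


def stage_quant(cfg: dict, outdir: Path) -> dict:
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    min_reads = cfg["quant"]["min_reads"]
    min_log2fc = cfg["quant"]["min_log2fc"]
    ledger = {}
    for fraction in cfg["fractions"]:
        per_rep: dict[str, dict[int, list]] = {"nonchimeric": {}, "chimeric": {}}
        for rep in range(1, cfg["replicates"] + 1):
            nonchim, chim, inp = _load_library_fragments(outdir, fraction, rep)
            nonchim_d, rm_n = quant.deduplicate(nonchim)
            chim_d, rm_c = quant.deduplicate(chim) if chim else ([], 0)
            inp_d, rm_i = quant.deduplicate(inp)
            input_total = len(inp_d)
            # each peak universe is RPM-normalized to its own deduplicated
            # mapped-fragment total (nonchimeric vs chimeric libraries)
            for peak_type, frags in (("nonchimeric", nonchim_d), ("chimeric", chim_d)):
                clusters = quant.call_clusters(frags)
                per_rep[peak_type][rep] = (
                    quant.score_clusters(
                        clusters, len(frags), inp_d, input_total,
                        sample=fraction, replicate=rep, peak_type=peak_type,
                    )
                    if frags
                    else []
                )
            ledger[f"{fraction}_rep{rep}_dedup"] = {
                "n_in": len(nonchim) + len(chim) + len(inp),
                "n_kept": len(nonchim_d) + len(chim_d) + input_total,
                "dropped": {"pcr_duplicate": rm_n + rm_c + rm_i},
            }
        finals = []
        for peak_type in ("nonchimeric", "chimeric"):
            if peak_type == "chimeric" and not cfg["quant"]["filter_chimeric"]:
                reps = per_rep[peak_type]
                finals.extend(
                    quant.filter_and_reproduce(reps[1], reps[2], 1, 1e-9)
                )
                continue
            reps = per_rep[peak_type]
            finals.extend(
                quant.filter_and_reproduce(reps[1], reps[2], min_reads, min_log2fc)
            )
            io.write_peaks(
                peak_dir / f"{fraction}.rep1.{peak_type}.tsv", reps[1]
            )
            io.write_peaks(
                peak_dir / f"{fraction}.rep2.{peak_type}.tsv", reps[2]
            )
        io.write_peaks(peak_dir / f"{fraction}.final.tsv", finals)
    return ledger


def stage_annotate(cfg: dict, outdir: Path) -> dict:
    annot_dir = outdir / "annot"
    annot_dir.mkdir(exist_ok=True)
    transcripts = io.read_gtf(outdir / "ref" / "annotation.gtf")
    priority = tuple(cfg["annotate"]["priority"])
    all_peaks = []
    for fraction in cfg["fractions"]:
        peaks = io.read_peaks(outdir / "peaks" / f"{fraction}.final.tsv")
        annotate.annotate_peaks(peaks, transcripts, priority)
        all_peaks.extend(peaks)
    io.write_peaks(annot_dir / "peaks_annotated.tsv", all_peaks)
    annotate.feature_distribution(all_peaks).to_csv(
        annot_dir / "feature_distribution.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    return {"all": {"n_in": len(all_peaks), "n_kept": len(all_peaks), "dropped": {}}}


def stage_families(cfg: dict, outdir: Path) -> dict:
    fam_dir = outdir / "families"
    fam_dir.mkdir(exist_ok=True)
    mirnas = io.read_mirnas(
        outdir / "ref" / "mirnas.fa", outdir / "ref" / "families.tsv"
    )
    mirnas = families.assign_families(
        mirnas, family_map={m.name: m.family_id for m in mirnas if m.family_id}
    )
    frags = []
    for _, fraction, rep in _libraries(cfg):
        name = _lib_name(fraction, rep, "IP")
        lib = io.read_fragments(
            outdir / "chimera" / f"{name}.bed",
            outdir / "chimera" / f"{name}.meta.tsv",
        )
        deduped, _ = quant.deduplicate(lib) if lib else ([], 0)
        frags.extend(deduped)
    n_before = len(frags)
    if cfg["families"]["use_allowlist"]:
        allowlist = {m.name for m in mirnas if m.allowlisted}
        frags, n_removed = families.apply_allowlist(frags, allowlist)
    else:
        n_removed = 0
    summaries, cumulative = families.family_fractions(
        frags, mirnas, top_n=cfg["families"]["top_n"]
    )
    pd.DataFrame(
        [
            {
                "family_id": s.family_id,
                "seed": s.seed,
                "members": ",".join(s.members),
                "count": s.chimeric_read_count,
                "fraction": f"{s.fraction_of_total:.6g}",
                "rank": s.rank,
            }
            for s in summaries
        ],
        columns=["family_id", "seed", "members", "count", "fraction", "rank"],
    ).to_csv(fam_dir / "family_summary.tsv", sep="\t", index=False)
    io.write_json(
        fam_dir / "summary.json",
        {"cumulative_top_n": cumulative, "top_n": cfg["families"]["top_n"],
         "n_fragments": len(frags)},
    )
    return {
        "all": {
            "n_in": n_before,
            "n_kept": len(frags),
            "dropped": {"not_allowlisted": n_removed} if n_removed else {},
        }
    }


def stage_prioritize(cfg: dict, outdir: Path) -> dict:
    cand_dir = outdir / "candidates"
    cand_dir.mkdir(exist_ok=True)
    peaks = io.read_peaks(outdir / "annot" / "peaks_annotated.tsv")
    expr = pd.read_csv(outdir / "ref" / "expression.tsv", sep="\t")
    fractions = tuple(cfg["fractions"])
    counts = prioritize.count_utr3_chimeric_peaks(peaks, fractions)
    candidates = prioritize.select_candidates(
        counts, expr,
        min_abs_log2fc=cfg["prioritize"]["min_abs_log2fc"],
        fractions=fractions,
        strict_gt=cfg["prioritize"]["strict_gt"],
    )
    prioritize.candidates_frame(candidates).to_csv(
        cand_dir / "candidates.tsv", sep="\t", index=False
    )
    n_sel = sum(c.selected for c in candidates)
    return {
        "all": {
            "n_in": len(candidates),
            "n_kept": n_sel,
            "dropped": {"not_selected": len(candidates) - n_sel},
        }
    }


STAGES = [
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("align", stage_align),
    ("chimera", stage_chimera),
    ("quant", stage_quant),
    ("annotate", stage_annotate),
    ("families", stage_families),
    ("prioritize", stage_prioritize),
]


def run_all(config: dict | None, outdir: str | Path) -> dict:
    """Run every stage in order; returns the accounting report.

    The resolved configuration is echoed to ``run_config.json`` and the
    per-stage read/fragment/peak accounting to ``ledger.json``.  Partial
    outputs are preserved when a stage fails, and the failing stage is
    named in the raised error.
    """
    cfg = resolve_config(config) if not _is_resolved(config) else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_json(outdir / "run_config.json", cfg)
    report: dict = {"stages": {}}
    for name, fn in STAGES:
        try:
            report["stages"][name] = fn(cfg, outdir)
        except Exception as exc:  # preserve partial outputs, name the stage
            io.write_json(outdir / "ledger.json", report)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        io.write_json(outdir / "ledger.json", report)
    return report


def _is_resolved(config) -> bool:
    return isinstance(config, dict) and set(config) == set(DEFAULT_CONFIG)
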
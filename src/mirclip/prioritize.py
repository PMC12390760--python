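"""Candidate-gene prioritization.

A gene is selected for experimental follow-up when it satisfies both
criteria:

(i)  binding evidence — strictly more than 5 chimeric 3'UTR peaks in at
     least one subcellular fraction, OR at least one chimeric 3'UTR peak
     in every fraction (cytoplasm, nucleus, chromatin by default); and
(ii) miRNA-dependent expression — |log2FC| between wild-type and
     miRNA-biogenesis-knockout cells at or above a threshold, flagged
     significant.

Genes with binding evidence but no expression measurement are flagged
"expression unknown" and never selected.
"""
from __future__ import annotations

import pandas as pd

from .models import CandidateGene, Peak

DEFAULT_FRACTIONS: tuple[str, ...] = ("cytoplasm", "nucleus", "chromatin")


def count_utr3_chimeric_peaks(
    final_peaks: list[Peak],
    fractions: tuple[str, ...] = DEFAULT_FRACTIONS,
) -> pd.DataFrame:
    """Gene x fraction table of chimeric final peaks annotated UTR3."""
    counts: dict[str, dict[str, int]] = {}
    for p in final_peaks:
        if p.peak_type != "chimeric" or p.annotation != "UTR3" or not p.gene_id:
            continue
        if p.sample not in fractions:
            continue
        counts.setdefault(p.gene_id, {f: 0 for f in fractions})[p.sample] += 1
    df = pd.DataFrame(
        [{"gene_id": g, **row} for g, row in sorted(counts.items())],
        columns=["gene_id", *fractions],
    )
    return df.fillna(0).astype({f: int for f in fractions}) if len(df) else df


def select_candidates(
    count_table: pd.DataFrame,
    expression_table: pd.DataFrame,
    min_abs_log2fc: float = 1.0,
    fractions: tuple[str, ...] = DEFAULT_FRACTIONS,
    min_peaks_one_fraction: int = 5,
    strict_gt: bool = True,
) -> list[CandidateGene]:
    """Apply the two selection criteria and sort candidates.

    ``strict_gt`` reads the "more than 5 peaks" rule strictly (the
    default); set False for >= semantics.  Output is sorted by the maximum
    per-fraction UTR3 peak count, descending, then gene_id.
    """
    expr = {
        str(r.gene_id): (float(r.log2fc), bool(int(r.significant)))
        for r in expression_table.itertuples()
    }
    out: list[CandidateGene] = []
    for r in count_table.itertuples():
        per_fraction = {f: int(getattr(r, f)) for f in fractions}
        if strict_gt:
            any_gt5 = any(v > min_peaks_one_fraction for v in per_fraction.values())
        else:
            any_gt5 = any(v >= min_peaks_one_fraction for v in per_fraction.values())
        all_ge1 = all(v >= 1 for v in per_fraction.values())
        known = r.gene_id in expr
        lfc, sig = expr.get(r.gene_id, (None, False))
        expr_ok = (
            known and sig and lfc is not None and abs(lfc) >= min_abs_log2fc
        )
        out.append(
            CandidateGene(
                gene_id=str(r.gene_id),
                peaks_utr3_per_fraction=per_fraction,
                any_fraction_gt5=any_gt5,
                all_fractions_ge1=all_ge1,
                expr_log2fc=lfc,
                expr_significant=bool(sig),
                selected=(any_gt5 or all_ge1) and expr_ok,
                expression_known=known,
            )
        )
    out.sort(
        key=lambda c: (-max(c.peaks_utr3_per_fraction.values(), default=0), c.gene_id)
    )
    return out


def candidates_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    """Auditability table with every intermediate flag."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "gene_id": c.gene_id,
                **{f"peaks_utr3_{k}": v for k, v in c.peaks_utr3_per_fraction.items()},
                "any_fraction_gt5": int(c.any_fraction_gt5),
                "all_fractions_ge1": int(c.all_fractions_ge1),
                "expr_log2fc": "" if c.expr_log2fc is None else c.expr_log2fc,
                "expr_significant": int(c.expr_significant),
                "expression_known": int(c.expression_known),
                "selected": int(c.selected),
            }
        )
    return pd.DataFrame(rows)
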
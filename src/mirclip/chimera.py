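"""Chimeric-read deconvolution.

Reads that fail to map to the genome (after repeat filtering) are tested
for a mature miRNA at their 5' end — the orientation produced by the
on-bead ligation, which joins the miRNA 3' end to the target fragment 5'
end.  The miRNA portion is then trimmed and the residual target fragment
is mapped to the genome, yielding aligned fragments tagged with the
guiding miRNA.
"""
from __future__ import annotations

from typing import Optional

from .align import SeedIndex, map_read
from .models import AlignedFragment, ChimeraCall, MiRNA, ReadRecord, revcomp


def detect_chimera(
    sequence: str,
    mirnas: list[MiRNA],
    min_mirna_match: int = 18,
    max_mismatches: int = 1,
    min_target_length: int = 18,
    search_3prime: bool = False,
) -> Optional[ChimeraCall]:
    """Find the best ungapped miRNA match at the read 5' end.

    Best = longest matched span, ties broken by fewest mismatches, then by
    lexicographically smallest miRNA name; equally scoring co-winners are
    recorded in ``ambiguous_with``.  Returns None when no miRNA reaches
    ``min_mirna_match`` bases within ``max_mismatches``, or when the
    residual target is shorter than ``min_target_length``.

    ``search_3prime`` flips the geometry for chemistries that ligate the
    target first (the read is reversed-complemented before matching).
    """
    if not mirnas:
        raise ValueError("empty miRNA set")
    read = revcomp(sequence) if search_3prime else sequence
    best: list[tuple[int, int, str]] = []  # (match_length, mismatches, name)
    for m in sorted(mirnas, key=lambda m: m.name):
        span = min(len(m.sequence), len(read))
        if span < min_mirna_match:
            continue
        # mismatches are non-decreasing in span: walk out to the longest
        # span still within budget
        mm = 0
        best_len = 0
        best_mm = 0
        for i in range(span):
            if read[i] != m.sequence[i]:
                mm += 1
                if mm > max_mismatches:
                    break
            if i + 1 >= min_mirna_match:
                best_len, best_mm = i + 1, mm
        if best_len >= min_mirna_match:
            best.append((best_len, best_mm, m.name))
    if not best:
        return None
    best.sort(key=lambda t: (-t[0], t[1], t[2]))
    top_len, top_mm, _ = best[0]
    winners = [t for t in best if t[0] == top_len and t[1] == top_mm]
    match_length = top_len
    if len(read) - match_length < min_target_length:
        return None
    return ChimeraCall(
        read_id="",
        mirna_name=winners[0][2],
        match_length=match_length,
        mismatches=top_mm,
        target_span=(match_length, len(read)),
        ambiguous_with=tuple(w[2] for w in winners[1:]),
    )


def classify_unmapped_read(
    read: ReadRecord,
    mirnas: list[MiRNA],
    min_mirna_match: int = 18,
    max_mismatches: int = 1,
    min_target_length: int = 18,
) -> tuple[Optional[ChimeraCall], str]:
    """Chimera call plus an accounting reason for non-calls.

    Reasons: ``chimeric``, ``mirna_only`` (match covers essentially the
    whole read, no usable target residue), ``no_mirna_match``.
    """
    call = detect_chimera(
        read.sequence, mirnas, min_mirna_match, max_mismatches,
        min_target_length=min_target_length,
    )
    if call is not None:
        return (
            ChimeraCall(
                read_id=read.read_id,
                mirna_name=call.mirna_name,
                match_length=call.match_length,
                mismatches=call.mismatches,
                target_span=call.target_span,
                ambiguous_with=call.ambiguous_with,
            ),
            "chimeric",
        )
    # distinguish miRNA-only reads from plain non-matches
    probe = detect_chimera(
        read.sequence, mirnas, min_mirna_match, max_mismatches, min_target_length=0
    )
    if probe is not None:
        return None, "mirna_only"
    return None, "no_mirna_match"


def resolve_chimeras(
    calls: list[ChimeraCall],
    reads_by_id: dict[str, ReadRecord],
    index: SeedIndex,
    max_mismatches: int = 2,
) -> tuple[list[AlignedFragment], dict]:
    """Trim the miRNA portion and map each residual target fragment.

    Uniquely mapped fragments become AlignedFragments carrying the call's
    miRNA tag; multi-mapped and unmapped targets are counted and dropped.
    """
    fragments: list[AlignedFragment] = []
    dropped = {"target_multi": 0, "target_unmapped": 0}
    for call in calls:
        read = reads_by_id[call.read_id]
        target = read.sequence[call.target_span[0] : call.target_span[1]]
        res = map_read(index, target, max_mismatches=max_mismatches)
        if res.status == "unique":
            fragments.append(
                AlignedFragment(
                    chrom=res.chrom,
                    start=res.start,
                    end=res.end,
                    strand=res.strand,
                    umi=read.umi,
                    read_id=read.read_id,
                    sample=read.sample,
                    role=read.role,
                    replicate=read.replicate,
                    mirna_tag=call.mirna_name,
                    mismatches=res.mismatches,
                )
            )
        elif res.status == "multi":
            dropped["target_multi"] += 1
        else:
            dropped["target_unmapped"] += 1
    ledger = {
        "n_in": len(calls),
        "n_kept": len(fragments),
        "dropped": {k: v for k, v in dropped.items() if v},
    }
    return fragments, ledger
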
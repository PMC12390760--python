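"""miRNA seed families, allowlisting, and family-level read fractions.

A family is the equivalence class of miRNAs sharing the seed (nucleotides
2-8 by default).  Family read fractions are computed over deduplicated
chimeric fragments, and an optional allowlist (miRGeneDB-style) restricts
which miRNAs contribute.
"""
from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Iterable, Optional

from .models import AlignedFragment, FamilySummary, MiRNA, extract_seed


def assign_families(
    mirnas: list[MiRNA],
    family_map: Optional[dict[str, str]] = None,
    seed_window: tuple[int, int] = (2, 8),
) -> list[MiRNA]:
    """Attach family ids.

    With an explicit map (miRNA name -> family id) the map wins and must
    cover only known names; otherwise families are the equivalence classes
    of identical seeds, each named after its lexicographically smallest
    member.
    """
    if family_map is not None:
        unknown = sorted(set(family_map) - {m.name for m in mirnas})
        if unknown:
            raise ValueError(f"family map names unknown miRNAs: {', '.join(unknown)}")
        return [
            replace(m, family_id=family_map.get(m.name, m.family_id)) for m in mirnas
        ]
    by_seed: dict[str, list[MiRNA]] = {}
    for m in mirnas:
        by_seed.setdefault(extract_seed(m.sequence, seed_window), []).append(m)
    fam_of: dict[str, str] = {}
    for seed, members in by_seed.items():
        fam = min(x.name for x in members)
        for x in members:
            fam_of[x.name] = fam
    return [replace(m, family_id=fam_of[m.name]) for m in mirnas]


def apply_allowlist(
    chimeric_fragments: list[AlignedFragment], allowlist: Iterable[str]
) -> tuple[list[AlignedFragment], int]:
    """Drop fragments whose miRNA tag is outside the allowlist.

    An empty allowlist keeps everything (logged upstream).  Returns
    (kept, n_removed).
    """
    allowed = set(allowlist)
    if not allowed:
        return list(chimeric_fragments), 0
    kept = [f for f in chimeric_fragments if f.mirna_tag in allowed]
    return kept, len(chimeric_fragments) - len(kept)


def family_fractions(
    chimeric_fragments: list[AlignedFragment],
    mirnas: list[MiRNA],
    top_n: int = 8,
) -> tuple[list[FamilySummary], float]:
    """Per-family chimeric fragment counts, fractions, and descending ranks.

    Also returns the cumulative fraction of the ``top_n`` largest
    families.  Fragments must carry miRNA tags; miRNAs must carry family
    assignments (see :func:`assign_families`).
    """
    fam_of = {m.name: m.family_id for m in mirnas}
    members: dict[str, list[str]] = {}
    seeds: dict[str, str] = {}
    for m in mirnas:
        if m.family_id is None:
            raise ValueError(f"miRNA {m.name} has no family assignment")
        members.setdefault(m.family_id, []).append(m.name)
        seeds[m.family_id] = m.seed
    counts: dict[str, int] = {}
    for f in chimeric_fragments:
        if not f.mirna_tag:
            continue
        fam = fam_of.get(f.mirna_tag)
        if fam is None:
            raise ValueError(f"fragment tagged with unknown miRNA {f.mirna_tag}")
        counts[fam] = counts.get(fam, 0) + 1
    total = sum(counts.values())
    if total == 0:
        warnings.warn("no chimeric fragments; empty family summary")
        return [], 0.0
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    summaries = [
        FamilySummary(
            family_id=fam,
            members=tuple(sorted(members[fam])),
            seed=seeds[fam],
            chimeric_read_count=n,
            fraction_of_total=n / total,
            rank=i + 1,
        )
        for i, (fam, n) in enumerate(ordered)
    ]
    cumulative = sum(s.fraction_of_total for s in summaries[:top_n])
    return summaries, cumulative
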
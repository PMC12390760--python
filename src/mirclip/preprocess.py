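"""UMI extraction and 3' adapter trimming.

These are the first stages applied to every raw library: the leading
``umi_length`` bases move from the sequence into the read name (so that
downstream deduplication can recover them from FASTQ alone), then the 3'
adapter is trimmed by ungapped suffix-vs-prefix matching.
"""
from __future__ import annotations

from dataclasses import replace

from .models import ReadRecord

UMI_DELIMITER = "_"


def extract_umi(read: ReadRecord, umi_length: int, delimiter: str = UMI_DELIMITER):
    """Move the first ``umi_length`` bases into the UMI field.

    The UMI is appended to the read id after ``delimiter``.  Returns the
    shortened read, or None when the read is too short to contain a UMI
    plus at least one insert base (caller counts the drop).
    """
    if umi_length == 0:
        return replace(read, umi="")
    if len(read.sequence) < umi_length + 1:
        return None
    umi = read.sequence[:umi_length]
    return replace(
        read,
        read_id=f"{read.read_id}{delimiter}{umi}",
        sequence=read.sequence[umi_length:],
        quality=read.quality[umi_length:],
        umi=umi,
    )


def umi_from_read_id(read_id: str, delimiter: str = UMI_DELIMITER) -> str:
    return read_id.rsplit(delimiter, 1)[1]


def trim_adapter(
    read: ReadRecord,
    adapter: str,
    min_overlap: int = 3,
    max_mismatch_rate: float = 0.1,
) -> ReadRecord:
    """Remove a 3' adapter by ungapped suffix/prefix alignment.

    Everything from the first (leftmost, hence longest-suffix) position
    where the read suffix matches a prefix of the adapter — with at least
    ``min_overlap`` aligned bases and a mismatch rate of at most
    ``max_mismatch_rate`` — is removed.  An internal full-adapter
    occurrence therefore also trims everything downstream of it.
    No match is a no-op.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq = read.sequence
    # trim to a fixpoint: removing a suffix can expose a shorter qualifying
    # adapter-prefix suffix (tandem partial copies), and trimming must be
    # idempotent
    while True:
        cut = _first_adapter_hit(seq, adapter, min_overlap, max_mismatch_rate)
        if cut is None:
            break
        seq = seq[:cut]
    if len(seq) == len(read.sequence):
        return read
    return replace(read, sequence=seq, quality=read.quality[: len(seq)])


def _first_adapter_hit(
    seq: str, adapter: str, min_overlap: int, max_mismatch_rate: float
):
    n = len(seq)
    alen = len(adapter)
    for i in range(0, n - min_overlap + 1):
        length = min(n - i, alen)
        if length < min_overlap:
            break
        allowed = int(max_mismatch_rate * length)
        mm = 0
        j = 0
        while j < length:
            if seq[i + j] != adapter[j]:
                mm += 1
                if mm > allowed:
                    break
            j += 1
        if j == length:
            return i
    return None


def preprocess_reads(
    reads: list[ReadRecord],
    umi_length: int = 10,
    adapter: str = "AGATCGGAAGAGCACACGTCT",
    min_overlap: int = 3,
    max_mismatch_rate: float = 0.1,
    min_length: int = 18,
) -> tuple[list[ReadRecord], dict]:
    """Run UMI extraction then adapter trimming over a library.

    Reads shorter than ``min_length`` after trimming are discarded (too
    short to map or to contain a miRNA).  Returns the kept reads and an
    accounting ledger ``{n_in, n_kept, dropped: {reason: n}}``.
    """
    kept: list[ReadRecord] = []
    dropped = {"too_short_for_umi": 0, "too_short_after_trim": 0}
    for r in reads:
        r2 = extract_umi(r, umi_length)
        if r2 is None:
            dropped["too_short_for_umi"] += 1
            continue
        r3 = trim_adapter(r2, adapter, min_overlap, max_mismatch_rate)
        if len(r3.sequence) < min_length:
            dropped["too_short_after_trim"] += 1
            continue
        kept.append(r3)
    ledger = {
        "n_in": len(reads),
        "n_kept": len(kept),
        "dropped": {k: v for k, v in dropped.items() if v},
    }
    return kept, ledger
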
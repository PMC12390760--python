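"""qPCR arithmetic: relative expression, splicing ratios, and the t-test.

Relative expression is the standard 2^-ddCt with reference-gene
normalization (the study normalizes to RPL19); the exon splicing readout
is the inclusion:skipping ratio 2^-(Ct_inclusion - Ct_skipping),
optionally divided by a full-length transcript abundance factor.
Technical replicates are averaged on the Ct (cycle) scale before
exponentiation, and amplification efficiency is fixed at 2.
"""
from __future__ import annotations

from typing import Optional

from scipy import stats

from .models import CtRecord


def relative_expression(
    target: CtRecord,
    reference: CtRecord,
    target_ctrl: CtRecord,
    reference_ctrl: CtRecord,
) -> float:
    """2^-ddCt fold change of target vs control condition.

    ddCt = (mean Ct_target - mean Ct_reference)
         - (mean Ct_target_ctrl - mean Ct_reference_ctrl).
    """
    for rec, role in ((reference, "reference"), (reference_ctrl, "reference")):
        if rec.target_role != role:
            raise ValueError(
                f"record {rec.sample_id}/{rec.primer_set} is not a reference record"
            )
    ddct = (target.mean_ct - reference.mean_ct) - (
        target_ctrl.mean_ct - reference_ctrl.mean_ct
    )
    return 2.0 ** (-ddct)


def splicing_ratio(
    inclusion: CtRecord,
    skipping: CtRecord,
    full_length_norm: Optional[float] = None,
) -> tuple[float, Optional[float]]:
    """Exon inclusion:skipping ratio 2^-(Ct_incl - Ct_skip).

    Returns (raw_ratio, normalized_ratio); the normalized value is the raw
    ratio divided by ``full_length_norm`` (relative abundance of the
    full-length transcript) when supplied, else None.
    """
    if inclusion.target_role != "inclusion" or skipping.target_role != "skipping":
        raise ValueError(
            "splicing_ratio needs one inclusion and one skipping record "
            f"(got {inclusion.target_role!r}, {skipping.target_role!r})"
        )
    raw = 2.0 ** (-(inclusion.mean_ct - skipping.mean_ct))
    if full_length_norm is None:
        return raw, None
    return raw, raw / full_length_norm


def two_sample_test(values_a, values_b, welch: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample Student's t-test (pooled variance by default).

    ``welch=True`` switches to the unequal-variance form.
    """
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError("each group needs at least 2 biological replicates")
    t, p = stats.ttest_ind(values_a, values_b, equal_var=not welch)
    return float(t), float(p)
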
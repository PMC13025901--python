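"""Major-transcript (MT) calling and alternative-MT (AMT) detection.

The MT of a gene in one condition is its highest-expressed transcript,
accepted only when it clears a margin over the runner-up: in
``absolute`` mode the difference ``top - second`` must exceed the
margin (FPKM units); in ``fold`` mode the ratio ``top / second`` must.
A gene whose confident MT identity differs between the two conditions
is an AMT gene. Gene-level expression change between conditions is
binned into four categories on ``|E2 - E1| / E1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Set

import pandas as pd
from scipy import stats

from .model import ValidationError

CHANGE_BINS = ("0-50%", "50-100%", "100-200%", ">200%")


@dataclass
class MajorTranscriptCall:
    gene_id: str
    condition: str
    mt_id: Optional[str]
    mt_level: float
    runner_up_level: float
    margin_satisfied: bool
    top_ranked_id: Optional[str] = None  # argmax even when margin fails


@dataclass
class AMTRecord:
    gene_id: str
    mt_condition1: str
    mt_condition2: str
    change_ratio: float = float("nan")  # signed (E2 - E1) / E1
    change_category: Optional[str] = None


def call_major_transcript(
    gene_id: str,
    condition: str,
    transcript_expr: Mapping[str, float],
    margin: float = 10.0,
    margin_mode: str = "absolute",
) -> MajorTranscriptCall:
    """Call the major transcript of one gene in one condition.

    ``transcript_expr`` maps transcript id to its mean expression (FPKM
    across replicates). Single-isoform genes satisfy the margin
    trivially; in fold mode a runner-up of zero satisfies it too.
    """
    if margin_mode not in ("absolute", "fold"):
        raise ValidationError(f"unknown margin_mode {margin_mode!r}")
    if any(v < 0 for v in transcript_expr.values()):
        raise ValidationError(f"{gene_id}: negative expression")
    if not transcript_expr:
        raise ValidationError(f"{gene_id}: no expressed transcripts")
    ranked = sorted(
        transcript_expr.items(), key=lambda kv: (-kv[1], kv[0])
    )
    top_id, top = ranked[0]
    if len(ranked) == 1:
        return MajorTranscriptCall(
            gene_id, condition, top_id, top, 0.0, True, top_id
        )
    second = ranked[1][1]
    if margin_mode == "absolute":
        ok = (top - second) > margin
    else:
        ok = True if second == 0 else (top / second) > margin
    return MajorTranscriptCall(
        gene_id,
        condition,
        top_id if ok else None,
        top,
        second,
        ok,
        top_id,
    )


def call_major_transcripts(
    transcript_expr_by_gene: Mapping[str, Mapping[str, float]],
    condition: str,
    margin: float = 10.0,
    margin_mode: str = "absolute",
) -> dict:
    return {
        gid: call_major_transcript(gid, condition, expr, margin, margin_mode)
        for gid, expr in transcript_expr_by_gene.items()
    }


def detect_amt(
    calls_c1: Mapping[str, MajorTranscriptCall],
    calls_c2: Mapping[str, MajorTranscriptCall],
    require_margin_both: bool = True,
):
    """Split genes into AMT / MT-constant / indeterminate.

    With ``require_margin_both`` (default) a gene needs a confident MT
    in both conditions; otherwise the top-ranked transcript is compared
    regardless of the margin outcome.
    """
    amt: list = []
    constant: list = []
    indeterminate: list = []
    for gid in sorted(set(calls_c1) & set(calls_c2)):
        c1, c2 = calls_c1[gid], calls_c2[gid]
        if require_margin_both:
            id1, id2 = c1.mt_id, c2.mt_id
        else:
            id1, id2 = c1.top_ranked_id, c2.top_ranked_id
        if id1 is None or id2 is None:
            indeterminate.append(gid)
        elif id1 != id2:
            amt.append(AMTRecord(gid, id1, id2))
        else:
            constant.append(gid)
    return amt, constant, indeterminate


def categorize_ratio(ratio: float) -> str:
    """Bin |ratio| into the half-open categories [0,.5), [.5,1), [1,2), [2,inf)."""
    r = abs(ratio)
    if r < 0.5:
        return CHANGE_BINS[0]
    if r < 1.0:
        return CHANGE_BINS[1]
    if r < 2.0:
        return CHANGE_BINS[2]
    return CHANGE_BINS[3]


def categorize_change(
    amt_genes: Sequence[AMTRecord],
    constant_genes: Sequence[str],
    gene_expr_c1: Mapping[str, float],
    gene_expr_c2: Mapping[str, float],
):
    """Expression-change category distributions for AMT vs MT-constant genes.

    Returns (table, chi2_p, n_excluded): ``table`` is a DataFrame of
    counts per bin per group; ``chi2_p`` is the two-sided chi-square
    homogeneity p-value (NaN when a margin of the table is empty);
    genes with E1 = 0 are excluded and counted.
    """
    counts = {g: {b: 0 for b in CHANGE_BINS} for g in ("AMT", "MT-constant")}
    excluded = 0

    def _add(group: str, gid: str, record: Optional[AMTRecord] = None):
        nonlocal excluded
        e1 = gene_expr_c1.get(gid, 0.0)
        e2 = gene_expr_c2.get(gid, 0.0)
        if e1 <= 0:
            excluded += 1
            return
        ratio = (e2 - e1) / e1
        cat = categorize_ratio(ratio)
        counts[group][cat] += 1
        if record is not None:
            record.change_ratio = ratio
            record.change_category = cat

    for rec in amt_genes:
        _add("AMT", rec.gene_id, rec)
    for gid in constant_genes:
        _add("MT-constant", gid)

    table = pd.DataFrame(counts).T[list(CHANGE_BINS)]
    obs = table.values
    if obs.sum() == 0 or (obs.sum(axis=1) == 0).any():
        p = float("nan")
    else:
        keep = obs.sum(axis=0) > 0
        p = float(stats.chi2_contingency(obs[:, keep]).pvalue)
    return table, p, excluded


def intersect_deg(
    amt_genes: Iterable[str],
    deg_up: Set[str],
    deg_down: Set[str],
) -> dict:
    """DE-AMT intersection with direction split and Venn counts."""
    amt = set(amt_genes)
    deg = deg_up | deg_down
    both = amt & deg
    return {
        "de_amt_total": len(both),
        "de_amt_up": len(amt & deg_up),
        "de_amt_down": len(amt & deg_down),
        "amt_only": len(amt - deg),
        "deg_only": len(deg - amt),
        "both": len(both),
    }
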
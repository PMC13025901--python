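"""Terminus extension of reference transcripts with assembled models.

Short-read assembled transcript models overlapping a reference
transcript's terminal exon and protruding past its terminus provide
evidence that the annotated terminus is too short. With at least
``min_support`` protruding models on the same strand, the transcription
end site is moved to the *longest* protruding 3' end, while the
transcription start site is moved only to the *shortest* protruding 5'
end (the conservative reading of using short 5' ends to define starts).
Only terminal exon boundaries move; intron chains are untouched, so the
operation is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import pandas as pd

from .model import AnnotationSet, GenomicInterval, TranscriptModel


@dataclass(frozen=True)
class TerminusExtension:
    transcript_id: str
    end: str  # five_prime / three_prime
    old_boundary: int
    new_boundary: int
    n_supporting_models: int


def _protrusions(
    t: TranscriptModel, assembled: AnnotationSet, which: str
) -> list:
    """Assembled-model termini protruding past t's terminus.

    A candidate must overlap the relevant terminal exon on the same
    strand and protrude beyond the transcript boundary in the
    biological direction of that end.
    """
    three_prime = which == "three_prime"
    # genomic side of the boundary: on '+' the 3' end is the right edge
    right_side = (t.strand == "+") == three_prime
    terminal_exon = t.exons[-1] if right_side else t.exons[0]
    out = []
    for a in assembled:
        if a.chrom != t.chrom or a.strand != t.strand:
            continue
        if not (a.start < terminal_exon.end and terminal_exon.start < a.end):
            continue
        if right_side and a.end > t.end:
            out.append(a.end)
        elif not right_side and a.start < t.start:
            out.append(a.start)
    return out


def _extend_transcript(
    t: TranscriptModel,
    assembled: AnnotationSet,
    min_support: int,
    extend_five_prime: bool,
) -> Tuple[TranscriptModel, list]:
    extensions = []
    exons = list(t.exons)

    cands3 = _protrusions(t, assembled, "three_prime")
    if len(cands3) >= min_support:
        # longest protruding 3' end
        new_tes = max(cands3) if t.strand == "+" else min(cands3)
        idx = -1 if t.strand == "+" else 0
        old = t.tes
        e = exons[idx]
        exons[idx] = GenomicInterval(
            e.chrom,
            e.start if t.strand == "+" else new_tes,
            new_tes if t.strand == "+" else e.end,
            e.strand,
        )
        extensions.append(
            TerminusExtension(
                t.transcript_id, "three_prime", old, new_tes, len(cands3)
            )
        )

    if extend_five_prime:
        cands5 = _protrusions(t, assembled, "five_prime")
        if len(cands5) >= min_support:
            # shortest protruding 5' end (least protrusion, conservative)
            new_tss = min(cands5) if t.strand == "-" else max(cands5)
            idx = 0 if t.strand == "+" else -1
            old = t.tss
            e = exons[idx]
            exons[idx] = GenomicInterval(
                e.chrom,
                new_tss if t.strand == "+" else e.start,
                e.end if t.strand == "+" else new_tss,
                e.strand,
            )
            extensions.append(
                TerminusExtension(
                    t.transcript_id, "five_prime", old, new_tss, len(cands5)
                )
            )

    if not extensions:
        return t, []
    return (
        TranscriptModel(
            transcript_id=t.transcript_id,
            exons=tuple(exons),
            gene_id=t.gene_id,
            read_support=t.read_support,
            source=t.source,
        ),
        extensions,
    )


def extend_termini(
    reference: AnnotationSet,
    assembled: AnnotationSet,
    min_support: int = 2,
    extend_five_prime: bool = True,
) -> Tuple[AnnotationSet, list]:
    """Extend reference termini with assembled-model evidence.

    Returns the extended annotation plus the list of
    :class:`TerminusExtension` records (empty entries are omitted).
    """
    out = AnnotationSet()
    all_ext = []
    for t in sorted(reference, key=lambda t: t.transcript_id):
        new_t, ext = _extend_transcript(
            t, assembled, min_support, extend_five_prime
        )
        out.add(new_t)
        all_ext.extend(ext)
    return out, all_ext


def extensions_to_frame(extensions) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": e.transcript_id,
                "end": e.end,
                "old_boundary": e.old_boundary,
                "new_boundary": e.new_boundary,
                "n_supporting_models": e.n_supporting_models,
            }
            for e in extensions
        ],
        columns=[
            "transcript_id",
            "end",
            "old_boundary",
            "new_boundary",
            "n_supporting_models",
        ],
    )
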
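"""Alternative-splicing event detection and typing.

Events are found pairwise between transcripts of one gene. For each
unordered pair the genomic axis is partitioned at *sync points* —
coordinates that are exon boundaries of the same polarity (exon start or
exon end) in both transcripts, transcript termini included. Every
maximal region between consecutive sync points where the two exonic
structures differ is a variant region, typed as:

* **ES** (exon skipping) — one form is intronic across the region, the
  other contributes one or more complete exons strictly inside;
* **IR** (intron retention) — an intron of one form lies fully inside an
  exon of the other (detected by direct containment, so a mono-exonic
  transcript can act as the retaining form);
* **A5SS / A3SS** — the two forms share one flank of an intron but
  differ at the other; the label follows the biological 5'/3' side, so
  it is strand-aware;
* **MEE** (mutually exclusive exons) — each form contributes exactly one
  complete exon strictly inside, the two exons do not overlap;
* **complex** — any other difference; reported but excluded from the
  five-way statistics.

Differences outside the outermost sync points (terminus jitter,
5'-truncation) are not splicing events and yield nothing. Events are
deduplicated gene-wide on (type, anchors, variant region).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AnnotationSet, ExpressionMatrix, TranscriptModel, ValidationError

EVENT_TYPES = ("ES", "IR", "A3SS", "A5SS", "MEE")


@dataclass(frozen=True)
class ASEvent:
    gene_id: str
    event_type: str
    inclusion_form_id: str
    exclusion_form_id: str
    anchor_left: int
    anchor_right: int
    region_start: int
    region_end: int
    strand: str

    @property
    def key(self):
        """Gene-wide deduplication key."""
        return (
            self.event_type,
            self.anchor_left,
            self.anchor_right,
            self.region_start,
            self.region_end,
        )


@dataclass
class GeneASProfile:
    gene_id: str
    n_events: int
    pattern_set: frozenset
    n_transcripts: int


# ---------------------------------------------------------------------------
# pairwise decomposition
# ---------------------------------------------------------------------------

def _sites(t: TranscriptModel):
    """(coordinate, polarity) pairs; 'a' = intron->exon, 'd' = exon->intron.

    Transcript termini are included as pseudo-sites so that events whose
    variant region reaches a shared terminus are still anchored, while
    jittered termini produce no anchor and hence no spurious events.
    """
    acceptors = {e.start for e in t.exons}
    donors = {e.end for e in t.exons}
    return acceptors, donors


def _fragments(t: TranscriptModel, lo: int, hi: int):
    """Exonic intervals of t clipped to [lo, hi], sorted."""
    out = []
    for e in t.exons:
        s, w = max(e.start, lo), min(e.end, hi)
        if s < w:
            out.append((s, w))
    return out


def _detect_ir(x: TranscriptModel, y: TranscriptModel, gene_id: str):
    """IR events where an intron of x is fully exonic inside an exon of y."""
    events = []
    for d, a in x.intron_chain:
        for f in y.exons:
            if f.start < d and a < f.end:
                events.append(
                    ASEvent(
                        gene_id=gene_id,
                        event_type="IR",
                        inclusion_form_id=y.transcript_id,
                        exclusion_form_id=x.transcript_id,
                        anchor_left=d,
                        anchor_right=a,
                        region_start=d,
                        region_end=a,
                        strand=x.strand,
                    )
                )
                break
    return events


def _type_region(
    a: TranscriptModel,
    b: TranscriptModel,
    c1: int,
    c2: int,
    gene_id: str,
) -> Optional[ASEvent]:
    frags_a = _fragments(a, c1, c2)
    frags_b = _fragments(b, c1, c2)
    if frags_a == frags_b:
        return None
    strand = a.strand
    cont_a = frags_a == [(c1, c2)]
    cont_b = frags_b == [(c1, c2)]
    if cont_a or cont_b:
        # retained-intron pattern: handled exhaustively by _detect_ir
        return None

    def _complete_inside(frags, t):
        starts = {e.start for e in t.exons}
        ends = {e.end for e in t.exons}
        return all(
            c1 < s and w < c2 and s in starts and w in ends for s, w in frags
        )

    # exon skipping: one side intronic throughout
    if not frags_a or not frags_b:
        inc, exc = (a, b) if frags_a else (b, a)
        frags = frags_a or frags_b
        if _complete_inside(frags, inc):
            return ASEvent(
                gene_id,
                "ES",
                inc.transcript_id,
                exc.transcript_id,
                c1,
                c2,
                frags[0][0],
                frags[-1][1],
                strand,
            )
        return _complex(a, b, c1, c2, gene_id)

    # alternative donor/acceptor: single fragment each, one shared edge
    if len(frags_a) == 1 and len(frags_b) == 1:
        (sa, ea), (sb, eb) = frags_a[0], frags_b[0]
        if sa == sb == c1 and ea != eb:
            # differing genomic exon end (left-anchored fragments)
            etype = "A5SS" if strand == "+" else "A3SS"
            inc, exc = (a, b) if ea > eb else (b, a)
            return ASEvent(
                gene_id,
                etype,
                inc.transcript_id,
                exc.transcript_id,
                c1,
                c2,
                min(ea, eb),
                max(ea, eb),
                strand,
            )
        if ea == eb == c2 and sa != sb:
            # differing genomic exon start (right-anchored fragments)
            etype = "A3SS" if strand == "+" else "A5SS"
            inc, exc = (a, b) if sa < sb else (b, a)
            return ASEvent(
                gene_id,
                etype,
                inc.transcript_id,
                exc.transcript_id,
                c1,
                c2,
                min(sa, sb),
                max(sa, sb),
                strand,
            )
        # mutually exclusive exons: complete, non-overlapping
        if (
            _complete_inside(frags_a, a)
            and _complete_inside(frags_b, b)
            and (ea <= sb or eb <= sa)
        ):
            return ASEvent(
                gene_id,
                "MEE",
                a.transcript_id,
                b.transcript_id,
                c1,
                c2,
                min(sa, sb),
                max(ea, eb),
                strand,
            )
    return _complex(a, b, c1, c2, gene_id)


def _complex(a, b, c1, c2, gene_id):
    return ASEvent(
        gene_id,
        "complex",
        a.transcript_id,
        b.transcript_id,
        c1,
        c2,
        c1,
        c2,
        a.strand,
    )


def decompose_pair(
    a: TranscriptModel, b: TranscriptModel, gene_id: str
) -> list:
    """All typed variant regions between two transcripts of one gene."""
    if a.chrom != b.chrom or a.strand != b.strand:
        raise ValidationError(
            f"{gene_id}: transcripts {a.transcript_id}/{b.transcript_id} "
            "are on different chrom/strand"
        )
    events = _detect_ir(a, b, gene_id) + _detect_ir(b, a, gene_id)
    if a.is_mono_exon or b.is_mono_exon:
        # mono-exonic transcripts participate only as IR retaining forms
        return events
    acc_a, don_a = _sites(a)
    acc_b, don_b = _sites(b)
    sync = sorted((acc_a & acc_b) | (don_a & don_b))
    for c1, c2 in zip(sync, sync[1:]):
        ev = _type_region(a, b, c1, c2, gene_id)
        if ev is not None:
            events.append(ev)
    return events


def detect_events(
    gene_transcripts: Sequence[TranscriptModel],
    gene_id: Optional[str] = None,
) -> list:
    """Detect and deduplicate AS events among transcripts of one gene."""
    if gene_id is None:
        gene_id = gene_transcripts[0].gene_id or "?"
    ts = sorted(gene_transcripts, key=lambda t: t.transcript_id)
    seen = {}
    for a, b in itertools.combinations(ts, 2):
        for ev in decompose_pair(a, b, gene_id):
            seen.setdefault(ev.key, ev)
    return [seen[k] for k in sorted(seen)]


def detect_events_catalog(catalog: AnnotationSet) -> list:
    """Run detect_events for every gene with >= 2 transcripts."""
    events = []
    for gid in sorted(catalog.genes):
        ts = catalog.gene_transcripts(gid)
        if len(ts) >= 2:
            events.extend(detect_events(ts, gid))
    return events


# ---------------------------------------------------------------------------
# gene profiles and summary statistics
# ---------------------------------------------------------------------------

def profile_genes(events: Iterable[ASEvent], catalog: AnnotationSet):
    """Per-gene AS profiles plus a catalog-level summary.

    ``complex`` regions are excluded from the five-way proportions and
    from the per-gene pattern sets.
    """
    typed = [e for e in events if e.event_type in EVENT_TYPES]
    by_gene: dict = {}
    for e in typed:
        by_gene.setdefault(e.gene_id, []).append(e)
    profiles = [
        GeneASProfile(
            gene_id=gid,
            n_events=len(evs),
            pattern_set=frozenset(e.event_type for e in evs),
            n_transcripts=len(catalog.genes.get(gid, [])),
        )
        for gid, evs in sorted(by_gene.items())
    ]
    n_total = len(typed)
    type_counts = {t: 0 for t in EVENT_TYPES}
    for e in typed:
        type_counts[e.event_type] += 1
    summary = {
        "n_events": n_total,
        "n_complex": sum(1 for e in events if e.event_type == "complex"),
        "n_as_genes": len(by_gene),
        "type_counts": type_counts,
        "type_proportions": {
            t: (c / n_total if n_total else float("nan"))
            for t, c in type_counts.items()
        },
        "genes_multi_event": sum(1 for p in profiles if p.n_events > 2),
        "genes_multi_pattern": sum(1 for p in profiles if len(p.pattern_set) >= 2),
        "genes_all_patterns": sum(
            1 for p in profiles if len(p.pattern_set) == len(EVENT_TYPES)
        ),
    }
    return profiles, summary


@dataclass
class CorrelationReport:
    r_transcripts_vs_exons: float
    p_transcripts_vs_exons: float
    n_all: int
    r_transcripts_vs_exons_high_expr: float
    p_transcripts_vs_exons_high_expr: float
    n_high_expr: int
    r_transcripts_vs_expression: float
    p_transcripts_vs_expression: float
    n_expr: int


def _pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), len(x)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(x)


def correlate_diversity(
    catalog: AnnotationSet,
    gene_expression: Optional[Mapping[str, float]] = None,
    high_expr_threshold: float = 30.0,
) -> CorrelationReport:
    """Pearson correlations between isoform diversity and gene structure.

    ``gene_expression`` maps gene id to a gene-level FPKM; the
    high-expression stratum keeps genes above ``high_expr_threshold``.
    """
    genes = sorted(catalog.genes)
    n_tx = [len(catalog.genes[g]) for g in genes]
    n_ex = [max(t.n_exons for t in catalog.gene_transcripts(g)) for g in genes]
    r1, p1, n1 = _pearson(n_tx, n_ex)
    if gene_expression is not None:
        expressed = [g for g in genes if g in gene_expression]
        hi = [g for g in expressed if gene_expression[g] > high_expr_threshold]
        r2, p2, n2 = _pearson(
            [len(catalog.genes[g]) for g in hi],
            [max(t.n_exons for t in catalog.gene_transcripts(g)) for g in hi],
        )
        r3, p3, n3 = _pearson(
            [len(catalog.genes[g]) for g in expressed],
            [gene_expression[g] for g in expressed],
        )
    else:
        r2 = p2 = r3 = p3 = float("nan")
        n2 = n3 = 0
    return CorrelationReport(r1, p1, n1, r2, p2, n2, r3, p3, n3)


def events_to_frame(events: Iterable[ASEvent]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": e.gene_id,
            "event_type": e.event_type,
            "inclusion_form": e.inclusion_form_id,
            "exclusion_form": e.exclusion_form_id,
            "anchor_left": e.anchor_left,
            "anchor_right": e.anchor_right,
            "region_start": e.region_start,
            "region_end": e.region_end,
            "strand": e.strand,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "event_type",
            "inclusion_form",
            "exclusion_form",
            "anchor_left",
            "anchor_right",
            "region_start",
            "region_end",
            "strand",
        ],
    )
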
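"""Structural classification of observed transcripts against a reference.

Each observed transcript is placed in exactly one of eight categories:

* **FSM** — intron chain identical to a reference transcript;
* **ISM** — intron chain a contiguous proper sub-chain of a reference
  transcript (5'- and/or 3'-truncated model);
* **NIC** — every splice site known within the assigned gene, but the
  chain matches no reference transcript (novel combination);
* **NNC** — at least one splice site absent from the assigned gene;
* **fusion** — exonic overlap with two or more same-strand genes;
* **genic** — mono-exonic inside a gene without a junction match;
* **antisense** — overlaps annotated genes only on the opposite strand;
* **intergenic** — overlaps no annotated gene.

Junction comparison is exact by default; ``junction_tolerance`` allows a
+/- fuzz window per splice site. Mono-exonic observed transcripts can
still be FSM when they reciprocally overlap a mono-exon reference
transcript by >= 80%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import AnnotationSet, TranscriptModel, ValidationError

CATEGORIES = (
    "FSM",
    "ISM",
    "NIC",
    "NNC",
    "fusion",
    "genic",
    "antisense",
    "intergenic",
)

#: categories whose transcripts come from annotated genes
KNOWN_GENE_CATEGORIES = ("FSM", "ISM", "NIC", "NNC", "fusion", "genic")


@dataclass(frozen=True)
class AlignmentSummary:
    """Per-transcript alignment quality record."""

    transcript_id: str
    identity: float
    coverage: float
    length: int = 0
    tss_equivalence_group: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValidationError(
                f"{self.transcript_id}: identity/coverage must be in [0,1]"
            )


@dataclass
class StructuralCall:
    transcript_id: str
    category: str
    assigned_gene_id: Optional[str] = None
    matched_reference_transcript: Optional[str] = None
    n_novel_splice_sites: int = 0
    junction_match_fraction: float = 0.0
    mono_exon: bool = False


@dataclass
class CatalogSummary:
    """Catalog-level tallies; percentages are derived at report time."""

    n_transcripts: int = 0
    n_known_transcripts: int = 0  # FSM only (distinct novel termini excluded)
    n_novel_transcripts: int = 0
    n_annotated_category: int = 0  # FSM + ISM
    n_genes: int = 0
    n_annotated_genes: int = 0
    n_novel_genes: int = 0
    genes_with_multiple_isoforms: int = 0
    genes_with_ge10_isoforms: int = 0
    category_counts: dict = field(default_factory=dict)
    novel_from_known_genes: int = 0
    novel_from_novel_genes: int = 0
    mean_length_known: float = float("nan")
    mean_length_novel: float = float("nan")


# ---------------------------------------------------------------------------
# alignment-record filtering
# ---------------------------------------------------------------------------

def filter_alignments(
    records: Iterable[AlignmentSummary],
    min_identity: float = 0.9,
    min_coverage: float = 0.85,
) -> set:
    """Alignment QC filter and 5'-degradation merge.

    A record is removed only when strictly below a threshold (identity
    < ``min_identity`` or coverage < ``min_coverage``). Within each
    ``tss_equivalence_group`` (same intron chain and 3' end, records
    differing only at the 5' terminus) a single representative — the
    longest — is retained.
    """
    passing = [
        r
        for r in records
        if r.identity >= min_identity and r.coverage >= min_coverage
    ]
    kept: set = set()
    by_group: dict = {}
    for r in passing:
        if r.tss_equivalence_group is None:
            kept.add(r.transcript_id)
        else:
            by_group.setdefault(r.tss_equivalence_group, []).append(r)
    for group in by_group.values():
        best = max(group, key=lambda r: (r.length, r.transcript_id))
        kept.add(best.transcript_id)
    return kept


def read_alignment_summaries(path: str) -> list:
    """Read alignments.tsv (transcript_id, identity, coverage[, length, tss_group])."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AlignmentSummary(
                transcript_id=str(row.transcript_id),
                identity=float(row.identity),
                coverage=float(row.coverage),
                length=int(getattr(row, "length", 0) or 0),
                tss_equivalence_group=(
                    str(row.tss_group)
                    if "tss_group" in df.columns and pd.notna(row.tss_group)
                    else None
                ),
            )
        )
    return records


# ---------------------------------------------------------------------------
# junction-chain helpers
# ---------------------------------------------------------------------------

def _chains_equal(a: Sequence, b: Sequence, tol: int) -> bool:
    if len(a) != len(b):
        return False
    return all(
        abs(x[0] - y[0]) <= tol and abs(x[1] - y[1]) <= tol
        for x, y in zip(a, b)
    )


def _is_contiguous_subchain(sub: Sequence, full: Sequence, tol: int) -> bool:
    """True if ``sub`` equals a contiguous window of ``full`` (proper)."""
    if not sub or len(sub) >= len(full):
        return False
    for i in range(len(full) - len(sub) + 1):
        if _chains_equal(sub, full[i : i + len(sub)], tol):
            return True
    return False


def _site_known(site: int, sites: Sequence[int], tol: int) -> bool:
    if tol == 0:
        return site in sites
    return any(abs(site - s) <= tol for s in sites)


def _exonic_overlap_bp(t: TranscriptModel, ref_ts: Sequence[TranscriptModel]) -> int:
    """Overlap between t's exons and the exonic union of reference models."""
    segs = sorted(
        (e.start, e.end) for r in ref_ts for e in r.exons
    )
    merged: list = []
    for s, e in segs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    total = 0
    for ex in t.exons:
        for s, e in merged:
            total += max(0, min(ex.end, e) - max(ex.start, s))
    return total


# ---------------------------------------------------------------------------
# classification cascade
# ---------------------------------------------------------------------------

def classify_transcript(
    t: TranscriptModel,
    reference: AnnotationSet,
    junction_tolerance: int = 0,
) -> StructuralCall:
    """Classify one observed transcript (see module docstring cascade)."""
    tol = junction_tolerance
    same = reference.genes_overlapping(t.chrom, t.start, t.end, t.strand)
    anti_strand = "-" if t.strand == "+" else "+"
    opposite = reference.genes_overlapping(t.chrom, t.start, t.end, anti_strand)

    if not same:
        if opposite:
            return StructuralCall(
                t.transcript_id, "antisense", mono_exon=t.is_mono_exon
            )
        return StructuralCall(
            t.transcript_id, "intergenic", mono_exon=t.is_mono_exon
        )

    # per-gene evidence: matched junctions and exonic overlap
    gene_stats = {}
    for gid in same:
        ref_ts = reference.gene_transcripts(gid)
        gene_introns = {ic for r in ref_ts for ic in r.intron_chain}
        matched = sum(
            1
            for intron in t.intron_chain
            if any(
                abs(intron[0] - gi[0]) <= tol and abs(intron[1] - gi[1]) <= tol
                for gi in gene_introns
            )
        )
        overlap = _exonic_overlap_bp(t, ref_ts)
        gene_stats[gid] = (matched, overlap)

    exonic_genes = [g for g, (_, ov) in gene_stats.items() if ov > 0]
    if len(exonic_genes) >= 2:
        assigned = max(exonic_genes, key=lambda g: gene_stats[g])
        return StructuralCall(
            t.transcript_id,
            "fusion",
            assigned_gene_id=assigned,
            junction_match_fraction=_jmf(t, gene_stats[assigned][0]),
            mono_exon=t.is_mono_exon,
        )

    assigned = max(same, key=lambda g: (gene_stats[g][0], gene_stats[g][1], g))
    ref_ts = reference.gene_transcripts(assigned)
    jmf = _jmf(t, gene_stats[assigned][0])

    if not t.is_mono_exon:
        chain = t.intron_chain
        for r in sorted(ref_ts, key=lambda r: r.transcript_id):
            if _chains_equal(chain, r.intron_chain, tol):
                return StructuralCall(
                    t.transcript_id,
                    "FSM",
                    assigned_gene_id=assigned,
                    matched_reference_transcript=r.transcript_id,
                    junction_match_fraction=1.0,
                )
        for r in sorted(ref_ts, key=lambda r: r.transcript_id):
            if _is_contiguous_subchain(chain, r.intron_chain, tol):
                return StructuralCall(
                    t.transcript_id,
                    "ISM",
                    assigned_gene_id=assigned,
                    matched_reference_transcript=r.transcript_id,
                    junction_match_fraction=1.0,
                )
        donors = sorted({ic[0] for r in ref_ts for ic in r.intron_chain})
        acceptors = sorted({ic[1] for r in ref_ts for ic in r.intron_chain})
        novel_sites = 0
        for d, a in chain:
            if not _site_known(d, donors, tol):
                novel_sites += 1
            if not _site_known(a, acceptors, tol):
                novel_sites += 1
        category = "NIC" if novel_sites == 0 else "NNC"
        return StructuralCall(
            t.transcript_id,
            category,
            assigned_gene_id=assigned,
            n_novel_splice_sites=novel_sites,
            junction_match_fraction=jmf,
        )

    # mono-exonic over a same-strand gene
    for r in sorted(ref_ts, key=lambda r: r.transcript_id):
        if r.is_mono_exon:
            inter = max(
                0, min(t.end, r.end) - max(t.start, r.start)
            )
            if (
                inter >= 0.8 * t.exonic_length
                and inter >= 0.8 * r.exonic_length
            ):
                return StructuralCall(
                    t.transcript_id,
                    "FSM",
                    assigned_gene_id=assigned,
                    matched_reference_transcript=r.transcript_id,
                    junction_match_fraction=1.0,
                    mono_exon=True,
                )
    return StructuralCall(
        t.transcript_id, "genic", assigned_gene_id=assigned, mono_exon=True
    )


def _jmf(t: TranscriptModel, matched: int) -> float:
    n = len(t.intron_chain)
    return matched / n if n else 0.0


def assign_novel_genes(
    calls: Mapping[str, StructuralCall], observed: AnnotationSet
) -> None:
    """Group antisense/intergenic transcripts into novel gene loci.

    Single-linkage merge of same-chrom, same-strand overlapping novel
    transcripts; loci are numbered deterministically by genomic order.
    """
    novel = sorted(
        (
            observed[tid]
            for tid, c in calls.items()
            if c.category in ("antisense", "intergenic")
        ),
        key=lambda t: (t.chrom, t.strand, t.start, t.transcript_id),
    )
    loci: list = []  # (chrom, strand, start, end, [tids])
    for t in novel:
        if (
            loci
            and loci[-1][0] == t.chrom
            and loci[-1][1] == t.strand
            and t.start < loci[-1][3]
        ):
            loci[-1][3] = max(loci[-1][3], t.end)
            loci[-1][4].append(t.transcript_id)
        else:
            loci.append([t.chrom, t.strand, t.start, t.end, [t.transcript_id]])
    for i, locus in enumerate(loci, start=1):
        gid = f"NOVELG_{i:05d}"
        for tid in locus[4]:
            calls[tid].assigned_gene_id = gid


def apply_gene_assignments(
    observed: AnnotationSet, calls: Mapping[str, StructuralCall]
) -> AnnotationSet:
    """Rebuild the observed catalog with classifier gene assignments."""
    out = AnnotationSet()
    for t in sorted(observed, key=lambda t: t.transcript_id):
        call = calls.get(t.transcript_id)
        out.add(
            TranscriptModel(
                transcript_id=t.transcript_id,
                exons=t.exons,
                gene_id=call.assigned_gene_id if call else None,
                read_support=t.read_support,
                source=t.source,
            )
        )
    return out


def classify_catalog(
    observed: AnnotationSet,
    reference: AnnotationSet,
    junction_tolerance: int = 0,
) -> dict:
    """Classify every observed transcript; returns transcript_id -> call."""
    calls = {
        t.transcript_id: classify_transcript(t, reference, junction_tolerance)
        for t in observed
    }
    assign_novel_genes(calls, observed)
    return calls


# ---------------------------------------------------------------------------
# ORF prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ORF:
    """Longest open reading frame in transcript (mRNA) coordinates."""

    start: int  # 0-based position of the A of ATG on the spliced mRNA
    end: int  # position just past the stop codon
    aa_length: int  # peptide length, stop excluded

    @property
    def stop_position(self) -> int:
        """Spliced position of the first base of the stop codon."""
        return self.end - 3


_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """5'->3' mRNA sequence of a transcript from a genome mapping."""
    try:
        chrom_seq = genome[t.chrom]
    except KeyError:
        raise ValidationError(f"{t.transcript_id}: chrom {t.chrom} not in genome")
    seq = "".join(str(chrom_seq[e.start : e.end]) for e in t.exons)
    if len(seq) != t.exonic_length:
        raise ValidationError(
            f"{t.transcript_id}: transcript extends past contig end"
        )
    if t.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq.upper()


def predict_orf(
    t: TranscriptModel, genome: Mapping[str, str], min_aa: int = 100
) -> Optional[ORF]:
    """Longest ATG->stop ORF on the mRNA sense strand, or None.

    ``min_aa`` only affects the coding call made by callers; the longest
    complete ORF is returned regardless of its length.
    """
    seq = spliced_sequence(t, genome)
    best: Optional[ORF] = None
    for frame in range(3):
        start: Optional[int] = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                aa = (pos - start) // 3
                if best is None or aa > best.aa_length:
                    best = ORF(start=start, end=pos + 3, aa_length=aa)
                start = None
    return best


# ---------------------------------------------------------------------------
# catalog summary
# ---------------------------------------------------------------------------

def summarize_catalog(
    calls: Mapping[str, StructuralCall],
    observed: AnnotationSet,
    reference: AnnotationSet,
) -> CatalogSummary:
    """Tally a classified catalog into Table-1-style fields.

    Known transcripts are FSM only: an ISM shares all junctions with an
    annotated model but its distinct termini do not certify an annotated
    transcript, so the annotated-category tally (FSM+ISM) is reported
    separately rather than folded into the known/novel split.
    """
    summary = CatalogSummary()
    summary.n_transcripts = len(calls)
    summary.category_counts = {c: 0 for c in CATEGORIES}
    by_gene: dict = {}
    known_lengths: list = []
    novel_lengths: list = []
    for tid, call in calls.items():
        summary.category_counts[call.category] += 1
        if call.assigned_gene_id is not None:
            by_gene.setdefault(call.assigned_gene_id, []).append(tid)
        length = observed[tid].exonic_length
        if call.category == "FSM":
            known_lengths.append(length)
        else:
            novel_lengths.append(length)
            if call.category in KNOWN_GENE_CATEGORIES:
                summary.novel_from_known_genes += 1
            else:
                summary.novel_from_novel_genes += 1

    summary.n_known_transcripts = summary.category_counts["FSM"]
    summary.n_novel_transcripts = (
        summary.n_transcripts - summary.n_known_transcripts
    )
    summary.n_annotated_category = (
        summary.category_counts["FSM"] + summary.category_counts["ISM"]
    )
    annotated = {g for g in by_gene if g in reference.genes}
    summary.n_annotated_genes = len(annotated)
    summary.n_novel_genes = len(by_gene) - len(annotated)
    summary.n_genes = len(by_gene)
    summary.genes_with_multiple_isoforms = sum(
        1 for tids in by_gene.values() if len(tids) > 1
    )
    summary.genes_with_ge10_isoforms = sum(
        1 for tids in by_gene.values() if len(tids) >= 10
    )
    if known_lengths:
        summary.mean_length_known = sum(known_lengths) / len(known_lengths)
    if novel_lengths:
        summary.mean_length_novel = sum(novel_lengths) / len(novel_lengths)
    return summary


_CALL_COLUMNS = [
    "transcript_id",
    "category",
    "assigned_gene_id",
    "matched_reference_transcript",
    "n_novel_splice_sites",
    "junction_match_fraction",
    "mono_exon",
]


def calls_to_frame(calls: Mapping[str, StructuralCall]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": c.transcript_id,
            "category": c.category,
            "assigned_gene_id": c.assigned_gene_id,
            "matched_reference_transcript": c.matched_reference_transcript,
            "n_novel_splice_sites": c.n_novel_splice_sites,
            "junction_match_fraction": round(c.junction_match_fraction, 4),
            "mono_exon": c.mono_exon,
        }
        for c in calls.values()
    ]
    return (
        pd.DataFrame(rows, columns=_CALL_COLUMNS)
        .sort_values("transcript_id")
        .reset_index(drop=True)
    )
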
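"""Alternative-polyadenylation analysis.

Transcript 3' ends (TES) are clustered per gene by single linkage with
a fixed window; surviving clusters are polyadenylation sites (PAS).
Genes with >= 2 supported PASs are APA genes. For each APA gene the
span between the first and last PAS (in transcription direction) is the
UTRR; isoforms ending downstream of its midpoint are distal (M),
upstream proximal (m), and the gene is an M gene or a P gene according
to the M:m expression ratio. The PAS with the highest usage in a
condition is the major PAS (mPAS); a change of mPAS identity between
conditions is an mPAS shift. The canonical poly(A) signal is sought by
exhaustive hexamer counting in a fixed window upstream of each PAS.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import AnnotationSet, TranscriptModel, ValidationError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class PASCluster:
    gene_id: str
    representative_position: int
    member_transcript_ids: list
    member_positions: list
    read_support: int
    per_condition_usage: dict = field(default_factory=dict)
    strand: str = "+"


@dataclass
class APAGeneRecord:
    gene_id: str
    strand: str
    pas_list: list  # PASCluster, ordered 5'->3' in transcription direction
    utrr_length: int = 0
    midpoint: float = 0.0
    m_expression: dict = field(default_factory=dict)  # condition -> distal sum
    p_expression: dict = field(default_factory=dict)  # condition -> proximal sum
    mp_status: dict = field(default_factory=dict)  # condition -> M/P/tie
    mpas: dict = field(default_factory=dict)  # condition -> PAS position
    mpas_shift: Optional[bool] = None

    @property
    def n_pas(self) -> int:
        return len(self.pas_list)


# ---------------------------------------------------------------------------
# PAS clustering
# ---------------------------------------------------------------------------

def cluster_pas(
    gene_transcripts: Sequence[TranscriptModel],
    gene_id: Optional[str] = None,
    cluster_window: int = 24,
    min_support: int = 2,
) -> list:
    """Single-linkage clustering of transcript 3' ends into PASs.

    Two ends join the same cluster when they are within
    ``cluster_window`` nt of a member. Cluster support is the summed
    long-read support of its members; clusters below ``min_support``
    are discarded. The representative is the support-weighted modal end
    (ties resolved to the downstream-most position in transcription
    direction).
    """
    if gene_id is None:
        gene_id = gene_transcripts[0].gene_id or "?"
    strand = gene_transcripts[0].strand
    ends = sorted(
        ((t.tes, t) for t in gene_transcripts),
        key=lambda x: (x[0], x[1].transcript_id),
    )
    groups: list = []
    for pos, t in ends:
        if groups and pos - groups[-1][-1][0] <= cluster_window:
            groups[-1].append((pos, t))
        else:
            groups.append([(pos, t)])
    clusters = []
    for grp in groups:
        support = sum(t.read_support for _, t in grp)
        if support < min_support:
            continue
        weight = Counter()
        for pos, t in grp:
            weight[pos] += max(t.read_support, 1)
        top = max(weight.values())
        candidates = [p for p, w in weight.items() if w == top]
        rep = max(candidates) if strand == "+" else min(candidates)
        clusters.append(
            PASCluster(
                gene_id=gene_id,
                representative_position=rep,
                member_transcript_ids=[t.transcript_id for _, t in grp],
                member_positions=[p for p, _ in grp],
                read_support=support,
                strand=strand,
            )
        )
    # order 5'->3' in transcription direction
    clusters.sort(
        key=lambda c: c.representative_position, reverse=(strand == "-")
    )
    return clusters


def call_apa_genes(
    clusters_by_gene: Mapping[str, Sequence[PASCluster]],
) -> dict:
    """APA genes: >= 2 surviving PAS clusters; builds UTRR geometry."""
    records = {}
    for gid, clusters in sorted(clusters_by_gene.items()):
        if len(clusters) < 2:
            continue
        strand = clusters[0].strand
        positions = [c.representative_position for c in clusters]
        utrr = abs(positions[-1] - positions[0])
        if utrr == 0:
            continue
        midpoint = (positions[0] + positions[-1]) / 2.0
        records[gid] = APAGeneRecord(
            gene_id=gid,
            strand=strand,
            pas_list=list(clusters),
            utrr_length=utrr,
            midpoint=midpoint,
        )
    return records


# ---------------------------------------------------------------------------
# distal/proximal classification and major PAS
# ---------------------------------------------------------------------------

def _is_downstream(position: int, midpoint: float, strand: str) -> Optional[bool]:
    """True distal, False proximal, None exactly at the midpoint."""
    if position == midpoint:
        return None
    if strand == "+":
        return position > midpoint
    return position < midpoint


def classify_Mm(
    record: APAGeneRecord,
    isoform_expr: Mapping[str, Mapping[str, float]],
    conditions: Sequence[str],
) -> APAGeneRecord:
    """Distal (M) vs proximal (m) expression sums and M/P gene status.

    ``isoform_expr`` maps condition -> transcript id -> expression.
    Isoforms whose PAS sits exactly on the midpoint are excluded from
    both sums. Status is M when M/m > 1, P when < 1, tie when equal.
    """
    tx_side: dict = {}
    for cluster in record.pas_list:
        side = _is_downstream(
            cluster.representative_position, record.midpoint, record.strand
        )
        for tid in cluster.member_transcript_ids:
            tx_side[tid] = side
    for cond in conditions:
        expr = isoform_expr.get(cond, {})
        m_sum = sum(
            expr.get(tid, 0.0) for tid, side in tx_side.items() if side is True
        )
        p_sum = sum(
            expr.get(tid, 0.0) for tid, side in tx_side.items() if side is False
        )
        record.m_expression[cond] = m_sum
        record.p_expression[cond] = p_sum
        if m_sum > p_sum:
            record.mp_status[cond] = "M"
        elif m_sum < p_sum:
            record.mp_status[cond] = "P"
        else:
            record.mp_status[cond] = "tie"
    return record


def call_mpas(
    record: APAGeneRecord,
    usage_by_condition: Mapping[str, Mapping[int, float]],
    conditions: Sequence[str],
) -> APAGeneRecord:
    """Major PAS per condition (highest usage; ties go downstream).

    ``usage_by_condition`` maps condition -> PAS representative
    position -> usage weight (long-read support or expression). A
    condition with zero total usage gets no mPAS and the shift flag
    stays undefined.
    """
    for cond in conditions:
        usage = usage_by_condition.get(cond, {})
        weights = {
            c.representative_position: usage.get(c.representative_position, 0.0)
            for c in record.pas_list
        }
        total = sum(weights.values())
        if total <= 0:
            record.mpas[cond] = None
            continue
        top = max(weights.values())
        candidates = [p for p, w in weights.items() if w == top]
        record.mpas[cond] = (
            max(candidates) if record.strand == "+" else min(candidates)
        )
    m1, m2 = (record.mpas.get(c) for c in conditions[:2])
    record.mpas_shift = None if (m1 is None or m2 is None) else (m1 != m2)
    return record


# ---------------------------------------------------------------------------
# poly(A)-signal hexamer scan
# ---------------------------------------------------------------------------

def scan_pas_signal(
    genome: Mapping[str, str],
    clusters: Iterable[PASCluster],
    chrom_of_gene: Mapping[str, str],
    window_up: int = 50,
) -> pd.DataFrame:
    """Count all overlapping hexamers in the window upstream of each PAS.

    The window is taken on the mRNA sense strand (reverse complement on
    '-'); windows truncated at a contig edge are flagged. Returns a
    frequency table sorted by count with AATAAA's rank recoverable from
    the row order.
    """
    counts: Counter = Counter()
    truncated = 0
    for cluster in clusters:
        chrom = chrom_of_gene[cluster.gene_id]
        seq = str(genome[chrom])
        pos = cluster.representative_position
        if cluster.strand == "+":
            lo, hi = max(0, pos - window_up), pos
            window = seq[lo:hi]
            if pos - window_up < 0:
                truncated += 1
        else:
            lo, hi = pos, min(len(seq), pos + window_up)
            window = seq[lo:hi].translate(_COMPLEMENT)[::-1]
            if pos + window_up > len(seq):
                truncated += 1
        window = window.upper()
        for i in range(len(window) - 5):
            counts[window[i : i + 6]] += 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["hexamer", "count"])
    df.attrs["n_truncated_windows"] = truncated
    return df


def hexamer_rank(table: pd.DataFrame, motif: str = "AATAAA") -> Optional[int]:
    """1-based rank of a motif in the hexamer table (None if absent)."""
    hits = table.index[table["hexamer"] == motif]
    return int(hits[0]) + 1 if len(hits) else None


# ---------------------------------------------------------------------------
# 3'-UTR lengths
# ---------------------------------------------------------------------------

def utr3_length(
    t: TranscriptModel,
    stop_spliced_position: int,
) -> int:
    """3'-UTR length: spliced distance from the end of the stop codon to the 3' end."""
    length = t.exonic_length - stop_spliced_position
    if length < 0:
        raise ValidationError(
            f"{t.transcript_id}: PAS upstream of stop codon "
            f"(stop at {stop_spliced_position}, length {t.exonic_length})"
        )
    return length


def utr3_length_distribution(
    transcripts: Iterable[TranscriptModel],
    stop_positions: Mapping[str, int],
    bin_width: int = 100,
):
    """Histogram of 3'-UTR lengths; transcripts without an ORF are counted out.

    ``stop_positions`` maps transcript id to the spliced position just
    past the stop codon (``ORF.end``). Returns (histogram DataFrame,
    n_excluded, modal_bin_start).
    """
    lengths = []
    excluded = 0
    for t in transcripts:
        stop = stop_positions.get(t.transcript_id)
        if stop is None:
            excluded += 1
            continue
        try:
            lengths.append(utr3_length(t, stop))
        except ValidationError:
            excluded += 1
    if not lengths:
        return pd.DataFrame(columns=["bin_start", "count"]), excluded, None
    bins: Counter = Counter((length // bin_width) * bin_width for length in lengths)
    df = pd.DataFrame(
        sorted(bins.items()), columns=["bin_start", "count"]
    )
    modal = int(df.loc[df["count"].idxmax(), "bin_start"])
    return df, excluded, modal


# ---------------------------------------------------------------------------
# whole-catalog driver
# ---------------------------------------------------------------------------

def analyze_apa(
    catalog: AnnotationSet,
    isoform_expr: Mapping[str, Mapping[str, float]],
    conditions: Sequence[str],
    cluster_window: int = 24,
    min_support: int = 2,
    usage_by_expression: bool = False,
    support_by_condition: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> dict:
    """Cluster, call APA genes, and fill M/P status and mPAS per gene.

    ``isoform_expr``: condition -> transcript id -> FPKM. mPAS usage is
    per-condition long-read support (``support_by_condition``:
    condition -> transcript id -> reads) when available, matching how
    stage-pooled long-read libraries are counted; with
    ``usage_by_expression`` (or when no per-condition support exists)
    usage is the isoform expression instead.
    """
    clusters_by_gene = {}
    for gid in sorted(catalog.genes):
        ts = catalog.gene_transcripts(gid)
        clusters = cluster_pas(
            ts, gid, cluster_window=cluster_window, min_support=min_support
        )
        if clusters:
            clusters_by_gene[gid] = clusters
    records = call_apa_genes(clusters_by_gene)
    use_expr = usage_by_expression or support_by_condition is None
    for gid, record in records.items():
        classify_Mm(record, isoform_expr, conditions)
        usage = {}
        for cond in conditions:
            if use_expr:
                weights = isoform_expr.get(cond, {})
            else:
                weights = support_by_condition.get(cond, {})
            per_pas = {}
            for cluster in record.pas_list:
                w = sum(
                    float(weights.get(tid, 0.0))
                    for tid in cluster.member_transcript_ids
                )
                per_pas[cluster.representative_position] = w
                cluster.per_condition_usage[cond] = w
            usage[cond] = per_pas
        call_mpas(record, usage, conditions)
    return records
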
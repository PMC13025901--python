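"""Shared genomic data model.

All internal coordinates are 0-based, half-open ``[start, end)``. The
1-based inclusive convention of GTF/GFF3 exists only inside the I/O
functions in :mod:`isodiv.annotation_io`. Strand-aware quantities (TSS,
TES, intron chain order) are derived, never stored, so a transcript can
never carry inconsistent termini.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-")
SOURCES = ("reference", "observed", "assembled")


class ValidationError(ValueError):
    """Raised when a record violates a data-model invariant."""


class ParseError(ValueError):
    """Raised on malformed input files; message names the offending line."""


class DesignError(ValueError):
    """Raised when an expression table and its sample design disagree."""


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent configuration."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval on one strand of one sequence."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered, strand-aware exon chain.

    ``exons`` are ascending by coordinate regardless of strand; the
    biological 5'->3' order is recovered via ``strand``. ``read_support``
    is the number of full-length long reads collapsed into this model
    (0 for reference/assembled records).
    """

    transcript_id: str
    exons: tuple
    gene_id: Optional[str] = None
    read_support: int = 0
    source: str = "observed"

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"{self.transcript_id}: exons span multiple chroms/strands"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
            if b.start == a.end:
                raise ValidationError(
                    f"{self.transcript_id}: zero-length intron between "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        if self.read_support < 0:
            raise ValidationError(f"{self.transcript_id}: negative read_support")
        if self.source not in SOURCES:
            raise ValidationError(f"{self.transcript_id}: bad source {self.source!r}")

    # -- derived geometry ------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_mono_exon(self) -> bool:
        return len(self.exons) == 1

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def intron_chain(self) -> tuple:
        """Ordered (donor, acceptor) coordinate pairs in genomic order.

        Each pair is the half-open intron ``[end_of_left_exon,
        start_of_right_exon)``. Empty for mono-exon transcripts.
        """
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def splice_sites(self) -> frozenset:
        """All internal exon boundaries (donor and acceptor coordinates)."""
        sites = set()
        for d, a in self.intron_chain:
            sites.add(d)
            sites.add(a)
        return frozenset(sites)

    @property
    def tss(self) -> int:
        """Biological 5' terminus (min coordinate on +, max on -)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Biological 3' terminus (max coordinate on +, min on -)."""
        return self.end if self.strand == "+" else self.start

    def spliced_position(self, genomic: int) -> int:
        """Map a genomic coordinate to its 5'->3' position on the mRNA."""
        offset = 0
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        for e in exons:
            if e.start <= genomic <= e.end:
                if self.strand == "+":
                    return offset + (genomic - e.start)
                return offset + (e.end - genomic)
            offset += len(e)
        raise ValidationError(
            f"{self.transcript_id}: position {genomic} is not exonic"
        )


class AnnotationSet:
    """A collection of transcripts with a gene-level interval index."""

    def __init__(self, transcripts: Sequence[TranscriptModel] = ()) -> None:
        self.transcripts: dict = {}
        self.genes: dict = {}
        self._tree: dict = {}
        self._dirty = True
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValidationError(f"duplicate transcript_id {t.transcript_id!r}")
        self.transcripts[t.transcript_id] = t
        if t.gene_id is not None:
            self.genes.setdefault(t.gene_id, []).append(t.transcript_id)
        self._dirty = True

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def gene_transcripts(self, gene_id: str) -> list:
        return [self.transcripts[tid] for tid in self.genes[gene_id]]

    def gene_span(self, gene_id: str):
        """(chrom, start, end, strand) covering all transcripts of the gene."""
        ts = self.gene_transcripts(gene_id)
        return (
            ts[0].chrom,
            min(t.start for t in ts),
            max(t.end for t in ts),
            ts[0].strand,
        )

    def _rebuild_index(self) -> None:
        self._tree = {}
        for gid in self.genes:
            chrom, start, end, strand = self.gene_span(gid)
            self._tree.setdefault(chrom, IntervalTree()).addi(
                start, end, (gid, strand)
            )
        self._dirty = False

    def genes_overlapping(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> list:
        """Gene ids whose span overlaps [start, end), optionally one strand."""
        if self._dirty:
            self._rebuild_index()
        tree = self._tree.get(chrom)
        if tree is None:
            return []
        hits = [
            iv.data[0]
            for iv in tree.overlap(start, end)
            if strand is None or iv.data[1] == strand
        ]
        return sorted(set(hits))


@dataclass
class ExpressionMatrix:
    """Features x samples table with a two-condition replicate design.

    ``unit`` tags the scale ('counts', 'cpm' or 'fpkm'); operations that
    require a particular unit check the tag rather than guessing.
    """

    values: "pandas.DataFrame"  # noqa: F821 - imported lazily by callers
    design: Mapping[str, str]
    unit: str = "counts"
    feature_lengths: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        import pandas as pd

        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if (self.values.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
        missing = [s for s in self.values.columns if s not in self.design]
        if missing:
            raise DesignError(f"samples absent from design: {missing}")
        conditions = sorted(set(self.design[s] for s in self.values.columns))
        if len(conditions) != 2:
            raise DesignError(
                f"design must have exactly two conditions, got {conditions}"
            )

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def conditions(self) -> list:
        return sorted(set(self.design[s] for s in self.values.columns))

    def condition_samples(self, condition: str) -> list:
        return [s for s in self.values.columns if self.design[s] == condition]

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)],
            dict(self.design),
            unit=self.unit,
            feature_lengths=self.feature_lengths,
        )

    def condition_means(self, condition: str) -> "pandas.Series":  # noqa: F821
        return self.values[self.condition_samples(condition)].mean(axis=1)
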
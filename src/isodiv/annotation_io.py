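"""Reading and writing annotations and expression tables.

GTF/GFF3 parsing is delegated to :mod:`gffutils` (in-memory database);
this module only converts between the file convention (1-based,
inclusive) and the internal 0-based half-open convention, and groups
exons into :class:`~isodiv.model.TranscriptModel` records. BED12
observed catalogs are decoded from blockStarts/blockSizes directly.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional

import gffutils
import pandas as pd
import yaml

from .model import (
    AnnotationSet,
    DesignError,
    ExpressionMatrix,
    GenomicInterval,
    ParseError,
    TranscriptModel,
    ValidationError,
)

__all__ = [
    "read_annotation",
    "read_bed12",
    "write_annotation",
    "read_expression",
    "load_design",
    "compute_cpm",
    "compute_fpkm",
]


def _prevalidate_gtf(path: str) -> None:
    """Cheap structural scan so parse errors can name the line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 8 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[3]!r}, {fields[4]!r}"
                ) from None
            if start > end or start < 1:
                raise ParseError(
                    f"{path}:{lineno}: invalid coordinate range {start}-{end}"
                )
            if fields[6] not in ("+", "-", "."):
                raise ParseError(f"{path}:{lineno}: invalid strand {fields[6]!r}")


def _feature_transcript_id(feat, tx2gene: dict) -> Optional[str]:
    if "transcript_id" in feat.attributes:
        return feat.attributes["transcript_id"][0]
    if "Parent" in feat.attributes:  # GFF3 exon -> parent mRNA/transcript
        return feat.attributes["Parent"][0]
    return None


def read_annotation(path: str, source_tag: str = "reference") -> AnnotationSet:
    """Read a GTF or GFF3 file into an :class:`AnnotationSet`.

    File coordinates (1-based inclusive) become 0-based half-open.
    ``gene_id`` is optional for observed models; read support is taken
    from a ``read_support`` attribute when present.
    """
    _prevalidate_gtf(path)
    with open(path) as fh:
        has_features = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_features:
        return AnnotationSet()
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # GFF3: transcript-level features carry the gene assignment via Parent.
    tx2gene: dict = {}
    tx_support: dict = {}
    for ftype in ("transcript", "mRNA"):
        for feat in db.features_of_type(ftype):
            tid = (
                feat.attributes["transcript_id"][0]
                if "transcript_id" in feat.attributes
                else feat.id
            )
            if "gene_id" in feat.attributes:
                tx2gene[tid] = feat.attributes["gene_id"][0]
            elif "Parent" in feat.attributes:
                tx2gene[tid] = feat.attributes["Parent"][0]
            if "read_support" in feat.attributes:
                tx_support[tid] = int(feat.attributes["read_support"][0])

    exons_by_tx: dict = {}
    for feat in db.features_of_type("exon"):
        tid = _feature_transcript_id(feat, tx2gene)
        if tid is None:
            raise ParseError(
                f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} "
                "has no transcript_id/Parent"
            )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        exons_by_tx.setdefault(tid, []).append(iv)
        if "gene_id" in feat.attributes and tid not in tx2gene:
            tx2gene[tid] = feat.attributes["gene_id"][0]
        if "read_support" in feat.attributes and tid not in tx_support:
            tx_support[tid] = int(feat.attributes["read_support"][0])

    annotation = AnnotationSet()
    for tid in exons_by_tx:
        annotation.add(
            TranscriptModel(
                transcript_id=tid,
                exons=tuple(exons_by_tx[tid]),
                gene_id=tx2gene.get(tid),
                read_support=tx_support.get(tid, 0),
                source=source_tag,
            )
        )
    return annotation


def read_bed12(path: str, source_tag: str = "observed") -> AnnotationSet:
    """Read observed transcript models from BED12 (blockStarts/blockSizes)."""
    annotation = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}:{lineno}: BED12 requires 12 fields, got {len(fields)}"
                )
            chrom, start, name = fields[0], int(fields[1]), fields[3]
            strand = fields[5]
            score = fields[4]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(starts, sizes)
            )
            support = int(float(score)) if score not in (".", "") else 0
            annotation.add(
                TranscriptModel(
                    transcript_id=name,
                    exons=exons,
                    read_support=support,
                    source=source_tag,
                )
            )
    return annotation


def write_annotation(annotation: AnnotationSet, path: str) -> None:
    """Write an AnnotationSet as GTF with a fixed deterministic ordering.

    Round-trip contract: ``read_annotation(write_annotation(A))``
    reproduces every exon chain, id and read support exactly.
    """
    records = sorted(
        annotation,
        key=lambda t: (t.chrom, t.start, t.transcript_id),
    )
    with open(path, "w") as fh:
        fh.write("##gtf produced by isodiv\n")
        for t in records:
            attrs = f'transcript_id "{t.transcript_id}";'
            if t.gene_id is not None:
                attrs = f'gene_id "{t.gene_id}"; ' + attrs
            if t.read_support:
                attrs += f' read_support "{t.read_support}";'
            fh.write(
                f"{t.chrom}\tisodiv\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\tisodiv\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def read_expression(path: str, design: Mapping[str, str]) -> ExpressionMatrix:
    """Read a TSV count table (feature id column + one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate feature ids {dupes[:5]}")
    return ExpressionMatrix(df, dict(design), unit="counts")


def load_design(path: str) -> dict:
    """Load a YAML sample -> condition mapping."""
    with open(path) as fh:
        design = yaml.safe_load(fh)
    if not isinstance(design, dict):
        raise DesignError(f"{path}: design file must map sample -> condition")
    return {str(k): str(v) for k, v in design.items()}


def compute_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: ``count / library_size * 1e6`` per sample."""
    if m.unit != "counts":
        raise ValidationError(f"compute_cpm requires counts, got {m.unit}")
    libsizes = m.values.sum(axis=0)
    zero = libsizes[libsizes == 0].index.tolist()
    if zero:
        raise ValidationError(f"zero library size for samples: {zero}")
    cpm = m.values.div(libsizes, axis=1) * 1e6
    return ExpressionMatrix(
        cpm, dict(m.design), unit="cpm", feature_lengths=m.feature_lengths
    )


def compute_fpkm(m: ExpressionMatrix) -> ExpressionMatrix:
    """FPKM: ``count * 1e9 / (library_size * feature_length_bp)``.

    Feature length is the annotated exonic (spliced) length.
    """
    if m.unit != "counts":
        raise ValidationError(f"compute_fpkm requires counts, got {m.unit}")
    if m.feature_lengths is None:
        raise ValidationError("compute_fpkm requires feature_lengths")
    missing = [f for f in m.feature_ids if f not in m.feature_lengths]
    if missing:
        raise ValidationError(f"missing feature lengths: {missing[:5]}")
    lengths = pd.Series({f: m.feature_lengths[f] for f in m.feature_ids})
    if (lengths <= 0).any():
        bad = lengths[lengths <= 0].index.tolist()
        raise ValidationError(f"non-positive feature lengths: {bad[:5]}")
    libsizes = m.values.sum(axis=0)
    zero = libsizes[libsizes == 0].index.tolist()
    if zero:
        raise ValidationError(f"zero library size for samples: {zero}")
    fpkm = m.values.mul(1e9).div(libsizes, axis=1).div(lengths, axis=0)
    return ExpressionMatrix(
        fpkm, dict(m.design), unit="fpkm", feature_lengths=m.feature_lengths
    )
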
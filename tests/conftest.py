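import pytest

from isodiv.model import AnnotationSet, GenomicInterval, TranscriptModel


def make_tx(tid, exons, strand="+", chrom="chr1", gene=None, support=0, source="observed"):
    return TranscriptModel(
        transcript_id=tid,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        gene_id=gene,
        read_support=support,
        source=source,
    )


@pytest.fixture
def toy_reference():
    """One 3-exon gene (g1, + strand) and one 2-exon gene on '-'."""
    return AnnotationSet(
        [
            make_tx("r1", [(100, 200), (300, 400), (500, 600)], gene="g1",
                    source="reference"),
            make_tx("r2", [(100, 200), (500, 600)], gene="g1",
                    source="reference"),
            make_tx("r3", [(2000, 2150), (2300, 2400)], strand="-", gene="g2",
                    source="reference"),
        ]
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic bundle shared across pipeline tests."""
    from isodiv.synthetic_data import SimConfig, simulate_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    objects = simulate_bundle(
        SimConfig(n_genes=60, n_observed=240, rng_seed=42), str(outdir)
    )
    objects["dir"] = str(outdir)
    return objects
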
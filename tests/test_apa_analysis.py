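import numpy as np
import pytest

from isodiv.apa_analysis import (
    APAGeneRecord,
    PASCluster,
    call_apa_genes,
    call_mpas,
    classify_Mm,
    cluster_pas,
    hexamer_rank,
    scan_pas_signal,
    utr3_length,
    utr3_length_distribution,
)
from isodiv.model import ValidationError
from conftest import make_tx


def _mono(tid, end, strand="+", support=1):
    if strand == "+":
        return make_tx(tid, [(max(0, end - 50), end)], support=support)
    return make_tx(tid, [(end, end + 50)], strand=strand, support=support)


class TestClustering:
    def test_linkage_window_splits_distant_ends(self):
        ts = [_mono("a", 100), _mono("b", 105), _mono("c", 130)]
        clusters = cluster_pas(ts, "g", cluster_window=24, min_support=1)
        assert [sorted(c.member_positions) for c in clusters] == [[100, 105], [130]]

    def test_all_ends_within_window_form_one_cluster(self):
        ts = [_mono("a", 100), _mono("b", 110), _mono("c", 120)]
        assert len(cluster_pas(ts, "g", min_support=1)) == 1

    def test_min_support_discards_weak_clusters(self):
        ts = [_mono("a", 100, support=1), _mono("b", 500, support=5)]
        clusters = cluster_pas(ts, "g", min_support=2)
        assert [c.representative_position for c in clusters] == [500]

    def test_raising_min_support_never_increases_pas_count(self):
        rng = np.random.default_rng(0)
        ts = [
            _mono(f"t{i}", int(rng.integers(100, 2000)), support=int(rng.integers(1, 5)))
            for i in range(30)
        ]
        previous = None
        for ms in (1, 2, 3, 5, 8):
            n = len(cluster_pas(ts, "g", min_support=ms))
            if previous is not None:
                assert n <= previous
            previous = n

    def test_every_transcript_in_exactly_one_cluster(self):
        rng = np.random.default_rng(1)
        ts = [
            _mono(f"t{i}", int(rng.integers(100, 1500)), support=2)
            for i in range(25)
        ]
        clusters = cluster_pas(ts, "g", min_support=1)
        members = [tid for c in clusters for tid in c.member_transcript_ids]
        assert sorted(members) == sorted(t.transcript_id for t in ts)
        assert sum(c.read_support for c in clusters) == sum(
            t.read_support for t in ts
        )

    def test_representative_is_support_weighted_mode(self):
        ts = [
            _mono("a", 100, support=1),
            _mono("b", 104, support=5),
            _mono("c", 104, support=1),
        ]
        clusters = cluster_pas(ts, "g", min_support=1)
        assert clusters[0].representative_position == 104


def _record(positions, strand="+"):
    clusters = [
        PASCluster(
            gene_id="g",
            representative_position=p,
            member_transcript_ids=[f"t{p}"],
            member_positions=[p],
            read_support=5,
            strand=strand,
        )
        for p in positions
    ]
    records = call_apa_genes({"g": clusters})
    return records.get("g")


class TestAPAGeometry:
    def test_single_cluster_is_not_apa(self):
        assert _record([100]) is None

    def test_two_clusters_make_an_apa_gene(self):
        rec = _record([100, 400])
        assert rec.n_pas == 2
        assert rec.utrr_length == 300
        assert rec.midpoint == 250.0

    def test_mm_classification_plus_strand(self):
        rec = _record([100, 400])
        expr = {"c1": {"t100": 10.0, "t400": 30.0}}
        classify_Mm(rec, expr, ["c1"])
        assert rec.m_expression["c1"] == 30.0
        assert rec.p_expression["c1"] == 10.0
        assert rec.mp_status["c1"] == "M"

    def test_mm_classification_strand_symmetric(self):
        rec = _record([400, 100], strand="-")  # transcription order 5'->3'
        expr = {"c1": {"t100": 30.0, "t400": 10.0}}  # distal = lower coord
        classify_Mm(rec, expr, ["c1"])
        assert rec.mp_status["c1"] == "M"

    def test_zero_proximal_expression_is_m_gene(self):
        rec = _record([100, 400])
        classify_Mm(rec, {"c1": {"t100": 0.0, "t400": 5.0}}, ["c1"])
        assert rec.mp_status["c1"] == "M"


class TestMajorPAS:
    def test_usage_switch_flags_shift(self):
        rec = _record([100, 400])
        usage = {"c1": {100: 10.0, 400: 2.0}, "c2": {100: 1.0, 400: 9.0}}
        call_mpas(rec, usage, ["c1", "c2"])
        assert rec.mpas == {"c1": 100, "c2": 400}
        assert rec.mpas_shift is True

    def test_stable_usage_is_not_a_shift(self):
        rec = _record([100, 400])
        usage = {"c1": {100: 10.0, 400: 2.0}, "c2": {100: 8.0, 400: 2.0}}
        call_mpas(rec, usage, ["c1", "c2"])
        assert rec.mpas_shift is False

    def test_zero_usage_leaves_shift_undefined(self):
        rec = _record([100, 400])
        usage = {"c1": {100: 10.0, 400: 2.0}, "c2": {}}
        call_mpas(rec, usage, ["c1", "c2"])
        assert rec.mpas["c2"] is None and rec.mpas_shift is None


class TestSignalScan:
    def _cluster(self, pos, strand="+"):
        return PASCluster(
            gene_id="g",
            representative_position=pos,
            member_transcript_ids=["t"],
            member_positions=[pos],
            read_support=3,
            strand=strand,
        )

    def test_planted_hexamer_counted(self):
        seq = "C" * 80 + "AATAAA" + "C" * 20
        genome = {"chr1": seq}
        table = scan_pas_signal(genome, [self._cluster(106)], {"g": "chr1"})
        row = table[table["hexamer"] == "AATAAA"]
        assert int(row["count"].iloc[0]) == 1

    def test_all_c_window_has_no_a_hexamers(self):
        genome = {"chr1": "C" * 200}
        table = scan_pas_signal(genome, [self._cluster(150)], {"g": "chr1"})
        assert set(table["hexamer"]) == {"CCCCCC"}

    def test_minus_strand_scans_reverse_complement(self):
        # sense-strand AATAAA upstream of a '-' PAS is genomic TTTATT after it
        seq = "G" * 100 + "TTTATT" + "G" * 50
        genome = {"chr1": seq}
        table = scan_pas_signal(
            genome, [self._cluster(80, strand="-")], {"g": "chr1"}
        )
        row = table[table["hexamer"] == "AATAAA"]
        assert int(row["count"].iloc[0]) == 1

    def test_rank_helper(self):
        import pandas as pd

        table = pd.DataFrame(
            {"hexamer": ["TTTTTT", "AATAAA"], "count": [9, 5]}
        )
        assert hexamer_rank(table) == 2
        assert hexamer_rank(table, "ACGTAC") is None


class TestUTRLengths:
    def test_stop_to_pas_distance(self):
        t = make_tx("t", [(0, 1150)])
        assert utr3_length(t, 900) == 250

    def test_pas_upstream_of_stop_rejected(self):
        t = make_tx("t", [(0, 500)])
        with pytest.raises(ValidationError):
            utr3_length(t, 900)

    def test_histogram_mode_matches_planted_lengths(self):
        ts = [make_tx(f"t{i}", [(0, 1000 + i)]) for i in range(20)]
        stops = {f"t{i}": 1000 + i - 250 for i in range(20)}
        hist, excluded, mode = utr3_length_distribution(ts, stops)
        assert excluded == 0
        assert mode == 200

    def test_transcripts_without_orf_are_counted_out(self):
        ts = [make_tx("a", [(0, 1000)]), make_tx("b", [(0, 1000)])]
        hist, excluded, mode = utr3_length_distribution(ts, {"a": 700})
        assert excluded == 1
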
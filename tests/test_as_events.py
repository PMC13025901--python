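import numpy as np
import pytest

from isodiv.as_events import (
    correlate_diversity,
    decompose_pair,
    detect_events,
    profile_genes,
)
from isodiv.model import AnnotationSet, ValidationError
from conftest import make_tx
from oracle_as import oracle_pair_events


def _keys(events):
    return {
        (e.event_type, e.anchor_left, e.anchor_right, e.region_start, e.region_end)
        for e in events
    }


class TestCanonicalEvents:
    def test_skipped_exon(self):
        a = make_tx("a", [(0, 100), (200, 300), (400, 500)])
        b = make_tx("b", [(0, 100), (400, 500)])
        events = detect_events([a, b], "g")
        assert _keys(events) == {("ES", 100, 400, 200, 300)}

    def test_retained_intron_with_mono_exon_form(self):
        a = make_tx("a", [(0, 100), (200, 300)])
        b = make_tx("b", [(0, 300)])
        events = detect_events([a, b], "g")
        assert _keys(events) == {("IR", 100, 200, 100, 200)}
        ir = events[0]
        assert ir.inclusion_form_id == "b"  # the retaining form

    def test_retained_intron_between_multi_exon_forms(self):
        a = make_tx("a", [(0, 100), (200, 300), (400, 500), (600, 700)])
        b = make_tx("b", [(0, 100), (200, 500), (600, 700)])
        events = detect_events([a, b], "g")
        assert _keys(events) == {("IR", 300, 400, 300, 400)}

    def test_alternative_donor_is_a5ss_on_plus(self):
        a = make_tx("a", [(0, 100), (200, 300)])
        b = make_tx("b", [(0, 120), (200, 300)])
        events = detect_events([a, b], "g")
        assert _keys(events) == {("A5SS", 0, 200, 100, 120)}

    def test_alternative_acceptor_is_a3ss_on_plus(self):
        a = make_tx("a", [(0, 100), (200, 300)])
        b = make_tx("b", [(0, 100), (220, 300)])
        events = detect_events([a, b], "g")
        assert _keys(events) == {("A3SS", 100, 300, 200, 220)}

    def test_mutually_exclusive_exons(self):
        a = make_tx("a", [(0, 100), (200, 250), (400, 500)])
        b = make_tx("b", [(0, 100), (300, 350), (400, 500)])
        events = detect_events([a, b], "g")
        assert _keys(events) == {("MEE", 100, 400, 200, 350)}

    def test_terminus_jitter_creates_no_events(self):
        a = make_tx("a", [(0, 100), (200, 300)])
        b = make_tx("b", [(20, 100), (200, 350)])
        assert detect_events([a, b], "g") == []

    def test_mixed_strands_rejected(self):
        a = make_tx("a", [(0, 100), (200, 300)])
        b = make_tx("b", [(0, 100), (200, 300)], strand="-")
        with pytest.raises(ValidationError):
            detect_events([a, b], "g")


class TestStrandSemantics:
    def _donor_variant_events(self, strand):
        a = make_tx("a", [(0, 100), (200, 300)], strand=strand)
        b = make_tx("b", [(0, 120), (200, 300)], strand=strand)
        return detect_events([a, b], "g")

    def test_flipping_strand_label_swaps_a5ss_a3ss(self):
        plus = self._donor_variant_events("+")
        minus = self._donor_variant_events("-")
        assert [e.event_type for e in plus] == ["A5SS"]
        assert [e.event_type for e in minus] == ["A3SS"]

    def test_true_mirror_preserves_labels(self):
        C = 1000
        a = make_tx("a", [(0, 100), (200, 300)])
        b = make_tx("b", [(0, 120), (200, 300)])
        am = make_tx("a", [(C - 100, C), (C - 300, C - 200)], strand="-")
        bm = make_tx("b", [(C - 120, C), (C - 300, C - 200)], strand="-")
        assert [e.event_type for e in detect_events([a, b], "g")] == [
            e.event_type for e in detect_events([am, bm], "g")
        ]

    @pytest.mark.parametrize("etype", ["ES", "IR", "MEE"])
    def test_es_ir_mee_are_strand_invariant(self, etype):
        chains = {
            "ES": ([(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]),
            "IR": ([(0, 100), (200, 300)], [(0, 300)]),
            "MEE": (
                [(0, 100), (200, 250), (400, 500)],
                [(0, 100), (300, 350), (400, 500)],
            ),
        }
        ca, cb = chains[etype]
        for strand in "+-":
            a = make_tx("a", ca, strand=strand)
            b = make_tx("b", cb, strand=strand)
            assert [e.event_type for e in detect_events([a, b], "g")] == [etype]


class TestOracleEquivalence:
    def _random_chain(self, rng, max_exons=6):
        """Random exon chain on a coarse coordinate grid."""
        n_slots = 12
        n_exons = int(rng.integers(1, max_exons + 1))
        starts = sorted(rng.choice(n_slots, size=n_exons, replace=False))
        chain = []
        for s in starts:
            lo = s * 50
            hi = lo + int(rng.integers(1, 4)) * 10
            if chain and lo <= chain[-1][1]:
                lo = chain[-1][1] + 10
                hi = lo + 20
            chain.append((lo, hi))
        return chain

    def test_pairwise_decomposition_equals_base_level_oracle(self):
        rng = np.random.default_rng(2024)
        for trial in range(400):
            strand = "+" if trial % 2 == 0 else "-"
            ca = self._random_chain(rng)
            cb = self._random_chain(rng)
            a = make_tx("a", ca, strand=strand)
            b = make_tx("b", cb, strand=strand)
            got = _keys(decompose_pair(a, b, "g"))
            expected = oracle_pair_events(ca, cb, strand)
            assert got == expected, (ca, cb, strand)

    def test_event_multiset_independent_of_input_order(self):
        a = make_tx("a", [(0, 100), (200, 300), (400, 500)])
        b = make_tx("b", [(0, 100), (400, 500)])
        c = make_tx("c", [(0, 100), (200, 300), (400, 550)])
        fwd = _keys(detect_events([a, b, c], "g"))
        rev = _keys(detect_events([c, b, a], "g"))
        assert fwd == rev


class TestProfiles:
    def test_zero_events_give_empty_profiles(self):
        cat = AnnotationSet([make_tx("a", [(0, 100)], gene="g")])
        profiles, summary = profile_genes([], cat)
        assert profiles == []
        assert np.isnan(summary["type_proportions"]["ES"])

    def test_single_es_gene_profile(self):
        a = make_tx("a", [(0, 100), (200, 300), (400, 500)], gene="g")
        b = make_tx("b", [(0, 100), (400, 500)], gene="g")
        cat = AnnotationSet([a, b])
        events = detect_events([a, b], "g")
        profiles, summary = profile_genes(events, cat)
        assert profiles[0].pattern_set == frozenset({"ES"})
        assert summary["type_proportions"]["ES"] == 1.0

    def test_planted_mix_recovered_within_tolerance(self, small_bundle):
        truth = small_bundle["truth"]
        planted = {}
        for gt in truth.genes.values():
            for ev in gt.events:
                planted[ev.event_type] = planted.get(ev.event_type, 0) + 1
        assert sum(planted.values()) > 20


class TestCorrelations:
    def test_constant_transcript_count_gives_nan(self):
        cat = AnnotationSet(
            [
                make_tx(f"t{i}", [(i * 1000, i * 1000 + 100), (i * 1000 + 200, i * 1000 + 300)], gene=f"g{i}")
                for i in range(5)
            ]
        )
        report = correlate_diversity(cat)
        assert np.isnan(report.r_transcripts_vs_exons)

    def test_planted_linear_relation_gives_r_one(self):
        ts = []
        for i in range(6):
            n_exons = i + 2
            exons = [(i * 10_000 + k * 200, i * 10_000 + k * 200 + 100) for k in range(n_exons)]
            for j in range(i + 1):
                shift = [(s, e) for s, e in exons]
                ts.append(make_tx(f"g{i}_t{j}", shift[: n_exons - (0)], gene=f"g{i}"))
        # make ids unique per gene; transcripts per gene = i+1, exons = i+2
        cat = AnnotationSet(ts)
        report = correlate_diversity(cat)
        assert report.r_transcripts_vs_exons == pytest.approx(1.0)

    def test_positive_dependence_detected(self, small_bundle):
        cat = small_bundle["observed"]
        from isodiv.catalog_classify import classify_catalog, apply_gene_assignments

        calls = classify_catalog(cat, small_bundle["reference"])
        assigned = apply_gene_assignments(cat, calls)
        report = correlate_diversity(assigned)
        assert report.n_all >= 3
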
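import itertools

import pytest

from isodiv.catalog_classify import (
    CATEGORIES,
    AlignmentSummary,
    classify_catalog,
    classify_transcript,
    filter_alignments,
    predict_orf,
    spliced_sequence,
    summarize_catalog,
)
from isodiv.model import AnnotationSet, GenomicInterval, TranscriptModel
from conftest import make_tx


class TestAlignmentFilter:
    def test_identity_below_threshold_removed(self):
        rec = AlignmentSummary("t", identity=0.89, coverage=0.99)
        assert filter_alignments([rec]) == set()

    def test_exact_boundary_retained(self):
        rec = AlignmentSummary("t", identity=0.9, coverage=0.85)
        assert filter_alignments([rec]) == {"t"}

    def test_five_prime_duplicates_merge_to_longest(self):
        recs = [
            AlignmentSummary("short", 0.99, 0.99, length=950, tss_equivalence_group="g"),
            AlignmentSummary("long", 0.99, 0.99, length=1000, tss_equivalence_group="g"),
        ]
        assert filter_alignments(recs) == {"long"}

    def test_empty_input_gives_empty_output(self):
        assert filter_alignments([]) == set()


class TestClassificationCascade:
    def test_exact_chain_is_fsm(self, toy_reference):
        t = make_tx("o", [(90, 200), (300, 400), (500, 650)])
        call = classify_transcript(t, toy_reference)
        assert call.category == "FSM"
        assert call.matched_reference_transcript == "r1"

    def test_truncated_chain_is_ism(self, toy_reference):
        t = make_tx("o", [(320, 400), (500, 600)])
        assert classify_transcript(t, toy_reference).category == "ISM"

    def test_known_sites_new_combination_is_nic(self):
        exons = [(100, 200), (300, 400), (500, 600), (700, 800)]
        ref = AnnotationSet(
            [
                make_tx("full", exons, gene="g", source="reference"),
                make_tx("skip2", [exons[0], exons[2], exons[3]], gene="g",
                        source="reference"),
            ]
        )
        # skip exon 3: every splice site known, combination novel
        nic = make_tx("o", [exons[0], exons[1], exons[3]])
        call = classify_transcript(nic, ref)
        assert call.category == "NIC"
        assert call.n_novel_splice_sites == 0

    def test_novel_site_is_nnc(self, toy_reference):
        t = make_tx("o", [(100, 200), (310, 400), (500, 600)])
        call = classify_transcript(t, toy_reference)
        assert call.category == "NNC"
        assert call.n_novel_splice_sites == 1

    def test_mono_exon_in_gene_is_genic(self, toy_reference):
        t = make_tx("o", [(150, 350)])
        assert classify_transcript(t, toy_reference).category == "genic"

    def test_opposite_strand_is_antisense(self, toy_reference):
        t = make_tx("o", [(150, 350)], strand="-")
        assert classify_transcript(t, toy_reference).category == "antisense"

    def test_no_overlap_is_intergenic(self, toy_reference):
        t = make_tx("o", [(5000, 5400)])
        assert classify_transcript(t, toy_reference).category == "intergenic"

    def test_spanning_two_genes_is_fusion(self):
        ref = AnnotationSet(
            [
                make_tx("a1", [(100, 200), (300, 400)], gene="gA", source="reference"),
                make_tx("b1", [(1000, 1100), (1200, 1300)], gene="gB", source="reference"),
            ]
        )
        t = make_tx("o", [(100, 200), (300, 400), (1000, 1100), (1200, 1300)])
        call = classify_transcript(t, ref)
        assert call.category == "fusion"

    def test_subchain_calls_match_exhaustive_oracle(self):
        """Every contiguous sub-chain of a 5-exon gene must be FSM or ISM."""
        exons = [(i * 200, i * 200 + 100) for i in range(1, 6)]
        ref = AnnotationSet(
            [make_tx("full", exons, gene="g", source="reference")]
        )
        full_introns = make_tx("full2", exons).intron_chain
        for i, j in itertools.combinations(range(6), 2):
            if j - i < 2:
                continue
            sub = make_tx("o", exons[i:j])
            expected = "FSM" if sub.intron_chain == full_introns else "ISM"
            assert classify_transcript(sub, ref).category == expected

    def test_translation_invariance(self, toy_reference):
        shift = 50_000
        moved_ref = AnnotationSet(
            [
                make_tx(
                    t.transcript_id,
                    [(e.start + shift, e.end + shift) for e in t.exons],
                    strand=t.strand,
                    gene=t.gene_id,
                    source="reference",
                )
                for t in toy_reference
            ]
        )
        for exons, strand in [
            ([(90, 200), (300, 400), (500, 650)], "+"),
            ([(150, 350)], "+"),
            ([(150, 350)], "-"),
        ]:
            base = classify_transcript(make_tx("o", exons, strand=strand), toy_reference)
            moved = classify_transcript(
                make_tx("o", [(s + shift, e + shift) for s, e in exons], strand=strand),
                moved_ref,
            )
            assert base.category == moved.category

    def test_categories_partition_catalog(self, small_bundle):
        calls = classify_catalog(small_bundle["observed"], small_bundle["reference"])
        assert len(calls) == len(small_bundle["observed"])
        assert all(c.category in CATEGORIES for c in calls.values())


class TestORF:
    def test_simple_orf(self):
        genome = {"chr1": "ATGAAATAA"}
        t = make_tx("t", [(0, 9)])
        orf = predict_orf(t, genome)
        assert (orf.start, orf.end, orf.aa_length) == (0, 9, 2)

    def test_no_start_codon_gives_none(self):
        genome = {"chr1": "CCCCCCCCCCCC"}
        assert predict_orf(make_tx("t", [(0, 12)]), genome) is None

    def test_minus_strand_uses_reverse_complement(self):
        # revcomp of TTACATTTACAT... plant ATG..TAA on '-' sense
        genome = {"chr1": "TTATTTCAT"}  # revcomp = ATGAAATAA
        orf = predict_orf(make_tx("t", [(0, 9)], strand="-"), genome)
        assert orf.aa_length == 2

    def test_matches_brute_force_scan(self):
        import numpy as np

        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        genome = {"chr1": seq}
        t = make_tx("t", [(0, 2000)])
        got = predict_orf(t, genome)

        stops = {"TAA", "TAG", "TGA"}
        best = None
        for i in range(len(seq) - 2):
            if seq[i : i + 3] == "ATG":
                for j in range(i + 3, len(seq) - 2, 3):
                    if seq[j : j + 3] in stops:
                        aa = (j - i) // 3
                        if best is None or aa > best[2]:
                            best = (i, j + 3, aa)
                        break
        assert best is not None and got is not None
        assert (got.start, got.end, got.aa_length) == best

    def test_spliced_sequence_concatenates_exons(self):
        genome = {"chr1": "AAACCCGGGTTT"}
        t = make_tx("t", [(0, 3), (6, 9)])
        assert spliced_sequence(t, genome) == "AAAGGG"


class TestSummary:
    def test_single_fsm_gene_has_no_multi_isoform_genes(self, toy_reference):
        obs = AnnotationSet([make_tx("o", [(100, 200), (300, 400), (500, 600)])])
        calls = classify_catalog(obs, toy_reference)
        s = summarize_catalog(calls, obs, toy_reference)
        assert s.genes_with_multiple_isoforms == 0
        assert s.n_known_transcripts == 1

    def test_counts_sum_to_total(self, small_bundle):
        calls = classify_catalog(small_bundle["observed"], small_bundle["reference"])
        s = summarize_catalog(
            calls, small_bundle["observed"], small_bundle["reference"]
        )
        assert sum(s.category_counts.values()) == s.n_transcripts
        assert s.n_known_transcripts + s.n_novel_transcripts == s.n_transcripts

    def test_summary_matches_truth_tallies(self, small_bundle):
        calls = classify_catalog(small_bundle["observed"], small_bundle["reference"])
        s = summarize_catalog(
            calls, small_bundle["observed"], small_bundle["reference"]
        )
        truth = small_bundle["truth"]
        for cat in CATEGORIES:
            expected = sum(
                1 for tt in truth.transcripts.values() if tt.category == cat
            )
            assert s.category_counts[cat] == expected
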
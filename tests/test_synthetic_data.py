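import numpy as np
import pytest

from isodiv.model import ConfigError
from isodiv.synthetic_data import (
    CONDITIONS,
    SimConfig,
    simulate_expression,
    simulate_observed_catalog,
    simulate_reference,
)


class TestConfig:
    def test_mix_must_sum_to_one(self):
        cfg = SimConfig()
        cfg.structural_category_mix["FSM"] += 0.5
        with pytest.raises(ConfigError, match="sum to 1"):
            cfg.validate()

    def test_fractions_bounded(self):
        with pytest.raises(ConfigError):
            SimConfig(fraction_amt_genes=1.5).validate()

    def test_pas_spacing_must_exceed_cluster_scale(self):
        with pytest.raises(ConfigError, match="pas_spacing"):
            SimConfig(pas_spacing=(30, 40)).validate()


class TestReference:
    def test_single_gene_single_isoform(self):
        cfg = SimConfig(n_genes=1, isoforms_per_gene=(1, 1), rng_seed=0)
        ref, genome, layouts = simulate_reference(cfg)
        assert len(ref.genes) == 1 and len(ref) == 1

    def test_same_seed_reproduces_everything(self):
        cfg = SimConfig(n_genes=30, rng_seed=5)
        ref1, genome1, _ = simulate_reference(cfg)
        ref2, genome2, _ = simulate_reference(SimConfig(n_genes=30, rng_seed=5))
        assert genome1 == genome2
        assert {t.transcript_id: t.exons for t in ref1} == {
            t.transcript_id: t.exons for t in ref2
        }

    def test_gene_loci_do_not_overlap(self):
        cfg = SimConfig(n_genes=200, rng_seed=1)
        ref, _, layouts = simulate_reference(cfg)
        by_chrom = {}
        for layout in layouts.values():
            by_chrom.setdefault(layout.chrom, []).append(layout.span)
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 >= e1

    def test_planted_nnc_recipe_has_novel_site(self):
        cfg = SimConfig(n_genes=40, n_observed=150, rng_seed=2)
        ref, _, layouts = simulate_reference(cfg)
        obs, truth = simulate_observed_catalog(cfg, ref, layouts)
        gene_sites = {
            gid: {s for t in ref.gene_transcripts(gid) for s in t.splice_sites}
            for gid in ref.genes
        }
        checked = 0
        for tid, tt in truth.transcripts.items():
            if tt.category == "NNC":
                novel = set(obs[tid].splice_sites) - gene_sites[tt.gene_id]
                assert novel, tid
                checked += 1
        assert checked > 0


class TestCatalog:
    def test_pure_fsm_mix_yields_only_fsm(self):
        mix = {c: 0.0 for c in SimConfig().structural_category_mix}
        mix["FSM"] = 1.0
        cfg = SimConfig(
            n_genes=20, n_observed=60, structural_category_mix=mix, rng_seed=3
        )
        ref, _, layouts = simulate_reference(cfg)
        obs, truth = simulate_observed_catalog(cfg, ref, layouts)
        assert {tt.category for tt in truth.transcripts.values()} == {"FSM"}

    def test_category_counts_match_mix_within_tolerance(self):
        cfg = SimConfig(n_genes=100, n_observed=400, rng_seed=4)
        ref, _, layouts = simulate_reference(cfg)
        obs, truth = simulate_observed_catalog(cfg, ref, layouts)
        counts = {}
        for tt in truth.transcripts.values():
            counts[tt.category] = counts.get(tt.category, 0) + 1
        for cat, target in cfg.structural_category_mix.items():
            assert abs(counts.get(cat, 0) / 400 - target) <= 0.05

    def test_every_planted_pas_has_an_observed_end(self, small_bundle):
        truth = small_bundle["truth"]
        realized = {}
        for tt in truth.transcripts.values():
            if tt.pas_position is not None:
                realized.setdefault(tt.gene_id, set()).add(tt.pas_position)
        for gid, gt in truth.genes.items():
            for cond, mpas in gt.mpas.items():
                if mpas is not None:
                    assert mpas in realized[gid]


class TestExpression:
    def test_zero_dispersion_counts_equal_rounded_means(self):
        cfg = SimConfig(n_genes=20, n_observed=60, nb_dispersion=0.0, rng_seed=6)
        ref, _, layouts = simulate_reference(cfg)
        obs, truth = simulate_observed_catalog(cfg, ref, layouts)
        m1, _ = simulate_expression(cfg, obs, truth)
        obs2, truth2 = simulate_observed_catalog(cfg, ref, layouts)
        m2, _ = simulate_expression(cfg, obs2, truth2)
        assert (m1.values.values == m2.values.values).all()
        assert (m1.values.values == np.rint(m1.values.values)).all()

    def test_non_de_genes_have_flat_expected_fold_change(self):
        cfg = SimConfig(
            n_genes=30, n_observed=90, nb_dispersion=0.0, fraction_de_genes=0.3,
            rng_seed=7,
        )
        ref, _, layouts = simulate_reference(cfg)
        obs, truth = simulate_observed_catalog(cfg, ref, layouts)
        m, truth = simulate_expression(cfg, obs, truth)
        c1, c2 = CONDITIONS
        gene_sums = {}
        for tid, tt in truth.transcripts.items():
            if tt.gene_id:
                g = gene_sums.setdefault(tt.gene_id, {c1: 0.0, c2: 0.0})
                for cond in CONDITIONS:
                    cols = [s for s in m.sample_ids if s.startswith(cond)]
                    g[cond] += float(m.values.loc[tid, cols].mean())
        for gid, sums in gene_sums.items():
            gt = truth.genes[gid]
            if gt.de or sums[c1] < 50:
                continue
            lfc = np.log2(sums[c2] / sums[c1])
            assert abs(lfc) < 0.1, gid

    def test_amt_flag_matches_planted_mt_identity(self, small_bundle):
        truth = small_bundle["truth"]
        c1, c2 = CONDITIONS
        for gt in truth.genes.values():
            if gt.amt is None:
                continue
            expected = (
                gt.mt.get(c1) is not None
                and gt.mt.get(c2) is not None
                and gt.mt[c1] != gt.mt[c2]
            )
            assert gt.amt == expected

    def test_planted_signal_dominates_hexamer_background(self):
        from isodiv.apa_analysis import hexamer_rank, scan_pas_signal
        from isodiv.catalog_classify import apply_gene_assignments, classify_catalog
        from isodiv.apa_analysis import cluster_pas

        cfg = SimConfig(n_genes=100, n_observed=300, pas_signal_rate=0.8, rng_seed=8)
        ref, genome, layouts = simulate_reference(cfg)
        obs, truth = simulate_observed_catalog(cfg, ref, layouts)
        m, truth = simulate_expression(cfg, obs, truth)
        catalog = apply_gene_assignments(obs, classify_catalog(obs, ref))
        clusters, chrom_of = [], {}
        for gid in sorted(catalog.genes):
            ts = catalog.gene_transcripts(gid)
            chrom_of[gid] = ts[0].chrom
            clusters.extend(cluster_pas(ts, gid, min_support=2))
        table = scan_pas_signal(genome, clusters, chrom_of)
        assert hexamer_rank(table) == 1
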
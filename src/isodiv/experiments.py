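"""Recovery experiments on synthetic data with planted ground truth.

Each function runs one self-contained experiment — generate a bundle
with known truth, run the relevant pipeline stages, score the result —
and returns plain numbers. They back both the acceptance test suite
and the ``scripts/acceptance.py`` reporting script.
"""

from __future__ import annotations

import filecmp
import os
import tempfile
from typing import Dict

import numpy as np
import pandas as pd

from .annotation_io import compute_fpkm
from .apa_analysis import analyze_apa, cluster_pas, hexamer_rank, scan_pas_signal
from .catalog_classify import apply_gene_assignments, classify_catalog
from .dge import nb_wald_test
from .model import ExpressionMatrix
from .mt_analysis import call_major_transcripts, detect_amt
from .synthetic_data import (
    CONDITIONS,
    SimConfig,
    simulate_expression,
    simulate_observed_catalog,
    simulate_reference,
)

FSM_ONLY_MIX = {
    "FSM": 1.0,
    "ISM": 0.0,
    "NIC": 0.0,
    "NNC": 0.0,
    "fusion": 0.0,
    "genic": 0.0,
    "antisense": 0.0,
    "intergenic": 0.0,
}


def _sub_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2**31 - 1))


# ---------------------------------------------------------------------------
# structural classification recovery
# ---------------------------------------------------------------------------

def structural_recovery(seed: int, jitter: bool = False) -> Dict[str, float]:
    """Category agreement with planted truth on a 400-transcript catalog."""
    cfg = SimConfig(
        n_genes=100,
        n_observed=400,
        tss_jitter=30 if jitter else 0,
        tes_jitter=10 if jitter else 0,
        rng_seed=_sub_seed(seed, 1),
    )
    reference, genome, layouts = simulate_reference(cfg)
    observed, truth = simulate_observed_catalog(cfg, reference, layouts)
    calls = classify_catalog(observed, reference)
    agree = sum(
        1
        for tid, call in calls.items()
        if call.category == truth.transcripts[tid].category
    )
    fsm_ism = [
        tid
        for tid, tt in truth.transcripts.items()
        if tt.category in ("FSM", "ISM")
    ]
    agree_fsm_ism = sum(
        1 for tid in fsm_ism if calls[tid].category == truth.transcripts[tid].category
    )
    return {
        "accuracy": agree / len(calls),
        "fsm_ism_accuracy": agree_fsm_ism / len(fsm_ism),
        "n": len(calls),
    }


# ---------------------------------------------------------------------------
# AS event detection vs planted truth and vs the base-level oracle
# ---------------------------------------------------------------------------

def as_event_recovery(seed: int) -> Dict[str, float]:
    """Planted-event recovery on an FSM-only multi-isoform catalog."""
    from .as_events import detect_events_catalog

    cfg = SimConfig(
        n_genes=250,
        n_observed=1200,
        isoforms_per_gene=(2, 4),
        structural_category_mix=dict(FSM_ONLY_MIX),
        pas_per_gene=(1, 1),
        tss_jitter=0,
        tes_jitter=0,
        rng_seed=_sub_seed(seed, 2),
    )
    reference, genome, layouts = simulate_reference(cfg)
    observed, truth = simulate_observed_catalog(cfg, reference, layouts)
    catalog = apply_gene_assignments(
        observed, classify_catalog(observed, reference)
    )
    events = detect_events_catalog(catalog)
    detected = {
        (e.gene_id, e.event_type, e.anchor_left, e.anchor_right,
         e.region_start, e.region_end)
        for e in events
    }
    planted = {
        (ev.gene_id, ev.event_type, ev.anchor_left, ev.anchor_right,
         ev.region_start, ev.region_end)
        for gt in truth.genes.values()
        for ev in gt.events
    }
    n = len(planted)
    return {
        "recall": len(planted & detected) / n if n else float("nan"),
        "precision": len(planted & detected) / len(detected) if detected else float("nan"),
        "n": n,
    }


# ---------------------------------------------------------------------------
# AMT recovery
# ---------------------------------------------------------------------------

def amt_recovery(seed: int, dispersion: float = 0.05) -> Dict[str, float]:
    """AMT precision/recall on a 500-gene two-condition simulation."""
    cfg = SimConfig(
        n_genes=500,
        n_observed=1600,
        isoforms_per_gene=(2, 4),
        structural_category_mix=dict(FSM_ONLY_MIX),
        pas_per_gene=(1, 1),
        nb_dispersion=dispersion,
        fraction_amt_genes=0.2,
        tss_jitter=0,
        tes_jitter=0,
        rng_seed=_sub_seed(seed, 3),
    )
    reference, genome, layouts = simulate_reference(cfg)
    observed, truth = simulate_observed_catalog(cfg, reference, layouts)
    matrix, truth = simulate_expression(cfg, observed, truth)
    catalog = apply_gene_assignments(
        observed, classify_catalog(observed, reference)
    )
    matrix.feature_lengths = {t.transcript_id: t.exonic_length for t in catalog}
    fpkm = compute_fpkm(matrix)
    by_gene: dict = {}
    for t in catalog:
        if t.gene_id:
            by_gene.setdefault(t.gene_id, []).append(t.transcript_id)
    mt_calls = {}
    for cond in CONDITIONS:
        means = fpkm.condition_means(cond)
        mt_calls[cond] = call_major_transcripts(
            {g: {tid: float(means[tid]) for tid in tids} for g, tids in by_gene.items()},
            cond,
        )
    amt, constant, indeterminate = detect_amt(
        mt_calls[CONDITIONS[0]], mt_calls[CONDITIONS[1]]
    )
    called = {a.gene_id for a in amt}
    true_amt = {g for g, gt in truth.genes.items() if gt.amt}
    tp = len(called & true_amt)
    return {
        "precision": tp / len(called) if called else float("nan"),
        "recall": tp / len(true_amt) if true_amt else float("nan"),
        "n": len(true_amt),
    }


# ---------------------------------------------------------------------------
# APA recovery
# ---------------------------------------------------------------------------

def apa_recovery(seed: int) -> Dict[str, float]:
    """M/P status, mPAS-shift and poly(A)-signal recovery on 200 APA genes."""
    cfg = SimConfig(
        n_genes=200,
        n_observed=1400,
        isoforms_per_gene=(1, 2),
        structural_category_mix=dict(FSM_ONLY_MIX),
        pas_per_gene=(2, 4),
        nb_dispersion=0.0,
        fraction_amt_genes=0.0,
        fraction_mpas_shift_genes=0.3,
        pas_signal_rate=0.8,
        tss_jitter=0,
        tes_jitter=10,
        rng_seed=_sub_seed(seed, 4),
    )
    reference, genome, layouts = simulate_reference(cfg)
    observed, truth = simulate_observed_catalog(cfg, reference, layouts)
    matrix, truth = simulate_expression(cfg, observed, truth)
    catalog = apply_gene_assignments(
        observed, classify_catalog(observed, reference)
    )
    matrix.feature_lengths = {t.transcript_id: t.exonic_length for t in catalog}
    fpkm = compute_fpkm(matrix)
    iso_expr = {
        cond: {tid: float(v) for tid, v in fpkm.condition_means(cond).items()}
        for cond in CONDITIONS
    }
    support = {
        cond: {tid: tt.support.get(cond, 0) for tid, tt in truth.transcripts.items()}
        for cond in CONDITIONS
    }
    records = analyze_apa(
        catalog, iso_expr, list(CONDITIONS), support_by_condition=support
    )
    mp_ok = mp_n = shift_ok = shift_n = 0
    for gid, rec in records.items():
        gt = truth.genes[gid]
        for cond in CONDITIONS:
            if gt.mp_status.get(cond):
                mp_n += 1
                mp_ok += rec.mp_status.get(cond) == gt.mp_status[cond]
        if gt.mpas_shift is not None and rec.mpas_shift is not None:
            shift_n += 1
            shift_ok += rec.mpas_shift == gt.mpas_shift
    clusters, chrom_of = [], {}
    for gid in sorted(catalog.genes):
        ts = catalog.gene_transcripts(gid)
        chrom_of[gid] = ts[0].chrom
        clusters.extend(cluster_pas(ts, gid, min_support=2))
    table = scan_pas_signal(genome, clusters, chrom_of)
    return {
        "mp_accuracy": mp_ok / mp_n if mp_n else float("nan"),
        "shift_accuracy": shift_ok / shift_n if shift_n else float("nan"),
        "aataaa_rank": float(hexamer_rank(table) or 0),
        "n_apa_genes": len(records),
        "n_pas": len(clusters),
    }


# ---------------------------------------------------------------------------
# NB Wald calibration and power
# ---------------------------------------------------------------------------

def null_type1_error(seed: int, n_genes: int = 2000, dispersion: float = 0.1) -> float:
    """Fraction of null genes with p < 0.05 in an equal-means simulation."""
    rng = np.random.default_rng(seed)
    mu = rng.uniform(50, 500, n_genes)
    n_param = 1.0 / dispersion
    counts = rng.negative_binomial(
        n_param, n_param / (n_param + mu[:, None]), size=(n_genes, 6)
    ).astype(float)
    samples = [f"c1_r{i}" for i in range(3)] + [f"c2_r{i}" for i in range(3)]
    m = ExpressionMatrix(
        pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)], columns=samples),
        {s: s.split("_")[0] for s in samples},
    )
    p = np.array([c.p_value for c in nb_wald_test(m)])
    return float((p < 0.05).mean())


def de_power(seed: int, n_de: int = 500, lfc: float = 2.0) -> float:
    """Fraction of planted DE genes (mean 100, dispersion 0.05) called up."""
    rng = np.random.default_rng(seed)
    n_param = 1.0 / 0.05
    mu1 = np.full(n_de, 100.0)
    mu2 = mu1 * 2.0**lfc
    c1 = rng.negative_binomial(n_param, n_param / (n_param + mu1[:, None]), size=(n_de, 3))
    c2 = rng.negative_binomial(n_param, n_param / (n_param + mu2[:, None]), size=(n_de, 3))
    bg_mu = rng.uniform(50, 500, 1500)
    bg = rng.negative_binomial(
        n_param, n_param / (n_param + bg_mu[:, None]), size=(1500, 6)
    )
    counts = np.vstack([np.hstack([c1, c2]), bg]).astype(float)
    samples = [f"c1_r{i}" for i in range(3)] + [f"c2_r{i}" for i in range(3)]
    m = ExpressionMatrix(
        pd.DataFrame(counts, index=[f"g{i}" for i in range(len(counts))], columns=samples),
        {s: s.split("_")[0] for s in samples},
    )
    calls = nb_wald_test(m)[:n_de]
    return float(np.mean([c.direction == "up" for c in calls]))


# ---------------------------------------------------------------------------
# full-pipeline determinism
# ---------------------------------------------------------------------------

def pipeline_determinism(seed: int) -> bool:
    """Same bundle + config run twice: every artifact byte-identical."""
    from .cli_report import PipelineConfig, run_pipeline
    from .synthetic_data import simulate_bundle

    with tempfile.TemporaryDirectory() as tmp:
        bundle = os.path.join(tmp, "bundle")
        simulate_bundle(
            SimConfig(n_genes=60, n_observed=240, rng_seed=_sub_seed(seed, 5)),
            bundle,
        )
        outs = []
        for run in ("r1", "r2"):
            outdir = os.path.join(tmp, run)
            run_pipeline(
                PipelineConfig(
                    observed=os.path.join(bundle, "observed.gtf"),
                    reference=os.path.join(bundle, "reference.gtf"),
                    counts=os.path.join(bundle, "counts.tsv"),
                    design=os.path.join(bundle, "design.yaml"),
                    genome=os.path.join(bundle, "genome.fa"),
                    support_by_stage=os.path.join(bundle, "support_by_stage.tsv"),
                    outdir=outdir,
                )
            )
            outs.append(outdir)
        return all(
            filecmp.cmp(
                os.path.join(outs[0], f), os.path.join(outs[1], f), shallow=False
            )
            for f in sorted(os.listdir(outs[0]))
        )
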
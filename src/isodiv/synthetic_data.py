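"""Synthetic transcriptome generator with planted ground truth.

The generator builds, deterministically from one seed:

1. a reference annotation — non-overlapping gene loci on two or more
   chromosomes and both strands; each gene has a full exon chain plus
   isoforms derived from it by one planted AS event each (ES, IR,
   A3SS, A5SS or MEE), placed at mutually non-adjacent exon slots so
   pairwise comparisons decompose exactly into the planted events;
2. a random genome with an AATAAA hexamer planted 10-30 nt upstream of
   each polyadenylation site at a configurable rate;
3. an observed catalog with transcripts constructed per structural
   category recipe (FSM termini may jitter; ISM drops 5'-terminal
   exons; NIC recombines known splice sites; NNC shifts one site to a
   novel coordinate; fusion concatenates two adjacent same-strand
   genes; genic is mono-exonic inside an intron; antisense mirrors
   exons to the opposite strand; intergenic sits between loci), each
   observed 3' end snapped (with jitter) to one of the gene's PASs;
4. two-condition negative-binomial expression with three replicates
   per condition. Per-gene isoform weights are planted first — biased
   PAS usage, condition-switched dominant isoforms, condition-switched
   major PAS, fold-changed gene means — and every truth label (MT per
   condition, AMT flag, DE status, M/P status, mPAS, shift) is then
   *derived* from the expected expression with the pipeline's own
   decision rules, so the truth is attainable exactly in the
   zero-dispersion limit.

Randomness: one root seed; each stage draws from its own spawned
substream, so stages are independently reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .model import (
    AnnotationSet,
    ConfigError,
    ExpressionMatrix,
    GenomicInterval,
    TranscriptModel,
)
from .annotation_io import write_annotation

CONDITIONS = ("d30", "d90")

_STAGE = {"reference": 0, "genome": 1, "catalog": 2, "expression": 3}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE[stage],))
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: catalog-style category shares used as the default observed mix
DEFAULT_CATEGORY_MIX = {
    "FSM": 0.1415,
    "ISM": 0.2539,
    "NIC": 0.2439,
    "NNC": 0.3224,
    "fusion": 0.0083,
    "genic": 0.0100,
    "antisense": 0.0100,
    "intergenic": 0.0100,
}

DEFAULT_AS_MIX = {"ES": 0.40, "IR": 0.30, "A3SS": 0.15, "A5SS": 0.10, "MEE": 0.05}


@dataclass
class SimConfig:
    n_genes: int = 200
    n_observed: int = 400
    isoforms_per_gene: Tuple[int, int] = (1, 4)
    exons_per_transcript: Tuple[int, int] = (6, 10)
    exon_length: Tuple[int, int] = (80, 300)
    intron_length: Tuple[int, int] = (100, 400)
    intergene_gap: Tuple[int, int] = (600, 2000)
    n_chroms: int = 2
    structural_category_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    as_event_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AS_MIX)
    )
    n_replicates: int = 3
    nb_mean_range: Tuple[float, float] = (50.0, 500.0)
    nb_dispersion: float = 0.1
    fraction_amt_genes: float = 0.2
    mt_margin: float = 30.0
    fraction_de_genes: float = 0.2
    log2fc_effect: float = 2.0
    pas_per_gene: Tuple[int, int] = (2, 4)
    pas_spacing: Tuple[int, int] = (100, 300)
    fraction_mpas_shift_genes: float = 0.3
    pas_signal_rate: float = 0.8
    tss_jitter: int = 30
    tes_jitter: int = 10
    support_scale: int = 50
    rng_seed: int = 0

    def validate(self) -> None:
        for name, mix in (
            ("structural_category_mix", self.structural_category_mix),
            ("as_event_mix", self.as_event_mix),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ConfigError(f"{name} must sum to 1")
            if any(v < 0 for v in mix.values()):
                raise ConfigError(f"{name} has negative entries")
        for frac in (
            self.fraction_amt_genes,
            self.fraction_de_genes,
            self.fraction_mpas_shift_genes,
            self.pas_signal_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must be in [0, 1]")
        if self.n_genes < 1 or self.n_observed < 1:
            raise ConfigError("n_genes and n_observed must be positive")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.pas_spacing[0] <= 2 * (24 + self.tes_jitter):
            raise ConfigError(
                "pas_spacing must exceed twice the cluster window plus "
                "end jitter, or planted PASs are not separable"
            )


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class PlantedEvent:
    gene_id: str
    event_type: str
    anchor_left: int
    anchor_right: int
    region_start: int
    region_end: int


@dataclass
class TranscriptTruth:
    transcript_id: str
    category: str
    gene_id: Optional[str] = None
    isoform_id: Optional[str] = None  # reference isoform copied (FSM)
    pas_position: Optional[int] = None
    support: Dict[str, int] = field(default_factory=dict)
    weights: Dict[str, float] = field(default_factory=dict)


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str = ""
    strand: str = "+"
    pas_positions: List[int] = field(default_factory=list)  # transcription order
    pas_has_signal: List[bool] = field(default_factory=list)
    mt: Dict[str, Optional[str]] = field(default_factory=dict)
    amt: Optional[bool] = None
    de: bool = False
    log2fc: float = 0.0
    mp_status: Dict[str, str] = field(default_factory=dict)
    mpas: Dict[str, Optional[int]] = field(default_factory=dict)
    mpas_shift: Optional[bool] = None
    events: List[PlantedEvent] = field(default_factory=list)


@dataclass
class TruthSet:
    transcripts: Dict[str, TranscriptTruth] = field(default_factory=dict)
    genes: Dict[str, GeneTruth] = field(default_factory=dict)
    conditions: Tuple[str, str] = CONDITIONS


# internal per-gene layout (not part of the public truth)
@dataclass
class _GeneLayout:
    gene_id: str
    chrom: str
    strand: str
    full_chain: List[Tuple[int, int]]
    isoform_chains: Dict[str, List[Tuple[int, int]]]  # isoform id -> chain
    pas_positions: List[int]  # transcription order; [0] = annotated TES
    pas_has_signal: List[bool]
    reserved_slots: set
    known_sites: set
    span: Tuple[int, int]  # includes PAS extensions


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def _plant_event(
    rng: np.random.Generator,
    layout: _GeneLayout,
    event_type: str,
) -> Optional[Tuple[List[Tuple[int, int]], PlantedEvent]]:
    """Derive a variant chain from the full chain for one AS event.

    Every recipe reserves the touched exon slots plus one flanking slot
    on each side, so no two planted events share or abut a modified
    boundary and pairwise decomposition cannot create side events.
    """
    chain = layout.full_chain
    n = len(chain)
    internal = [i for i in range(1, n - 1)]
    strand = layout.strand

    def free(slots):
        return not (set(slots) & layout.reserved_slots)

    candidates = internal[:]
    rng.shuffle(candidates)
    for i in candidates:
        s_i, e_i = chain[i]
        if event_type == "ES":
            if not free((i - 1, i, i + 1)):
                continue
            variant = chain[:i] + chain[i + 1 :]
            ev = PlantedEvent(
                layout.gene_id, "ES", chain[i - 1][1], chain[i + 1][0], s_i, e_i
            )
            layout.reserved_slots.update((i - 1, i, i + 1))
            return variant, ev
        if event_type == "IR":
            if i + 1 >= n - 1 + 1 or not free((i - 1, i, i + 1, i + 2)):
                continue
            if i + 1 > n - 1:
                continue
            merged = (s_i, chain[i + 1][1])
            variant = chain[:i] + [merged] + chain[i + 2 :]
            ev = PlantedEvent(
                layout.gene_id, "IR", e_i, chain[i + 1][0], e_i, chain[i + 1][0]
            )
            layout.reserved_slots.update((i - 1, i, i + 1, i + 2))
            return variant, ev
        if event_type in ("A5SS", "A3SS"):
            if not free((i - 1, i, i + 1)):
                continue
            # biological 5' side = genomic end on '+', genomic start on '-'
            move_end = (event_type == "A5SS") == (strand == "+")
            delta = int(rng.integers(15, 41))
            if (e_i - s_i) - delta < 40:
                continue
            if move_end:
                variant_exon = (s_i, e_i - delta)
                region = (e_i - delta, e_i)
                anchors = (s_i, chain[i + 1][0])
            else:
                variant_exon = (s_i + delta, e_i)
                region = (s_i, s_i + delta)
                anchors = (chain[i - 1][1], e_i)
            variant = chain[:i] + [variant_exon] + chain[i + 1 :]
            ev = PlantedEvent(
                layout.gene_id, event_type, anchors[0], anchors[1], *region
            )
            layout.reserved_slots.update((i - 1, i, i + 1))
            return variant, ev
        if event_type == "MEE":
            if i + 1 > n - 1 or not free((i - 1, i, i + 1)):
                continue
            gap_lo, gap_hi = e_i, chain[i + 1][0]
            exon_len = 50
            if gap_hi - gap_lo < exon_len + 20:
                continue
            x_start = gap_lo + 10
            x_end = x_start + exon_len
            variant = chain[:i] + [(x_start, x_end)] + chain[i + 1 :]
            ev = PlantedEvent(
                layout.gene_id,
                "MEE",
                chain[i - 1][1],
                chain[i + 1][0],
                s_i,
                x_end,
            )
            layout.reserved_slots.update((i - 1, i, i + 1))
            return variant, ev
    return None


def simulate_reference(cfg: SimConfig):
    """Build the reference annotation, gene layouts and genome sequences.

    Returns ``(reference, genome, layouts)`` where ``genome`` maps
    chromosome name to sequence string and ``layouts`` is the internal
    per-gene geometry consumed by :func:`simulate_observed_catalog`.
    """
    cfg.validate()
    rng = _stage_rng(cfg.rng_seed, "reference")
    cursors = {f"chrS{c + 1}": 1000 for c in range(cfg.n_chroms)}
    chrom_names = sorted(cursors)
    layouts: Dict[str, _GeneLayout] = {}
    reference = AnnotationSet()
    event_types = sorted(cfg.as_event_mix)
    event_probs = np.array([cfg.as_event_mix[t] for t in event_types])
    if event_probs.sum() > 0:
        event_probs = event_probs / event_probs.sum()

    for g in range(cfg.n_genes):
        gene_id = f"SIMG_{g + 1:05d}"
        chrom = chrom_names[g % cfg.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(*_hi(cfg.exons_per_transcript)))
        exon_lens = rng.integers(*_hi(cfg.exon_length), size=n_exons)
        intron_lens = rng.integers(*_hi(cfg.intron_length), size=n_exons - 1)
        start = cursors[chrom]
        chain = []
        pos = start
        for k in range(n_exons):
            chain.append((pos, pos + int(exon_lens[k])))
            pos = chain[-1][1]
            if k < n_exons - 1:
                pos += int(intron_lens[k])

        # polyadenylation sites, transcription order; [0] = annotated TES
        n_pas = int(rng.integers(*_hi(cfg.pas_per_gene)))
        # keep internal PASs well away from the UTRR midpoint so that
        # end jitter below the cluster window can never flip a
        # distal/proximal side assignment
        min_mid_dist = 3 * max(cfg.tes_jitter, 10)
        for _ in range(50):
            spacings = rng.integers(*_hi(cfg.pas_spacing), size=max(n_pas - 1, 1))
            offsets = np.concatenate([[0], np.cumsum(spacings[: n_pas - 1])])
            mid = (offsets[0] + offsets[-1]) / 2.0
            if all(abs(o - mid) >= min_mid_dist for o in offsets[1:-1]):
                break
        if strand == "+":
            pas = [chain[-1][1]]
            for sp in spacings[: n_pas - 1]:
                pas.append(pas[-1] + int(sp))
        else:
            pas = [chain[0][0]]
            for sp in spacings[: n_pas - 1]:
                pas.append(pas[-1] - int(sp))
        signals = [bool(rng.random() < cfg.pas_signal_rate) for _ in pas]

        layout = _GeneLayout(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            full_chain=chain,
            isoform_chains={},
            pas_positions=pas,
            pas_has_signal=signals,
            reserved_slots=set(),
            known_sites=set(),
            span=(min(chain[0][0], min(pas)), max(chain[-1][1], max(pas))),
        )

        n_iso = int(rng.integers(*_hi(cfg.isoforms_per_gene)))
        iso_id = f"{gene_id}.1"
        layout.isoform_chains[iso_id] = chain
        gene_events: List[PlantedEvent] = []
        for k in range(2, n_iso + 1):
            etype = str(rng.choice(event_types, p=event_probs))
            planted = _plant_event(rng, layout, etype)
            if planted is None:
                # try remaining types before giving up on this isoform
                for alt in event_types:
                    planted = _plant_event(rng, layout, alt)
                    if planted is not None:
                        break
            if planted is None:
                break
            variant, ev = planted
            layout.isoform_chains[f"{gene_id}.{k}"] = variant
            gene_events.append(ev)

        layout.known_sites = {
            coord
            for ch in layout.isoform_chains.values()
            for s, e in ch[1:-1]
            for coord in (s, e)
        } | {
            ch[0][1] for ch in layout.isoform_chains.values()
        } | {
            ch[-1][0] for ch in layout.isoform_chains.values()
        }
        layout.events = gene_events  # type: ignore[attr-defined]
        layouts[gene_id] = layout

        for iso_id, ch in layout.isoform_chains.items():
            reference.add(
                TranscriptModel(
                    transcript_id=iso_id,
                    exons=tuple(
                        GenomicInterval(chrom, s, e, strand) for s, e in ch
                    ),
                    gene_id=gene_id,
                    source="reference",
                )
            )
        gap = int(rng.integers(*_hi(cfg.intergene_gap)))
        cursors[chrom] = layout.span[1] + gap

    genome = _build_genome(cfg, layouts, cursors)
    return reference, genome, layouts


def _hi(rng_pair: Tuple[int, int]) -> Tuple[int, int]:
    """Inclusive (lo, hi) pair -> numpy-style half-open arguments."""
    return rng_pair[0], rng_pair[1] + 1


def _build_genome(cfg: SimConfig, layouts, cursors) -> Dict[str, str]:
    rng = _stage_rng(cfg.rng_seed, "genome")
    genome = {}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for chrom in sorted(cursors):
        length = cursors[chrom] + 1000
        seq = bases[rng.integers(0, 4, size=length)]
        genome[chrom] = seq
    # plant AATAAA 10-30 nt upstream of each PAS on the sense strand
    for gid in sorted(layouts):
        layout = layouts[gid]
        seq = genome[layout.chrom]
        for pas, has_signal in zip(layout.pas_positions, layout.pas_has_signal):
            if not has_signal:
                continue
            offset = int(rng.integers(10, 31))
            if layout.strand == "+":
                lo = pas - offset - 6
                motif = b"AATAAA"
            else:
                lo = pas + offset
                motif = b"TTTATT"  # reverse complement on the sense strand
            seq[lo : lo + 6] = np.frombuffer(motif, dtype="S1")
    return {c: genome[c].tobytes().decode() for c in genome}


# ---------------------------------------------------------------------------
# observed catalog
# ---------------------------------------------------------------------------

def _allocate(mix: Dict[str, float], n: int) -> Dict[str, int]:
    """Largest-remainder allocation of n items to mix proportions."""
    keys = sorted(mix)
    raw = {k: mix[k] * n for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    remainder = n - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:remainder]:
        counts[k] += 1
    return counts


def simulate_observed_catalog(
    cfg: SimConfig, reference: AnnotationSet, layouts
) -> Tuple[AnnotationSet, TruthSet]:
    """Construct the observed catalog per category recipe, with truth labels."""
    rng = _stage_rng(cfg.rng_seed, "catalog")
    truth = TruthSet()
    observed = AnnotationSet()
    counts = _allocate(cfg.structural_category_mix, cfg.n_observed)
    gene_ids = sorted(layouts)
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"OBS_{counter[0]:05d}"

    def add(exons, category, gene_id=None, iso_id=None, pas=None):
        tid = new_id()
        observed.add(
            TranscriptModel(
                transcript_id=tid,
                exons=tuple(exons),
                gene_id=None,
                read_support=1,  # replaced by simulate_expression
                source="observed",
            )
        )
        truth.transcripts[tid] = TranscriptTruth(
            transcript_id=tid,
            category=category,
            gene_id=gene_id,
            isoform_id=iso_id,
            pas_position=pas,
        )
        return tid

    def jitter(val: int, width: int, low_ok: int) -> int:
        if width <= 0:
            return val
        return max(low_ok, val + int(rng.integers(-width, width + 1)))

    # --- FSM: copy an isoform chain; snap 3' end to a PAS with jitter ----
    fsm_slots = [
        (gid, iso)
        for gid in gene_ids
        for iso in sorted(layouts[gid].isoform_chains)
    ]
    pas_cursor = {gid: 0 for gid in gene_ids}
    for j in range(counts["FSM"]):
        gid, iso = fsm_slots[j % len(fsm_slots)]
        layout = layouts[gid]
        chain = [list(x) for x in layout.isoform_chains[iso]]
        k = pas_cursor[gid] % len(layout.pas_positions)
        pas_cursor[gid] += 1
        pas = layout.pas_positions[k]
        end3 = jitter(pas, cfg.tes_jitter, 1)
        if layout.strand == "+":
            chain[-1][1] = max(end3, chain[-1][0] + 20)
            chain[0][0] = jitter(chain[0][0], cfg.tss_jitter, 1)
            chain[0][0] = min(chain[0][0], chain[0][1] - 20)
        else:
            chain[0][0] = min(end3, chain[0][1] - 20)
            chain[-1][1] = jitter(chain[-1][1], cfg.tss_jitter, 1)
            chain[-1][1] = max(chain[-1][1], chain[-1][0] + 20)
        add(
            _chain_to_exons(chain, layout),
            "FSM",
            gene_id=gid,
            iso_id=iso,
            pas=pas,
        )

    # --- ISM: drop >= 1 exons from the biological 5' end ----------------
    ism_genes = [
        gid for gid in gene_ids if len(layouts[gid].full_chain) >= 3
    ]
    for j in range(counts["ISM"]):
        placed = False
        for attempt in range(len(ism_genes)):
            gid = ism_genes[(j + attempt) % len(ism_genes)]
            layout = layouts[gid]
            chain = layout.full_chain
            max_drop = len(chain) - 2
            drops = list(rng.permutation(np.arange(1, max_drop + 1)))
            for d in drops:
                d = int(d)
                trunc = chain[d:] if layout.strand == "+" else chain[: len(chain) - d]
                # truncation must not coincide with another isoform's chain
                if any(
                    _intron_chain(trunc) == _intron_chain(c)
                    for c in layout.isoform_chains.values()
                ):
                    continue
                sub = [list(x) for x in trunc]
                k = pas_cursor[gid] % len(layout.pas_positions)
                pas_cursor[gid] += 1
                pas = layout.pas_positions[k]
                if layout.strand == "+":
                    sub[-1][1] = max(jitter(pas, cfg.tes_jitter, 1), sub[-1][0] + 20)
                else:
                    sub[0][0] = min(jitter(pas, cfg.tes_jitter, 1), sub[0][1] - 20)
                add(_chain_to_exons(sub, layout), "ISM", gene_id=gid, pas=pas)
                placed = True
                break
            if placed:
                break
        if not placed:
            raise ConfigError("cannot satisfy ISM mix: no eligible truncation")

    # --- NIC: skip an untouched internal exon (new known-site junction) -
    nic_genes = [
        gid for gid in gene_ids if len(layouts[gid].full_chain) >= 4
    ]
    for j in range(counts["NIC"]):
        for attempt in range(len(nic_genes)):
            gid = nic_genes[(j + attempt) % len(nic_genes)]
            layout = layouts[gid]
            chain = layout.full_chain
            slots = [
                i
                for i in range(1, len(chain) - 1)
                if i not in layout.reserved_slots
            ]
            if not slots:
                continue
            i = slots[int(rng.integers(0, len(slots)))]
            variant = chain[:i] + chain[i + 1 :]
            if any(
                variant == list(c) or _subchain(variant, c)
                for c in layout.isoform_chains.values()
            ):
                continue
            add(
                _chain_to_exons([list(x) for x in variant], layout),
                "NIC",
                gene_id=gid,
                pas=layout.pas_positions[0],
            )
            break
        else:
            raise ConfigError("cannot satisfy NIC mix: no eligible gene")

    # --- NNC: shift one internal splice site to a novel coordinate ------
    for j in range(counts["NNC"]):
        gid = nic_genes[j % len(nic_genes)]
        layout = layouts[gid]
        chain = layout.full_chain
        for _ in range(50):
            i = int(rng.integers(1, len(chain) - 1))
            s_i, e_i = chain[i]
            delta = int(rng.integers(5, 14))
            new_end = e_i - delta
            if new_end - s_i < 40 or new_end in layout.known_sites:
                continue
            variant = [list(x) for x in chain]
            variant[i][1] = new_end
            add(
                _chain_to_exons(variant, layout),
                "NNC",
                gene_id=gid,
                pas=layout.pas_positions[0],
            )
            break
        else:
            raise ConfigError("cannot place a novel splice site")

    # --- fusion: concatenate two adjacent same-strand genes -------------
    if counts["fusion"]:
        pairs = []
        by_chrom: Dict[str, list] = {}
        for gid in gene_ids:
            by_chrom.setdefault(layouts[gid].chrom, []).append(gid)
        for chrom, gids in sorted(by_chrom.items()):
            gids.sort(key=lambda g: layouts[g].span[0])
            for a, b in zip(gids, gids[1:]):
                if layouts[a].strand == layouts[b].strand:
                    pairs.append((a, b))
        if not pairs:
            raise ConfigError("fusion requested but no adjacent same-strand genes")
        for j in range(counts["fusion"]):
            a, b = pairs[j % len(pairs)]
            chain = [list(x) for x in layouts[a].full_chain] + [
                list(x) for x in layouts[b].full_chain
            ]
            add(_chain_to_exons(chain, layouts[a]), "fusion", gene_id=a)

    # --- genic: mono-exon inside the longest intron ----------------------
    for j in range(counts["genic"]):
        gid = gene_ids[j % len(gene_ids)]
        layout = layouts[gid]
        chain = layout.full_chain
        introns = [
            (chain[i][1], chain[i + 1][0]) for i in range(len(chain) - 1)
        ]
        lo, hi = max(introns, key=lambda iv: iv[1] - iv[0])
        length = min(hi - lo - 2, 200)
        add(
            [GenomicInterval(layout.chrom, lo + 1, lo + 1 + length, layout.strand)],
            "genic",
            gene_id=gid,
        )

    # --- antisense: exons mirrored to the opposite strand ----------------
    for j in range(counts["antisense"]):
        gid = gene_ids[(j * 7) % len(gene_ids)]
        layout = layouts[gid]
        anti = "-" if layout.strand == "+" else "+"
        exons = [
            GenomicInterval(layout.chrom, s, e, anti)
            for s, e in layout.full_chain[:2]
        ]
        add(exons, "antisense")

    # --- intergenic: mono-exon in a gap between loci ---------------------
    if counts["intergenic"]:
        gaps = []
        by_chrom = {}
        for gid in gene_ids:
            by_chrom.setdefault(layouts[gid].chrom, []).append(gid)
        for chrom, gids in sorted(by_chrom.items()):
            gids.sort(key=lambda g: layouts[g].span[0])
            for a, b in zip(gids, gids[1:]):
                lo, hi = layouts[a].span[1], layouts[b].span[0]
                if hi - lo >= 500:
                    gaps.append((chrom, lo, hi))
        if not gaps:
            raise ConfigError("intergenic requested but no gaps available")
        for j in range(counts["intergenic"]):
            chrom, lo, hi = gaps[j % len(gaps)]
            mid = (lo + hi) // 2
            strand = "+" if j % 2 == 0 else "-"
            add(
                [GenomicInterval(chrom, mid - 100, mid + 100, strand)],
                "intergenic",
            )

    for gid in gene_ids:
        layout = layouts[gid]
        truth.genes[gid] = GeneTruth(
            gene_id=gid,
            chrom=layout.chrom,
            strand=layout.strand,
            pas_positions=list(layout.pas_positions),
            pas_has_signal=list(layout.pas_has_signal),
            events=list(getattr(layout, "events", [])),
        )
    return observed, truth


def _chain_to_exons(chain, layout) -> list:
    return [
        GenomicInterval(layout.chrom, int(s), int(e), layout.strand)
        for s, e in chain
    ]


def _intron_chain(chain) -> list:
    return [(chain[i][1], chain[i + 1][0]) for i in range(len(chain) - 1)]


def _subchain(sub, full) -> bool:
    def introns(ch):
        return [(ch[i][1], ch[i + 1][0]) for i in range(len(ch) - 1)]

    a, b = introns(sub), introns(full)
    if not a or len(a) >= len(b):
        return False
    return any(a == b[i : i + len(a)] for i in range(len(b) - len(a) + 1))


# ---------------------------------------------------------------------------
# expression with planted weights; truth derived from expectations
# ---------------------------------------------------------------------------

def simulate_expression(
    cfg: SimConfig,
    observed: AnnotationSet,
    truth: TruthSet,
) -> Tuple[ExpressionMatrix, TruthSet]:
    """Two-condition NB counts per observed transcript; truth labels derived.

    Isoform weights per condition are planted gene by gene (dominant
    PAS 0.6, a favored isoform taking 0.8 of its PAS share; AMT genes
    switch the favored isoform between conditions, shift genes switch
    the dominant PAS), gene means are drawn from ``nb_mean_range`` and
    scaled by ``2**log2fc`` in the second condition for DE genes, and
    counts are drawn NB with dispersion ``nb_dispersion`` (the
    zero-dispersion limit yields the rounded means exactly).
    """
    rng = _stage_rng(cfg.rng_seed, "expression")
    c1, c2 = CONDITIONS
    members: Dict[str, list] = {}
    for tid, tt in truth.transcripts.items():
        if tt.gene_id is not None and tt.category in (
            "FSM",
            "ISM",
            "NIC",
            "NNC",
            "genic",
        ):
            members.setdefault(tt.gene_id, []).append(tid)
    for tids in members.values():
        tids.sort()

    eligible_amt = sorted(g for g, tids in members.items() if len(tids) >= 2)
    rng.shuffle(eligible_amt)
    amt_planted = set(eligible_amt[: int(cfg.fraction_amt_genes * len(eligible_amt))])

    gene_list = sorted(members)
    de_order = list(gene_list)
    rng.shuffle(de_order)
    de_planted = set(de_order[: int(cfg.fraction_de_genes * len(de_order))])

    multi_pas = sorted(
        g
        for g, tids in members.items()
        if len({truth.transcripts[t].pas_position for t in tids} - {None}) >= 2
    )
    rng.shuffle(multi_pas)
    shift_planted = set(
        multi_pas[: int(cfg.fraction_mpas_shift_genes * len(multi_pas))]
    )

    tids_all = sorted(observed.transcripts)
    samples = [f"{c}_r{i + 1}" for c in CONDITIONS for i in range(cfg.n_replicates)]
    design = {s: s.split("_r")[0] for s in samples}
    means = pd.DataFrame(0.0, index=tids_all, columns=samples)

    for gid in gene_list:
        tids = members[gid]
        gt = truth.genes[gid]
        mu = float(rng.uniform(*cfg.nb_mean_range))
        if gid in amt_planted:
            mu = max(mu, 0.5 * (cfg.nb_mean_range[0] + cfg.nb_mean_range[1]))
        lfc = 0.0
        if gid in de_planted:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc = sign * cfg.log2fc_effect
            gt.de, gt.log2fc = True, lfc

        weights = _plant_weights(
            rng,
            gid,
            tids,
            truth,
            amt=gid in amt_planted,
            shift=gid in shift_planted,
            lengths={tid: observed[tid].exonic_length for tid in tids},
        )
        for cond in CONDITIONS:
            scale = 2.0 ** lfc if cond == c2 else 1.0
            for tid in tids:
                w = weights[cond][tid]
                truth.transcripts[tid].weights[cond] = w
                for i in range(cfg.n_replicates):
                    means.loc[tid, f"{cond}_r{i + 1}"] = mu * w * scale

    # transcripts outside annotated genes: flat low expression
    for tid in tids_all:
        tt = truth.transcripts[tid]
        if tt.gene_id is None or tt.category in ("fusion",):
            level = float(rng.uniform(5.0, 50.0))
            means.loc[tid, :] = level
            for cond in CONDITIONS:
                tt.weights[cond] = 1.0

    # per-condition long-read support, proportional to planted weights
    support_rows = {}
    for tid in tids_all:
        tt = truth.transcripts[tid]
        s = {}
        for cond in CONDITIONS:
            w = tt.weights.get(cond, 0.0)
            s[cond] = int(round(cfg.support_scale * w)) if tt.gene_id else int(
                rng.integers(1, 6)
            )
        tt.support = s
        support_rows[tid] = s
        total = max(1, s[c1] + s[c2])
        t = observed[tid]
        observed.transcripts[tid] = TranscriptModel(
            transcript_id=t.transcript_id,
            exons=t.exons,
            gene_id=t.gene_id,
            read_support=total,
            source=t.source,
        )

    # draw counts
    alpha = cfg.nb_dispersion
    mu_arr = means.values
    if alpha <= 1e-8:
        counts = np.rint(mu_arr)
    else:
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + np.maximum(mu_arr, 1e-12))
        counts = rng.negative_binomial(n_param, p_param).astype(float)
        counts[mu_arr == 0] = 0.0
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=tids_all, columns=samples),
        design,
        unit="counts",
        feature_lengths={
            tid: observed[tid].exonic_length for tid in tids_all
        },
    )

    _derive_truth_labels(cfg, truth, members, means, matrix)
    return matrix, truth


def _plant_weights(rng, gid, tids, truth, amt, shift, lengths):
    """Per-condition isoform weight vectors implementing the planted biases.

    Biases (dominant PAS share, favored isoform) are specified on the
    FPKM scale, where the M/P and MT decision rules operate; the final
    count weights are obtained by multiplying the FPKM-share targets by
    transcript length, so length differences between 3'-isoforms do not
    erode the planted margins.
    """
    c1, c2 = CONDITIONS
    pas_of = {
        tid: truth.transcripts[tid].pas_position for tid in tids
    }
    pas_values = sorted({p for p in pas_of.values() if p is not None})
    gt = truth.genes[gid]
    order = gt.pas_positions  # transcription order

    def pas_weight_vector(dominant):
        w = {}
        rest = [p for p in pas_values if p != dominant]
        for p in pas_values:
            w[p] = 0.6 if p == dominant else 0.4 / max(len(rest), 1)
        return w

    used = [p for p in order if p in pas_values]
    if not used:
        used = pas_values or [None]
    # distal preference: the transcription-order last PAS dominates,
    # mirroring the observed bias toward distal site usage
    dom1 = used[-1]
    dom2 = used[-2] if shift and len(used) > 1 else dom1

    weights = {}
    fav1 = fav2 = None
    if amt:
        # favored isoform switches; keep both inside the dominant PAS
        # group when possible so AMT and mPAS planting stay independent
        in_dom1 = sorted(t for t in tids if pas_of[t] == dom1)
        in_dom2 = sorted(t for t in tids if pas_of[t] == dom2)
        fav1 = in_dom1[0] if in_dom1 else sorted(tids)[0]
        pool = [t for t in in_dom2 if t != fav1] or [
            t for t in sorted(tids) if t != fav1
        ]
        fav2 = pool[0]
    else:
        in_dom1 = sorted(t for t in tids if pas_of[t] == dom1)
        fav1 = fav2 = in_dom1[0] if in_dom1 else sorted(tids)[0]

    for cond, dom, fav in ((c1, dom1, fav1), (c2, dom2, fav2)):
        if not pas_values:
            w = {
                tid: (0.8 if tid == fav else 0.2 / max(len(tids) - 1, 1))
                for tid in tids
            }
            mean_len = sum(lengths.values()) / len(lengths)
            w = {t: w[t] * lengths[t] / mean_len for t in tids}
            total = sum(w.values())
            weights[cond] = {t: w[t] / total for t in tids}
            continue
        pw = pas_weight_vector(dom)
        w = {}
        for p in pas_values:
            group = sorted(t for t in tids if pas_of[t] == p)
            if not group:
                continue
            if fav in group:
                others = [t for t in group if t != fav]
                w[fav] = pw[p] * (0.8 if others else 1.0)
                for t in others:
                    w[t] = pw[p] * 0.2 / len(others)
            else:
                for t in group:
                    w[t] = pw[p] / len(group)
        nopas = sorted(t for t in tids if pas_of[t] is None)
        for t in nopas:  # genic transcripts: small flat share
            w[t] = 0.02
        mean_len = sum(lengths.values()) / len(lengths)
        w = {t: w.get(t, 0.0) * lengths[t] / mean_len for t in tids}
        total = sum(w.values())
        weights[cond] = {t: w[t] / total for t in tids}
    return weights


def _derive_truth_labels(cfg, truth, members, means, matrix):
    """Derive MT/AMT, M/P, mPAS and shift truth from expected expression."""
    from .mt_analysis import call_major_transcript

    c1, c2 = CONDITIONS
    lengths = matrix.feature_lengths
    libsize = {s: float(means[s].sum()) for s in means.columns}
    fpkm = {}
    for cond in CONDITIONS:
        cols = [s for s in means.columns if s.startswith(cond)]
        fpkm[cond] = {
            tid: float(
                np.mean(
                    [means.loc[tid, s] * 1e9 / (libsize[s] * lengths[tid]) for s in cols]
                )
            )
            for tid in means.index
        }

    for gid, tids in members.items():
        gt = truth.genes[gid]
        calls = {}
        for cond in CONDITIONS:
            expr = {tid: fpkm[cond][tid] for tid in tids}
            call = call_major_transcript(gid, cond, expr)
            calls[cond] = call
            gt.mt[cond] = call.mt_id
        gt.amt = (
            calls[c1].mt_id is not None
            and calls[c2].mt_id is not None
            and calls[c1].mt_id != calls[c2].mt_id
        )

        # PAS-level truth (only PASs realized by observed 3' ends)
        pas_of = {tid: truth.transcripts[tid].pas_position for tid in tids}
        realized = [p for p in gt.pas_positions if p in set(pas_of.values())]
        if len(realized) >= 2:
            first, last = realized[0], realized[-1]
            midpoint = (first + last) / 2.0
            for cond in CONDITIONS:
                m_sum = p_sum = 0.0
                for tid in tids:
                    p = pas_of[tid]
                    if p is None or p == midpoint:
                        continue
                    downstream = (p > midpoint) if gt.strand == "+" else (p < midpoint)
                    if downstream:
                        m_sum += fpkm[cond][tid]
                    else:
                        p_sum += fpkm[cond][tid]
                gt.mp_status[cond] = (
                    "M" if m_sum > p_sum else ("P" if m_sum < p_sum else "tie")
                )
                usage = {}
                for p in realized:
                    usage[p] = sum(
                        truth.transcripts[tid].support.get(cond, 0)
                        for tid in tids
                        if pas_of[tid] == p
                    )
                top = max(usage.values())
                if top <= 0:
                    gt.mpas[cond] = None
                else:
                    cands = [p for p, u in usage.items() if u == top]
                    gt.mpas[cond] = (
                        max(cands) if gt.strand == "+" else min(cands)
                    )
            if gt.mpas.get(c1) is None or gt.mpas.get(c2) is None:
                gt.mpas_shift = None
            else:
                gt.mpas_shift = gt.mpas[c1] != gt.mpas[c2]


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------

def simulate_bundle(cfg: SimConfig, outdir: str) -> dict:
    """Run all stages and write the artifact bundle to ``outdir``.

    Writes genome.fa, reference.gtf, observed.gtf, counts.tsv,
    design.yaml, support_by_stage.tsv and the truth TSVs. Returns the
    in-memory objects for callers that keep going.
    """
    os.makedirs(outdir, exist_ok=True)
    reference, genome, layouts = simulate_reference(cfg)
    observed, truth = simulate_observed_catalog(cfg, reference, layouts)
    matrix, truth = simulate_expression(cfg, observed, truth)

    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    write_annotation(reference, os.path.join(outdir, "reference.gtf"))
    write_annotation(observed, os.path.join(outdir, "observed.gtf"))
    matrix.values.to_csv(
        os.path.join(outdir, "counts.tsv"), sep="\t", index_label="transcript_id"
    )
    with open(os.path.join(outdir, "design.yaml"), "w") as fh:
        yaml.safe_dump(dict(matrix.design), fh, sort_keys=True)
    pd.DataFrame(
        [
            {
                "transcript_id": tid,
                CONDITIONS[0]: truth.transcripts[tid].support.get(CONDITIONS[0], 0),
                CONDITIONS[1]: truth.transcripts[tid].support.get(CONDITIONS[1], 0),
            }
            for tid in sorted(truth.transcripts)
        ]
    ).to_csv(os.path.join(outdir, "support_by_stage.tsv"), sep="\t", index=False)
    write_truth(truth, outdir)
    return {
        "reference": reference,
        "genome": genome,
        "observed": observed,
        "truth": truth,
        "matrix": matrix,
    }


def write_truth(truth: TruthSet, outdir: str) -> None:
    pd.DataFrame(
        [
            {
                "transcript_id": tid,
                "gene_id": tt.gene_id or "",
                "category": tt.category,
                "isoform_id": tt.isoform_id or "",
                "pas_position": tt.pas_position if tt.pas_position is not None else -1,
            }
            for tid, tt in sorted(truth.transcripts.items())
        ]
    ).to_csv(os.path.join(outdir, "truth_transcripts.tsv"), sep="\t", index=False)
    c1, c2 = truth.conditions
    pd.DataFrame(
        [
            {
                "gene_id": gid,
                "strand": gt.strand,
                "n_pas": len(gt.pas_positions),
                "mt_c1": gt.mt.get(c1) or "",
                "mt_c2": gt.mt.get(c2) or "",
                "amt": bool(gt.amt),
                "de": gt.de,
                "log2fc": gt.log2fc,
                "mp_c1": gt.mp_status.get(c1, ""),
                "mp_c2": gt.mp_status.get(c2, ""),
                "mpas_c1": gt.mpas.get(c1) if gt.mpas.get(c1) is not None else -1,
                "mpas_c2": gt.mpas.get(c2) if gt.mpas.get(c2) is not None else -1,
                "mpas_shift": "" if gt.mpas_shift is None else str(gt.mpas_shift),
            }
            for gid, gt in sorted(truth.genes.items())
        ]
    ).to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene_id": ev.gene_id,
                "event_type": ev.event_type,
                "anchor_left": ev.anchor_left,
                "anchor_right": ev.anchor_right,
                "region_start": ev.region_start,
                "region_end": ev.region_end,
            }
            for gid, gt in sorted(truth.genes.items())
            for ev in gt.events
        ]
    ).to_csv(os.path.join(outdir, "truth_events.tsv"), sep="\t", index=False)
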
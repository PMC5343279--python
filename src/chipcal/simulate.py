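"""Synthetic-data generator: every input the pipeline consumes, with
recorded ground truth, so each stage is testable without downloads.

What it emulates
----------------
* a small multi-chromosome genome of uniform-random sequence carrying
  regularly spaced multi-exon genes;
* three replicate ChIP-seq peak sets: planted truth sites with Gaussian
  boundary jitter, independent dropout, and decoy false positives;
* chromatin-mark tracks whose segments sit on each mark's characteristic
  genomic category, plus a conservation track elevated over a planted
  element and a binding-score track co-elevated there;
* a cluster of E-boxes (4 within 130 bp by default) planted inside an
  intron of the first gene, inside the conserved element;
* ChIP-qPCR Ct tables generated by inverting the percent-input formula
  from known fold enrichments;
* two-wave calcium-imaging traces (ER release after thapsigargin, then
  SOCE on Ca²⁺ re-addition) with condition-dependent SOCE amplitude.

All randomness flows from one integer seed; each artifact draws from its
own deterministic sub-stream, so regenerating one artifact never perturbs
another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .intervals import GeneModel, GenomicInterval, SignalTrack
from .motifs import scan_eboxes

BASES = np.array(list("ACGT"))

# fixed artifact -> sub-stream index; append only, never reorder
_STREAMS = {
    "annotation": 0, "sequence": 1, "truth": 2, "peaks": 3,
    "marks": 4, "conservation": 5, "qpcr": 6, "traces": 7, "motif": 8,
}


def stream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-artifact random substream of a single seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GenomeConfig:
    n_chroms: int = 2
    chrom_length: int = 200_000


@dataclass
class GeneConfig:
    n_genes: int = 24
    exons_per_gene: int = 4
    exon_len: int = 600           # > profile span so windows fit in one exon
    intron_len: int = 2000
    gap: int = 4000               # intergenic spacing; keeps gap centers > 1 kb from TSSs

    @property
    def footprint(self) -> int:
        return self.exons_per_gene * self.exon_len + (self.exons_per_gene - 1) * self.intron_len


@dataclass
class PeakConfig:
    n_true_sites: int = 60
    site_len: int = 300
    jitter_sd: float = 10.0
    fp_per_replicate: int = 15
    fn_rate: float = 0.05
    true_score_mean: float = 300.0
    true_score_sd: float = 50.0
    decoy_score_mean: float = 60.0
    decoy_score_sd: float = 5.0


@dataclass
class MarkConfig:
    # mark name -> genomic category whose features carry enriched segments
    categories: dict = field(default_factory=lambda: {
        "H3K4me3": "promoter", "H3K27ac": "promoter",
        "H3K4me1": "intronic", "H3K36me3": "exonic",
        "H3K9me3": "intergenic", "H3K27me3": "intergenic",
        "CTCF": "intergenic",
    })
    enriched_mean: float = 50.0
    enriched_sd: float = 5.0
    background_mean: float = 5.0
    background_sd: float = 1.0
    background_segments: int = 40
    segment_pad: int = 100        # enriched segment extends this far past its feature


@dataclass
class MotifCfg:
    cluster_n: int = 4
    cluster_span: int = 130
    background_density: float = 1.0 / 180.0  # intronic E-box density, per bp


@dataclass
class ConservationConfig:
    baseline_mean: float = 0.0
    exon_mean: float = 1.0        # coding sequence is conserved above background
    element_mean: float = 2.0
    sd: float = 0.3
    tile: int = 25                # bedGraph segment size, bp
    element_len: int = 300
    binding_scale: float = 100.0  # MACS-score-like amplitude over the element


@dataclass
class QpcrConfig:
    # planted fold enrichments per amplicon
    true_folds: dict = field(default_factory=lambda: {
        "Stim1_int2_P0": 35.0, "Stim1_int2_E14": 100.0,
        "Stim1_int1": 2.0, "Stim1_int3": 2.0, "nontarget": 1.0,
    })
    ct_noise_sd: float = 0.2
    n_replicates: int = 6
    input_ct_base: float = 24.0
    control_percent_input: float = 0.05  # %input of the control antibody
    input_fraction: float = 0.10


@dataclass
class TraceConfig:
    n_cells: int = 30
    frame_interval_s: float = 6.0
    duration_s: float = 600.0
    tg_time_s: float = 100.0
    ca_time_s: float = 400.0
    soce_scale: dict = field(default_factory=lambda: {
        "control": 1.0, "knockdown": 1.4, "rescue": 1.0,
    })
    noise_sd: float = 1.0         # a.u., on raw intensity
    baseline_au: float = 100.0
    background_au: float = 20.0
    wave1_amp_au: float = 150.0
    wave2_amp_au: float = 100.0
    tau1_s: float = 30.0
    tau2_s: float = 40.0
    cell_scatter_sd: float = 0.10  # lognormal per-cell amplitude scatter


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    genes: GeneConfig = field(default_factory=GeneConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    marks: MarkConfig = field(default_factory=MarkConfig)
    motif: MotifCfg = field(default_factory=MotifCfg)
    conservation: ConservationConfig = field(default_factory=ConservationConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    traces: TraceConfig = field(default_factory=TraceConfig)

    def __post_init__(self):
        for name, val in [
            ("n_chroms", self.genome.n_chroms), ("chrom_length", self.genome.chrom_length),
            ("n_genes", self.genes.n_genes), ("exons_per_gene", self.genes.exons_per_gene),
            ("exon_len", self.genes.exon_len), ("n_true_sites", self.peaks.n_true_sites),
            ("site_len", self.peaks.site_len), ("n_cells", self.traces.n_cells),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be > 0, got {val}")
        if not 0 <= self.peaks.fn_rate < 1:
            raise ValueError(f"fn_rate must be in [0, 1), got {self.peaks.fn_rate}")
        ratio = self.traces.duration_s / self.traces.frame_interval_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("frame_interval_s must divide duration_s")
        for f in self.qpcr.true_folds.values():
            if f <= 0:
                raise ValueError(f"true fold enrichments must be > 0, got {f}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        kwargs = {}
        sections = {
            "genome": GenomeConfig, "genes": GeneConfig, "peaks": PeakConfig,
            "marks": MarkConfig, "motif": MotifCfg,
            "conservation": ConservationConfig, "qpcr": QpcrConfig, "traces": TraceConfig,
        }
        for key, val in raw.items():
            if key == "seed":
                kwargs["seed"] = int(val)
            elif key in sections:
                kwargs[key] = sections[key](**val)
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# annotation + sequence


@dataclass
class Annotation:
    models: list[GeneModel]
    sequences: dict[str, str]
    introns: list[tuple[str, int, int]]          # ground truth
    gene_starts: dict[str, int]                   # gene_id -> chrom offset


def make_annotation(cfg: SimConfig) -> Annotation:
    """Place non-overlapping multi-exon genes and draw random sequence."""
    g, gn = cfg.genes, cfg.genome
    unit = g.footprint + g.gap
    capacity_per_chrom = max(0, (gn.chrom_length - g.gap) // unit)
    if capacity_per_chrom * gn.n_chroms < g.n_genes:
        raise ValueError(
            f"{g.n_genes} genes of footprint {g.footprint} bp (+{g.gap} bp gaps) "
            f"do not fit in {gn.n_chroms} x {gn.chrom_length} bp"
        )
    rng = stream(cfg.seed, "annotation")
    seq_rng = stream(cfg.seed, "sequence")
    models, introns, gene_starts = [], [], {}
    for i in range(g.n_genes):
        chrom = f"chr{i // capacity_per_chrom + 1}"
        slot = i % capacity_per_chrom
        start = g.gap + slot * unit
        exons = tuple(
            (start + k * (g.exon_len + g.intron_len),
             start + k * (g.exon_len + g.intron_len) + g.exon_len)
            for k in range(g.exons_per_gene)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i:03d}"
        gm = GeneModel(gid, f"tx{i:03d}", chrom, strand, exons)
        models.append(gm)
        gene_starts[gid] = start
        introns.extend((chrom, s, e) for s, e in gm.introns)
    sequences = {
        f"chr{c + 1}": "".join(seq_rng.choice(BASES, size=gn.chrom_length))
        for c in range(gn.n_chroms)
    }
    return Annotation(models, sequences, introns, gene_starts)


# ---------------------------------------------------------------------------
# truth sites and replicate peaks


@dataclass
class TruthSite:
    interval: GenomicInterval
    category: str


def make_truth_sites(cfg: SimConfig, annotation: Annotation) -> list[TruthSite]:
    """Plant truth sites unambiguously: one category per site.

    Sites are centred on feature representatives chosen so that, even
    after boundary jitter, the midpoint category is unchanged: the TSS
    (promoter), the third exon's centre (exonic, > 1 kb from the TSS),
    the second intron's centre (intronic), and gap centres (intergenic).
    """
    g = cfg.genes
    half = cfg.peaks.site_len // 2
    n = cfg.peaks.n_true_sites
    per_cat = [n // 4 + (1 if i < n % 4 else 0) for i in range(4)]
    models = annotation.models
    needed = max(per_cat)
    if needed > len(models):
        raise ValueError(f"need {needed} genes for {n} truth sites, have {len(models)}")
    if g.exons_per_gene < 3 or g.intron_len < cfg.peaks.site_len + 400:
        raise ValueError("gene structure too small to plant unambiguous sites")
    sites: list[TruthSite] = []
    for i in range(per_cat[0]):  # promoter: centred at the TSS
        gm = models[i]
        c = gm.tss
        sites.append(TruthSite(GenomicInterval(gm.chrom, c - half, c + half), "promoter"))
    for i in range(per_cat[1]):  # exonic: centre of exon 3
        gm = models[i]
        s, e = gm.exons[2]
        c = (s + e) // 2
        sites.append(TruthSite(GenomicInterval(gm.chrom, c - half, c + half), "exonic"))
    for i in range(per_cat[2]):  # intronic: centre of intron 2
        gm = models[i]
        s, e = gm.introns[1]
        c = (s + e) // 2
        sites.append(TruthSite(GenomicInterval(gm.chrom, c - half, c + half), "intronic"))
    for i in range(per_cat[3]):  # intergenic: centre of the gap before gene i
        gm = models[i]
        c = annotation.gene_starts[gm.gene_id] - g.gap // 2
        sites.append(TruthSite(GenomicInterval(gm.chrom, c - half, c + half), "intergenic"))
    sites.sort(key=lambda t: t.interval.sort_key())
    for a, b in zip(sites, sites[1:]):
        if a.interval.overlaps(b.interval):
            raise ValueError("planted truth sites overlap; adjust gene/gap geometry")
    return sites


def make_replicate_peaks(
    cfg: SimConfig,
    truth_sites: list[TruthSite],
    n_replicates: int = 3,
) -> list[list[GenomicInterval]]:
    """Replicates = jittered truth sites (with dropout) plus decoys.

    Decoys are rejection-sampled to be disjoint from every truth site and
    from all decoys of every replicate, so a consensus over decoys alone
    is empty by construction.
    """
    p, gn = cfg.peaks, cfg.genome
    rng = stream(cfg.seed, "peaks")
    chroms = [f"chr{c + 1}" for c in range(gn.n_chroms)]
    margin = int(4 * p.jitter_sd) + 1
    blocked: list[GenomicInterval] = [
        GenomicInterval(t.interval.chrom,
                        max(0, t.interval.start - margin),
                        t.interval.end + margin)
        for t in truth_sites
    ]
    replicates: list[list[GenomicInterval]] = []
    for rep in range(n_replicates):
        peaks: list[GenomicInterval] = []
        for i, site in enumerate(truth_sites):
            if rng.random() < p.fn_rate:
                continue
            iv = site.interval
            s = max(0, int(round(iv.start + rng.normal(0, p.jitter_sd))))
            e = int(round(iv.end + rng.normal(0, p.jitter_sd)))
            if e <= s:
                e = s + 1
            score = max(50.0, rng.normal(p.true_score_mean, p.true_score_sd))
            peaks.append(GenomicInterval(iv.chrom, s, e, score=score, name=f"true{i:03d}"))
        for j in range(p.fp_per_replicate):
            for _ in range(10_000):
                chrom = chroms[int(rng.integers(len(chroms)))]
                s = int(rng.integers(0, gn.chrom_length - p.site_len))
                cand = GenomicInterval(chrom, s, s + p.site_len)
                if not any(cand.overlaps(b) for b in blocked):
                    break
            else:
                raise RuntimeError("could not place a disjoint decoy")
            score = max(50.0, rng.normal(p.decoy_score_mean, p.decoy_score_sd))
            peaks.append(GenomicInterval(cand.chrom, cand.start, cand.end,
                                         score=score, name=f"decoy_r{rep}_{j:03d}"))
            blocked.append(cand)
        peaks.sort(key=lambda x: x.sort_key())
        replicates.append(peaks)
    return replicates


# ---------------------------------------------------------------------------
# motif planting


def plant_ebox_cluster(
    seq: str, position: int, n: int, span: int, rng: np.random.Generator
) -> str:
    """Rewrite seq[position:position+span] to hold exactly ``n`` E-boxes.

    The window's non-motif bases are resampled until a scan of the window
    (with 5 bp of flanking context) finds exactly the planted occurrences,
    so no accidental CANNTG survives inside or across the window edges.
    """
    if span < 6 * n:
        raise ValueError(f"span {span} too small for {n} non-overlapping E-boxes")
    if position < 0 or position + span > len(seq):
        raise ValueError("window outside sequence")
    slack = span - 6 * n
    for _ in range(10_000):
        cuts = np.sort(rng.integers(0, slack + 1, size=n)) if n else np.array([], int)
        starts = [int(c) + 6 * k for k, c in enumerate(cuts)]
        window = rng.choice(BASES, size=span)
        for s in starts:
            nn = rng.choice(BASES, size=2)
            window[s:s + 6] = ["C", "A", nn[0], nn[1], "T", "G"]
        window_str = "".join(window)
        lo = max(0, position - 5)
        ctx = seq[lo:position] + window_str + seq[position + span:position + span + 5]
        hits = {h.position - (position - lo) for h in scan_eboxes(ctx)}
        if hits == set(starts):
            return seq[:position] + window_str + seq[position + span:]
    raise RuntimeError("could not plant E-box cluster without accidental hits")


@dataclass
class PlantedElement:
    chrom: str
    start: int            # conserved-element start
    end: int
    cluster_start: int    # E-box cluster window
    cluster_end: int
    ebox_positions: list[int]


def plant_element(cfg: SimConfig, annotation: Annotation) -> PlantedElement:
    """Plant the conserved, E-box-clustered element in intron 2 of gene 0.

    Mirrors the biology being emulated: a transcription-factor binding
    element inside an intron, carrying a cluster of E-boxes and elevated
    conservation, coinciding with the intronic truth site of gene 0.
    """
    gm = annotation.models[0]
    s, e = gm.introns[1]
    center = (s + e) // 2
    half = cfg.conservation.element_len // 2
    mstart = center - cfg.motif.cluster_span // 2
    rng = stream(cfg.seed, "motif")
    seq = annotation.sequences[gm.chrom]
    seq = plant_ebox_cluster(seq, mstart, cfg.motif.cluster_n, cfg.motif.cluster_span, rng)
    annotation.sequences[gm.chrom] = seq
    hits = [
        mstart + h.position
        for h in scan_eboxes(seq[mstart:mstart + cfg.motif.cluster_span])
    ]
    return PlantedElement(
        gm.chrom, center - half, center + half,
        mstart, mstart + cfg.motif.cluster_span, hits,
    )


# ---------------------------------------------------------------------------
# signal tracks


def make_tracks(
    cfg: SimConfig,
    annotation: Annotation,
    truth_sites: list[TruthSite],
    element: PlantedElement | None = None,
) -> tuple[dict[str, SignalTrack], SignalTrack, SignalTrack]:
    """Mark tracks, conservation track, and a binding-score track.

    Each mark's enriched segments cover every feature of its configured
    category (promoter windows, exons, introns, or intergenic gap
    centres); low-score background segments fill in elsewhere. The
    conservation track tiles the genome with baseline-mean noise,
    elevated to element-mean over the planted element; the binding track
    is a MACS-score-like plateau over the same element.
    """
    m, gn, g = cfg.marks, cfg.genome, cfg.genes
    rng = stream(cfg.seed, "marks")
    chrom_names = [f"chr{c + 1}" for c in range(gn.n_chroms)]

    features: dict[str, list[tuple[str, int, int]]] = {
        "promoter": [], "exonic": [], "intronic": [], "intergenic": []
    }
    for gm in annotation.models:
        t = gm.tss
        features["promoter"].append((gm.chrom, max(0, t - 1000), t + 1000))
        features["exonic"].extend((gm.chrom, s, e) for s, e in gm.exons)
        features["intronic"].extend((gm.chrom, s, e) for s, e in gm.introns)
        start = annotation.gene_starts[gm.gene_id]
        c = start - g.gap // 2
        features["intergenic"].append((gm.chrom, c - 500, c + 500))

    mark_tracks: dict[str, SignalTrack] = {}
    for name, category in m.categories.items():
        track = SignalTrack()
        placed: list[tuple[str, int, int]] = []
        for chrom, s, e in features[category]:
            s2, e2 = max(0, s - m.segment_pad), min(gn.chrom_length, e + m.segment_pad)
            track.add(chrom, s2, e2, max(0.1, rng.normal(m.enriched_mean, m.enriched_sd)),
                      _validate=False)
            placed.append((chrom, s2, e2))
        for _ in range(m.background_segments):
            for _try in range(10_000):
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                s = int(rng.integers(0, gn.chrom_length - 400))
                e = s + 400
                if not any(c == chrom and s < pe and ps < e for c, ps, pe in placed):
                    break
            else:
                continue
            track.add(chrom, s, e, max(0.1, rng.normal(m.background_mean, m.background_sd)),
                      _validate=False)
            placed.append((chrom, s, e))
        track._sort_and_validate()
        mark_tracks[name] = track

    cons_cfg = cfg.conservation
    crng = stream(cfg.seed, "conservation")
    exon_lookup: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for chrom, s, e in features["exonic"]:
        exon_lookup[chrom].append((s, e))
    conservation = SignalTrack()
    binding = SignalTrack()
    for chrom in chrom_names:
        exons_here = exon_lookup[chrom]
        for s in range(0, gn.chrom_length, cons_cfg.tile):
            e = min(s + cons_cfg.tile, gn.chrom_length)
            in_element = (
                element is not None and chrom == element.chrom
                and s < element.end and element.start < e
            )
            if in_element:
                mean = cons_cfg.element_mean
            elif any(s < xe and xs < e for xs, xe in exons_here):
                mean = cons_cfg.exon_mean
            else:
                mean = cons_cfg.baseline_mean
            conservation.add(chrom, s, e, crng.normal(mean, cons_cfg.sd), _validate=False)
            if in_element:
                binding.add(
                    chrom, s, e,
                    max(0.0, crng.normal(cons_cfg.binding_scale, cons_cfg.binding_scale * 0.05)),
                    _validate=False,
                )
    conservation._sort_and_validate()
    binding._sort_and_validate()
    return mark_tracks, conservation, binding


# ---------------------------------------------------------------------------
# qPCR tables


def make_ct_table(cfg: SimConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """Invert the percent-input arithmetic from planted fold enrichments.

    Per replicate: the input Ct sits at a base value; the control-antibody
    Ct is placed so the control recovers the configured %input; the
    target-antibody Ct is control Ct − log2(fold) + Gaussian noise.
    Returns (tidy Ct table, amplicon -> planted fold).
    """
    q = cfg.qpcr
    rng = stream(cfg.seed, "qpcr")
    adj = q.input_ct_base - np.log2(1.0 / q.input_fraction)
    control_ct = adj - np.log2(q.control_percent_input / 100.0)
    rows = []
    for amplicon, fold in q.true_folds.items():
        if fold <= 0:
            raise ValueError(f"true fold must be > 0, got {fold}")
        for rep in range(1, q.n_replicates + 1):
            target_ct = control_ct - np.log2(fold) + rng.normal(0.0, q.ct_noise_sd)
            rows.extend([
                {"sample_id": amplicon, "antibody": "input", "amplicon": amplicon,
                 "replicate": rep, "ct": float(q.input_ct_base)},
                {"sample_id": amplicon, "antibody": "control", "amplicon": amplicon,
                 "replicate": rep, "ct": float(control_ct)},
                {"sample_id": amplicon, "antibody": "target", "amplicon": amplicon,
                 "replicate": rep, "ct": float(target_ct)},
            ])
    return pd.DataFrame(rows), dict(q.true_folds)


# ---------------------------------------------------------------------------
# calcium traces


def _alpha(t: np.ndarray, t0: float, tau: float) -> np.ndarray:
    """Alpha-function wave shape, unit peak at t0 + tau."""
    dt = np.clip(t - t0, 0.0, None)
    return (dt / tau) * np.exp(1.0 - dt / tau)


def make_traces(cfg: SimConfig):
    """Two-wave fluorescence traces per condition, plus ground truth.

    Returns (list of FluorescenceTrace, ground truth dict holding the
    per-condition SOCE scale and per-cell amplitude multipliers).
    """
    from .soce import FluorescenceTrace

    tr = cfg.traces
    if tr.ca_time_s <= tr.tg_time_s:
        raise ValueError("ca_time_s must be after tg_time_s")
    rng = stream(cfg.seed, "traces")
    times = np.arange(0.0, tr.duration_s + tr.frame_interval_s / 2, tr.frame_interval_s)
    traces, truth_cells = [], {}
    for cond in sorted(tr.soce_scale):
        scale = tr.soce_scale[cond]
        for i in range(tr.n_cells):
            c1 = float(np.exp(rng.normal(0.0, tr.cell_scatter_sd)))
            c2 = float(np.exp(rng.normal(0.0, tr.cell_scatter_sd)))
            raw = (
                tr.baseline_au
                + c1 * tr.wave1_amp_au * _alpha(times, tr.tg_time_s, tr.tau1_s)
                + c2 * scale * tr.wave2_amp_au * _alpha(times, tr.ca_time_s, tr.tau2_s)
                + rng.normal(0.0, tr.noise_sd, size=times.shape)
            )
            cell = f"{cond}_{i:03d}"
            traces.append(
                FluorescenceTrace(times, raw, tr.background_au,
                                  tr.tg_time_s, tr.ca_time_s, cell, cond)
            )
            truth_cells[cell] = {"wave1_scale": c1, "wave2_scale": c2 * scale}
    truth = {"soce_scale": dict(tr.soce_scale), "cells": truth_cells}
    return traces, truth
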
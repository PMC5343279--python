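"""End-to-end orchestration: simulate inputs, then run every analysis
stage, writing a manifest with checksums and the exact configuration used.

Given a seed the whole run is byte-reproducible: rerunning with the same
configuration produces identical files and an identical manifest (the
manifest records content checksums, not timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotate as ann
from . import consensus as cons
from . import context as ctx
from . import io as cio
from . import motifs, qpcr, soce
from .simulate import (
    SimConfig, make_annotation, make_ct_table, make_replicate_peaks,
    make_traces, make_tracks, make_truth_sites, plant_element,
)

log = logging.getLogger("chipcal")

ALL_STAGES = (
    "simulate", "consensus", "annotate", "context",
    "motif", "conserve", "qpcr", "soce",
)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    promoter_halfwidth: int = 1000
    window: int = 50
    span: int = 550
    step: int = 1
    n_random_regions: int = 20
    input_fraction: float = 0.10
    early_s: float = 50.0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(raw.pop("sim", {}))
        stages = tuple(raw.pop("stages", ALL_STAGES))
        return cls(sim=sim, stages=stages, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the configured stages; return the manifest (also written to disk).

    Stages that later stages depend on are run implicitly when needed
    (everything consumes the simulated inputs). A failure aborts with an
    error naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {
        "simdir": outdir / "sim",
        "tg_ca": (config.sim.traces.tg_time_s, config.sim.traces.ca_time_s),
    }
    manifest: dict = {"config": config.sim.to_dict(), "stages": [], "files": {}}
    manifest["config"]["pipeline"] = {
        "promoter_halfwidth": config.promoter_halfwidth, "window": config.window,
        "span": config.span, "step": config.step,
        "n_random_regions": config.n_random_regions,
        "input_fraction": config.input_fraction, "early_s": config.early_s,
    }

    wanted = [s for s in ALL_STAGES if s in config.stages]
    for stage in wanted:
        t0 = time.monotonic()
        try:
            _STAGE_FUNCS[stage](config, outdir, state)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError(stage, exc) from exc
        log.info("stage %s: %.2f s", stage, time.monotonic() - t0)
        manifest["stages"].append(stage)

    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(outdir))] = _sha256(f)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    sim = cfg.sim
    d = outdir / "sim"
    d.mkdir(exist_ok=True)
    annotation = make_annotation(sim)
    element = plant_element(sim, annotation)
    truth = make_truth_sites(sim, annotation)
    reps = make_replicate_peaks(sim, truth)
    marks, conservation, binding = make_tracks(sim, annotation, truth, element)
    ct_table, folds = make_ct_table(sim)
    traces, trace_truth = make_traces(sim)

    cio.write_fasta(d / "genome.fa", annotation.sequences)
    cio.write_gene_models(d / "genes.bed12", annotation.models)
    for i, peaks in enumerate(reps, start=1):
        cio.write_peaks(d / f"rep{i}.bed", peaks)
    (d / "marks").mkdir(exist_ok=True)
    for name, track in marks.items():
        cio.write_track(d / "marks" / f"{name}.bedGraph", track)
    cio.write_track(d / "conservation.bedGraph", conservation)
    cio.write_track(d / "binding.bedGraph", binding)
    cio.write_ct_table(d / "qpcr_ct.csv", ct_table)
    frames = []
    import pandas as pd

    for tr in traces:
        frames.append(pd.DataFrame({
            "time_s": tr.times, "cell_id": tr.cell_id, "condition": tr.condition,
            "raw": np.round(tr.raw, 4), "background": tr.background,
        }))
    cio.write_trace_table(d / "traces.csv", pd.concat(frames, ignore_index=True))

    ground_truth = {
        "truth_sites": [
            {"chrom": t.interval.chrom, "start": t.interval.start,
             "end": t.interval.end, "category": t.category}
            for t in truth
        ],
        "element": {
            "chrom": element.chrom, "start": element.start, "end": element.end,
            "cluster_start": element.cluster_start, "cluster_end": element.cluster_end,
            "ebox_positions": element.ebox_positions,
        },
        "introns": [list(t) for t in annotation.introns],
        "qpcr_folds": folds,
        "trace_truth": trace_truth,
    }
    (d / "ground_truth.json").write_text(
        json.dumps(ground_truth, indent=2, sort_keys=True) + "\n"
    )
    state.update(
        annotation=annotation, element=element, truth=truth, reps=reps,
        marks=marks, conservation=conservation, binding=binding,
        ct_table=ct_table, traces=traces, simdir=d,
    )


def _require(state: dict, key: str, stage: str):
    """Fetch a stage input, falling back to files a previous run wrote."""
    if key in state:
        return state[key]
    loader = _LOADERS.get(key)
    if loader is None:
        raise RuntimeError(f"stage {stage!r}: no input {key!r}; run simulate first")
    try:
        state[key] = loader(state)
    except FileNotFoundError as exc:
        raise RuntimeError(
            f"stage {stage!r}: missing input file {exc.filename!r}"
        ) from exc
    return state[key]


def _simdir(state: dict) -> Path:
    d = state.get("simdir")
    if d is None or not Path(d).is_dir():
        raise FileNotFoundError(2, "no simulated inputs", str(d))
    return Path(d)


def _load_reps(state):
    d = _simdir(state)
    paths = sorted(d.glob("rep*.bed"))
    if not paths:
        raise FileNotFoundError(2, "no replicate peak files", str(d / "rep*.bed"))
    return [cio.read_peaks(p) for p in paths]


class _LoadedAnnotation:
    def __init__(self, d: Path):
        self.models = cio.read_gene_models(d / "genes.bed12")
        self.sequences = cio.read_fasta(d / "genome.fa")
        self.introns = [
            (m.chrom, s, e) for m in self.models for s, e in m.introns
        ]


def _load_element(state):
    gt = json.loads((_simdir(state) / "ground_truth.json").read_text())
    from .simulate import PlantedElement

    e = gt["element"]
    return PlantedElement(e["chrom"], e["start"], e["end"],
                          e["cluster_start"], e["cluster_end"], e["ebox_positions"])


def _load_consensus(state):
    reps = _require(state, "reps", "consensus")
    return cons.intersect_replicates(reps)


def _load_traces(state):
    df = cio.read_trace_table(_simdir(state) / "traces.csv")
    # event times come from the run configuration echoed into state
    tg, ca = state.get("tg_ca", (100.0, 400.0))
    return soce.traces_from_frame(df, tg, ca)


_LOADERS = {
    "reps": _load_reps,
    "annotation": lambda state: _LoadedAnnotation(_simdir(state)),
    "element": _load_element,
    "consensus": _load_consensus,
    "marks": lambda state: {
        p.stem: cio.read_track(p) for p in sorted((_simdir(state) / "marks").glob("*.bedGraph"))
    },
    "conservation": lambda state: cio.read_track(_simdir(state) / "conservation.bedGraph"),
    "binding": lambda state: cio.read_track(_simdir(state) / "binding.bedGraph"),
    "ct_table": lambda state: cio.read_ct_table(_simdir(state) / "qpcr_ct.csv"),
    "traces": _load_traces,
}


def _stage_consensus(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    reps = _require(state, "reps", "consensus")
    peaks = cons.intersect_replicates(reps)
    state["consensus"] = peaks
    cio.write_peaks(outdir / "consensus.bed", [p.interval for p in peaks])
    with open(outdir / "consensus_scores.tsv", "w") as fh:
        n = len(peaks[0].replicate_scores) if peaks else 3
        heads = "\t".join(f"score_rep{i+1}" for i in range(n))
        fh.write(f"chrom\tstart\tend\tmin_score\t{heads}\n")
        for p in peaks:
            scores = "\t".join(f"{s:g}" for s in p.replicate_scores)
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                     f"\t{p.min_score:g}\t{scores}\n")


def _stage_annotate(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    peaks = _require(state, "consensus", "annotate")
    models = _require(state, "annotation", "annotate").models
    annotations = ann.annotate_peaks(peaks, models, cfg.promoter_halfwidth)
    state["annotations"] = annotations
    ann.annotations_to_frame(annotations).to_csv(
        outdir / "annotations.tsv", sep="\t", index=False
    )
    ann.category_summary(annotations).to_csv(
        outdir / "category_summary.tsv", sep="\t", index=False, float_format="%.2f"
    )
    ann.tss_distance_histogram(annotations).to_csv(
        outdir / "tss_histogram.tsv", sep="\t", index=False
    )


def _stage_context(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    annotations = _require(state, "annotations", "context")
    marks = _require(state, "marks", "context")
    genome_size = cfg.sim.genome.n_chroms * cfg.sim.genome.chrom_length
    matrix = ctx.category_means(annotations, marks, genome_size=genome_size)
    matrix.to_csv(outdir / "context.tsv", sep="\t", float_format="%.4f")
    state["context"] = matrix


def _stage_motif(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    annotation = _require(state, "annotation", "motif")
    element = _require(state, "element", "motif")
    seq = annotation.sequences[element.chrom]
    window = seq[element.cluster_start:element.cluster_end]
    hits = motifs.scan_eboxes(window)
    intron_seqs = [annotation.sequences[c][s:e] for c, s, e in annotation.introns]
    density, bp_per_motif = motifs.background_density(intron_seqs)
    fold = motifs.cluster_enrichment(
        len(hits), element.cluster_end - element.cluster_start,
        cfg.sim.motif.background_density,
    )
    report = {
        "cluster_window": [element.cluster_start, element.cluster_end],
        "n_eboxes": len(hits),
        "ebox_positions": [element.cluster_start + h.position for h in hits],
        "intronic_density_per_bp": density,
        "intronic_bp_per_motif": bp_per_motif,
        "fold_enrichment_vs_configured_background": fold,
    }
    (outdir / "motif_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    state["motif_report"] = report


def _stage_conserve(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    element = _require(state, "element", "conserve")
    conservation = _require(state, "conservation", "conserve")
    binding = _require(state, "binding", "conserve")
    models = _require(state, "annotation", "conserve").models
    center = (element.start + element.end) // 2
    lo = center - cfg.span // 2
    cons_prof = motifs.track_profile(
        conservation, element.chrom, lo, lo + cfg.span, cfg.window, cfg.step
    )
    bind_prof = motifs.track_profile(
        binding, element.chrom, lo, lo + cfg.span, cfg.window, cfg.step
    )
    rho = motifs.profile_concordance(cons_prof, bind_prof)
    _, mean_ex = motifs.random_region_profiles(
        models, conservation, "exonic", n=cfg.n_random_regions,
        span=cfg.span, window=cfg.window, step=cfg.step,
        rng=np.random.default_rng(np.random.SeedSequence(cfg.sim.seed, spawn_key=(101,))),
    )
    _, mean_in = motifs.random_region_profiles(
        models, conservation, "intronic", n=cfg.n_random_regions,
        span=cfg.span, window=cfg.window, step=cfg.step,
        rng=np.random.default_rng(np.random.SeedSequence(cfg.sim.seed, spawn_key=(102,))),
    )
    with open(outdir / "profiles.tsv", "w") as fh:
        fh.write("window_midpoint\telement_conservation\telement_binding"
                 "\tmean_exonic_conservation\tmean_intronic_conservation\n")
        rel = cons_prof.midpoints - lo
        for i in range(len(rel)):
            fh.write(f"{rel[i]:g}\t{cons_prof.means[i]:.4f}\t{bind_prof.means[i]:.4f}"
                     f"\t{mean_ex.means[i]:.4f}\t{mean_in.means[i]:.4f}\n")
    (outdir / "concordance.json").write_text(
        json.dumps({"spearman_binding_vs_conservation": rho}, indent=2, sort_keys=True) + "\n"
    )
    state["concordance"] = rho


def _stage_qpcr(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    ct_table = _require(state, "ct_table", "qpcr")
    table = qpcr.enrichment_table(ct_table, input_fraction=cfg.input_fraction)
    table.to_csv(outdir / "enrichment.csv", index=False, float_format="%.4f")
    state["enrichment"] = table


def _stage_soce(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    traces = _require(state, "traces", "soce")
    metrics = [soce.wave_metrics(t, early_s=cfg.early_s) for t in traces]
    df = soce.metrics_frame(metrics)
    df.to_csv(outdir / "soce_metrics.csv", index=False, float_format="%.5f")
    summary, ratios = soce.cohort_summary(df)
    summary.to_csv(outdir / "soce_summary.csv", index=False, float_format="%.5f")
    ratios.to_csv(outdir / "soce_ratios.csv", index=False, float_format="%.5f")
    state["soce_summary"] = summary
    state["soce_ratios"] = ratios


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "consensus": _stage_consensus,
    "annotate": _stage_annotate,
    "context": _stage_context,
    "motif": _stage_motif,
    "conserve": _stage_conserve,
    "qpcr": _stage_qpcr,
    "soce": _stage_soce,
}
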
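import numpy as np
import pytest

from chipcal.consensus import intersect_replicates
from chipcal.motifs import scan_eboxes
from chipcal.simulate import (
    SimConfig, make_annotation, make_ct_table, make_replicate_peaks,
    make_traces, make_tracks, make_truth_sites, plant_ebox_cluster,
    plant_element, stream,
)


class TestConfig:
    def test_defaults_validate(self):
        SimConfig(seed=0)

    def test_fn_rate_range(self):
        with pytest.raises(ValueError, match="fn_rate"):
            SimConfig.from_dict({"peaks": {"fn_rate": 1.0}})

    def test_frame_interval_must_divide_duration(self):
        with pytest.raises(ValueError, match="divide"):
            SimConfig.from_dict({"traces": {"frame_interval_s": 7.0}})

    def test_dict_round_trip(self):
        cfg = SimConfig(seed=5)
        assert SimConfig.from_dict(cfg.to_dict()).to_dict() == cfg.to_dict()


class TestMakeAnnotation:
    def test_two_small_genes(self):
        cfg = SimConfig(seed=0)
        cfg.genes.n_genes = 2
        cfg.genes.exons_per_gene = 2
        ann = make_annotation(cfg)
        assert len(ann.models) == 2
        assert sum(len(m.introns) for m in ann.models) == 2

    def test_same_seed_identical(self):
        a = make_annotation(SimConfig(seed=7))
        b = make_annotation(SimConfig(seed=7))
        assert a.sequences == b.sequences
        assert a.models == b.models

    def test_genes_too_large_rejected(self):
        cfg = SimConfig(seed=0)
        cfg.genes.exon_len = 300_000
        with pytest.raises(ValueError, match="fit"):
            make_annotation(cfg)

    def test_intron_ground_truth_matches_models(self):
        ann = make_annotation(SimConfig(seed=0))
        expected = [(m.chrom, s, e) for m in ann.models for s, e in m.introns]
        assert ann.introns == expected


class TestReplicatePeaks:
    def test_noise_free_replicates_copy_truth(self, sim0):
        cfg = SimConfig(seed=0)
        cfg.peaks.fn_rate = 0.0
        cfg.peaks.fp_per_replicate = 0
        cfg.peaks.jitter_sd = 0.0
        truth = sim0["truth"]
        reps = make_replicate_peaks(cfg, truth)
        for rep in reps:
            assert [(p.start, p.end) for p in rep] == [
                (t.interval.start, t.interval.end) for t in truth
            ]

    def test_dropout_is_binomial(self, sim0):
        cfg = SimConfig(seed=1)
        cfg.peaks.fn_rate = 0.5
        cfg.peaks.fp_per_replicate = 0
        truth = sim0["truth"]  # 60 sites
        n = len(truth)
        reps = make_replicate_peaks(cfg, truth, n_replicates=20)
        sd = np.sqrt(n * 0.25)
        for rep in reps:
            assert abs(len(rep) - n * 0.5) < 4 * sd

    def test_decoys_alone_yield_empty_consensus(self, sim0):
        cfg = SimConfig(seed=2)
        reps = make_replicate_peaks(cfg, sim0["truth"])
        decoys = [[p for p in rep if p.name.startswith("decoy")] for rep in reps]
        assert intersect_replicates(decoys) == []

    def test_determinism(self, sim0):
        cfg = SimConfig(seed=0)
        a = make_replicate_peaks(cfg, sim0["truth"])
        b = make_replicate_peaks(cfg, sim0["truth"])
        assert a == b


class TestPlantEboxCluster:
    def test_plants_exactly_four_in_130(self):
        rng = stream(0, "motif")
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), size=1000))
        out = plant_ebox_cluster(seq, 400, 4, 130, rng)
        assert len(scan_eboxes(out[400:530])) == 4
        assert out[:400] == seq[:400] and out[530:] == seq[530:]

    def test_zero_motifs(self):
        rng = stream(0, "motif")
        seq = "".join(np.random.default_rng(2).choice(list("ACGT"), size=500))
        out = plant_ebox_cluster(seq, 100, 0, 130, rng)
        assert scan_eboxes(out[100:230]) == []

    def test_overfull_window_rejected(self):
        rng = stream(0, "motif")
        with pytest.raises(ValueError, match="too small"):
            plant_ebox_cluster("A" * 1000, 0, 22, 130, rng)

    def test_window_outside_sequence_rejected(self):
        rng = stream(0, "motif")
        with pytest.raises(ValueError, match="outside"):
            plant_ebox_cluster("A" * 100, 50, 2, 130, rng)

    def test_no_boundary_artifacts(self):
        """No accidental E-box spans the rewritten window's edges."""
        rng = stream(3, "motif")
        seq = "".join(np.random.default_rng(3).choice(list("ACGT"), size=1000))
        out = plant_ebox_cluster(seq, 400, 4, 130, rng)
        # window occupies [5, 135) of the scanned slice; a hit starting
        # before 5 or after 129 would cross a window edge
        hits = [h.position for h in scan_eboxes(out[395:535])]
        assert len(hits) == 4
        assert all(5 <= h <= 129 for h in hits)


class TestTracks:
    def test_promoter_mark_enriched_at_promoters(self, sim0):
        track = sim0["marks"]["H3K4me3"]
        models = sim0["annotation"].models
        prom_vals = [
            max(v for _, _, v in track.overlapping(m.chrom, m.tss - 500, m.tss + 500))
            for m in models
        ]
        assert np.mean(prom_vals) > 20.0

    def test_conservation_elevated_at_element(self, sim0):
        el = sim0["element"]
        cons = sim0["conservation"]
        elem = cons.per_bp(el.chrom, el.start, el.end).mean()
        away = cons.per_bp(el.chrom, el.end + 5000, el.end + 6000).mean()
        assert elem > away + 1.0

    def test_flat_when_element_matches_baseline(self):
        cfg = SimConfig(seed=0)
        cfg.conservation.element_mean = cfg.conservation.baseline_mean
        cfg.conservation.exon_mean = cfg.conservation.baseline_mean
        ann = make_annotation(cfg)
        el = plant_element(cfg, ann)
        truth = make_truth_sites(cfg, ann)
        _, cons, _ = make_tracks(cfg, ann, truth, el)
        elem = cons.per_bp(el.chrom, el.start, el.end).mean()
        away = cons.per_bp(el.chrom, el.end + 5000, el.end + 6000).mean()
        assert abs(elem - away) < 0.5  # within sampling noise of the tile sd

    def test_seeded_reproducibility(self, sim0):
        cfg = SimConfig(seed=0)
        marks, cons, bind = make_tracks(
            cfg, sim0["annotation"], sim0["truth"], sim0["element"]
        )
        assert cons == sim0["conservation"]
        assert bind == sim0["binding"]
        assert marks.keys() == sim0["marks"].keys()


class TestStreams:
    def test_substreams_differ(self):
        a = stream(0, "peaks").integers(0, 2**31, size=5)
        b = stream(0, "marks").integers(0, 2**31, size=5)
        assert not np.array_equal(a, b)

    def test_substreams_reproducible(self):
        a = stream(9, "qpcr").integers(0, 2**31, size=5)
        b = stream(9, "qpcr").integers(0, 2**31, size=5)
        assert np.array_equal(a, b)
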
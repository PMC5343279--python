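import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chipcal.intervals import SignalTrack
from chipcal.motifs import (
    MotifHit, background_density, cluster_enrichment, profile_concordance,
    random_region_profiles, scan_eboxes, sliding_profile, track_profile,
)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def brute_force_eboxes(seq: str) -> list[int]:
    out = []
    for i in range(len(seq) - 5):
        k = seq[i : i + 6]
        if k[0] == "C" and k[1] == "A" and k[4] == "T" and k[5] == "G" and "N" not in k:
            out.append(i)
    return out


class TestScanEboxes:
    def test_single_hit(self):
        (hit,) = scan_eboxes("CAGCTG")
        assert (hit.position, hit.seq) == (0, "CAGCTG")

    def test_overlapping_hits(self):
        hits = scan_eboxes("CACATGTG")
        assert [h.position for h in hits] == [0, 2]

    def test_no_overlap_mode(self):
        assert [h.position for h in scan_eboxes("CACATGTG", overlapping=False)] == [0]

    def test_n_never_matches(self):
        assert scan_eboxes("CANNTG") == []

    @given(st.text(alphabet="ACGTN", max_size=200))
    def test_matches_brute_force(self, seq):
        assert [h.position for h in scan_eboxes(seq)] == brute_force_eboxes(seq)

    @given(st.text(alphabet="ACGT", max_size=200))
    def test_reverse_complement_symmetry(self, seq):
        # CANNTG is its own reverse complement as a pattern class
        assert len(scan_eboxes(seq)) == len(scan_eboxes(revcomp(seq)))

    def test_motifhit_validates(self):
        with pytest.raises(ValueError):
            MotifHit(0, "AAAAAA")


class TestBackgroundDensity:
    def test_one_hit_per_180bp(self):
        # an intron engineered to one E-box per 180 bp
        unit = "CACGTG" + "A" * 174
        density, bp_per = background_density([unit * 50])
        assert density == pytest.approx(1 / 180)
        assert bp_per == pytest.approx(180.0)

    def test_motif_free_sequence(self):
        density, bp_per = background_density(["A" * 1000])
        assert density == 0.0
        assert bp_per == np.inf

    def test_pooling_over_sequences(self):
        unit = "CACGTG" + "A" * 174
        d_pooled, _ = background_density([unit * 10, "A" * 0 + unit * 5])
        d_single, _ = background_density([unit * 15])
        assert d_pooled == pytest.approx(d_single)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            background_density([])


class TestClusterEnrichment:
    def test_four_in_130_vs_intronic_background(self):
        # ~5.5-fold: "approximately fivefold" at the printed precision
        fold = cluster_enrichment(4, 130, 1 / 180)
        assert fold == pytest.approx(4 / 130 * 180)
        assert fold == pytest.approx(5.54, abs=0.005)

    def test_expectation_gives_unity(self):
        d = 1 / 180
        assert cluster_enrichment(int(d * 3600), 3600, d) == pytest.approx(1.0)

    def test_doubling_window_halves_fold(self):
        assert cluster_enrichment(4, 260, 1 / 180) == pytest.approx(
            cluster_enrichment(4, 130, 1 / 180) / 2
        )

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            cluster_enrichment(4, 130, 0.0)


def naive_profile(values, window, step):
    means = []
    for s in range(0, len(values) - window + 1, step):
        means.append(float(np.mean(values[s : s + window])))
    return np.array(means)


class TestSlidingProfile:
    def test_constant_series(self):
        prof = sliding_profile(np.full(550, 3.5), window=50)
        assert np.allclose(prof.means, 3.5)

    def test_window_count_550_50_1(self):
        prof = sliding_profile(np.zeros(550), window=50, step=1)
        assert len(prof.means) == 501
        assert np.all(np.diff(prof.midpoints) > 0)

    @pytest.mark.parametrize("window,step", [(50, 1), (50, 10), (7, 3), (1, 1)])
    def test_matches_naive_oracle(self, window, step):
        rng = np.random.default_rng(11)
        values = rng.normal(size=550)
        prof = sliding_profile(values, window=window, step=step)
        assert np.allclose(prof.means, naive_profile(values, window, step), atol=1e-9)

    def test_step_function_moving_average(self):
        values = np.concatenate([np.zeros(275), np.full(275, 10.0)])
        prof = sliding_profile(values, window=50)
        assert np.allclose(prof.means, naive_profile(values, 50, 1), atol=1e-9)

    def test_span_smaller_than_window_rejected(self):
        with pytest.raises(ValueError, match="span"):
            sliding_profile(np.zeros(40), window=50)

    def test_track_expansion_fills_uncovered_with_zero(self):
        track = SignalTrack({"chr1": [(100, 150, 2.0)]})
        prof = track_profile(track, "chr1", 100, 200, window=100, step=1)
        assert prof.means[0] == pytest.approx(1.0)  # half covered at 2.0


class TestProfileConcordance:
    def test_self_correlation(self):
        prof = sliding_profile(np.random.default_rng(0).normal(size=200), window=20)
        assert profile_concordance(prof, prof) == pytest.approx(1.0)

    def test_negation(self):
        values = np.random.default_rng(1).normal(size=200)
        a = sliding_profile(values, window=20)
        b = sliding_profile(-values, window=20)
        assert profile_concordance(a, b) == pytest.approx(-1.0)

    def test_grid_mismatch_rejected(self):
        a = sliding_profile(np.zeros(100), window=10)
        b = sliding_profile(np.zeros(100), window=20)
        with pytest.raises(ValueError, match="grid"):
            profile_concordance(a, b)

    def test_planted_element_concordance(self, sim0):
        """Binding and conservation co-elevated at the planted element."""
        el = sim0["element"]
        center = (el.start + el.end) // 2
        lo = center - 275
        cons = track_profile(sim0["conservation"], el.chrom, lo, lo + 550)
        bind = track_profile(sim0["binding"], el.chrom, lo, lo + 550)
        assert profile_concordance(cons, bind) > 0.8


class TestRandomRegionProfiles:
    def test_single_region_mean_is_itself(self, sim0):
        profs, mean = random_region_profiles(
            sim0["annotation"].models, sim0["conservation"], "intronic",
            n=1, seed=5,
        )
        assert np.allclose(profs[0].means, mean.means)

    def test_seeded_determinism(self, sim0):
        args = (sim0["annotation"].models, sim0["conservation"], "intronic")
        _, a = random_region_profiles(*args, n=5, seed=9)
        _, b = random_region_profiles(*args, n=5, seed=9)
        assert np.array_equal(a.means, b.means)

    def test_exons_more_conserved_than_introns(self, sim0):
        """Planted exon conservation shows up in the averaged profiles."""
        models = sim0["annotation"].models
        _, ex = random_region_profiles(models, sim0["conservation"], "exonic", n=20, seed=3)
        _, intr = random_region_profiles(models, sim0["conservation"], "intronic", n=20, seed=3)
        assert ex.means.mean() > intr.means.mean() + 0.5

    def test_insufficient_candidates_rejected(self, sim0):
        with pytest.raises(ValueError, match="regions"):
            random_region_profiles(
                sim0["annotation"].models, sim0["conservation"], "exonic",
                n=10_000, seed=0,
            )
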
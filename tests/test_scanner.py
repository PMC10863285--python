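"""Scanning arithmetic, site calling, variant locality, landscape statistics."""

import numpy as np
import pytest
from scipy import stats

from ssbscan.scanner import (
    ScoreTrack,
    SpeciesLandscape,
    build_species_landscape,
    call_putative_sites,
    cpg_ssb_correlation,
    n_windows,
    normalized_genome_sampling,
    scan_sequence,
    variant_delta_track,
)
from ssbscan.seqcore import GenomeSequence, write_bedgraph, read_bedgraph


def _genome(n, seed=0, name="chrT"):
    rng = np.random.default_rng(seed)
    return GenomeSequence(name, "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)]))


class TestScanArithmetic:
    @pytest.mark.parametrize("length,stride,expected",
                             [(300, 1, 50), (251, 1, 1), (300, 10, 5)])
    def test_window_counts(self, tiny_model, length, stride, expected):
        track = scan_sequence(tiny_model, _genome(length), stride=stride)
        assert len(track.scores) == expected
        assert len(track.scores) == n_windows(length, 251, stride)

    def test_window_count_closed_form_property(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            length = int(rng.integers(251, 5000))
            stride = int(rng.integers(1, 50))
            starts = list(range(0, length - 251 + 1, stride))
            assert n_windows(length, 251, stride) == len(starts)

    def test_too_short_sequence_raises(self, tiny_model):
        with pytest.raises(ValueError):
            scan_sequence(tiny_model, _genome(250))

    def test_scores_bounded_and_deterministic(self, tiny_model):
        genome = _genome(400)
        a = scan_sequence(tiny_model, genome)
        b = scan_sequence(tiny_model, genome)
        assert np.array_equal(a.scores, b.scores)
        assert a.scores.min() >= 0 and a.scores.max() <= 1

    def test_n_windows_flagged(self, tiny_model):
        genome = GenomeSequence("c", "A" * 400 + "N" + "A" * 400)
        track = scan_sequence(tiny_model, genome)
        flagged = {i for i, c in enumerate(track.centers)
                   if abs(int(c) - 400) <= 125}
        assert {i for i in range(len(track.scores)) if track.has_n[i]} == flagged
        assert track.has_n.any() and not track.has_n.all()


class TestCallSites:
    def test_threshold_selects_middle_center(self):
        track = ScoreTrack("chr1", 0, np.array([0.1, 0.9, 0.4]))
        sites = call_putative_sites(track, 0.5)
        assert len(sites) == 1 and sites[0].position == 126

    def test_zero_threshold_calls_everything(self):
        track = ScoreTrack("chr1", 0, np.array([0.1, 0.9, 0.4]))
        assert len(call_putative_sites(track, 0.0)) == 3

    def test_no_calls_below_threshold(self):
        track = ScoreTrack("chr1", 0, np.array([0.1, 0.2]))
        assert call_putative_sites(track, 0.5) == []


class TestVariantDelta:
    def test_identity_substitution_gives_zero_delta(self, tiny_model):
        genome = _genome(800)
        pos = 400
        delta = variant_delta_track(tiny_model, genome, "chrT", pos,
                                    genome.residues[pos], genome.residues[pos])
        assert np.array_equal(delta.delta, np.zeros_like(delta.delta))

    def test_nonzero_deltas_confined_to_overlapping_windows(self, tiny_model):
        genome = _genome(900, seed=2)
        pos = 450
        ref = genome.residues[pos]
        alt = "A" if ref != "A" else "C"
        delta = variant_delta_track(tiny_model, genome, "chrT", pos, ref, alt)
        centers = delta.ref_track.centers
        outside = np.abs(centers - pos) > 125
        assert np.array_equal(delta.delta[outside], np.zeros(outside.sum()))
        assert len(delta.delta) == 501 - 251 + 1

    def test_reference_mismatch_raises(self, tiny_model):
        genome = GenomeSequence("chrT", "A" * 600)
        with pytest.raises(ValueError, match="reference check"):
            variant_delta_track(tiny_model, genome, "chrT", 300, "C", "G")


class TestNormalizedSampling:
    def test_bounds_and_count(self):
        genome = _genome(10_000, seed=3)
        starts, seqs = normalized_genome_sampling(genome, n=1000, L=251, seed=1)
        assert len(starts) == len(seqs) == 1000
        assert starts.min() >= 0 and starts.max() <= 10_000 - 251
        assert all(len(s) == 251 for s in seqs)

    def test_same_seed_identical(self):
        genome = _genome(5000, seed=4)
        a, _ = normalized_genome_sampling(genome, n=200, L=251, seed=9)
        b, _ = normalized_genome_sampling(genome, n=200, L=251, seed=9)
        assert np.array_equal(a, b)

    def test_n_windows_resampled(self):
        residues = "A" * 1000 + "N" * 300 + "C" * 1000
        genome = GenomeSequence("c", residues)
        _, seqs = normalized_genome_sampling(genome, n=300, L=251, seed=2)
        assert all("N" not in s for s in seqs)

    def test_uniformity_chi_square(self):
        genome = _genome(10_251, seed=5)
        starts, _ = normalized_genome_sampling(genome, n=10_000, L=251, seed=3)
        counts, _ = np.histogram(starts, bins=10, range=(0, 10_000))
        chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
        # 10 bins -> 9 dof; reject only below alpha = 0.001
        assert chi2 < stats.chi2.ppf(0.999, df=9)

    def test_short_chromosome_raises(self):
        with pytest.raises(ValueError):
            normalized_genome_sampling(GenomeSequence("c", "ACGT"), n=5, L=251)


class TestCorrelation:
    def _ls(self, species, cpg, count):
        return SpeciesLandscape(species, 1000, count, cpg)

    def test_perfect_positive(self):
        ls = [self._ls("a", 1, 2), self._ls("b", 2, 4), self._ls("c", 3, 6)]
        r, p = cpg_ssb_correlation(ls)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        ls = [self._ls("a", 1, 3), self._ls("b", 2, 2), self._ls("c", 3, 1)]
        r, _ = cpg_ssb_correlation(ls)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        # x=(1,2,3), y=(1,3,2): cov = 0.5, sd_x = sd_y = 1 -> r = 0.5
        ls = [self._ls("a", 1, 1), self._ls("b", 2, 3), self._ls("c", 3, 2)]
        r, _ = cpg_ssb_correlation(ls)
        assert r == pytest.approx(0.5)

    def test_degenerate_variance_raises(self):
        ls = [self._ls("a", 1, 2), self._ls("b", 1, 4), self._ls("c", 1, 6)]
        with pytest.raises(ValueError):
            cpg_ssb_correlation(ls)

    def test_too_few_species_raises(self):
        with pytest.raises(ValueError):
            cpg_ssb_correlation([self._ls("a", 1, 2), self._ls("b", 2, 4)])


class TestTrainedModelIntegration:
    def test_landscape_correlation_positive_across_gc_gradient(self, benchmark_run):
        """Predicted break counts rise with CpG content across synthetic species."""
        from ssbscan.simgen import SimConfig, generate_background_genome

        model = benchmark_run.model
        landscapes = []
        for i, gc in enumerate((0.30, 0.38, 0.46, 0.54, 0.62)):
            at = (1.0 - gc) / 2.0
            cfg = SimConfig(genome_length=100_000, n_chromosomes=2, n_sites=3,
                            min_site_spacing=300,
                            composition=(at, gc / 2.0, gc / 2.0, at),
                            seed=1000 + i)
            genome = generate_background_genome(cfg)["chr1"]
            landscapes.append(build_species_landscape(
                model, genome, f"gc{gc:.2f}", n=600, seed=i))
        r, _ = cpg_ssb_correlation(landscapes)
        assert r > 0

    def test_snp_destroying_planted_motif_has_negative_delta(self, benchmark_run):
        """Breaking the central GGC of a true site drops its predicted score."""
        model = benchmark_run.model
        bundle = benchmark_run.bundle
        site = next(s for s in bundle.sites if s.chrom == "chr1")
        genome = bundle.genomes["chr1"]
        assert genome.residues[site.position - 1 : site.position + 2] == "GGC"
        delta = variant_delta_track(model, genome, "chr1", site.position,
                                    genome.residues[site.position], "A")
        i = int(np.where(delta.ref_track.centers == site.position)[0][0])
        assert delta.delta[i] < 0


class TestLandscapeAndTrackIO:
    def test_species_landscape_counts(self, tiny_model):
        genome = _genome(4000, seed=6)
        ls = build_species_landscape(tiny_model, genome, "toy", n=50, seed=1)
        assert ls.n_windows == 50
        assert 0 <= ls.ssb_count <= 50
        assert ls.mean_cpg > 0

    def test_track_bedgraph_round_trip(self, tiny_model, tmp_path):
        track = scan_sequence(tiny_model, _genome(300, seed=7))
        path = tmp_path / "t.bedGraph"
        write_bedgraph(track.chrom, track.centers, track.scores, path)
        records = read_bedgraph(path)
        got = np.array([r[3] for r in records])
        assert np.allclose(got, track.scores, atol=5e-7)
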
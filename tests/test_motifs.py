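"""PWM scoring, the per-site motif predicate, and the fraction report."""

import numpy as np
import pytest

import oxichip as ox

REVCOMP = str.maketrans("ACGT", "TGCA")


@pytest.fixture(scope="module")
def pwm() -> ox.PWM:
    return ox.make_informative_pwm()


class TestBestLogOdds:
    def test_consensus_attains_max_score(self, pwm):
        assert ox.best_log_odds(pwm, pwm.consensus) == pytest.approx(pwm.max_score)

    def test_reverse_complement_scores_identically(self, pwm):
        rc = pwm.consensus.translate(REVCOMP)[::-1]
        assert ox.best_log_odds(pwm, rc) == pytest.approx(pwm.max_score)

    def test_uniform_pwm_scores_zero_everywhere(self):
        flat = ox.PWM(name="flat", counts=np.full((6, 4), 10.0))
        rng = np.random.default_rng(5)
        for _ in range(5):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
            assert ox.best_log_odds(flat, seq) == pytest.approx(0.0, abs=1e-12)

    def test_embedded_consensus_found_at_any_offset(self, pwm):
        rng = np.random.default_rng(7)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        seq = flank[:13] + pwm.consensus + flank[13:]
        assert ox.best_log_odds(pwm, seq) == pytest.approx(pwm.max_score)

    def test_n_bases_score_as_background(self, pwm):
        assert ox.best_log_odds(pwm, "N" * len(pwm)) == pytest.approx(0.0, abs=1e-12)

    def test_sequence_shorter_than_motif_rejected(self, pwm):
        with pytest.raises(ValueError, match="shorter than motif"):
            ox.best_log_odds(pwm, "ACGT")


class TestSiteHasMotif:
    def test_planted_consensus_detected(self, single_run, pwm):
        planted = single_run.truth[single_run.truth["has_motif"]]
        params = ox.MotifScanParams(seed=0, background_samples=0)
        for row in planted.itertuples(index=False):
            assert ox.site_has_motif(pwm, single_run.genome, row.chrom, row.center, params)

    def test_zero_threshold_always_hits(self, toy_genome, pwm):
        params = ox.MotifScanParams(threshold_fraction=0.0, seed=0)
        assert ox.site_has_motif(pwm, toy_genome, "chrT", 5000, params)

    def test_raising_threshold_never_creates_hits(self, toy_genome, pwm):
        rng = np.random.default_rng(11)
        centers = rng.integers(200, 9800, 50)
        previous = None
        for thr in (0.5, 0.7, 0.9, 1.0):
            params = ox.MotifScanParams(threshold_fraction=thr, seed=0)
            hits = {
                int(c)
                for c in centers
                if ox.site_has_motif(pwm, toy_genome, "chrT", int(c), params)
            }
            if previous is not None:
                assert hits <= previous
            previous = hits

    def test_window_truncated_at_chromosome_end(self, toy_genome, pwm):
        params = ox.MotifScanParams(seed=0)
        # center 10 bases from the end: window truncates but still >= motif
        assert isinstance(
            ox.site_has_motif(pwm, toy_genome, "chrT", 9950, params), bool
        )

    def test_truncation_below_motif_length_rejected(self, pwm):
        tiny = ox.GenomeModel(chroms=[("c", 30)], sequences={"c": "A" * 30})
        params = ox.MotifScanParams(scan_window=200, seed=0)
        # whole chromosome (30 bp) is longer than the motif, so use a custom
        # genome whose remaining stretch is too short
        micro = ox.GenomeModel(chroms=[("c", 10)], sequences={"c": "A" * 10})
        with pytest.raises(ValueError, match="shorter than motif"):
            ox.site_has_motif(pwm, micro, "c", 5, params)
        assert isinstance(ox.site_has_motif(pwm, tiny, "c", 15, params), bool)

    def test_random_window_hit_rate_is_low(self, pwm):
        # Monte-Carlo over random windows at the default 0.8 threshold
        rng = np.random.default_rng(17)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2_000_000))
        genome = ox.GenomeModel(chroms=[("chrR", 2_000_000)], sequences={"chrR": seq})
        params = ox.MotifScanParams(seed=23, background_samples=10_000)
        rate = ox.background_motif_fraction(pwm, genome, params)
        assert rate < 0.02

    def test_genome_reverse_complement_leaves_calls_unchanged(self, pwm):
        rng = np.random.default_rng(29)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        fwd = ox.GenomeModel(chroms=[("c", 5000)], sequences={"c": seq})
        rev = ox.GenomeModel(
            chroms=[("c", 5000)], sequences={"c": seq.translate(REVCOMP)[::-1]}
        )
        params = ox.MotifScanParams(seed=0)
        for center in rng.integers(150, 4850, 40):
            center = int(center)
            mirrored = 5000 - center  # same physical window on the flipped strand
            assert ox.site_has_motif(pwm, fwd, "c", center, params) == ox.site_has_motif(
                pwm, rev, "c", mirrored, params
            )


class TestFractionReport:
    def test_saturated_when_consensus_at_every_site(self, pwm):
        L = len(pwm)
        block = ("AC" * 200)[:300]
        seq = "".join(
            block[: 150 - L // 2] + pwm.consensus + block[150 - L // 2 + L :]
            for _ in range(10)
        )
        genome = ox.GenomeModel(chroms=[("c", len(seq))], sequences={"c": seq})
        sites = [ox.Peak("c", i * 300 + 100, i * 300 + 200) for i in range(10)]
        params = ox.MotifScanParams(seed=3, background_samples=500)
        report = ox.motif_fraction_report(sites, pwm, genome, params)
        assert report.loc[report["class"] == "all", "fraction"].item() == 1.0

    def test_identical_seed_identical_background(self, single_run, pwm):
        params = ox.MotifScanParams(seed=99, background_samples=1000)
        sites = single_run.results.sites.head(5)
        a = ox.motif_fraction_report(sites, pwm, single_run.genome, params)
        b = ox.motif_fraction_report(sites, pwm, single_run.genome, params)
        assert a["background_fraction"].equals(b["background_fraction"])

    def test_empty_sites_rejected(self, toy_genome, pwm):
        with pytest.raises(ValueError, match="empty"):
            ox.motif_fraction_report([], pwm, toy_genome)
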
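"""The window/fold/p classification rule and its exact test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oxichip as ox
from oxichip.differential import SCALE


def reads_at(midpoints, chrom="chrT"):
    """ReadSet whose read midpoints are exactly *midpoints*."""
    return ox.ReadSet([(chrom, m, m + 1, "+") for m in midpoints])


class TestWindowCount:
    def test_half_open_boundary_semantics(self):
        # window 200 at center 100 covers [0, 200): 199 in, 200 out
        rs = reads_at([150, 199, 200])
        assert ox.window_count(rs, "chrT", 100, 200) == 2

    def test_empty_readset(self):
        assert ox.window_count(reads_at([]), "chrT", 100, 200) == 0

    def test_odd_window_rejected(self):
        with pytest.raises(ValueError, match="even"):
            ox.window_count(reads_at([10]), "chrT", 100, 3)


class TestDifferentialPvalue:
    def test_balanced_counts_give_one(self):
        assert ox.differential_pvalue(5, 5, 1000, 1000) == 1.0

    def test_one_sided_extreme_hand_summed(self):
        # all 10 reads in B at equal depths: two tail atoms of 0.5^10 each
        assert ox.differential_pvalue(0, 10, 1000, 1000) == pytest.approx(
            2 * 0.5**10, abs=1e-15
        )

    def test_empty_window_returns_one(self):
        assert ox.differential_pvalue(0, 0, 1000, 1000) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ox.differential_pvalue(-1, 5, 1000, 1000)

    @settings(derandomize=True, max_examples=200)
    @given(
        ca=st.integers(0, 500),
        cb=st.integers(0, 500),
        da=st.integers(1, 10**7),
        db=st.integers(1, 10**7),
    )
    def test_swap_symmetry_and_range(self, ca, cb, da, db):
        p = ox.differential_pvalue(ca, cb, da, db)
        q = ox.differential_pvalue(cb, ca, db, da)
        # mathematically p > 0; extreme imbalances may underflow to 0.0
        assert 0 <= p <= 1
        assert p == pytest.approx(q, rel=1e-9)


class TestFoldChange:
    def test_symmetry_gives_unity(self):
        assert ox.fold_change(7, 7, 500, 500) == 1.0

    def test_zero_counts_pseudocount_only(self):
        assert ox.fold_change(0, 0, 10**6, 10**6) == 1.0

    def test_stated_formula(self):
        # (40 + 1) / (10 + 1) at depths of ten million
        assert ox.fold_change(10, 40, 10**7, 10**7, pseudocount=1.0) == pytest.approx(
            41 / 11
        )

    @settings(derandomize=True, max_examples=100)
    @given(
        ca=st.integers(0, 1000),
        cb=st.integers(0, 1000),
        da=st.integers(1, 10**6),
        db=st.integers(1, 10**6),
        m=st.integers(1, 50),
    )
    def test_depth_and_count_scaling_invariance(self, ca, cb, da, db, m):
        f1 = ox.fold_change(ca, cb, da, db)
        f2 = ox.fold_change(ca * m, cb * m, da * m, db * m)
        assert f2 == pytest.approx(f1, rel=1e-12)


class TestClassifySite:
    @pytest.mark.parametrize(
        "fold, p, label",
        [
            (4.0, 1e-4, "induced"),  # both thresholds inclusive
            (0.25, 1e-4, "repressed"),
            (3.9, 1e-10, "common"),
            (0.26, 1e-10, "common"),
            (100.0, 2e-4, "common"),
            (0.25, 1e-6, "repressed"),
        ],
    )
    def test_inclusive_thresholds(self, fold, p, label):
        assert ox.classify_site(fold, p) == label


class TestCompareConditions:
    def test_partition_and_sorted_output(self, single_run):
        res = single_run.results
        counts = res.class_counts
        assert sum(counts.values()) == res.n_sites
        sites = res.sites
        assert list(sites.sort_values(["chrom", "center"]).index) == list(sites.index)

    def test_condition_swap_flips_labels_sitewise(self, single_run):
        m = single_run
        swapped = ox.compare_conditions(
            m.results.model.peaks_b,
            m.results.model.peaks_a,
            m.results.model.reads_b,
            m.results.model.reads_a,
        )
        a, b = m.results.sites, swapped.sites
        assert (a["center"] == b["center"]).all()
        flip = {"induced": "repressed", "repressed": "induced", "common": "common"}
        assert (a["label"].map(flip) == b["label"]).all()
        np.testing.assert_allclose(a["fold_change"] * b["fold_change"].to_numpy(),
                                   np.ones(len(a)), rtol=1e-9)

    def test_empty_condition_b_peaks_still_evaluates(self, single_run):
        m = single_run
        res = ox.compare_conditions(
            m.results.model.peaks_a, [], m.results.model.reads_a, m.results.model.reads_b
        )
        assert res.n_sites > 0
        assert set(res.sites["label"]) <= {"induced", "repressed", "common"}

    def test_merged_centers_separated_by_half_window(self, single_run):
        sites = single_run.results.sites
        for _, sub in sites.groupby("chrom"):
            assert (np.diff(sub["center"].to_numpy()) >= 100).all()

    def test_scaling_counts_never_loses_significance(self):
        params = ox.DiffParams()
        for ca, cb in [(10, 90), (3, 47), (50, 9), (0, 30)]:
            base = ox.classify_site(
                ox.fold_change(ca, cb, 10**5, 10**5),
                ox.differential_pvalue(ca, cb, 10**5, 10**5),
                params,
            )
            scaled = ox.classify_site(
                ox.fold_change(ca * 100, cb * 100, 10**7, 10**7),
                ox.differential_pvalue(ca * 100, cb * 100, 10**7, 10**7),
                params,
            )
            if base != "common":
                assert scaled == base

    def test_summary_and_volcano_table(self, single_run):
        res = single_run.results
        text = res.summary()
        assert "induced" in text and str(res.n_sites) in text
        volcano = res.volcano_table()
        assert {"log2_fold", "neg_log10_p"} <= set(volcano.columns)
        assert len(volcano) == res.n_sites
        assert (volcano["neg_log10_p"] >= 0).all()
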
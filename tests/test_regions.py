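import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methkey import abnormal_density, bin_profile, bin_rd, key_bin_filter, promoter_bin
from methkey.methylation import condition_means
from methkey.regions import KEY_BINS, PROMOTER_BINS, RegionBins

from conftest import random_beta_setup, tiny_sheet


class TestPromoterBin:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (10_001, 16),   # first position downstream of the TSS: bin 16 = (0, 100]
            (10_100, 16),
            (10_101, 17),
            (10_000, 15),   # the TSS itself closes bin 15 = (-100, 0]
            (9_801, 14),    # bin 14 opens at -200
            (9_800, 13),
            (10_200, 17),   # bin 17 closes at +200: bins 14-17 = (-200, +200]
            (8_500, 1),     # upstream promoter edge folds into bin 1
            (11_500, 30),
            (11_501, None),
            (8_499, None),
        ],
    )
    def test_plus_strand_boundaries(self, pos, expected):
        assert promoter_bin(pos, tss=10_000, strand="+") == expected

    def test_minus_strand_mirror_example(self):
        # 50 bp downstream of a minus-strand TSS lies at a smaller coordinate
        assert promoter_bin(9_950, tss=10_000, strand="-") == 16

    @given(offset=st.integers(-1500, 1500))
    def test_every_promoter_position_maps_to_exactly_one_bin(self, offset):
        for strand in "+-":
            mu = promoter_bin(10_000 + offset, 10_000, strand)
            assert mu is not None and 1 <= mu <= PROMOTER_BINS

    @given(offset=st.integers(-1499, 1500).filter(lambda o: o % 100 != 0))
    def test_strand_mirror_for_interior_offsets(self, offset):
        """Reversing the strand maps bin mu to 31 - mu for the same position."""
        pos = 50_000 + offset
        mu_plus = promoter_bin(pos, 50_000, "+")
        mu_minus = promoter_bin(pos, 50_000, "-")
        assert mu_plus + mu_minus == PROMOTER_BINS + 1


class TestRegionBins:
    def test_even_split_of_1kb_utr(self):
        rb = RegionBins([(1_001, 2_000)], "+")
        assert rb.bin(1_001) == 1 and rb.bin(1_100) == 1
        assert rb.bin(1_101) == 2
        assert rb.bin(2_000) == 10

    def test_minus_strand_runs_backwards(self):
        rb = RegionBins([(1_001, 2_000)], "-")
        assert rb.bin(2_000) == 1 and rb.bin(1_001) == 10

    def test_concatenated_intervals(self):
        # two 500 bp exons: 1000 bp total, bins of 100 laid over the concatenation
        rb = RegionBins([(1_001, 1_500), (9_001, 9_500)], "+")
        assert rb.bin(1_500) == 5
        assert rb.bin(9_001) == 6  # continues where the first interval stopped
        assert rb.bin(5_000) is None

    def test_short_region_leaves_empty_bins(self):
        rb = RegionBins([(100, 104)], "+")  # length 5 < 10 bins
        bins = {rb.bin(p) for p in range(100, 105)}
        assert bins == {1, 2, 3, 4, 5}

    def test_last_bin_absorbs_remainder(self):
        rb = RegionBins([(1, 105)], "+")  # 105 bp -> bin length 10, last bin 15 bp
        assert rb.bin(105) == 10 and rb.bin(91) == 10


class TestBinProfile:
    def test_bin_mean_of_condition_means(self):
        sheet = tiny_sheet(2, 1)
        from test_methylation import annotation_for, beta_at

        bm = beta_at(
            [10_010, 10_020],
            {"T0": [0.1, 0.5], "T1": [0.3, 0.3], "N0": [0.6, 0.6]},
            sheet,
        )
        prof = bin_profile(bm, annotation_for(10_000), sheet, regions=("promoter",))
        row = prof.loc[("g0", "promoter", 16)]
        assert row.beta_t == pytest.approx(0.3)  # mean of probe means 0.2 and 0.4
        assert row.m_r == 2

    def test_empty_bins_are_missing(self):
        sheet = tiny_sheet(1, 1)
        from test_methylation import annotation_for, beta_at

        bm = beta_at([10_010], {"T0": [0.5], "N0": [0.5]}, sheet)
        prof = bin_profile(bm, annotation_for(10_000), sheet, regions=("promoter",))
        assert len(prof) == 1
        assert ("g0", "promoter", 15) not in prof.index

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        bm, ann, sheet = random_beta_setup(rng, n_genes=5, n_probes=150)
        prof = bin_profile(bm, ann, sheet, regions=("promoter",))
        means = condition_means(bm, sheet)
        for gid, grow in ann.genes.iterrows():
            per_bin = {}
            for pid, prow in bm.manifest.table.iterrows():
                mu = promoter_bin(int(prow.pos), int(grow.tss), grow.strand)
                if mu is not None:
                    per_bin.setdefault(mu, []).append(pid)
            for mu, pids in per_bin.items():
                row = prof.loc[(gid, "promoter", mu)]
                assert row.m_r == len(pids)
                assert row.beta_t == pytest.approx(means.loc[pids, "beta_t"].mean(), abs=1e-12)

    def test_single_bin_reduces_to_promoter_mean(self, default_study, default_result):
        """The m_r-weighted mean over the 30 bins equals the gene-level
        promoter methylation (the binned statistic refines, not redefines)."""
        prof = default_result.profile
        meth = default_result.meth.table
        sub = prof.xs("promoter", level="region")
        for gid in meth.index[meth["m_r"] > 0][:40]:
            bins = sub.loc[gid]
            pooled = float((bins["beta_t"] * bins["m_r"]).sum() / bins["m_r"].sum())
            assert pooled == pytest.approx(meth.loc[gid, "beta_t"], abs=1e-12)
            assert bins["m_r"].sum() == meth.loc[gid, "m_r"]


class TestBinRD:
    def test_exact_threshold_is_not_abnormal(self):
        idx = pd.MultiIndex.from_tuples(
            [("g0", "promoter", 1), ("g0", "promoter", 2)],
            names=["feature_id", "region", "bin"],
        )
        prof = pd.DataFrame(
            {"beta_t": [0.36, 0.5], "beta_p": [0.3, 0.5], "m_r": [1, 1]}, index=idx
        )
        out = bin_rd(prof)
        assert out["rd"].iloc[0] == pytest.approx(0.2, rel=1e-8)
        assert not out["abnormal"].iloc[0]  # strict inequality
        assert out["rd"].iloc[1] == 0.0

    def test_sign_matches_direction(self, default_result):
        prof = default_result.profile
        assert (np.sign(prof["rd"]) == np.sign(prof["beta_t"] - prof["beta_p"])).all()


class TestDensityAndKeyBins:
    def make_profile(self, entries):
        idx = pd.MultiIndex.from_tuples(
            [(g, "promoter", b) for g, b, _ in entries],
            names=["feature_id", "region", "bin"],
        )
        prof = pd.DataFrame(
            {
                "beta_t": [0.5] * len(entries),
                "beta_p": [0.5] * len(entries),
                "m_r": [1] * len(entries),
                "rd": [r for _, _, r in entries],
            },
            index=idx,
        )
        prof["abnormal"] = prof["rd"].abs() > 0.2
        return prof

    def test_key_bin_membership(self):
        prof = self.make_profile([("gA", 3, 0.9), ("gB", 15, 0.9), ("gC", 15, 0.1)])
        assert key_bin_filter(prof, {"gA", "gB", "gC"}) == {"gB"}

    def test_density_counts_and_missing_denominator(self):
        prof = self.make_profile([("gA", 1, 0.9), ("gB", 1, 0.0), ("gC", 2, -0.9)])
        dens = abnormal_density(prof, {"gA", "gB", "gC"})
        assert dens.loc[1, "n_abnormal"] == 1 and dens.loc[1, "n_genes"] == 2
        assert dens.loc[2, "fraction"] == 1.0
        assert dens.loc[3, "n_genes"] == 0 and np.isnan(dens.loc[3, "fraction"])

    def test_empty_gene_set(self, default_result):
        dens = abnormal_density(default_result.profile, set())
        assert (dens["n_abnormal"] == 0).all()

    def test_planted_key_bin_effects_concentrate_in_key_bins(
        self, default_study, default_result
    ):
        truth = default_study.truth.table
        planted = set(truth.index[truth["label"].isin(["D-Hyper", "U-Hypo"])])
        dens = abnormal_density(default_result.profile, planted)
        top = dens["fraction"].astype(float).nlargest(4).index
        assert set(top) <= set(KEY_BINS)
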
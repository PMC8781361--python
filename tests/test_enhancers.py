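import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methkey import assign_targets, call_dme, spearman_shortcut
from methkey.enhancers import enhancer_probe_ids, patient_vectors
from methkey.io import EnhancerSet, GeneAnnotation


def annotation_at(tss_list, chrom="chr1"):
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(tss_list))],
            "symbol": [f"G{i}" for i in range(len(tss_list))],
            "chrom": chrom,
            "strand": "+",
            "tss": tss_list,
        }
    )
    return GeneAnnotation(genes, {})


def enhancers_at(centers, chrom="chr1", half=100):
    t = pd.DataFrame(
        {
            "enhancer_id": [f"e{i}" for i in range(len(centers))],
            "chrom": chrom,
            "start": [c - half for c in centers],
            "end": [c + half for c in centers],
            "center": centers,
        }
    )
    return EnhancerSet(t)


class TestAssignTargets:
    def test_nearest_tss_wins(self):
        out = assign_targets(enhancers_at([1_800]), annotation_at([1_000, 5_000]))
        assert list(out.itertuples(index=False))[0][:3] == ("e0", "g0", 800)

    def test_equidistant_tie_goes_to_smaller_tss(self):
        out = assign_targets(enhancers_at([2_000]), annotation_at([1_000, 3_000]))
        assert out["gene_id"].iloc[0] == "g0"

    def test_tie_on_tss_breaks_lexicographically(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["gB", "gA"],
                "symbol": ["B", "A"],
                "chrom": "chr1",
                "strand": ["+", "-"],
                "tss": [4_000, 4_000],
            }
        )
        out = assign_targets(enhancers_at([4_100]), GeneAnnotation(genes, {}))
        assert out["gene_id"].iloc[0] == "gA"

    def test_beyond_window_unassigned(self):
        out = assign_targets(enhancers_at([5_000_000]), annotation_at([1_000]))
        assert out.empty

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(9)
        tss = sorted(rng.choice(np.arange(1_000, 3_000_000), size=30, replace=False))
        centers = list(rng.integers(1_000, 3_000_000, size=40))
        ann, enh = annotation_at(tss), enhancers_at(centers)
        got = assign_targets(enh, ann).set_index("enhancer_id")
        for i, c in enumerate(centers):
            cands = sorted(
                ((abs(t - c), t, f"g{k}") for k, t in enumerate(tss)),
            )
            d, _, gid = cands[0]
            if d > 1_000_000:
                assert f"e{i}" not in got.index
            else:
                assert got.loc[f"e{i}", "gene_id"] == gid
                assert got.loc[f"e{i}", "distance"] == d


class TestSpearmanShortcut:
    def test_perfect_antimonotone_via_d_squared(self):
        # ranks (1,2,3) vs (3,2,1): sum d^2 = 8, r = 1 - 48/24 = -1
        assert spearman_shortcut([1, 2, 3], [6, 5, 4]) == pytest.approx(-1.0, abs=1e-15)

    def test_monotone_is_plus_one(self):
        assert spearman_shortcut([1, 5, 9, 11], [0.1, 0.2, 0.3, 0.9]) == pytest.approx(1.0)

    def test_tie_free_matches_pearson_of_ranks(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            x = rng.permutation(n) + rng.uniform(0, 0.4, n)
            y = rng.permutation(n) + rng.uniform(0, 0.4, n)
            expected = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert spearman_shortcut(x, y) == pytest.approx(expected, abs=1e-12)
            assert spearman_shortcut(x, y) == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-12
            )

    def test_ties_fall_back_to_midrank_pearson(self):
        x = [1.0, 1.0, 2.0, 3.0, 4.0]
        y = [5.0, 4.0, 4.0, 2.0, 1.0]
        assert spearman_shortcut(x, y) == pytest.approx(
            stats.spearmanr(x, y).statistic, abs=1e-12
        )

    def test_symmetric_and_monotone_invariant(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=7), rng.normal(size=7)
        r = spearman_shortcut(x, y)
        assert spearman_shortcut(y, x) == pytest.approx(r, abs=1e-15)
        assert spearman_shortcut(np.exp(x), y**3) == pytest.approx(r, abs=1e-15)

    def test_constant_vector_returns_nan(self):
        assert np.isnan(spearman_shortcut([1.0, 1.0, 1.0], [1, 2, 3]))

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            spearman_shortcut([1, 2], [2, 1])


class TestPatientVectors:
    def test_equal_beta_gives_zero_rd_and_pseudocount_fc(self, default_study):
        study = default_study
        sheet = study.sheet
        probes = list(study.beta.values.index[:3])
        norm = pd.DataFrame(
            0, index=study.counts.values.index, columns=study.counts.values.columns
        )
        from methkey.io import BetaMatrix

        beta = BetaMatrix(study.beta.values.copy(), study.manifest)
        # force equal cancer/para beta for one patient
        pairs = sheet.matched_pairs()
        beta.values.loc[probes, pairs["cancer"].iloc[0]] = 0.4
        beta.values.loc[probes, pairs["paracancer"].iloc[0]] = 0.4
        vec = patient_vectors(beta, norm, sheet, probes, norm.index[0])
        assert vec["rd"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert (vec["fc"] == 1.0).all()  # (0+1)/(0+1)

    def test_matches_per_patient_recomputation(self, default_study, default_result):
        study = default_study
        from methkey.expression import normalize, size_factors
        from methkey.methylation import filter_probes

        beta_qc, _ = filter_probes(study.beta)
        norm = normalize(study.counts, size_factors(study.counts))
        probe_map = enhancer_probe_ids(beta_qc, study.enhancers)
        eid = next(e for e, p in probe_map.items() if p)
        gid = study.counts.values.index[0]
        vec = patient_vectors(beta_qc, norm, study.sheet, probe_map[eid], gid)
        for prow in study.sheet.matched_pairs().itertuples(index=False):
            bt = beta_qc.values.loc[probe_map[eid], prow.cancer].mean()
            bp = beta_qc.values.loc[probe_map[eid], prow.paracancer].mean()
            assert vec.loc[prow.patient_id, "rd"] == pytest.approx(
                (bt - bp) / (bp + 1e-9), abs=1e-12
            )
            assert vec.loc[prow.patient_id, "fc"] == pytest.approx(
                (norm.at[gid, prow.cancer] + 1) / (norm.at[gid, prow.paracancer] + 1),
                abs=1e-12,
            )

    def test_no_probes_is_error(self, default_study):
        with pytest.raises(ValueError, match="no probes"):
            patient_vectors(
                default_study.beta,
                default_study.counts.values,
                default_study.sheet,
                [],
                "g0000",
            )


class TestCallDME:
    def test_promoter_abnormal_gene_is_excluded(self, default_study, default_result):
        """No called pair may have promoter |RD| > 0.2 (the step-3 filter)."""
        called = default_result.dme.called
        assert (called["promoter_rd"].abs() <= 0.2).all()
        assert (called["r"] < -0.4).all()
        assert (called["enhancer_rd"].abs() > 0.2).all()

    def test_call_invariant_to_input_order(self, default_study):
        from methkey.expression import normalize, size_factors
        from methkey.methylation import filter_probes, gene_promoter_beta

        study = default_study
        beta_qc, _ = filter_probes(study.beta)
        norm = normalize(study.counts, size_factors(study.counts))
        meth = gene_promoter_beta(beta_qc, study.annotation, study.sheet)
        res1 = call_dme(beta_qc, norm, study.sheet, study.enhancers, study.annotation, meth)
        shuffled = EnhancerSet(
            study.enhancers.table.sample(frac=1, random_state=1).reset_index(drop=True)
        )
        res2 = call_dme(beta_qc, norm, study.sheet, shuffled, study.annotation, meth)
        a = res1.pairs.sort_values("enhancer_id").reset_index(drop=True)
        b = res2.pairs.sort_values("enhancer_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
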
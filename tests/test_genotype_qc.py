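import numpy as np
import pandas as pd
import pytest

from ricapanel import genotype_qc as qc
from ricapanel import synthetic_data as sd
from ricapanel.core import GenotypeError, GenotypeMatrix, MarkerRecord


def one_marker_matrix(calls, alleles=("A", "G")):
    m = [MarkerRecord("chr01:100", "chr01", 100, alleles)]
    samples = [f"s{i}" for i in range(len(calls))]
    return GenotypeMatrix(markers=m, samples=samples, calls=np.array(calls).reshape(-1, 1))


class TestMarkerQC:
    def test_counting_example(self):
        gm = one_marker_matrix(["AA", "AA", "AG", "GG"])
        row = qc.marker_qc(gm).iloc[0]
        assert row["call_rate"] == 1.0
        assert row["het"] == 0.25
        assert row["maf"] == 0.375
        # 25% heterozygosity correctly trips the >=10% het filter
        assert row["fail_reasons"] == "HIGH_HET"

    def test_boundaries_fail_inclusively(self):
        gm = one_marker_matrix(["AA", "AA", "AA", "NN"])  # CR = 0.75
        row = qc.marker_qc(gm).iloc[0]
        assert not row["pass"] and "LOW_CR" in row["fail_reasons"]
        gm2 = one_marker_matrix(["AG"] + ["AA"] * 9)  # het = 0.10
        row2 = qc.marker_qc(gm2).iloc[0]
        assert "HIGH_HET" in row2["fail_reasons"]

    def test_all_missing_marker_fails_cr_only(self):
        gm = one_marker_matrix(["NN", "NN"])
        row = qc.marker_qc(gm).iloc[0]
        assert row["call_rate"] == 0.0
        assert np.isnan(row["maf"]) and np.isnan(row["het"])
        assert row["fail_reasons"] == "LOW_CR"

    def test_allele_count_is_integer(self, structured_matrix):
        table = qc.marker_qc(structured_matrix)
        called = (~structured_matrix.missing_mask()).sum(axis=0)
        alt = structured_matrix.dosage()
        alt_freq = np.nansum(alt, axis=0) / (2 * called)
        counts = table["maf"].to_numpy() * 2 * called
        assert np.allclose(counts, np.round(counts))
        assert np.allclose(table["maf"], np.minimum(alt_freq, 1 - alt_freq), equal_nan=True)


class TestFilterMarkers:
    def test_two_stage_removal_counts(self, small_panel):
        """97 engineered low-call-rate and 5 high-het markers are removed
        exactly, mirroring a 995 -> 898 -> 893 two-stage filter."""
        panel = sd.simulate_panel(995, seed=21)
        model = sd.population_model(panel, n_subpops=1, divergence=0.0,
                                    residual_het_rate=0.0, missing_rate=0.0, seed=22)
        gm = sd.simulate_inbreds(panel, model, 40)
        rng = np.random.default_rng(23)
        bad = rng.choice(995, size=102, replace=False)
        low_cr, high_het = bad[:97], bad[97:]
        calls = gm.calls.copy()
        for j in low_cr:
            calls[:15, j] = "NN"  # CR = 25/40 < 0.75... boundary-inclusive
        for j in high_het:
            het = gm.markers[j].ref + gm.markers[j].alt
            calls[:5, j] = het  # het = 5/40 = 12.5% >= 10%
        gm = GenotypeMatrix(markers=gm.markers, samples=gm.samples, calls=calls,
                            sample_meta=gm.sample_meta)
        table = qc.marker_qc(gm)
        n_low_cr = (table["fail_reasons"].str.contains("LOW_CR")).sum()
        assert n_low_cr == 97
        after_cr = 995 - n_low_cr
        assert after_cr == 898
        with pytest.warns(UserWarning, match="removed"):
            kept = qc.filter_markers(gm, table)
        assert kept.n_markers == 893

    def test_idempotent(self, structured_matrix):
        once = qc.filter_markers(structured_matrix)
        twice = qc.filter_markers(once)
        assert twice == once


class TestConsensus:
    @pytest.mark.parametrize(
        "reps,expected",
        [
            (["AA", "AA", "AG"], "AA"),  # strict majority
            (["AA", "GG"], "NN"),  # tie
            (["AG"], "AG"),  # single replicate
            (["NN", "NN"], "NN"),  # all missing
            (["NN", "AA", "AA"], "AA"),  # missing ignored
        ],
    )
    def test_majority_rule(self, reps, expected):
        out = qc.consensus_genotype(np.array(reps).reshape(-1, 1))
        assert out[0] == expected


class TestRepeatability:
    def test_formula_on_small_example(self):
        # 4 reps x 10 loci, one locus has one mismatching replicate
        m = [MarkerRecord(f"chr01:{100 + i}", "chr01", 100 + i, ("A", "G")) for i in range(10)]
        calls = np.full((4, 10), "AA", dtype="U2")
        calls[0, 0] = "GG"
        meta = pd.DataFrame({"replicate_group": ["acc1"] * 4},
                            index=[f"r{i}" for i in range(4)])
        gm = GenotypeMatrix(markers=m, samples=list(meta.index), calls=calls, sample_meta=meta)
        res = qc.repeatability(gm, min_reps=4)
        assert res.per_locus_e[0] == 0.25
        assert res.mean_e_l == pytest.approx(0.025)
        assert res.R == pytest.approx(97.5)

    def test_perfect_replicates_give_R_100(self, clean_pop_matrix):
        reps = sd.simulate_replicates(clean_pop_matrix.subset_samples(
            clean_pop_matrix.samples[:5]), 4, 0.0, seed=1)
        assert qc.repeatability(reps).R == 100.0

    def test_error_rate_recovered_within_3sd(self, small_panel):
        model = sd.population_model(small_panel, n_subpops=1, divergence=0.0,
                                    residual_het_rate=0.0, missing_rate=0.0, seed=31)
        truth = sd.simulate_inbreds(small_panel, model, 38)
        reps = sd.simulate_replicates(truth, 4, 0.01, seed=32)
        res = qc.repeatability(reps, min_reps=4)
        n_calls = res.per_locus_n.sum()
        sd3 = 3 * np.sqrt(0.01 * 0.99 / n_calls)
        # consensus of 4 reps at 1% error is almost always the truth
        assert abs(res.mean_e_l - 0.01) < sd3 + 0.001
        assert res.R == pytest.approx(99.0, abs=0.3)

    def test_no_replicated_accession_errors(self, clean_pop_matrix):
        with pytest.raises(GenotypeError):
            qc.repeatability(clean_pop_matrix, min_reps=4)


class TestConcordance:
    def test_identical_matrices_100(self, structured_matrix):
        pairs = [(s, s) for s in structured_matrix.samples[:10]]
        res = qc.concordance(structured_matrix, structured_matrix, pairs)
        assert res.concordance == 100.0

    def test_single_mismatch_ratio(self):
        m = [MarkerRecord(f"chr01:{i+1}", "chr01", i + 1, ("A", "G")) for i in range(100)]
        a = GenotypeMatrix(markers=m, samples=["x"], calls=np.full((1, 100), "AA", dtype="U2"))
        calls_b = np.full((1, 100), "AA", dtype="U2")
        calls_b[0, 0] = "GG"
        b = GenotypeMatrix(markers=m, samples=["x"], calls=calls_b)
        res = qc.concordance(a, b, [("x", "x")])
        assert res.concordance == pytest.approx(99.0)

    def test_opposite_strand_reconciled(self):
        # platform B reports an A/G marker on the opposite strand (T/C)
        ma = [MarkerRecord("chr01:5", "chr01", 5, ("A", "G"))]
        mb = [MarkerRecord("other", "chr01", 5, ("C", "T"))]
        a = GenotypeMatrix(markers=ma, samples=["x", "y"], calls=np.array([["AG"], ["AA"]]))
        b = GenotypeMatrix(markers=mb, samples=["x", "y"], calls=np.array([["CT"], ["TT"]]))
        res = qc.concordance(a, b, [("x", "x"), ("y", "y")])
        assert res.concordance == 100.0

    def test_missing_excluded_from_comparison(self):
        m = [MarkerRecord(f"chr01:{i+1}", "chr01", i + 1, ("A", "G")) for i in range(4)]
        a = GenotypeMatrix(markers=m, samples=["x"], calls=np.array([["AA", "AA", "NN", "AA"]]))
        b = GenotypeMatrix(markers=m, samples=["x"], calls=np.array([["AA", "NN", "AA", "GG"]]))
        res = qc.concordance(a, b, [("x", "x")])
        assert res.n_compared_calls == 2
        assert res.concordance == 50.0

    def test_no_shared_markers_errors(self):
        a = GenotypeMatrix(markers=[MarkerRecord("m", "chr01", 5, ("A", "G"))],
                           samples=["x"], calls=np.array([["AA"]]))
        b = GenotypeMatrix(markers=[MarkerRecord("m", "chr02", 5, ("A", "G"))],
                           samples=["x"], calls=np.array([["AA"]]))
        with pytest.raises(GenotypeError):
            qc.concordance(a, b, [("x", "x")])


class TestLdKnnImputation:
    def test_duplicate_sample_fills_from_twin(self, small_panel):
        model = sd.population_model(small_panel, n_subpops=1, divergence=0.0,
                                    residual_het_rate=0.0, missing_rate=0.0, seed=41)
        gm = sd.simulate_inbreds(small_panel, model, 10)
        calls = np.vstack([gm.calls, gm.calls[0:1]])
        calls[-1, 5] = "NN"
        gm2 = GenotypeMatrix(markers=gm.markers, samples=gm.samples + ["twin"], calls=calls)
        imp = qc.impute_ld_knn(gm2, l_sites=10, k_neighbors=1)
        assert imp.calls[-1, 5] == gm.calls[0, 5]

    def test_never_alters_called_genotypes(self, structured_matrix):
        imp = qc.impute_ld_knn(structured_matrix, l_sites=10, k_neighbors=10)
        called = ~structured_matrix.missing_mask()
        assert np.array_equal(imp.calls[called], structured_matrix.calls[called])
        assert imp.missing_mask().sum() <= structured_matrix.missing_mask().sum()

    def test_beats_mode_imputation_on_ld_blocks(self, small_panel):
        model = sd.population_model(small_panel, n_subpops=1, divergence=0.0,
                                    residual_het_rate=0.0, missing_rate=0.0, seed=43,
                                    ld_block_size=10, ld_fidelity=0.97)
        truth = sd.simulate_inbreds(small_panel, model, 80)
        rng = np.random.default_rng(44)
        calls = truth.calls.copy()
        calls[rng.random(calls.shape) < 0.05] = "NN"
        obs = GenotypeMatrix(markers=truth.markers, samples=truth.samples, calls=calls)
        mask = obs.missing_mask()
        knn = qc.impute_ld_knn(obs, l_sites=15, k_neighbors=15)
        mode = qc.impute_mode(obs)
        acc_knn = (knn.calls[mask] == truth.calls[mask]).mean()
        acc_mode = (mode.calls[mask] == truth.calls[mask]).mean()
        assert acc_knn > acc_mode

    def test_too_small_matrix_rejected(self):
        gm = one_marker_matrix(["AA", "NN"])
        with pytest.raises(GenotypeError):
            qc.impute_ld_knn(gm)
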
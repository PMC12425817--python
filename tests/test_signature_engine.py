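"""Context matrices, ID83 rules, KL-NMF behavior, reference refitting."""

import numpy as np
import pandas as pd
import pytest

from mutscape import signature_engine as se
from mutscape.catalogs import id83_labels, sbs96_labels


class TestSbsChannels:
    def test_pyrimidine_reference_kept(self):
        assert se.sbs_channel("C", "T", "ACG") == "A[C>T]G"

    def test_purine_reference_reverse_complemented(self):
        assert se.sbs_channel("G", "A", "CGT") == "A[C>T]G"

    def test_ambiguous_context_excluded(self):
        assert se.sbs_channel("C", "T", "NCG") is None

    def test_matrix_conserves_counts(self, small_bundle):
        muts = small_bundle.truth_mutations
        mat, excluded = se.build_sbs_matrix(muts)
        snvs = muts[muts["variant_class"] == "SNV"]
        assert mat.to_numpy().sum() + excluded == len(snvs)
        per_sample = snvs.groupby("sample_id").size()
        assert (mat.sum(axis=1).loc[per_sample.index] <= per_sample).all()
        assert list(mat.columns) == sbs96_labels()


class TestClassifyIndel:
    F25 = "A" * 25
    G25 = "G" * 25

    @pytest.mark.parametrize(
        "indel_type, seq, flank5, flank3, expected",
        [
            # 1-bp T deletion inside a TTTTT run: 4 identical bases remain
            ("del", "T", "G" + "A" * 24, "TTTT" + "G" + "A" * 20, "1:Del:T:4"),
            # deleted A reported on the purine strand maps to the T channel
            ("del", "A", "G" * 25, "AAAA" + "G" * 21, "1:Del:T:4"),
            ("ins", "C", "A" * 25, "G" * 25, "1:Ins:C:0"),
            # long homopolymer capped at the 5+ channel
            ("del", "T", "T" * 25, "T" * 25, "1:Del:T:5"),
            # 4-bp deletion with 2-bp flanking microhomology, not in a repeat
            ("del", "ACGT", "G" * 25, "AC" + "T" * 23, "4:Del:M:2"),
            # tandem-repeat deletion
            ("del", "AC", "G" * 25, "ACAC" + "G" * 21, "2:Del:R:2"),
            ("ins", "ACG", "G" * 25, "ACG" + "T" * 22, "3:Ins:R:1"),
            # no repeat, no microhomology
            ("del", "CCGA", "G" * 25, "T" * 25, "4:Del:R:0"),
            # 6-bp deletion falls in the 5+ size class
            ("del", "ACGTAC", "G" * 25, "T" * 25, "5:Del:R:0"),
        ],
    )
    def test_rule_oracle_channels(self, indel_type, seq, flank5, flank3, expected):
        assert se.classify_indel(indel_type, seq, flank5, flank3) == expected

    def test_insufficient_flank_unclassifiable(self):
        assert se.classify_indel("del", "A", "AAAA", "AAAA") is None

    def test_all_channels_are_valid_labels(self):
        labels = set(id83_labels())
        rng = np.random.default_rng(0)
        for _ in range(200):
            L = int(rng.integers(1, 8))
            seq = "".join(rng.choice(list("ACGT"), L))
            f5 = "".join(rng.choice(list("ACGT"), 30))
            f3 = "".join(rng.choice(list("ACGT"), 30))
            kind = str(rng.choice(["ins", "del"]))
            ch = se.classify_indel(kind, seq, f5, f3)
            assert ch in labels


class TestKlNmf:
    def test_objective_nonincreasing(self):
        rng = np.random.default_rng(0)
        V = rng.poisson(5, size=(20, 8)).astype(float)
        _, _, history, _ = se.klnmf(V, k=3, rng=rng, max_iter=60, tol=0)
        diffs = np.diff(history)
        assert (diffs <= 1e-8 * np.maximum(np.abs(history[:-1]), 1)).all()

    def test_rank_one_fixed_point_is_channel_sum(self):
        rng = np.random.default_rng(1)
        V = rng.poisson(20, size=(10, 6)).astype(float)
        W, H, _, _ = se.klnmf(V, k=1, rng=rng, max_iter=500)
        expected = V.sum(axis=1) / V.sum()
        assert np.allclose(W[:, 0], expected, atol=1e-4)

    def test_extraction_deterministic_under_seed(self, sbs_catalog):
        rng = np.random.default_rng(5)
        profiles = pd.DataFrame(
            rng.dirichlet(np.ones(5), size=15), columns=sbs_catalog.columns
        )
        counts = np.vstack(
            [rng.multinomial(400, profiles.iloc[i] @ sbs_catalog.T) for i in range(15)]
        )
        mat = pd.DataFrame(counts, columns=list(sbs_catalog.index))
        r1 = se.extract_denovo(mat, k_range=range(1, 4), n_replicates=4, seed=7)
        r2 = se.extract_denovo(mat, k_range=range(1, 4), n_replicates=4, seed=7)
        assert r1["selected_k"] == r2["selected_k"]
        pd.testing.assert_frame_equal(
            r1["selected"].signatures, r2["selected"].signatures
        )


class TestDecompose:
    def test_two_signature_mixture_recovered(self, sbs_catalog):
        v = 600 * sbs_catalog["SBS1"] + 400 * sbs_catalog["SBS3"]
        samples = pd.DataFrame([v.to_numpy()], columns=sbs_catalog.index, index=["s"])
        expo = se.decompose_to_reference(samples, sbs_catalog)
        assert expo.loc["s", "SBS1"] == pytest.approx(600, rel=1e-6)
        assert expo.loc["s", "SBS3"] == pytest.approx(400, rel=1e-6)
        others = expo.drop(columns=["SBS1", "SBS3"])
        assert float(others.abs().to_numpy().max()) < 1e-6

    def test_zero_vector_gives_zero_exposures(self, sbs_catalog):
        samples = pd.DataFrame(
            np.zeros((1, 96)), columns=sbs_catalog.index, index=["s"]
        )
        assert (se.decompose_to_reference(samples, sbs_catalog).to_numpy() == 0).all()

    def test_single_signature_catalog_closed_form(self, sbs_catalog):
        cat1 = sbs_catalog[["SBS2"]]
        rng = np.random.default_rng(2)
        v = rng.poisson(50, 96).astype(float)
        samples = pd.DataFrame([v], columns=cat1.index, index=["s"])
        expo = se.decompose_to_reference(samples, cat1)
        w = cat1.to_numpy().ravel()
        assert expo.loc["s", "SBS2"] == pytest.approx(max(0.0, v @ w / (w @ w)), rel=1e-9)

    def test_matches_brute_force_subset(self, sbs_catalog):
        rng = np.random.default_rng(3)
        mix = 500 * sbs_catalog["SBS2"] + 500 * sbs_catalog["SBS13"]
        v = rng.poisson(np.maximum(mix, 0)).astype(float)
        samples = pd.DataFrame([v], columns=sbs_catalog.index, index=["s"])
        expo = se.decompose_to_reference(samples, sbs_catalog)
        active = set(expo.columns[(expo.loc["s"] > 1e-9)])
        # brute force: smallest subset whose reconstruction cosine is within
        # the elimination tolerance of the full fit
        from itertools import combinations
        from scipy.optimize import nnls

        W = sbs_catalog.to_numpy()
        full_cos = se.cosine(W @ nnls(W, v)[0], v)
        best = None
        for r in range(1, 6):
            for subset in combinations(range(5), r):
                coef, _ = nnls(W[:, subset], v)
                if full_cos - se.cosine(W[:, subset] @ coef, v) < 0.01:
                    best = {sbs_catalog.columns[i] for i in subset}
                    break
            if best:
                break
        assert active == best

    def test_permuting_samples_permutes_exposures(self, sbs_catalog):
        rng = np.random.default_rng(4)
        samples = pd.DataFrame(
            rng.poisson(5, size=(6, 96)).astype(float),
            columns=sbs_catalog.index,
            index=[f"s{i}" for i in range(6)],
        )
        perm = samples.iloc[::-1]
        a = se.decompose_to_reference(samples, sbs_catalog)
        b = se.decompose_to_reference(perm, sbs_catalog)
        pd.testing.assert_frame_equal(a.iloc[::-1], b)


class TestRefitAndCorrelations:
    def test_kl_refit_recovers_true_exposures(self, exposure_cohort, sbs_catalog):
        mat = exposure_cohort.truth["context_matrix"]
        expo = se.refit_exposures(mat, sbs_catalog)
        truth = exposure_cohort.truth["exposures"]
        cosines = [
            se.cosine(expo.iloc[i], truth.iloc[i]) for i in range(len(expo))
        ]
        assert np.mean(cosines) >= 0.95
        # totals conserved within 1% for converged Poisson fits
        ratio = expo.sum(axis=1) / mat.sum(axis=1)
        assert np.allclose(ratio, 1.0, atol=0.01)

    def test_identical_covariate_perfect_correlation(self):
        rng = np.random.default_rng(0)
        expo = pd.DataFrame({"SBS3": rng.gamma(2, 100, 50)})
        out = se.exposure_correlations(expo, expo.rename(columns={"SBS3": "hrd"}))
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_planted_hrd_correlation_recovered(self, exposure_cohort, sbs_catalog):
        mat = exposure_cohort.truth["context_matrix"]
        expo = se.refit_exposures(mat, sbs_catalog)
        hrd = exposure_cohort.truth["hrd"].set_index("sample_id")["hrd_score"]
        truth_r = np.corrcoef(
            exposure_cohort.truth["exposures"]["SBS3"], hrd.loc[expo.index]
        )[0, 1]
        out = se.exposure_correlations(expo[["SBS3"]], hrd.to_frame())
        # estimated exposures attenuate the correlation, never inflate it
        assert truth_r - 0.2 <= out.loc[0, "r"] <= truth_r + 0.1
        assert out.loc[0, "r"] > 0.2
        assert out.loc[0, "p"] < 0.001

    def test_zero_variance_covariate_undefined(self):
        expo = pd.DataFrame({"SBS1": [1.0, 2.0, 3.0, 4.0]})
        cov = pd.DataFrame({"flat": [5.0, 5.0, 5.0, 5.0]})
        out = se.exposure_correlations(expo, cov)
        assert np.isnan(out.loc[0, "r"])
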
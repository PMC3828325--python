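import json

import numpy as np
import pandas as pd
import pytest

from xplatsig import (SignatureParams, PathwaySignatureModel, SignatureResults,
                      quantile_normalize, select_signature_genes,
                      compute_metagenes, fit_probit_gibbs,
                      fit_probit_penalized_mle, create_signature,
                      loocv_predict, cross_platform_predict, signature_overlap)

FAST = SignatureParams(n_genes=40, n_metagenes=2, seed=3,
                       n_iterations=400, n_burnin=100)


def cohort(seed=0, n_probes=120, n_sig=20, n_per_class=8, effect=2.0):
    """Minimal labelled cohort: first n_sig probes carry the effect."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    base = rng.uniform(4, 12, size=n_probes)[:, None] \
        + rng.standard_normal((n_probes, n))
    base[:n_sig, n_per_class:] += effect
    samples = [f"c{i}" for i in range(n_per_class)] \
        + [f"t{i}" for i in range(n_per_class)]
    expr = pd.DataFrame(base, index=[f"p{i:03d}" for i in range(n_probes)],
                        columns=samples)
    labels = pd.Series([0] * n_per_class + [1] * n_per_class,
                       index=samples, name="label")
    return expr, labels


class TestQuantileNormalize:
    def test_hand_worked_small_matrix(self):
        # classic worked example: sort each column, average across
        # columns, hand the means back by rank
        mat = pd.DataFrame({"s1": [5.0, 2.0, 3.0, 4.0],
                            "s2": [4.0, 1.0, 4.0, 2.0],
                            "s3": [3.0, 4.0, 6.0, 8.0]},
                           index=list("abcd"))
        ref = np.sort(mat.to_numpy(), axis=0).mean(axis=1)  # [2, 2.67, 4, 5.67]
        out = quantile_normalize(mat)
        expected_s1 = [ref[3], ref[0], ref[1], ref[2]]
        assert np.allclose(out["s1"], expected_s1)
        # tie in s2 (two 4.0 at ranks 3,4) averages the reference values
        tie_value = 0.5 * (ref[2] + ref[3])
        assert out.loc["a", "s2"] == pytest.approx(tie_value)
        assert out.loc["c", "s2"] == pytest.approx(tie_value)

    def test_columns_share_sorted_values(self, tiny_expression):
        out = quantile_normalize(tiny_expression)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for col in out.columns:
            assert np.allclose(np.sort(out[col].to_numpy()), ref, atol=1e-12)

    def test_idempotent(self, tiny_expression):
        once = quantile_normalize(tiny_expression)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice, atol=1e-12,
                                      check_exact=False)

    def test_column_matching_reference_is_unchanged(self):
        ref = np.array([1.0, 2.0, 5.0, 9.0])
        mat = pd.DataFrame({"s1": [5.0, 1.0, 9.0, 2.0]})
        out = quantile_normalize(mat, reference=ref)
        assert np.allclose(out["s1"], [5.0, 1.0, 9.0, 2.0])

    def test_reference_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            quantile_normalize(pd.DataFrame({"s": [1.0, 2.0]}),
                               reference=np.arange(5.0))


class TestGeneSelection:
    def test_perfect_tracker_ranks_first(self):
        expr, labels = cohort(seed=1)
        expr.loc["p000"] = labels.to_numpy(float)  # exact 0/1 tracker
        sel = select_signature_genes(expr, labels, 10)
        assert sel["probe_id"].iloc[0] == "p000"
        assert abs(sel["r"].iloc[0]) == pytest.approx(1.0)

    def test_all_genes_boundary(self):
        expr, labels = cohort(seed=2, n_probes=25)
        sel = select_signature_genes(expr, labels, 25)
        assert len(sel) == 25

    def test_matches_bruteforce_oracle(self):
        expr, labels = cohort(seed=3, n_probes=20, n_sig=5)
        y = labels.to_numpy(float)
        oracle = {}
        for pid, row in expr.iterrows():
            x = row.to_numpy()
            oracle[pid] = (((x - x.mean()) * (y - y.mean())).sum()
                           / np.sqrt(((x - x.mean())**2).sum()
                                     * ((y - y.mean())**2).sum()))
        order = sorted(oracle, key=lambda p: (-abs(oracle[p]), p))
        sel = select_signature_genes(expr, labels, 20)
        assert sel["probe_id"].tolist() == order
        for pid, r in zip(sel["probe_id"], sel["r"]):
            assert r == pytest.approx(oracle[pid], abs=1e-12)

    def test_abs_r_non_increasing(self):
        expr, labels = cohort(seed=4)
        sel = select_signature_genes(expr, labels, 30)
        assert (np.diff(np.abs(sel["r"])) <= 1e-12).all()

    def test_single_class_is_an_error(self):
        expr, labels = cohort(seed=5)
        with pytest.raises(Exception, match="class"):
            select_signature_genes(expr, (labels * 0), 5)


class TestMetagenes:
    def test_rank_one_matrix_reconstructed(self):
        u = np.array([1.0, -2.0, 0.5, 3.0])
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        mat = pd.DataFrame(np.outer(u, v))
        basis, means, scales, scores = compute_metagenes(mat, 1)
        z = (mat.to_numpy() - means[:, None]) / scales[:, None]
        recon = basis @ scores
        assert np.allclose(recon, z, atol=1e-10)

    def test_orthonormal_basis(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.standard_normal((10, 8)))
        basis, *_ = compute_metagenes(mat, 2)
        assert np.allclose(basis.T @ basis, np.eye(2), atol=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.standard_normal((10, 8)))
        basis, means, scales, scores = compute_metagenes(mat, 2)
        z = (mat.to_numpy() - means[:, None]) / scales[:, None]
        evals, evecs = np.linalg.eigh(z @ z.T)
        top = evecs[:, np.argsort(evals)[::-1][:2]]
        for j in range(2):
            dot = abs(top[:, j] @ basis[:, j])
            assert dot == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.standard_normal((12, 6)))
        basis, *_ = compute_metagenes(mat, 3)
        for j in range(3):
            assert basis[np.argmax(np.abs(basis[:, j])), j] > 0

    def test_k_exceeding_rank_is_an_error(self):
        mat = pd.DataFrame(np.outer([1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError, match="rank"):
            compute_metagenes(mat, 2)


class TestProbit:
    @staticmethod
    def scores_and_labels(seed=0, n=40, separated=False):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, 2))
        if separated:
            y = (x[:, 0] > 0).astype(int)
        else:
            eta = 0.8 * x[:, 0] - 0.3 * x[:, 1]
            y = (eta + rng.standard_normal(n) > 0).astype(int)
        return x, y

    def test_symmetric_data_gives_near_zero_intercept(self):
        x, y = self.scores_and_labels(seed=1)
        x = np.vstack([x, -x])
        y = np.concatenate([y, 1 - y])  # exactly symmetric design
        mean, sd = fit_probit_gibbs(x, y, rng=np.random.default_rng(0),
                                    n_iterations=1500, n_burnin=300)
        assert abs(mean[0]) < 3 * max(sd[0], 1e-6)

    def test_gibbs_agrees_with_penalized_mle(self):
        x, y = self.scores_and_labels(seed=2, n=60)
        mean, _sd = fit_probit_gibbs(x, y, rng=np.random.default_rng(1),
                                     n_iterations=4000, n_burnin=1000)
        map_est = fit_probit_penalized_mle(x, y)
        assert np.allclose(mean, map_est, atol=0.1)

    def test_penalized_mle_matches_statsmodels_at_weak_prior(self):
        sm = pytest.importorskip("statsmodels.api")
        x, y = self.scores_and_labels(seed=3, n=80)
        ours = fit_probit_penalized_mle(x, y, tau2=1e8)
        X = np.column_stack([np.ones(len(y)), x])
        ref = sm.Probit(y, X).fit(disp=0).params
        assert np.allclose(ours, ref, atol=1e-4)

    def test_separation_stays_finite(self):
        # complete separation drives the unpenalized MLE to infinity;
        # the proper prior must keep both fitters finite and bounded
        x, y = self.scores_and_labels(seed=4, separated=True)
        mean, _ = fit_probit_gibbs(x, y, rng=np.random.default_rng(2),
                                   n_iterations=1000, n_burnin=200)
        assert np.isfinite(mean).all()
        map_est = fit_probit_penalized_mle(x, y)
        assert np.isfinite(map_est).all()
        assert np.abs(map_est).max() < 10 * np.sqrt(100.0)  # within prior scale


class TestSignaturePipeline:
    def test_true_signature_probes_dominate_selection(self):
        # small cohort: most selected probes should carry the planted
        # effect (the full-scale check lives in the acceptance suite)
        expr, labels = cohort(seed=6, n_probes=200, n_sig=40,
                              n_per_class=10, effect=3.0)
        res = create_signature(expr, labels, FAST)
        hit = res.selected_genes["probe_id"].str.slice(1).astype(int) < 40
        assert hit.mean() >= 0.8

    def test_same_seed_byte_identical_serialization(self):
        expr, labels = cohort(seed=7)
        r1 = create_signature(expr, labels, FAST).to_json()
        r2 = create_signature(expr, labels, FAST).to_json()
        assert r1 == r2

    def test_too_many_metagenes_is_an_error(self):
        expr, labels = cohort(seed=8, n_per_class=3)
        params = SignatureParams(n_genes=10, n_metagenes=7)
        with pytest.raises(ValueError, match="samples"):
            PathwaySignatureModel(labels, expr, params=params)

    def test_training_samples_separate(self):
        expr, labels = cohort(seed=9, effect=3.0)
        res = create_signature(expr, labels, FAST)
        pred = res.predict(expr)
        assert (pred.loc[labels[labels == 0].index, "probability"] < 0.5).all()
        assert (pred.loc[labels[labels == 1].index, "probability"] > 0.5).all()

    def test_probabilities_strictly_inside_unit_interval(self):
        expr, labels = cohort(seed=10, effect=5.0)
        res = create_signature(expr, labels, FAST)
        p = res.predict(expr)["probability"]
        assert ((p > 0) & (p < 1)).all()

    def test_label_flip_maps_probabilities_to_complement(self):
        expr, labels = cohort(seed=11)
        params = SignatureParams(n_genes=40, n_metagenes=2, seed=3,
                                 sampler="penalized_mle")
        p = create_signature(expr, labels, params).predict(expr)["probability"]
        q = create_signature(expr, 1 - labels, params).predict(expr)["probability"]
        assert np.allclose(p, 1 - q, atol=1e-4)

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        expr, labels = cohort(seed=12)
        res = create_signature(expr, labels, FAST)
        path = tmp_path / "model.json"
        res.to_json(path)
        back = SignatureResults.from_json(path)
        pd.testing.assert_frame_equal(back.predict(expr), res.predict(expr))


class TestMissingGenes:
    def _fitted(self):
        expr, labels = cohort(seed=13, n_probes=300, n_sig=60)
        params = SignatureParams(n_genes=100, n_metagenes=2, seed=1,
                                 sampler="penalized_mle")
        return create_signature(expr, labels, params), expr

    def test_small_fraction_dropped_with_warning(self, caplog):
        res, expr = self._fitted()
        lost = res.selected_genes["probe_id"].iloc[:3]  # 3% of 100
        with caplog.at_level("WARNING"):
            pred = res.predict(expr.drop(index=lost))
        assert len(pred) == expr.shape[1]
        assert any("signature gene" in r.message for r in caplog.records)

    def test_large_fraction_is_an_error_listing_genes(self):
        res, expr = self._fitted()
        lost = res.selected_genes["probe_id"].iloc[:10]  # 10% > 5%
        with pytest.raises(ValueError, match=lost.iloc[0]):
            res.predict(expr.drop(index=lost))


class TestLoocv:
    def test_one_probability_per_sample(self):
        expr, labels = cohort(seed=14, n_per_class=4)
        params = SignatureParams(n_genes=30, n_metagenes=2, seed=0,
                                 sampler="penalized_mle")
        out = loocv_predict(expr, labels, params)
        assert len(out) == len(labels)
        assert set(out.index) == set(labels.index)

    def test_strong_effect_separates_classes_completely(self):
        expr, labels = cohort(seed=15, n_per_class=10, effect=2.5)
        out = loocv_predict(expr, labels, FAST)
        assert out.loc[out.label == 0, "probability"].max() \
            < out.loc[out.label == 1, "probability"].min()

    def test_too_few_samples_per_class_is_an_error(self):
        expr, labels = cohort(seed=16, n_per_class=2)
        with pytest.raises(ValueError, match="3"):
            loocv_predict(expr, labels, FAST)


class TestCrossPlatform:
    def test_overlap_identity_and_disjoint(self, small_mapping):
        mut = small_mapping.mutual_pairs().head(20)
        sel_a = pd.DataFrame({"probe_id": mut["probe_a"],
                              "r": np.linspace(1, 0.5, 20)})
        sel_b = pd.DataFrame({"probe_id": mut["probe_b"],
                              "r": np.linspace(1, 0.5, 20)})
        common_args = dict(
            quantile_reference=None, gene_means=np.zeros(20),
            gene_scales=np.ones(20), metagene_basis=np.zeros((20, 2)),
            probit_coefficients=np.zeros(3),
            probit_coefficient_sd=np.zeros(3),
            params=SignatureParams(n_genes=20))
        res_a = SignatureResults(selected_genes=sel_a, platform_id="A",
                                 **common_args)
        res_b = SignatureResults(selected_genes=sel_b, platform_id="B",
                                 **common_args)
        assert signature_overlap(res_a, res_b, small_mapping)[
            "percent_overlap"] == 100.0
        tail = small_mapping.mutual_pairs().tail(20)
        res_b2 = SignatureResults(
            selected_genes=pd.DataFrame({"probe_id": tail["probe_b"],
                                         "r": np.linspace(1, 0.5, 20)}),
            platform_id="B", **common_args)
        assert signature_overlap(res_a, res_b2, small_mapping)[
            "percent_overlap"] == 0.0

    def test_cross_platform_tracks_same_platform(self, small_bundle,
                                                 small_mapping,
                                                 mapped_training):
        tr_a, _tr_b = mapped_training
        mut = small_mapping.mutual_pairs()
        te_a = small_bundle.expr_test_a.loc[mut["probe_a"]]
        te_b = small_bundle.expr_test_b.loc[mut["probe_b"]]
        res = create_signature(tr_a, small_bundle.labels, FAST,
                               platform_id="A")
        same = res.predict(te_a)["probability"]
        cross = cross_platform_predict(res, small_mapping,
                                       te_b)["probability"]
        assert np.corrcoef(same, cross)[0, 1] > 0.85

    def test_wrong_platform_mapping_is_an_error(self, small_mapping):
        expr, labels = cohort(seed=17)
        res = create_signature(expr, labels, FAST, platform_id="Z")
        with pytest.raises(ValueError, match="platform"):
            res.predict(expr, mapping=small_mapping)
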
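"""Proliferation-potential signature: selection, scoring, validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from temqtl.signature import (
    SignatureModel,
    build_signature,
    correlate_genes,
    cross_visit_replicate,
    null_gene_count,
    score_individuals,
    split_half_validate,
)


def _null_frame(n=100, m=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.standard_normal((n, m)),
                        index=[f"I{i}" for i in range(n)],
                        columns=[f"g{j}" for j in range(m)])


class TestCorrelateGenes:
    def test_self_correlation_hits_floor(self):
        E = _null_frame()
        y = E["g0"].to_numpy()
        corr = correlate_genes(E, y, n_perm=500, seed=1)
        assert corr.loc["g0", "pearson_r"] == pytest.approx(1.0)
        assert corr.loc["g0", "permutation_p"] == pytest.approx(1 / 501)

    def test_null_p_roughly_uniform(self):
        E = _null_frame(n=182, m=60, seed=2)
        y = np.random.default_rng(3).standard_normal(182)
        corr = correlate_genes(E, y, n_perm=400, seed=4)
        from scipy import stats
        ks = stats.kstest(corr["permutation_p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_correlation_detected(self):
        rng = np.random.default_rng(5)
        n = 182
        y = rng.standard_normal(n)
        hits = 0
        for rep in range(20):
            g = 0.3 * y + np.sqrt(1 - 0.09) * rng.standard_normal(n)
            E = pd.DataFrame({"g": g})
            corr = correlate_genes(E, y, n_perm=1000, seed=rep,
                                   min_individuals=20)
            hits += corr.loc["g", "permutation_p"] < 0.01
        assert hits >= 16   # Fisher-z power at r=0.3, n=182 is ~0.98

    def test_constant_gene_skipped(self):
        E = _null_frame(n=50, m=3)
        E["g1"] = 1.0
        corr = correlate_genes(E, E["g0"].to_numpy(), n_perm=200, seed=6)
        assert np.isnan(corr.loc["g1", "pearson_r"])


class TestBuildAndScore:
    def test_weights_are_correlation_signs(self, cohort182):
        _, co = cohort182
        corr = correlate_genes(co.expr_rest, co.phenotypes["pi"], n_perm=500, seed=7)
        model = build_signature(corr)
        for g, w in model.weights.items():
            assert w == np.sign(corr.loc[g, "pearson_r"])

    def test_truth_recovery_and_sign_split(self, cohort182):
        cfg, co = cohort182
        corr = correlate_genes(co.expr_rest, co.phenotypes["pi"], n_perm=500, seed=8)
        model = build_signature(corr)
        truth = co.truth.signature_genes
        found = truth.index.intersection(model.weights.index)
        assert len(found) / len(truth) > 0.8
        agree = (model.weights.loc[found] == truth.loc[found, "sign"]).mean()
        assert agree == 1.0

    def test_empty_and_full_selection(self):
        corr = pd.DataFrame({"pearson_r": [0.1, -0.2], "permutation_p": [0.5, 0.9],
                             "n": 50}, index=["a", "b"])
        assert build_signature(corr).empty
        full = build_signature(corr, threshold=1.0)
        assert list(full.weights) == [1.0, -1.0]

    def test_single_gene_score_is_zscore(self):
        E = _null_frame(n=60, m=2, seed=9)
        model = SignatureModel(weights=pd.Series({"g0": 1.0}), threshold=0.01)
        s, _ = score_individuals(model, E)
        z = (E["g0"] - E["g0"].mean()) / E["g0"].std(ddof=0)
        assert np.allclose(s, z)

    def test_training_r_near_planted(self, cohort182):
        cfg, co = cohort182
        corr = correlate_genes(co.expr_rest, co.phenotypes["pi"], n_perm=500, seed=10)
        model = build_signature(corr)
        _, r = score_individuals(model, co.expr_rest, co.phenotypes["pi"])
        assert abs(r - cfg.signature_r) < 0.1

    def test_missing_gene_raises(self):
        E = _null_frame(n=30, m=2)
        model = SignatureModel(weights=pd.Series({"nope": 1.0}), threshold=0.01)
        with pytest.raises(KeyError, match="nope"):
            score_individuals(model, E)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_score_antisymmetry(self, seed):
        E = _null_frame(n=40, m=5, seed=seed)
        w = pd.Series({"g0": 1.0, "g2": -1.0, "g4": 1.0})
        m1 = SignatureModel(weights=w, threshold=0.01)
        m2 = SignatureModel(weights=-w, threshold=0.01)
        s1, _ = score_individuals(m1, E)
        s2, _ = score_individuals(m2, E)
        assert np.allclose(s1, -s2)


class TestNullCount:
    def test_null_counts_match_binomial(self):
        # independent null genes: count ~ Binomial(m, threshold)
        E = _null_frame(n=182, m=215, seed=11)
        y = np.random.default_rng(12).standard_normal(182)
        out = null_gene_count(E, y, n_perm=4000, threshold=0.01, seed=13)
        from scipy import stats
        binom = stats.binom(215, 0.01)
        ks_grid = np.arange(0, 12)
        emp = np.array([(out["counts"] == k).mean() for k in ks_grid])
        theo = binom.pmf(ks_grid)
        assert 0.5 * np.abs(emp - theo).sum() < 0.05   # total variation

    def test_observed_count_beyond_null(self):
        E = _null_frame(n=100, m=20, seed=14)
        y = np.random.default_rng(15).standard_normal(100)
        out = null_gene_count(E, y, n_perm=300, seed=16, observed_count=21)
        assert out["p"] == pytest.approx(1 / 301)

    def test_threshold_one_counts_everything(self):
        E = _null_frame(n=50, m=8, seed=17)
        y = np.random.default_rng(18).standard_normal(50)
        out = null_gene_count(E, y, n_perm=50, threshold=1.0, seed=19)
        assert (out["counts"] == 8).all()


class TestValidation:
    def test_split_half_on_planted_cohort(self, cohort182):
        _, co = cohort182
        folds = split_half_validate(co.expr_rest, co.phenotypes["pi"].to_numpy(),
                                    seed=20, n_perm=300)
        assert len(folds) == 2
        for f in folds:
            assert f["informative"]
            assert f["r"] > 0
            assert f["p"] < 0.05

    def test_split_deterministic(self, cohort182):
        _, co = cohort182
        a = split_half_validate(co.expr_rest, co.phenotypes["pi"].to_numpy(),
                                seed=21, n_perm=100)
        b = split_half_validate(co.expr_rest, co.phenotypes["pi"].to_numpy(),
                                seed=21, n_perm=100)
        assert a[0]["r"] == b[0]["r"] and a[1]["p"] == b[1]["p"]

    def test_overfitting_direction_on_null(self):
        # in-sample r after selection exceeds held-out r on a null cohort
        E = _null_frame(n=120, m=80, seed=22)
        y = np.random.default_rng(23).standard_normal(120)
        corr = correlate_genes(E, y, n_perm=300, seed=24)
        model = build_signature(corr, threshold=0.2)
        if not model.empty:
            _, r_train = score_individuals(model, E, y)
            folds = split_half_validate(E, y, seed=25, threshold=0.2, n_perm=100)
            held = [f["r"] for f in folds if f["informative"]]
            if held:
                assert r_train > np.mean(held)

    def test_cross_visit_identical_copy(self, cohort182):
        _, co = cohort182
        y = co.phenotypes["pi"].to_numpy()
        rf, pf, rb, pb = cross_visit_replicate(
            co.expr_rest, y, co.expr_rest, y, n_perm=200, seed=26)
        corr = correlate_genes(co.expr_rest, y, n_perm=1000, seed=0)
        # forward r equals the training r of the visit-1 signature
        model = build_signature(corr)
        _, r_train = score_individuals(model, co.expr_rest, y)
        assert rf == pytest.approx(r_train, abs=0.05)
        assert pf < 0.05

    def test_cross_visit_noisy_replicates(self, cohort182):
        _, co = cohort182
        rng = np.random.default_rng(27)
        E1 = co.expr_rest.values
        E2 = E1 + rng.standard_normal(E1.shape) * 0.5
        y1 = co.phenotypes["pi"].to_numpy()
        y2 = y1 + rng.standard_normal(len(y1)) * co.phenotypes["pi"].std() * 0.5
        rf, pf, rb, pb = cross_visit_replicate(E1, y1, E2, y2, n_perm=200, seed=28)
        assert rf > 0 and rb > 0

    def test_cross_visit_second_visit_simulation(self, cohort182):
        # a simulated re-assay keeps the latent proliferation propensity,
        # so the visit-1 signature predicts visit-2 proliferation
        from temqtl.synth import simulate_second_visit

        cfg, co = cohort182
        E2, y2 = simulate_second_visit(co, cfg, seed=30)
        assert E2.individuals.equals(co.expr_rest.individuals)
        E2b, y2b = simulate_second_visit(co, cfg, seed=30)
        assert np.allclose(E2.values, E2b.values)
        rf, pf, rb, pb = cross_visit_replicate(
            co.expr_rest, co.phenotypes["pi"].to_numpy(),
            E2.values, y2.to_numpy(), n_perm=200, seed=31)
        assert rf > 0.3 and pf < 0.05

    def test_disjoint_individuals_error(self):
        E1 = _null_frame(n=30, m=5, seed=29)
        E2 = _null_frame(n=30, m=5, seed=30)
        E2.index = [f"J{i}" for i in range(30)]
        with pytest.raises(ValueError, match="shared"):
            cross_visit_replicate(E1, np.zeros(30), E2, np.zeros(30))
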
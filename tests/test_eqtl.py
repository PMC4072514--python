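"""Cis-eQTL machinery: QC, PCs, windows, OLS, permutations, conditioning."""

import numpy as np
import pandas as pd
import pytest

from temqtl.containers import GenotypeMatrix
from temqtl.eqtl import (
    beta_to_fold,
    cis_window_snps,
    compute_genotype_pcs,
    conditional_scan,
    define_disease_locus,
    fdr_select,
    fit_snp_association,
    genotype_qc_filter,
    ld_r2,
    scan_gene_cis,
    state_difference_test,
)
from temqtl.synth import SimCohortConfig, simulate_cohort, simulate_genotypes


def _toy_genotypes(mafs, r2s=None, pos=None):
    m = len(mafs)
    rng = np.random.default_rng(0)
    D = rng.binomial(2, mafs, size=(30, m)).astype(float)
    snps = pd.DataFrame({
        "chrom": "1",
        "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
        "ref": "A", "alt": "G",
        "maf": mafs,
        "r2": r2s if r2s is not None else np.ones(m),
    }, index=pd.Index([f"s{i}" for i in range(m)], name="snp"))
    ids = pd.Index([f"I{i}" for i in range(30)])
    return GenotypeMatrix(pd.DataFrame(D, index=ids, columns=snps.index), snps)


class TestQcFilter:
    def test_maf_threshold_strict(self):
        g = _toy_genotypes([0.009, 0.01, 0.3])
        kept = genotype_qc_filter(g)
        assert list(kept.snps.index) == ["s1", "s2"]

    def test_quality_boundary_retained(self):
        g = _toy_genotypes([0.3, 0.3, 0.3], r2s=[0.39, 0.4, 0.9])
        kept = genotype_qc_filter(g)
        assert list(kept.snps.index) == ["s1", "s2"]

    def test_counting(self):
        rng = np.random.default_rng(1)
        mafs = np.concatenate([np.full(10, 0.005), rng.uniform(0.05, 0.5, 90)])
        g = _toy_genotypes(mafs)
        assert genotype_qc_filter(g).n_snps == 90

    def test_all_removed(self):
        g = _toy_genotypes([0.001, 0.002])
        with pytest.raises(ValueError, match="all SNPs"):
            genotype_qc_filter(g)


class TestGenotypePcs:
    def test_pc1_separates_subpopulations(self):
        cfg = SimCohortConfig(n_individuals=200, n_snps=2000, n_subpops=2,
                              fst=0.1, ld_block_size=1, seed=1)
        g = simulate_genotypes(cfg)
        pcs, frac = compute_genotype_pcs(g, k=5)
        labels = g.subpop.to_numpy()
        r = np.corrcoef(pcs["PC1"], labels)[0, 1]
        assert abs(r) > 0.9
        assert frac[0] > frac[1]

    def test_no_structure_small_fractions(self):
        cfg = SimCohortConfig(n_individuals=200, n_snps=2000, n_subpops=1,
                              fst=0.0, ld_block_size=1, seed=2)
        g = simulate_genotypes(cfg)
        _, frac = compute_genotype_pcs(g, k=5)
        assert np.all(frac < 3 / 200 + 0.02)

    def test_duplicate_individual_identical_rows(self):
        cfg = SimCohortConfig(n_individuals=50, n_snps=300, seed=3)
        g = simulate_genotypes(cfg)
        dos = g.dosages.copy()
        dos.iloc[1] = dos.iloc[0]
        g2 = GenotypeMatrix(dos, g.snps)
        pcs, _ = compute_genotype_pcs(g2, k=3)
        assert np.allclose(pcs.iloc[0], pcs.iloc[1], atol=1e-10)


class TestCisWindow:
    def test_boundaries_inclusive(self):
        g = _toy_genotypes([0.3] * 4, pos=[250_000, 750_000, 1_250_000, 1_250_001])
        gene = pd.Series({"chrom": "1", "tss": 500_000, "strand": "+"})
        assert cis_window_snps(gene, g) == ["s0", "s1"]  # tss-250k included
        gene2 = pd.Series({"chrom": "1", "tss": 1_000_000, "strand": "+"})
        assert cis_window_snps(gene2, g) == ["s1", "s2"]  # tss+250001 excluded

    def test_enumeration_in_position_order(self):
        offsets = [-300_000, -250_000, -100_000, -5, 0, 90_000, 249_999,
                   250_000, 250_001, 400_000]
        pos = [1_000_000 + o for o in offsets]
        g = _toy_genotypes([0.3] * 10, pos=pos)
        gene = pd.Series({"chrom": "1", "tss": 1_000_000, "strand": "+"})
        got = cis_window_snps(gene, g)
        assert got == [f"s{i}" for i in range(1, 8)]


class TestSnpAssociation:
    def _cov(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {**{f"PC{k}": rng.standard_normal(n) for k in range(1, 6)},
             "gender": rng.integers(0, 2, n).astype(float)}
        )

    def test_perfect_fit(self):
        n = 40
        cov = self._cov(n)
        d = np.tile([0.0, 1.0, 2.0, 1.0], n // 4)
        beta, se, p, _ = fit_snp_association(d, d, cov)
        assert beta == pytest.approx(1.0, abs=1e-10)
        assert p < 1e-12

    def test_frisch_waugh_oracle(self):
        # closed-form simple regression on residualized vectors
        rng = np.random.default_rng(5)
        n = 12
        cov = self._cov(n, seed=5)
        d = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 * d + rng.standard_normal(n)
        beta, se, p, _ = fit_snp_association(y, d, cov)

        import statsmodels.api as sm
        X = np.column_stack([np.ones(n), cov.to_numpy()])
        yr = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        dr = d - X @ np.linalg.lstsq(X, d, rcond=None)[0]
        slope = (yr @ dr) / (dr @ dr)
        assert beta == pytest.approx(slope, abs=1e-8)
        full = sm.OLS(y, np.column_stack([X, d])).fit()
        assert se == pytest.approx(full.bse[-1], abs=1e-8)
        assert p == pytest.approx(full.pvalues[-1], abs=1e-8)

    def test_monomorphic_rejected(self):
        cov = self._cov(20)
        with pytest.raises(ValueError, match="monomorphic"):
            fit_snp_association(np.random.default_rng(0).standard_normal(20),
                                np.ones(20), cov)

    def test_collinear_design_named(self):
        cov = self._cov(20)
        cov["PC2"] = cov["PC1"]
        with pytest.raises(ValueError, match="collinear"):
            fit_snp_association(np.arange(20.0),
                                np.random.default_rng(1).binomial(2, .4, 20).astype(float),
                                cov)


class TestScan:
    def test_lead_snp_recovery(self, small_cohort, eqtl_covariates):
        cfg, co = small_cohort
        cov = eqtl_covariates(co)
        hits = tot = 0
        for g, row in co.truth.eqtl_map.iterrows():
            if abs(row["beta_rest"]) < 0.8:
                continue
            res = scan_gene_cis(g, co.truth.gene_annotation, co.genotypes,
                                co.expr_rest.values, cov, n_perm=500, seed=1)
            r2 = ld_r2(co.genotypes.dosages[res.lead_snp],
                       co.genotypes.dosages[row["causal_snp"]])
            tot += 1
            hits += (res.lead_snp == row["causal_snp"]) or (r2 > 0.8)
        assert tot >= 3
        assert hits == tot

    def test_empirical_floor(self, small_cohort, eqtl_covariates):
        cfg, co = small_cohort
        cov = eqtl_covariates(co)
        strong = co.truth.eqtl_map["beta_rest"].abs().idxmax()
        res = scan_gene_cis(strong, co.truth.gene_annotation, co.genotypes,
                            co.expr_rest.values, cov, n_perm=500, seed=2)
        assert res.lead.empirical_p == pytest.approx(1 / 501)

    def test_low_n_perm_refused(self, small_cohort, eqtl_covariates):
        cfg, co = small_cohort
        g = co.truth.eqtl_map.index[0]
        with pytest.raises(ValueError, match="n_perm"):
            scan_gene_cis(g, co.truth.gene_annotation, co.genotypes,
                          co.expr_rest.values, eqtl_covariates(co), n_perm=50)

    def test_determinism_across_calls(self, small_cohort, eqtl_covariates):
        cfg, co = small_cohort
        g = co.truth.eqtl_map.index[0]
        a = scan_gene_cis(g, co.truth.gene_annotation, co.genotypes,
                          co.expr_rest.values, eqtl_covariates(co), n_perm=300, seed=7)
        b = scan_gene_cis(g, co.truth.gene_annotation, co.genotypes,
                          co.expr_rest.values, eqtl_covariates(co), n_perm=300, seed=7)
        assert a.table.equals(b.table)


class TestFdr:
    def test_all_ones_nothing_flagged(self):
        df = pd.DataFrame({"empirical_p": [1.0, 1.0, 1.0]},
                          index=["a", "b", "c"])
        out = fdr_select(df)
        assert not out["significant"].any()

    def test_bh_hand_computation(self):
        df = pd.DataFrame({"empirical_p": [0.0001, 0.002, 0.9]},
                          index=["g1", "g2", "g3"])
        out = fdr_select(df)
        assert out["fdr_q"].tolist() == pytest.approx([0.0003, 0.003, 0.9])


class TestConditional:
    def test_causal_conditioning_explains(self, small_cohort, eqtl_covariates):
        cfg, co = small_cohort
        cov = eqtl_covariates(co)
        strong = co.truth.eqtl_map["beta_rest"].abs().idxmax()
        causal = co.truth.eqtl_map.loc[strong, "causal_snp"]
        c = conditional_scan(strong, causal, co.truth.gene_annotation,
                             co.genotypes, co.expr_rest.values, cov,
                             n_perm=500, seed=3)
        assert c.fully_explained

    def test_unlinked_conditioning_keeps_signal(self, small_cohort, eqtl_covariates):
        cfg, co = small_cohort
        cov = eqtl_covariates(co)
        strong = co.truth.eqtl_map["beta_rest"].abs().idxmax()
        tss = co.truth.gene_annotation.loc[strong, "tss"]
        far = (co.genotypes.snps["pos"] - tss).abs().idxmax()
        c = conditional_scan(strong, far, co.truth.gene_annotation,
                             co.genotypes, co.expr_rest.values, cov,
                             n_perm=500, seed=3)
        assert not c.fully_explained

    def test_perfect_proxy_always_explains(self, small_cohort, eqtl_covariates):
        cfg, co = small_cohort
        cov = eqtl_covariates(co)
        strong = co.truth.eqtl_map["beta_rest"].abs().idxmax()
        causal = co.truth.eqtl_map.loc[strong, "causal_snp"]
        dup = co.genotypes.dosages.copy()
        dup["dup_snp"] = dup[causal]
        meta = co.genotypes.snps.copy()
        row = meta.loc[causal].copy()
        row["pos"] = int(meta["pos"].max()) + 1000
        meta.loc["dup_snp"] = row
        g2 = GenotypeMatrix(dup, meta)
        c = conditional_scan(strong, "dup_snp", co.truth.gene_annotation,
                             g2, co.expr_rest.values, cov, n_perm=500, seed=4)
        assert c.fully_explained


class TestStateDifference:
    def test_reference_effect_pair(self):
        sc = state_difference_test(-0.366, 0.085, -0.805, 0.071)
        assert sc.p_delta == pytest.approx(7.38e-5, rel=0.02)

    def test_equal_betas(self):
        sc = state_difference_test(0.4, 0.1, 0.4, 0.2)
        assert sc.z == 0.0
        assert sc.p_delta == 1.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            state_difference_test(0.1, 0.0, 0.2, 0.1)


class TestFoldAndLd:
    @pytest.mark.parametrize("beta, fold", [(-0.805, 0.45), (0.0, 1.0), (1.112, 3.04)])
    def test_fold_values(self, beta, fold):
        assert round(beta_to_fold(beta), 2) == fold

    def test_exp_ln_identity(self):
        for f in (0.45, 1.0, 3.04, 10.0):
            assert beta_to_fold(np.log(f)) == pytest.approx(f, abs=1e-12)

    def test_identical_and_flipped_vectors(self):
        a = np.array([0, 0, 1, 1, 2, 2.0])
        assert ld_r2(a, a) == pytest.approx(1.0)
        assert ld_r2(a, 2 - a) == pytest.approx(1.0)

    def test_hand_pearson(self):
        a = np.array([0, 0, 1, 1, 2, 2.0])
        b = np.array([0, 1, 0, 1, 2, 2.0])
        # cov = 0.5, var_a = var_b = 2/3 -> r = 0.75, r^2 = 0.5625
        assert ld_r2(a, b) == pytest.approx(0.5625)

    def test_monomorphic_undefined(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(np.ones(6), np.array([0, 1, 2, 0, 1, 2.0]))


class TestDiseaseLocus:
    def _block_genotypes(self):
        rng = np.random.default_rng(2)
        base = rng.binomial(2, 0.4, 200).astype(float)
        cols, pos = {}, []
        # partners at +/-40 kb in perfect LD; unlinked SNPs beyond
        layout = [(-100_000, False), (-40_000, True), (0, True),
                  (40_000, True), (100_000, False)]
        for i, (off, linked) in enumerate(layout):
            cols[f"s{i}"] = base if linked else rng.binomial(2, 0.4, 200).astype(float)
            pos.append(1_000_000 + off)
        snps = pd.DataFrame({"chrom": "1", "pos": pos, "ref": "A", "alt": "G",
                             "maf": 0.4, "r2": 1.0},
                            index=pd.Index(list(cols), name="snp"))
        ids = pd.Index([f"I{i}" for i in range(200)])
        return GenotypeMatrix(pd.DataFrame(cols, index=ids), snps)

    def test_ld_span_extended_to_hotspots(self):
        g = self._block_genotypes()
        genes = pd.DataFrame({"chrom": ["1"], "tss": [1_000_000], "strand": ["+"]},
                             index=["geneA"])
        lo, hi = define_disease_locus("s2", g, hotspots=[940_000, 1_060_000],
                                      genes=genes)
        assert (lo, hi) == (940_000, 1_060_000)

    def test_no_partners_hotspot_window(self):
        g = self._block_genotypes()
        genes = pd.DataFrame({"chrom": ["1"], "tss": [1_000_000], "strand": ["+"]},
                             index=["geneA"])
        lo, hi = define_disease_locus("s0", g, hotspots=[880_000, 920_000],
                                      genes=genes)
        # hotspot-bounded window holds no gene TSS -> padded both sides
        assert (lo, hi) == (880_000 - 250_000, 920_000 + 250_000)

    def test_gene_free_interval_padded(self):
        g = self._block_genotypes()
        genes = pd.DataFrame({"chrom": ["1"], "tss": [5_000_000], "strand": ["+"]},
                             index=["geneB"])
        lo, hi = define_disease_locus("s2", g, hotspots=[940_000, 1_060_000],
                                      genes=genes)
        assert (lo, hi) == (940_000 - 250_000, 1_060_000 + 250_000)
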
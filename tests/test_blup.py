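"""Mixed-model tests: A-matrix, REML vs closed forms, AIC search, GxY gate, h²."""

import numpy as np
import pandas as pd
import pytest

from cranqtl.blup import (
    RandomTerm,
    VarianceComponents,
    build_terms,
    compute_A,
    fit_reml,
    fixed_design,
    gate_gxy,
    heritability,
    incidence,
    select_model_aic,
)


def vc_of(sa=0.0, sge=None, se=1.0):
    comps = {"genotype": sa}
    if sge is not None:
        comps["gxy"] = sge
    return VarianceComponents(comps, se, 0.0, 0.0, len(comps) + 2, True, 0)


class TestAMatrix:
    def test_matches_centered_crossproduct_oracle(self):
        rng = np.random.default_rng(40)
        M = rng.integers(0, 3, size=(25, 60)).astype(float)
        A = compute_A(pd.DataFrame(M)).to_numpy()
        p = M.mean(axis=0) / 2
        W = M - 2 * p
        oracle = W @ W.T / (2 * np.sum(p * (1 - p)))
        assert np.allclose(A, oracle, atol=1e-10)

    def test_duplicate_genotypes_share_diagonal(self):
        rng = np.random.default_rng(41)
        M = rng.integers(0, 3, size=(10, 40)).astype(float)
        M[1] = M[0]
        A = compute_A(pd.DataFrame(M)).to_numpy()
        assert A[0, 1] == pytest.approx(A[0, 0], abs=1e-12)

    def test_psd_and_symmetric(self):
        rng = np.random.default_rng(42)
        A = compute_A(pd.DataFrame(rng.integers(0, 3, (20, 50)).astype(float)))
        assert np.allclose(A, A.T)
        assert np.linalg.eigvalsh(A.to_numpy()).min() > -1e-8

    def test_monomorphic_only_errors(self):
        M = np.ones((5, 12))
        with pytest.raises(ValueError):
            compute_A(pd.DataFrame(M))


class TestREML:
    def balanced_oneway(self, seed, ng=60, reps=4, sa2=3.0, se2=1.0):
        rng = np.random.default_rng(seed)
        g = np.repeat(np.arange(ng), reps)
        y = rng.normal(0, np.sqrt(sa2), ng)[g] + rng.normal(0, np.sqrt(se2), ng * reps)
        Z, lev = incidence(g)
        return y, Z, lev, g

    def test_matches_balanced_anova_closed_form(self):
        y, Z, lev, g = self.balanced_oneway(43)
        ng, reps = len(lev), len(y) // len(lev)
        vc, _ = fit_reml(y, np.ones((len(y), 1)),
                         [RandomTerm("genotype", Z, None, lev)])
        gm = pd.Series(y).groupby(g).mean()
        mse = float(((y - gm[g].to_numpy()) ** 2).sum()) / (len(y) - ng)
        msa = reps * float(((gm - gm.mean()) ** 2).sum()) / (ng - 1)
        assert vc.residual == pytest.approx(mse, abs=1e-6)
        assert vc.components["genotype"] == pytest.approx((msa - mse) / reps, abs=1e-6)

    def test_constant_response_zero_variances(self):
        Z, lev = incidence(np.repeat(np.arange(10), 3))
        vc, blup = fit_reml(np.full(30, 7.0), np.ones((30, 1)),
                            [RandomTerm("genotype", Z, None, lev)])
        assert vc.components["genotype"] == 0.0
        assert np.allclose(blup.effects["genotype"], 0.0)

    def test_blup_shrinkage_and_centering(self):
        """With A = I, BLUPs shrink genotype means toward zero and sum to ~0."""
        y, Z, lev, g = self.balanced_oneway(44)
        vc, blup = fit_reml(y, np.ones((len(y), 1)),
                            [RandomTerm("genotype", Z, None, lev)])
        u = blup.effects["genotype"]
        adj_means = pd.Series(y - y.mean()).groupby(g).mean().to_numpy()
        assert np.all(np.abs(u) <= np.abs(adj_means) + 1e-9)
        assert abs(u.sum()) < 1e-6 * len(u)

    def test_dense_multi_term_path_agrees_with_fast_path(self):
        """Adding a null second term must not change the genotype variance much,
        and the two likelihood code paths agree on the shared model."""
        y, Z, lev, g = self.balanced_oneway(45, ng=30, reps=3)
        X = np.ones((len(y), 1))
        vc1, _ = fit_reml(y, X, [RandomTerm("genotype", Z, None, lev)])
        rng = np.random.default_rng(0)
        Z2, lev2 = incidence(rng.integers(0, 5, len(y)))
        vc2, _ = fit_reml(y, X, [RandomTerm("genotype", Z, None, lev),
                                 RandomTerm("block", Z2, None, lev2)])
        assert vc2.components["genotype"] == pytest.approx(
            vc1.components["genotype"], rel=0.15)

    def test_rank_deficient_fixed_design_rejected(self):
        y = np.arange(6.0)
        X = np.ones((6, 2))
        Z, lev = incidence([0, 0, 1, 1, 2, 2])
        with pytest.raises(ValueError):
            fit_reml(y, X, [RandomTerm("genotype", Z, None, lev)])


class TestModelSelection:
    @staticmethod
    def field_data(rng, ng=64, row_sd=0.0):
        data = pd.DataFrame({
            "genotype": [f"g{i:02d}" for i in range(ng)],
            "row": np.repeat(np.arange(1, 9), 8),
            "col": np.tile(np.arange(1, 9), 8),
            "year": 2011,
        })
        y = (rng.normal(0, 1.0, ng)
             + rng.normal(0, row_sd, 8)[data["row"] - 1]
             + rng.normal(0, 0.5, ng))
        data["value"] = y
        return data, y

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(46)
        data, y = self.field_data(rng)
        subset, vc, blup, terms, tab = select_model_aic(
            y, np.ones((len(y), 1)), data, optional=())
        assert subset == ()
        assert len(tab) == 1

    def test_strong_row_effect_selects_row_term(self):
        hits = 0
        n_sim = 25
        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            data, y = self.field_data(rng, row_sd=2.0)
            subset, *_ = select_model_aic(y, np.ones((len(y), 1)), data,
                                          optional=("row", "col"))
            hits += "row" in subset
        assert hits >= int(0.9 * n_sim)

    def test_pure_noise_prefers_small_models(self):
        sizes = []
        for s in range(20):
            rng = np.random.default_rng(2000 + s)
            data, y = self.field_data(rng, row_sd=0.0)
            subset, *_ = select_model_aic(y, np.ones((len(y), 1)), data,
                                          optional=("row", "col"))
            sizes.append(len(subset))
        assert np.mean(sizes) < 1.0
        assert sizes.count(0) >= 10


class TestGxYGate:
    @staticmethod
    def gxy_data(rng, ng=40, years=3, reps=2, sge=0.0):
        recs = []
        g_eff = rng.normal(0, 1.0, ng)
        for yidx in range(years):
            ge = rng.normal(0, np.sqrt(sge), ng) if sge > 0 else np.zeros(ng)
            for i in range(ng):
                for _ in range(reps):
                    recs.append((f"g{i:02d}", 2011 + yidx,
                                 g_eff[i] + ge[i] + rng.normal(0, 1.0)))
        return pd.DataFrame(recs, columns=["genotype", "year", "value"])

    def fit_pair(self, data):
        y = data["value"].to_numpy()
        X, _ = fixed_design(data, year_fixed=True)
        with_ge = build_terms(data, include=(), gxy=True)
        without = build_terms(data, include=(), gxy=False)
        vc1, _ = fit_reml(y, X, with_ge)
        vc0, _ = fit_reml(y, X, without)
        return vc1, vc0

    def test_identical_fits_drop_ge(self):
        vc1 = vc_of(sa=1.0, sge=0.0, se=1.0)
        vc1.loglik = -100.0
        vc0 = vc_of(sa=1.0, se=1.0)
        vc0.loglik = -100.0
        keep, stat, p = gate_gxy(vc1, vc0)
        assert not keep and stat == 0.0 and p == 1.0

    def test_large_interaction_detected(self):
        rng = np.random.default_rng(47)
        vc1, vc0 = self.fit_pair(self.gxy_data(rng, sge=2.0))
        keep, stat, p = gate_gxy(vc1, vc0)
        assert keep and p < 0.001

    def test_null_interaction_mostly_dropped(self):
        kept = 0
        for s in range(20):
            rng = np.random.default_rng(3000 + s)
            vc1, vc0 = self.fit_pair(self.gxy_data(rng, ng=25, sge=0.0))
            keep, *_ = gate_gxy(vc1, vc0)
            kept += keep
        assert kept <= 4   # nominal 5% type-I rate

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            gate_gxy(vc_of(sa=1.0), vc_of(sa=1.0))


class TestHeritability:
    def test_direct_formulas(self):
        assert heritability(vc_of(sa=3.0, se=1.0)) == pytest.approx(0.75)
        assert heritability(vc_of(sa=1.0, sge=1.0, se=1.0), True, 2) == pytest.approx(0.5)
        assert heritability(vc_of(sa=0.0, se=1.0)) == 0.0

    def test_grid_in_unit_interval(self):
        vals = [0.0, 0.5, 1.0, 3.0]
        for sa in vals:
            for sge in vals:
                for se in vals:
                    for n in (1, 2, 3):
                        h_w = heritability(vc_of(sa=sa, se=se))
                        h_a = heritability(vc_of(sa=sa, sge=sge, se=se), True, n)
                        for h in (h_w, h_a):
                            if not np.isnan(h):
                                assert 0.0 <= h <= 1.0

    def test_across_ge_within_ordering(self):
        """Across-year h² >= within-year h² whenever sge <= se*(n-1)."""
        vals = [0.0, 0.5, 1.0, 3.0]
        for sa in vals:
            for sge in vals:
                for se in vals:
                    for n in (2, 3):
                        if sge <= se * (n - 1) and sa + se > 0:
                            h_w = heritability(vc_of(sa=sa, se=se))
                            h_a = heritability(vc_of(sa=sa, sge=sge, se=se), True, n)
                            if not (np.isnan(h_w) or np.isnan(h_a)):
                                assert h_a >= h_w - 1e-12

    def test_zero_denominator_flagged(self):
        assert np.isnan(heritability(vc_of(sa=0.0, se=0.0)))
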
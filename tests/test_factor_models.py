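"""PCA/EFA/CFA on genetic covariance matrices: recovery and fit-index behavior."""

import numpy as np
import pytest

from pygsem import factor_models as fm
from pygsem.ldsc import GeneticCovariance, build_S_V
from pygsem.simulate import TruthModel, simulate_sumstats, simulate_true_effects
from pygsem.sumstats import SumstatsTable

from conftest import ld_scores_frame, three_cluster_truth


def _gc_from_matrix(S, se=0.01, subset="even_chr", traits=None):
    """A GeneticCovariance with homoskedastic sampling variances (for unit tests)."""
    S = np.asarray(S, dtype=float)
    k = S.shape[0]
    p = k * (k + 1) // 2
    return GeneticCovariance(
        traits=traits or [f"t{i+1}" for i in range(k)],
        S=S, V=np.eye(p) * se ** 2, intercepts=np.eye(k),
        n_blocks=0, subset=subset)


class TestSmoothToPD:
    def test_pd_input_returned_unchanged(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        out = fm.smooth_to_pd(S)
        assert (out == S).all()

    def test_excess_correlation_shrunk_below_one(self):
        S = np.array([[1.0, 1.2], [1.2, 1.0]])
        out = fm.smooth_to_pd(S)
        assert abs(out[0, 1]) < 1.0
        np.testing.assert_allclose(np.diag(out), [1.0, 1.0])

    def test_indefinite_matrix_gets_floor_eigenvalue(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((10, 10))
        S = (A + A.T) / 2
        np.fill_diagonal(S, np.abs(np.diag(S)) + 0.5)
        out = fm.smooth_to_pd(S)
        # rescaling to preserve the diagonal can nudge the smallest
        # eigenvalue, but positive definiteness must hold
        assert np.linalg.eigvalsh(out).min() > 0
        np.testing.assert_allclose(np.diag(out), np.diag(S))


class TestPCAScree:
    def test_identity_correlation_retains_nothing(self):
        gc = _gc_from_matrix(np.eye(10), subset="odd_chr")
        res = fm.pca_scree(gc)
        np.testing.assert_allclose(res.eigenvalues, np.ones(10), atol=1e-9)
        assert res.n_retained == 0

    def test_kaiser_rule_counts_strictly_above_one(self):
        # correlation matrix with eigenvalues {2.1, 1.3, 1.05, ...}
        target = np.array([2.1, 1.3, 1.05, 0.4, 0.35, 0.3, 0.25, 0.25])
        target = target / target.sum() * 8
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        S = Q @ np.diag(target) @ Q.T
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        gc = _gc_from_matrix(S, subset="odd_chr")
        res = fm.pca_scree(gc)
        assert res.n_retained == int((np.linalg.eigvalsh(S) > 1).sum())

    def test_three_cluster_truth_retains_three(self, study_3cluster):
        res = fm.pca_scree(study_3cluster["gc_odd_psy"])
        assert res.n_retained == 3

    def test_wrong_subset_warns(self, study_3cluster):
        with pytest.warns(UserWarning, match="odd"):
            fm.pca_scree(study_3cluster["gc_even"])


class TestEFA:
    def test_single_factor_loadings_recovered(self, ld_50k):
        # recovery is bounded by LDSC noise in the correlation entries
        # (SE ~ 0.03-0.07 per element at M = 50k), hence the mean/max bounds
        truth = TruthModel.from_standardized(
            np.full((6, 1), 0.7), [[1.0]], np.full(6, 0.2), np.full(6, 5e4))
        eff = simulate_true_effects(truth, ld_50k, 1.0, seed=41)
        tabs = simulate_sumstats(eff, truth, ld_50k, seed=42)
        tables = [SumstatsTable(t, name=n) for t, n in zip(tabs, truth.trait_names)]
        gc = build_S_V(tables, ld_scores_frame(ld_50k), subset="all")
        res = fm.efa_fit(gc, 1)
        assert np.mean(np.abs(res.loadings[:, 0] - 0.7)) < 0.05
        assert np.abs(res.loadings[:, 0] - 0.7).max() < 0.15

    def test_orthogonal_blocks_have_small_cross_loadings(self):
        L = np.zeros((8, 2))
        L[:4, 0] = 0.7
        L[4:, 1] = 0.6
        R = L @ L.T
        np.fill_diagonal(R, 1.0)
        gc = _gc_from_matrix(R)
        res = fm.efa_fit(gc, 2)
        primary = np.abs(res.loadings).argmax(axis=1)
        for i in range(8):
            other = 1 - primary[i]
            assert abs(res.loadings[i, other]) < 0.1

    def test_three_cluster_pattern_proposed(self, study_3cluster):
        res = fm.efa_fit(study_3cluster["gc_odd_psy"], 3)
        pattern = res.proposed_pattern()
        clusters = [set(c) for c in pattern.values()]
        assert {"alc", "can", "smk"} in clusters
        assert {"bip", "scz"} in clusters
        assert {"adhd", "anx", "asd", "mdd", "ptsd"} in clusters

    def test_saturated_limit_reproduces_correlations(self):
        rng = np.random.default_rng(3)
        L = rng.uniform(0.3, 0.7, size=(5, 1))
        R = L @ L.T
        np.fill_diagonal(R, 1.0)
        gc = _gc_from_matrix(R)
        res = fm.efa_fit(gc, 1)
        implied = res.loadings @ res.factor_corr @ res.loadings.T
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(implied[off], R[off], atol=1e-3)


def _cfa_text(pattern):
    return "\n".join(f"{f} =~ {' + '.join(ind)}" for f, ind in pattern.items())


PATTERN_10 = {"NMD": ["adhd", "anx", "asd", "mdd", "ptsd"],
              "SUT": ["alc", "can", "smk"],
              "DPF": ["bip", "scz"]}


class TestSpecParsing:
    def test_free_and_fixed_parameters_counted(self):
        text = "F =~ a + b + 0.5*c\nG =~ d + e\nLONE =~ 1*f\nf ~~ 0*f\nLONE ~ F + 0*G"
        spec = fm.FactorModelSpec.from_text(text, list("abcdef"))
        names = spec.param_names()
        assert "F=~a" in names and "F=~c" not in names
        assert "LONE~F" in names and "LONE~G" not in names
        assert "f~~f" not in names
        assert spec.df == spec.k * (spec.k + 1) // 2 - spec.n_free

    def test_unidentified_spec_rejected(self):
        text = "F =~ a + b\nG =~ a + b\nF ~~ G"   # more params than moments
        with pytest.raises(ValueError, match="identified"):
            fm.FactorModelSpec.from_text(text, ["a", "b"])

    def test_unknown_indicator_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            fm.FactorModelSpec.from_text("F =~ a + nope", ["a", "b"])


class TestCFA:
    def test_saturated_model_reproduces_S_exactly(self, study_3cluster):
        gc = study_3cluster["gc_even"]
        sub = ["adhd", "anx", "asd"]
        text = ("F1 =~ 1*adhd\nadhd ~~ 0*adhd\nF2 =~ 1*anx\nanx ~~ 0*anx\n"
                "F3 =~ 1*asd\nasd ~~ 0*asd\nF1 ~~ F2\nF1 ~~ F3\nF2 ~~ F3")
        spec = fm.FactorModelSpec.from_text(text, gc.traits)
        assert spec.df == 0
        fit = fm.GenomicFactorModel(gc, spec).fit()
        order = [gc.traits.index(t) for t in sub]
        S = fm.smooth_to_pd(gc.S)[np.ix_(order, order)]
        np.testing.assert_allclose(fit.model.implied_cov(fit.theta), S, atol=1e-6)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.srmr == pytest.approx(0.0, abs=1e-4)
        assert fit.cfi == 1.0

    def test_three_factor_loadings_recovered(self, study_3cluster):
        gc = study_3cluster["gc_even"]
        truth = study_3cluster["truth"]
        spec = fm.FactorModelSpec.from_text(_cfa_text(PATTERN_10), gc.traits)
        fit = fm.GenomicFactorModel(gc, spec).fit()
        assert fit.converged
        # single-run check: every loading consistent with truth at 3.5
        # sandwich SEs (cross-seed medians are checked separately)
        for i, trait in enumerate(truth.trait_names[:10]):
            f = list(PATTERN_10)[np.argmax(np.abs(truth.loadings[i]))]
            name = f"{f}=~{trait}"
            se = fit.bse[fit.param_names.index(name)]
            assert abs(fit.params[name] - truth.loadings[i].max()) < 3.5 * se

    def test_fixing_a_loading_cannot_improve_fit(self, study_3cluster):
        gc = study_3cluster["gc_even"]
        free = fm.GenomicFactorModel(
            gc, fm.FactorModelSpec.from_text(_cfa_text(PATTERN_10), gc.traits)).fit()
        # fix one loading at an off-truth value; the nested model cannot fit better
        txt = _cfa_text(PATTERN_10).replace("adhd", "0.05*adhd")
        fixed = fm.GenomicFactorModel(
            gc, fm.FactorModelSpec.from_text(txt, gc.traits)).fit()
        # nesting monotonicity holds exactly for the minimized discrepancy
        assert fixed.fmin >= free.fmin - 1e-9

    def test_identity_correlation_gives_null_loadings(self):
        gc = _gc_from_matrix(np.eye(6))
        text = "F =~ t1 + t2 + t3 + t4 + t5 + t6"
        fit = fm.GenomicFactorModel(
            gc, fm.FactorModelSpec.from_text(text, gc.traits)).fit()
        assert np.abs(fit.params[:6].to_numpy()).max() < 0.02

    def test_standardized_and_raw_solutions_imply_same_covariance(self, study_3cluster):
        gc = study_3cluster["gc_even"]
        spec = fm.FactorModelSpec.from_text(_cfa_text(PATTERN_10), gc.traits)
        fit = fm.GenomicFactorModel(gc, spec).fit()
        sigma = fit.model.implied_cov(fit.theta)
        std = fit.standardized()
        lam_std = np.zeros((10, 3))
        for f_i, f in enumerate(PATTERN_10):
            for t in PATTERN_10[f]:
                lam_std[spec.observed.index(t), f_i] = std.loc[f"{f}=~{t}", "std_est"]
        phi = fit.model.latent_cov(fit.theta)
        dphi = np.sqrt(np.diag(phi))
        phi_std = phi / np.outer(dphi, dphi)
        theta_std = np.array([std.loc[f"{t}~~{t}", "std_est"]
                              for t in spec.observed])
        implied_corr = lam_std @ phi_std @ lam_std.T + np.diag(theta_std)
        d = np.sqrt(np.diag(sigma))
        np.testing.assert_allclose(implied_corr, sigma / np.outer(d, d), atol=1e-6)


class TestFitIndices:
    def test_baseline_evaluated_as_model_gives_cfi_zero(self, study_3cluster):
        gc = study_3cluster["gc_even"]
        text = "\n".join(f"{t} ~~ {t}" for t in gc.traits[:5])
        spec = fm.FactorModelSpec.from_text(text, gc.traits)
        fit = fm.GenomicFactorModel(gc, spec).fit()
        assert fit.cfi == pytest.approx(0.0, abs=1e-6)

    def test_misspecified_model_has_larger_srmr(self, study_3cluster):
        gc = study_3cluster["gc_even"]
        right = fm.GenomicFactorModel(
            gc, fm.FactorModelSpec.from_text(_cfa_text(PATTERN_10), gc.traits)).fit()
        one = fm.GenomicFactorModel(
            gc, fm.FactorModelSpec.from_text(
                "F =~ " + " + ".join(sum(PATTERN_10.values(), [])),
                gc.traits)).fit()
        assert one.srmr > right.srmr


class TestLonelinessModels:
    def test_constrained_model_recovers_single_path(self, study_3cluster):
        gc = study_3cluster["gc_even"]
        models = fm.loneliness_models(gc, PATTERN_10, "lone", target_factor="NMD")
        row = models.constrained.standardized().loc["LONE~NMD"]
        assert abs(row["std_est"] - 0.66) < 3 * row["std_se"]
        # the two zero-constraints must actually be absent from the free set
        assert "LONE~SUT" not in models.constrained.param_names
        assert "LONE~DPF" not in models.constrained.param_names

    def test_uncorrelated_factors_make_adjustment_a_no_op(self, ld_50k):
        truth = three_cluster_truth(factor_corr=np.eye(3))
        eff = simulate_true_effects(truth, ld_50k, 1.0, seed=51)
        tabs = simulate_sumstats(eff, truth, ld_50k, seed=52)
        tables = [SumstatsTable(t, name=n) for t, n in zip(tabs, truth.trait_names)]
        gc = build_S_V(tables, ld_scores_frame(ld_50k), subset="even_chr")
        models = fm.loneliness_models(gc, PATTERN_10, "lone", target_factor="NMD")
        adj = models.adjusted
        for i, f in enumerate(PATTERN_10):
            uni = models.unadjusted[i]
            b_uni = uni.params[f"LONE~{f}"]
            se_uni = uni.bse[uni.param_names.index(f"LONE~{f}")]
            b_adj = adj.params[f"LONE~{f}"]
            se_adj = adj.bse[adj.param_names.index(f"LONE~{f}")]
            assert abs(b_uni - b_adj) < 2 * np.hypot(se_uni, se_adj) + 1e-3
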
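import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2

import polysometx as px
from polysometx.io import SampleDesign, ValidationError
from polysometx.te_model import (
    build_design,
    estimate_dispersions,
    fit_nb_glm,
    fit_nb_glm_batch,
    lrt_interaction,
    nb_loglik,
    run_te_test,
)


def random_instance(rng, n=8, p=3, phi=0.1):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta = rng.normal(0, 0.5, size=p)
    beta[0] += 2.0
    mu = np.exp(X @ beta)
    if phi > 0:
        y = rng.poisson(rng.gamma(1 / phi, mu * phi))
    else:
        y = rng.poisson(mu)
    return y.astype(float), X


class TestBuildDesign:
    def test_default_design_has_seven_columns(self, small_dataset):
        _, designs, _ = small_dataset
        dm = build_design(designs)
        # intercept + 2 cell-line + 1 replicate + knockdown + fraction + interaction
        assert dm.full.shape == (24, 7)
        assert dm.columns[-1] == "knockdown:fraction"
        assert np.linalg.matrix_rank(dm.full) == 7

    def test_reduced_is_full_without_interaction(self, small_dataset):
        _, designs, _ = small_dataset
        dm = build_design(designs)
        assert np.array_equal(dm.reduced, dm.full[:, :-1])

    def test_missing_fraction_level_rejected(self, small_dataset):
        _, designs, _ = small_dataset
        total_only = [d for d in designs if d.fraction == "total"]
        with pytest.raises(ValidationError, match="polysome"):
            build_design(total_only)

    def test_confounded_design_names_column(self):
        # replicate label perfectly aliases the knockdown indicator
        designs = [
            SampleDesign(f"s{i}", "cl", "r1" if c == "control" else "r2", c, f)
            for i, (c, f) in enumerate(
                [(c, f) for c in ("control", "knockdown") for f in ("total", "polysome")]
            )
        ]
        with pytest.raises(ValidationError, match="confounded"):
            build_design(designs)


class TestNBGLMFit:
    def test_intercept_only_poisson_mle_is_mean(self):
        fit = fit_nb_glm(np.array([3.0, 5.0]), np.ones((2, 1)), phi=0.0)
        assert np.allclose(fit.mu, 4.0, atol=1e-8)

    def test_saturated_design_fits_exactly(self):
        y = np.array([3.0, 7.0, 11.0, 2.0])
        X = np.eye(4)
        fit = fit_nb_glm(y, X, phi=0.2)
        assert np.allclose(fit.mu, y, atol=1e-6)

    def test_offsets_shift_intercept(self):
        y = np.array([10.0, 20.0, 40.0, 80.0])
        off = np.log(np.array([1.0, 2.0, 4.0, 8.0]))
        fit = fit_nb_glm(y, np.ones((4, 1)), offset=off, phi=0.0)
        assert fit.coef[0] == pytest.approx(np.log(10.0), abs=1e-8)

    def test_all_zero_gene_flagged_unusable(self):
        fit = fit_nb_glm(np.zeros(6), np.ones((6, 1)), phi=0.1)
        assert not fit.usable

    def test_matches_statsmodels_poisson_at_zero_dispersion(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        for _ in range(20):
            y, X = random_instance(rng, phi=0.0)
            fit = fit_nb_glm(y, X, phi=0.0)
            ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            assert np.allclose(fit.coef, ref.params, atol=1e-8)

    def test_irls_beats_random_and_derivative_free_search(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            y, X = random_instance(rng, phi=0.1)
            fit = fit_nb_glm(y, X, phi=0.1)
            # 200 random coefficient vectors never beat the IRLS optimum
            for _ in range(200):
                beta = fit.coef + rng.normal(0, 0.5, size=3)
                ll = nb_loglik(y, np.exp(np.clip(X @ beta, -50, 50)), 0.1)[0]
                assert ll <= fit.loglik + 1e-9
            # Nelder-Mead from a neutral start does not exceed IRLS by > 1e-6
            nm = minimize(
                lambda b: -nb_loglik(y, np.exp(np.clip(X @ b, -50, 50)), 0.1)[0],
                x0=np.zeros(3),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            assert fit.loglik >= -nm.fun - 1e-6

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            fit_nb_glm(np.array([-1.0, 2.0]), np.ones((2, 1)))
        with pytest.raises(ValidationError):
            fit_nb_glm(np.array([1.0, 2.0]), np.ones((2, 1)), phi=-0.5)


class TestDispersions:
    def test_shrinkage_limit_tagwise_equals_trend(self, small_dataset):
        cm, designs, _ = small_dataset
        dm = build_design(designs)
        nf = px.tmm_factors(cm)
        est = estimate_dispersions(cm, dm, nf, prior_df=1e6)
        log_ratio = np.log(est.tagwise / est.trend)
        assert np.abs(log_ratio).max() < 0.01

    def test_poisson_data_gives_near_zero_common(self):
        cfg = px.SimConfig(
            n_genes=500, frac_te_shifted=0.0, regulon_size=0,
            dispersion_trend=(0.0, 0.0), seed=13,
        )
        cm, designs, _ = px.simulate_dataset(cfg)
        est = estimate_dispersions(cm, build_design(designs), px.tmm_factors(cm))
        assert est.common <= 0.02

    def test_few_genes_falls_back_to_common(self, small_dataset):
        cm, designs, _ = small_dataset
        tiny = cm.subset_genes(cm.gene_ids[:20])
        with pytest.warns(UserWarning, match="common"):
            est = estimate_dispersions(tiny, build_design(designs), px.tmm_factors(tiny))
        assert np.allclose(est.tagwise, est.common)

    def test_dispersions_nonnegative(self, small_dataset):
        cm, designs, _ = small_dataset
        est = estimate_dispersions(cm, build_design(designs), px.tmm_factors(cm))
        assert (est.tagwise >= 0).all() and (est.trend >= 0).all() and est.common >= 0


class TestLRT:
    def test_identical_fits_give_p_one(self):
        stat, p, failed = lrt_interaction(-10.0, -10.0)
        assert stat[0] == 0.0 and p[0] == 1.0 and not failed[0]

    def test_chi_square_quantile(self):
        crit = chi2.ppf(0.95, 1)  # 3.841...
        _, p, _ = lrt_interaction(-5.0 + crit / 2, -5.0)
        assert p[0] == pytest.approx(0.05, abs=1e-12)

    def test_large_negative_statistic_flagged(self):
        stat, p, failed = lrt_interaction(-10.0, -9.0)
        assert failed[0] and np.isnan(p[0])

    def test_invariant_to_reference_level_relabeling(self):
        cfg = px.SimConfig(n_genes=60, regulon_size=0, seed=21)
        cm, designs, _ = px.simulate_dataset(cfg)
        nf = px.tmm_factors(cm)
        offset = np.log(nf.effective_lib_sizes.loc[list(cm.sample_ids)].to_numpy())
        Y = cm.values.astype(float)

        def stats(design_order):
            dm = build_design(design_order)
            cols = [design_order.index(d) for d in designs]  # align to cm columns
            Xf = dm.full[cols]
            Xr = dm.reduced[cols]
            full = fit_nb_glm_batch(Y, Xf, offset=offset, phi=0.1)
            red = fit_nb_glm_batch(Y, Xr, offset=offset, phi=0.1)
            return lrt_interaction(full.loglik, red.loglik)[0]

        base = stats(list(designs))
        rotated = stats(list(designs[8:]) + list(designs[:8]))  # new reference levels
        assert np.allclose(base, rotated, atol=1e-8)

    def test_matches_edger_glm_workflow(self, tmp_path):
        import shutil

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        cfg = px.SimConfig(n_genes=60, frac_te_shifted=0.2, regulon_size=0, seed=7)
        cm, designs, _ = px.simulate_dataset(cfg)
        dm = build_design(designs)
        nf = px.tmm_factors(cm)
        offset = np.log(nf.effective_lib_sizes.loc[list(cm.sample_ids)].to_numpy())
        Y = cm.values.astype(float)
        full = fit_nb_glm_batch(Y, dm.full, offset=offset, phi=0.08)
        red = fit_nb_glm_batch(Y, dm.reduced, offset=offset, phi=0.08)
        stat, _, _ = lrt_interaction(full.loglik, red.loglik)

        cm.frame.to_csv(tmp_path / "c.tsv", sep="\t")
        px.write_sample_sheet(designs, tmp_path / "s.tsv")
        np.savetxt(tmp_path / "off.txt", offset)
        script = f"""
        suppressMessages(library(edgeR))
        x <- as.matrix(read.delim("{tmp_path}/c.tsv", row.names=1))
        s <- read.delim("{tmp_path}/s.tsv")
        off <- scan("{tmp_path}/off.txt", quiet=TRUE)
        cell <- factor(s$cell_line, levels=unique(s$cell_line))
        rep <- factor(s$replicate, levels=unique(s$replicate))
        kd <- as.numeric(s$condition=="knockdown")
        poly <- as.numeric(s$fraction=="polysome")
        design <- model.matrix(~cell + rep + kd + poly + kd:poly)
        fit <- glmFit(x, design, dispersion=0.08, offset=off, prior.count=0)
        lrt <- glmLRT(fit, coef=ncol(design))
        write.table(data.frame(stat=lrt$table$LR,
                               coef=fit$coefficients[,ncol(design)]),
                    "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=600
        )
        assert out.returncode == 0, out.stderr
        res = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        assert np.allclose(res["stat"].to_numpy(), stat, atol=1e-5)
        assert np.allclose(
            res["coef"].to_numpy(), full.coef[:, dm.interaction_index], atol=1e-3
        )


class TestRunTETest:
    def test_nominated_implies_expressed_and_usable(self, small_te_table):
        _, _, _, table = small_te_table
        assert (table.loc[table.nominated, "expressed"]).all()
        assert (table.loc[table.nominated, "usable"]).all()
        assert table.p_value.dropna().between(0, 1).all()

    def test_precision_on_default_effect_sizes(self, small_te_table):
        _, _, truth, table = small_te_table
        nominated = table.index[table.nominated]
        if len(nominated) >= 10:
            precision = (truth.theta.loc[nominated] != 0).mean()
            assert precision >= 0.5

    def test_zero_threshold_nominates_nothing(self, small_dataset):
        cm, designs, _ = small_dataset
        table = run_te_test(cm, designs, p_threshold=0.0)
        assert table.nominated.sum() == 0

    def test_all_zero_gene_never_nominated(self, small_dataset):
        cm, designs, _ = small_dataset
        df = cm.frame.copy()
        df.iloc[0] = 0
        table = run_te_test(px.CountMatrix(df), designs)
        first = table.iloc[0]
        assert not first.usable and np.isnan(first.p_value) and not first.nominated

    def test_wald_agrees_with_lrt_on_strong_effects(self, small_dataset):
        cm, designs, _ = small_dataset
        lrt = run_te_test(cm, designs, test="lrt")
        wald = run_te_test(cm, designs, test="wald")
        strong = lrt.p_value < 1e-4
        if strong.any():
            assert (wald.loc[strong, "p_value"] < 0.01).all()
        # nomination rule is identical in structure
        assert (wald.nominated <= wald.expressed).all()
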
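"""Evolutionary-model ML fitting, AIC comparison, and ancestral estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phyloallom as pa
from phyloallom.evomodels import EvoModelFit, mvn_loglik


def bm_sample(tree, sigma2, root, rng, lam=1.0):
    """Direct MVN draw under lambda-scaled BM (independent of fit_model)."""
    C0 = pa.phylo_vcv(tree)
    C = pa.transform_covariance(C0, "lambda", {"lam": lam}).matrix
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    x = root + np.sqrt(sigma2) * (L @ rng.standard_normal(len(C)))
    return pd.Series(x, index=C0.taxa, name="trait")


class TestFitModel:
    def test_two_tip_closed_form(self):
        # (A:1,B:1) with values {0, 2}: C = I, GLS root = mean = 1,
        # ML sigma^2 (n-divisor) = ((0-1)^2 + (2-1)^2)/2 = 1
        tree = pa.parse_newick("(A:1,B:1,C:1);").prune_to(["A", "B", "C"])
        tree3 = pa.parse_newick("(A:1,B:1,C:1);")
        y = pd.Series([0.0, 2.0, 1.0], index=["A", "B", "C"], name="t")
        fit = pa.fit_model(tree3, y.to_frame(), "bm")
        assert fit.root[0] == pytest.approx(1.0)
        assert fit.rate_matrix[0, 0] == pytest.approx(np.mean((y - 1.0) ** 2))

    def test_star_data_on_star_tree_matches_lambda_zero(self):
        rng = np.random.default_rng(0)
        star = pa.parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        y = bm_sample(star, 0.5, 0.0, rng)
        f_bm = pa.fit_model(star, y.to_frame(), "bm")
        f_star = pa.fit_model(star, y.to_frame(), "star")
        # on a star tree the two covariance structures coincide
        assert f_bm.loglik == pytest.approx(f_star.loglik, abs=1e-9)

    @pytest.mark.parametrize("model", ["bm", "star", "ou", "eb"])
    def test_loglik_matches_dense_mvn_oracle(self, model):
        """Fitted lnL equals the dense multivariate-normal density evaluated
        at the fitted parameters, on complete instances with <= 8 tips."""
        rng = np.random.default_rng(21)
        for rep in range(10):
            n = int(rng.integers(4, 9))
            tree = pa.simulate_tree(n, birth_rate=0.4, seed=1000 + rep)
            Y = pd.DataFrame({
                "a": bm_sample(tree, 0.3, 1.0, rng).values,
                "b": bm_sample(tree, 0.1, -1.0, rng).values,
            }, index=tree.tip_labels)
            fit = pa.fit_model(tree, Y, model)
            C0 = pa.phylo_vcv(tree, order=list(Y.index))
            if model in ("bm", "star"):
                C = pa.transform_covariance(C0, "lambda",
                                            {"lam": 1.0 if model == "bm" else 0.0}).matrix
            elif model == "ou":
                C = pa.transform_covariance(C0, "ou", fit.shape_params).matrix
            else:
                C = pa.transform_covariance(C0, "eb", fit.shape_params).matrix
            y = Y.to_numpy().T.ravel()
            mean = np.repeat(fit.root, len(Y))
            cov = np.kron(fit.rate_matrix, C)
            assert fit.loglik == pytest.approx(mvn_loglik(y, mean, cov), abs=1e-6)

    def test_missing_data_matches_row_deleted_mvn(self):
        rng = np.random.default_rng(3)
        tree = pa.simulate_tree(6, birth_rate=0.4, seed=77)
        Y = pd.DataFrame({
            "a": bm_sample(tree, 0.3, 0.0, rng).values,
            "b": bm_sample(tree, 0.2, 1.0, rng).values,
        }, index=tree.tip_labels)
        Y.iloc[0, 1] = np.nan
        Y.iloc[3, 1] = np.nan
        fit = pa.fit_model(tree, Y, "bm")
        C = pa.phylo_vcv(tree, order=list(Y.index)).matrix
        obs = ~np.isnan(Y.to_numpy().T.ravel())
        y = Y.to_numpy().T.ravel()[obs]
        mean = np.repeat(fit.root, len(Y))[obs]
        cov = np.kron(fit.rate_matrix, C)[np.ix_(obs, obs)]
        assert fit.loglik == pytest.approx(mvn_loglik(y, mean, cov), abs=1e-5)
        # the optimum cannot beat an exhaustive parameter perturbation
        for _ in range(50):
            z = fit.root + rng.normal(0, 0.05, 2)
            D = np.diag(np.exp(rng.normal(0, 0.1, 2)))
            R2 = D @ fit.rate_matrix @ D
            assert mvn_loglik(y, np.repeat(z, len(Y))[obs],
                              np.kron(R2, C)[np.ix_(obs, obs)]) <= fit.loglik + 1e-6

    def test_sigma2_recovery_at_study_scale(self):
        """Median ML rate over repeated BM simulations at n = 34 stays within
        10% of the generating rate."""
        tree = pa.simulate_tree(34, birth_rate=0.2, seed=5, depth=73.0)
        rng = np.random.default_rng(11)
        est = []
        for _ in range(500):
            y = bm_sample(tree, 0.05, 0.0, rng)
            fit = pa.fit_model(tree, y.to_frame(), "bm")
            est.append(fit.rate_matrix[0, 0])
        assert np.median(est) == pytest.approx(0.05, rel=0.10)

    def test_aic_identity(self, standin_tree, log_traits):
        for model in ("bm", "star", "ou"):
            fit = pa.fit_model(standin_tree, log_traits[["log_cerebellum"]], model)
            assert fit.aic == 2 * fit.k - 2 * fit.loglik

    def test_unknown_model_rejected(self, cherry):
        with pytest.raises(pa.ParameterError):
            pa.fit_model(cherry, pd.DataFrame({"t": [0, 1]}, index=["A", "B"]), "acdc")


class TestCompareModels:
    def _fit(self, model, aic, k=4):
        lnL = (2 * k - aic) / 2.0
        return EvoModelFit(model, ["a"], ["t"], np.zeros(1), np.eye(1), {}, lnL, k, 10)

    def test_reported_gap_significantly_less(self):
        # AIC gap 6.63 between best and runner-up lands in the 4-7 band
        df = pa.compare_models([self._fit("bm", 6209.62), self._fit("eb", 6216.25)])
        assert df.loc[1, "delta_aic"] == pytest.approx(6.63)
        assert df.loc[1, "support"] == "significantly less"

    def test_identical_aic_comparable(self):
        df = pa.compare_models([self._fit("bm", 100.0), self._fit("ou", 100.0)])
        assert df.loc[1, "delta_aic"] == 0
        assert (df["support"] == "comparable").all()

    def test_small_gap_comparable(self):
        df = pa.compare_models([self._fit("bm", -19.13), self._fit("ou-diag", -16.03)])
        assert df.loc[1, "delta_aic"] == pytest.approx(3.10)
        assert df.loc[1, "support"] == "comparable"

    def test_large_gap_none(self):
        df = pa.compare_models([self._fit("bm", 0.0), self._fit("star", 58.0)])
        assert df.loc[1, "support"] == "none"

    def test_bm_preferred_on_bm_data(self):
        """Model-selection sanity: under BM generation, BM's AIC beats the
        scalar-OU AIC in at least 80% of datasets."""
        tree = pa.simulate_tree(34, birth_rate=0.2, seed=17, depth=73.0)
        rng = np.random.default_rng(23)
        wins = 0
        n_reps = 200
        for _ in range(n_reps):
            y = bm_sample(tree, 0.05, 0.0, rng).to_frame()
            if pa.fit_model(tree, y, "bm").aic <= pa.fit_model(tree, y, "ou").aic:
                wins += 1
        assert wins / n_reps >= 0.80


class TestLambdaContrast:
    def test_identical_likelihood_gives_p_one(self):
        f1 = EvoModelFit("bm", ["a"], ["t"], np.zeros(1), np.eye(1), {}, -5.0, 2, 10)
        f0 = EvoModelFit("star", ["a"], ["t"], np.zeros(1), np.eye(1), {}, -5.0, 2, 10)
        res = pa.lrt_fixed_lambda(f1, f0)
        assert res["statistic"] == 0
        assert res["p"] == 1.0

    def test_signal_detected_under_bm(self):
        """Data generated with full phylogenetic signal on a deep tree favour
        lambda = 1 in nearly every replicate."""
        tree = pa.simulate_tree(34, birth_rate=0.2, seed=29, depth=73.0)
        rng = np.random.default_rng(31)
        positive = 0
        n_reps = 200
        for _ in range(n_reps):
            y = bm_sample(tree, 0.05, 0.0, rng).to_frame()
            res = pa.lrt_fixed_lambda(pa.fit_model(tree, y, "bm"),
                                      pa.fit_model(tree, y, "star"))
            positive += res["statistic"] > 0
        assert positive / n_reps >= 0.95

    def test_no_signal_under_star_generation(self):
        tree = pa.simulate_tree(34, birth_rate=0.2, seed=37, depth=73.0)
        rng = np.random.default_rng(41)
        stats_ = []
        for _ in range(200):
            y = bm_sample(tree, 0.05, 0.0, rng, lam=0.0).to_frame()
            res = pa.lrt_fixed_lambda(pa.fit_model(tree, y, "bm"),
                                      pa.fit_model(tree, y, "star"))
            stats_.append(res["statistic"])
        assert np.mean(stats_) <= 0


class TestAce:
    def test_two_tip_weighted_root(self):
        # root of (A:a,B:b) is the branch-length-weighted GLS average
        tree = pa.parse_newick("(A:2.0,B:0.5);")
        y = pd.Series([1.0, 4.0], index=["A", "B"], name="t")
        fit = EvoModelFit("bm", ["A", "B"], ["t"], np.array([0.0]),
                          np.array([[1.0]]), {"lam": 1.0}, 0.0, 2, 2)
        ace = pa.ace_bm(tree, y, fit)
        expect = (1.0 / 2.0 + 4.0 / 0.5) / (1 / 2.0 + 1 / 0.5)
        assert ace[ace.is_root]["estimate"].iloc[0] == pytest.approx(expect)

    def test_constant_tips_reconstruct_constant(self):
        tree = pa.simulate_tree(8, birth_rate=0.3, seed=43)
        y = pd.Series(2.5, index=tree.tip_labels, name="t")
        fit = EvoModelFit("bm", tree.tip_labels, ["t"], np.array([2.5]),
                          np.array([[1e-4]]), {"lam": 1.0}, 0.0, 2, 8)
        ace = pa.ace_bm(tree, y, fit)
        np.testing.assert_allclose(ace["estimate"], 2.5, atol=1e-10)
        assert (ace["variance"] > 0).all()

    def test_matches_dense_kriging_oracle(self):
        """Node estimates and variances equal the dense GLS (universal
        kriging) formulas computed from the tip covariance matrix."""
        tree = pa.parse_newick("((A:1,B:1):1,(C:0.5,D:0.5):1.5);")
        y = pd.Series([0.0, 1.0, 3.0, 5.0], index=list("ABCD"), name="t")
        fit = pa.fit_model(tree, y.to_frame(), "bm")
        s2 = fit.rate_matrix[0, 0]
        ace = pa.ace_bm(tree, y, fit)
        order = list("ABCD")
        C = pa.phylo_vcv(tree, order=order).matrix
        Ci = np.linalg.inv(C)
        one = np.ones(4)
        z0 = (one @ Ci @ y.loc[order].values) / (one @ Ci @ one)
        # internal nodes: root (depth 0), MRCA(A,B) (depth 1), MRCA(C,D) (depth 1.5)
        shared = {  # covariance vector with each tip, and own depth
            "root": (np.zeros(4), 0.0),
            "ab": (np.array([1.0, 1.0, 0.0, 0.0]), 1.0),
            "cd": (np.array([0.0, 0.0, 1.5, 1.5]), 1.5),
        }
        for node, (c, t_a) in shared.items():
            est = z0 + c @ Ci @ (y.loc[order].values - z0)
            var = s2 * (t_a - c @ Ci @ c + (1 - one @ Ci @ c) ** 2 / (one @ Ci @ one))
            row = ace[np.isclose(ace["estimate"], est, atol=1e-8)]
            assert len(row) >= 1, node
            assert row["variance"].iloc[0] == pytest.approx(var, abs=1e-8)

    def test_root_estimate_invariant_to_tip_order(self, standin_tree, log_traits):
        y = log_traits["log_cerebellum"]
        a1 = pa.ace_bm(standin_tree, y)
        a2 = pa.ace_bm(standin_tree, y.iloc[::-1])
        assert a1[a1.is_root]["estimate"].iloc[0] == pytest.approx(
            a2[a2.is_root]["estimate"].iloc[0], abs=1e-9)

    def test_ci_brackets_estimate_and_backtransform(self, standin_tree, log_traits):
        ace = pa.ace_bm(standin_tree, log_traits["log_cerebellum"])
        assert ((ace["ci_low"] <= ace["estimate"]) & (ace["estimate"] <= ace["ci_high"])).all()
        np.testing.assert_allclose(ace["estimate_mm3"], 10 ** ace["estimate"])

    def test_non_bm_fit_rejected(self, standin_tree, log_traits):
        fit = pa.fit_model(standin_tree, log_traits[["log_cerebellum"]], "star")
        with pytest.raises(pa.ParameterError, match="BM"):
            pa.ace_bm(standin_tree, log_traits["log_cerebellum"], fit)


class TestRIndependentOracles:
    """Cross-checks against the R comparative-methods stack (ape/nlme)."""

    def test_ace_matches_ape(self, tmp_path, standin_tree, log_traits):
        import subprocess

        y = log_traits["log_cerebellum"]
        ace = pa.ace_bm(standin_tree, y)
        tree_file = tmp_path / "t.nwk"
        tree_file.write_text(pa.write_newick(standin_tree))
        data_file = tmp_path / "d.csv"
        y.to_frame().to_csv(data_file)
        script = f"""
        suppressMessages(library(ape))
        tr <- read.tree("{tree_file}")
        d <- read.csv("{data_file}", row.names=1)
        x <- setNames(d[tr$tip.label, 1], tr$tip.label)
        a <- ace(x, tr, type="continuous", method="ML")
        cat(a$ace[1], "\\n")
        """
        out = subprocess.run(["Rscript", "-"], input=script, text=True,
                             capture_output=True, check=True)
        root_r = float(out.stdout.strip().split()[-1])
        assert ace[ace.is_root]["estimate"].iloc[0] == pytest.approx(root_r, abs=1e-4)
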
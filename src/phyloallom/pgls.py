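"""Phylogenetic generalized least squares for allometric scaling.

A log-log regression of one volume on another estimates the allometric
exponent (the slope b of log10 y = a + b log10 x); the error covariance is
proportional to the phylogenetic covariance matrix so shared ancestry does
not masquerade as allometry.  Isometry (b = 1) is tested by whether the
slope's t-based confidence interval excludes 1; grade shifts between clades
(different intercepts and/or slopes) are tested by phylogenetic ANCOVA
F-tests in the whitened space; R^2_likelihood with Fisher's r-to-z contrast
compares fit quality between species subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tree import ParameterError, Phylogeny, PhyloCovariance, phylo_vcv, transform_covariance

__all__ = [
    "PglsFit",
    "GradeShiftTest",
    "pgls_fit",
    "isometry_test",
    "pancova",
    "fit_comparison",
]


@dataclass
class PglsFit:
    """A fitted phylogenetic (or ordinary, if C = I) regression line."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    ci95: tuple[float, float]        # slope CI
    ci99: tuple[float, float]
    sigma2: float                    # residual variance, (n - p)-divisor
    loglik: float                    # ML log-likelihood (n-divisor sigma^2)
    loglik_null: float               # intercept-only model, same C
    n: int
    df_resid: int
    cov_model: str
    x_name: str = "x"
    y_name: str = "y"
    taxa: list[str] = field(default_factory=list)
    rss: float = 0.0
    details: dict = field(default_factory=dict)

    @property
    def r2_likelihood(self) -> float:
        """R^2_lik = 1 - exp(-(2/n)(lnL_model - lnL_null)); a likelihood-based
        coefficient of determination valid under GLS."""
        return 1.0 - float(np.exp(-(2.0 / self.n) * (self.loglik - self.loglik_null)))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PglsFit {self.y_name} ~ {self.x_name} ({self.cov_model}, n={self.n}): "
            f"b={self.slope:.4f} [{self.ci95[0]:.3f}, {self.ci95[1]:.3f}], a={self.intercept:.4f}>"
        )


@dataclass
class GradeShiftTest:
    """Phylogenetic ANCOVA contrast of a restricted vs an extended design."""

    vary: str
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    rss_restricted: float
    rss_full: float
    coef_full: dict
    groups: dict


def _gls_solve(X: np.ndarray, y: np.ndarray, C: np.ndarray) -> tuple:
    """Whitened least squares; returns (beta, rss, XtCiX_inv, logdet_C, Lw)."""
    L = np.linalg.cholesky(C)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    XtX = Xw.T @ Xw
    cond = np.linalg.cond(XtX)
    if cond > 1e12:
        raise ParameterError(f"singular design (condition number {cond:.3g}); is x constant?")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet_C = 2.0 * float(np.log(np.diag(L)).sum())
    return beta, rss, XtX_inv, logdet_C, (Xw, yw)


def _ml_loglik(rss: float, n: int, logdet_C: float) -> float:
    s2 = rss / n
    return float(-0.5 * (n * np.log(2 * np.pi * s2) + logdet_C + n))


def _resolve_cov(tree: Phylogeny, species: Sequence[str], cov_model: str,
                 cov_params: Mapping | None) -> tuple[np.ndarray, str]:
    work = tree.prune_to(list(species))
    C0 = phylo_vcv(work, order=list(species))
    if cov_model in ("bm", "BM"):
        return C0.matrix, "BM"
    out = transform_covariance(C0, cov_model, cov_params or {})
    return out.matrix, out.model


def pgls_fit(
    tree: Phylogeny | None,
    x: pd.Series,
    y: pd.Series,
    cov_model: str = "bm",
    cov_params: Mapping | None = None,
    C: np.ndarray | None = None,
) -> PglsFit:
    """Fit y = a + b x by GLS with phylogenetic error covariance.

    ``x`` and ``y`` are species-indexed (log10) traits; species present in
    both are used, and the tree is pruned to them.  ``cov_model`` names the
    covariance transform (``"bm"`` default; ``"star"`` gives OLS).  A
    precomputed species-ordered covariance ``C`` may be passed instead of a
    tree.  Standard errors use the (n - 2)-divisor residual variance and
    t(n - 2) quantiles for the 95% and 99% slope CIs; the ML log-likelihood
    (n-divisor) is kept for R^2_likelihood comparisons.
    """
    common = x.dropna().index.intersection(y.dropna().index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 species with both traits, have {len(common)}")
    xs = x.loc[common].astype(float).to_numpy()
    ys = y.loc[common].astype(float).to_numpy()
    if C is None:
        if tree is None:
            raise ValueError("either a tree or a covariance matrix is required")
        Cm, tag = _resolve_cov(tree, list(common), cov_model, cov_params)
    else:
        Cm, tag = np.asarray(C, dtype=float), cov_model
    if np.linalg.cond(Cm) > 1e10:
        warnings.warn(f"ill-conditioned phylogenetic covariance (cond={np.linalg.cond(Cm):.3g})")
    n = len(common)
    X = np.column_stack([np.ones(n), xs])
    beta, rss, XtX_inv, logdet_C, _ = _gls_solve(X, ys, Cm)
    df = n - 2
    sigma2 = rss / df
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    t95 = stats.t.ppf(0.975, df)
    t99 = stats.t.ppf(0.995, df)
    # intercept-only null for R^2_likelihood
    _, rss0, _, _, _ = _gls_solve(np.ones((n, 1)), ys, Cm)
    return PglsFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        se_slope=float(se[1]),
        se_intercept=float(se[0]),
        ci95=(float(beta[1] - t95 * se[1]), float(beta[1] + t95 * se[1])),
        ci99=(float(beta[1] - t99 * se[1]), float(beta[1] + t99 * se[1])),
        sigma2=float(sigma2),
        loglik=_ml_loglik(rss, n, logdet_C),
        loglik_null=_ml_loglik(rss0, n, logdet_C),
        n=n,
        df_resid=df,
        cov_model=tag,
        x_name=str(x.name or "x"),
        y_name=str(y.name or "y"),
        taxa=list(common),
        rss=rss,
    )


def isometry_test(fit: PglsFit, null_slope: float = 1.0) -> dict:
    """Classify the allometry by whether the slope CI excludes the null.

    At each level: null inside the CI -> isometric; CI entirely above the
    null -> hyper-allometric (y outpaces x); CI entirely below ->
    hypo-allometric.  The 95% and 99% verdicts are reported separately.
    """
    def call(ci: tuple[float, float]) -> str:
        lo, hi = ci
        if lo <= null_slope <= hi:
            return "isometric"
        return "hyper-allometric" if null_slope < lo else "hypo-allometric"

    return {
        "null_slope": null_slope,
        "at95": call(fit.ci95),
        "at99": call(fit.ci99),
        "ci95": fit.ci95,
        "ci99": fit.ci99,
        "slope": fit.slope,
    }


def pancova(
    tree: Phylogeny | None,
    x: pd.Series,
    y: pd.Series,
    groups: pd.Series | Mapping[str, object],
    vary: Literal["intercept", "slope", "both"] = "both",
    cov_model: str = "bm",
    C: np.ndarray | None = None,
) -> GradeShiftTest:
    """Phylogenetic ANCOVA: does one clade follow a shifted regression?

    ``groups`` is a binary species partition.  The full design extends the
    common line with a group indicator (``vary="intercept"``, a grade shift),
    a group x slope interaction (``vary="slope"``), or both; the F statistic
    [(RSS_r - RSS_f)/dp] / [RSS_f/(n - p_f)] is computed after whitening by
    the phylogenetic covariance, with Pr(>F) from F(dp, n - p_f).
    """
    if vary not in ("intercept", "slope", "both"):
        raise ParameterError(f"vary must be intercept|slope|both, got {vary!r}")
    common = x.dropna().index.intersection(y.dropna().index)
    g = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    missing = [s for s in common if s not in g.index]
    if missing:
        raise ValueError(f"groups do not cover species: {missing}")
    g = g.loc[common]
    levels = sorted(pd.unique(g.astype(str)))
    if len(levels) != 2:
        raise ValueError(f"groups must form a binary partition, found levels {levels}")
    counts = g.astype(str).value_counts()
    if counts.min() < 2:
        raise ValueError(f"each group needs >= 2 species, found {counts.to_dict()}")
    xs = x.loc[common].astype(float).to_numpy()
    ys = y.loc[common].astype(float).to_numpy()
    ind = (g.astype(str) == levels[1]).to_numpy(dtype=float)
    if C is None:
        Cm, _ = _resolve_cov(tree, list(common), cov_model, None)
    else:
        Cm = np.asarray(C, dtype=float)
    n = len(common)
    X_r = np.column_stack([np.ones(n), xs])
    cols = {"both": [ind, ind * xs], "intercept": [ind], "slope": [ind * xs]}[vary]
    X_f = np.column_stack([X_r] + cols)
    _, rss_r, _, _, _ = _gls_solve(X_r, ys, Cm)
    beta_f, rss_f, _, _, _ = _gls_solve(X_f, ys, Cm)
    dp = X_f.shape[1] - X_r.shape[1]
    df_den = n - X_f.shape[1]
    if df_den <= 0:
        raise ValueError("not enough species for the full design")
    F = max(((rss_r - rss_f) / dp) / (rss_f / df_den), 0.0)
    p = float(stats.f.sf(F, dp, df_den))
    names = ["intercept", "slope"] + {"both": ["d_intercept", "d_slope"],
                                      "intercept": ["d_intercept"],
                                      "slope": ["d_slope"]}[vary]
    return GradeShiftTest(
        vary=vary,
        f_statistic=float(F),
        p_value=p,
        df_num=dp,
        df_den=df_den,
        rss_restricted=float(rss_r),
        rss_full=float(rss_f),
        coef_full=dict(zip(names, beta_f.tolist())),
        groups={lv: int(c) for lv, c in counts.items()},
    )


def fit_comparison(fit_pooled: PglsFit, fit_g1: PglsFit, fit_g2: PglsFit) -> dict:
    """Compare regression fit between two species subsets via Fisher's r-to-z.

    Each fit contributes r = sqrt(R^2_likelihood); the contrast
    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)) is standard normal
    under equal underlying fit, giving a two-sided p.  Groups of n <= 3 carry
    no information about r and are refused.
    """
    for f, tag in ((fit_g1, "group 1"), (fit_g2, "group 2")):
        if f.n <= 3:
            raise ValueError(f"{tag} has n={f.n} <= 3; comparison refused")
    r = {k: float(np.sqrt(max(f.r2_likelihood, 0.0)))
         for k, f in (("pooled", fit_pooled), ("g1", fit_g1), ("g2", fit_g2))}
    denom = np.sqrt(1.0 / (fit_g1.n - 3) + 1.0 / (fit_g2.n - 3))
    z = (np.arctanh(min(r["g1"], 0.999999)) - np.arctanh(min(r["g2"], 0.999999))) / denom
    return {
        "r2_likelihood": {"pooled": fit_pooled.r2_likelihood,
                          "g1": fit_g1.r2_likelihood, "g2": fit_g2.r2_likelihood},
        "r": r,
        "fisher_z": float(z),
        "p": float(2 * stats.norm.sf(abs(z))),
    }
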
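"""Maximum-likelihood trait-evolution models on a phylogeny.

Traits (log10 volumes) at the tips of a dated tree are modelled as a
multivariate normal whose among-species covariance comes from a named
evolutionary model — Brownian motion (optionally Pagel's-lambda scaled, with
lambda = 0 the star phylogeny), Ornstein--Uhlenbeck with a fixed root, or
Early Burst — and whose among-trait covariance R is estimated jointly.  The
stacked (trait x species) covariance is the Kronecker product R (x) C(theta);
missing trait values are handled exactly by deleting the corresponding rows
and columns of that stacked matrix.

Model support is compared by AIC; the lambda = 1 versus lambda = 0 contrast
(phylogenetic signal) is a chi-squared test; ancestral character estimation
(ACE) under the fitted BM model gives internal-node states with confidence
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tree import ParameterError, Phylogeny, PhyloCovariance, phylo_vcv, transform_covariance

__all__ = [
    "EvoModelFit",
    "MODELS",
    "fit_model",
    "compare_models",
    "lrt_fixed_lambda",
    "ace_bm",
    "mvn_loglik",
]

#: model tag -> (free shape parameter, fixed transform parameters)
MODELS: dict[str, dict] = {
    "bm": {"shape": None, "fixed": {"lam": 1.0}},
    "star": {"shape": None, "fixed": {"lam": 0.0}},
    "lambda": {"shape": "lambda", "fixed": {}},
    "ou": {"shape": "alpha", "fixed": {}},
    "ou-diag": {"shape": "alpha-per-trait", "fixed": {}},
    "eb": {"shape": "r", "fixed": {}},
}


@dataclass
class EvoModelFit:
    """A fitted trait-evolution model.

    ``rate_matrix`` is the ML among-trait covariance R (trait-units^2 per my
    under BM); its diagonal holds the per-trait rates sigma^2.  ``k`` counts
    root states + free entries of R + shape parameters, so the AIC identity
    AIC = 2k - 2 lnL is auditable from the object itself.
    """

    model: str
    taxa: list[str]
    trait_names: list[str]
    root: np.ndarray            # z0, one ancestral state per trait
    rate_matrix: np.ndarray     # R, p x p, ML (n-divisor)
    shape_params: dict
    loglik: float
    k: int
    n_obs: int
    converged: bool = True
    details: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def rates(self) -> np.ndarray:
        return np.diag(self.rate_matrix)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EvoModelFit {self.model} p={len(self.trait_names)} lnL={self.loglik:.3f} "
            f"k={self.k} AIC={self.aic:.2f} {self.shape_params}>"
        )


def mvn_loglik(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Gaussian log density via Cholesky; raises on a non-PD covariance."""
    L = np.linalg.cholesky(cov)
    dev = np.linalg.solve(L, y - mean)
    return float(-0.5 * (dev @ dev) - np.log(np.diag(L)).sum() - 0.5 * y.size * np.log(2 * np.pi))


def _as_matrix(traits) -> pd.DataFrame:
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    if not isinstance(traits, pd.DataFrame):
        raise TypeError("traits must be a species-indexed DataFrame or Series")
    return traits.astype(float)


def _shaped_cov(C0: PhyloCovariance, model: str, shape_value) -> np.ndarray:
    fixed = MODELS[model]["fixed"]
    shape = MODELS[model]["shape"]
    if shape is None:
        return transform_covariance(C0, "lambda", fixed).matrix
    if shape == "lambda":
        return transform_covariance(C0, "lambda", {"lam": shape_value}).matrix
    if shape == "alpha":
        return transform_covariance(C0, "ou", {"alpha": shape_value}).matrix
    if shape == "r":
        return transform_covariance(C0, "eb", {"r": shape_value}).matrix
    raise ParameterError(f"no single shared covariance for model {model!r}")


def _profile_complete(Y: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form ML of root states and trait covariance for complete data.

    Given the species covariance C, the GLS root and the n-divisor ML trait
    covariance maximize the likelihood jointly; the profile log-likelihood
    then depends only on C.
    """
    n, p = Y.shape
    L = np.linalg.cholesky(C)
    W = np.linalg.solve(L, Y)           # whitened traits
    w1 = np.linalg.solve(L, np.ones(n))
    z0 = (w1 @ W) / (w1 @ w1)
    E = W - np.outer(w1, z0)
    R = (E.T @ E) / n
    sign, logdet_R = np.linalg.slogdet(R)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular trait covariance")
    logdet_C = 2.0 * np.log(np.diag(L)).sum()
    lnL = -0.5 * (n * p * np.log(2 * np.pi) + p * logdet_C + n * logdet_R + n * p)
    return z0, R, float(lnL)


def _stacked_loglik(Y: np.ndarray, mask: np.ndarray, C: np.ndarray, z0: np.ndarray, R: np.ndarray) -> float:
    """Exact likelihood with missing entries: row-delete the stacked R (x) C."""
    obs = mask.T.ravel()                       # trait-major stacking
    y = Y.T.ravel()[obs]
    mean = np.repeat(z0, Y.shape[0])[obs]
    cov = np.kron(R, C)[np.ix_(obs, obs)]
    return mvn_loglik(y, mean, cov)


def _shape_grid(shape: str, depth: float) -> np.ndarray:
    if shape == "lambda":
        return np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    if shape == "alpha":
        return np.array([0.01, 0.1, 0.5, 2.0, 10.0]) / depth
    if shape == "r":
        return -np.array([1e-6, 0.01, 0.1, 0.5, 2.0]) / depth
    raise ParameterError(shape)


def _shape_bounds(shape: str, depth: float) -> tuple[float, float]:
    if shape == "lambda":
        return (0.0, 1.0)
    if shape == "alpha":
        return (1e-6 / depth, 100.0 / depth)
    if shape == "r":
        return (-50.0 / depth, 0.0)
    raise ParameterError(shape)


def _fit_shared_cov(
    Y: np.ndarray, mask: np.ndarray, C0: PhyloCovariance, model: str, depth: float, tol: float
) -> tuple[np.ndarray, np.ndarray, dict, float, bool]:
    """Fit any model whose covariance is one shared transform of C0."""
    shape = MODELS[model]["shape"]
    complete = bool(mask.all())
    p = Y.shape[1]
    warm: dict = {}

    def profile(sv) -> tuple[float, np.ndarray, np.ndarray]:
        C = _shaped_cov(C0, model, sv)
        if complete:
            z0, R, lnL = _profile_complete(Y, C)
            return lnL, z0, R
        # numeric optimization of z0 and chol(R) at this shape value;
        # complete-case closed form (then the previous optimum) as start
        if "theta" in warm:
            starts = [warm["theta"]]
        else:
            Yc = np.where(mask, Y, np.nan)
            starts = [_pack(*_moment_start(Yc))]
            full_rows = mask.all(axis=1)
            if full_rows.sum() >= p + 2:
                z_cc, R_cc, _ = _profile_complete(
                    Y[full_rows], C[np.ix_(full_rows.nonzero()[0], full_rows.nonzero()[0])])
                starts.append(_pack(z_cc, R_cc + 1e-8 * np.eye(p)))

        def neg(theta):
            z0, R = _unpack(theta, p)
            try:
                return -_stacked_loglik(Y, mask, C, z0, R)
            except np.linalg.LinAlgError:
                return 1e12

        bounds = ([(-1e3, 1e3)] * p + [(-20.0, 20.0)] * p
                  + [(-1e3, 1e3)] * (p * (p - 1) // 2))
        best = None
        for theta0 in starts:
            res = optimize.minimize(neg, theta0, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        warm["theta"] = best.x
        z0, R = _unpack(best.x, p)
        return -best.fun, z0, R

    if shape is None:
        lnL, z0, R = profile(None)
        return z0, R, {}, lnL, True

    lo, hi = _shape_bounds(shape, depth)
    best = None
    for sv in _shape_grid(shape, depth):
        sv = min(max(sv, lo), hi)
        try:
            lnL, z0, R = profile(sv)
        except np.linalg.LinAlgError:
            continue
        if best is None or lnL > best[0]:
            best = (lnL, z0, R, sv)
    if best is None:
        raise np.linalg.LinAlgError(f"no admissible {model} covariance found")

    def neg_profile(sv: float) -> float:
        try:
            return -profile(sv)[0]
        except np.linalg.LinAlgError:
            return 1e12

    res = optimize.minimize_scalar(neg_profile, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    lnL_ref = -res.fun
    converged = True
    if lnL_ref >= best[0] - 1e-6:
        sv = float(res.x)
        lnL, z0, R = profile(sv)
    else:  # scalar refinement trapped in a worse basin; keep the grid best
        lnL, z0, R, sv = best
        converged = False
    name = {"lambda": "lambda", "alpha": "alpha", "r": "r"}[shape]
    return z0, R, {name: float(sv)}, lnL, converged


def _moment_start(Y_nan: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.nanmean(Y_nan, axis=0)
    p = Y_nan.shape[1]
    R = np.zeros((p, p))
    for a in range(p):
        for b in range(p):
            both = ~np.isnan(Y_nan[:, a]) & ~np.isnan(Y_nan[:, b])
            if both.sum() > 1:
                R[a, b] = np.cov(Y_nan[both, a], Y_nan[both, b])[0, 1]
    R += np.eye(p) * (0.1 * np.trace(R) / p + 1e-6)
    return z, R


def _pack(z0: np.ndarray, R: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(R)
    p = len(z0)
    tril = L[np.tril_indices(p, -1)]
    return np.concatenate([z0, np.log(np.diag(L)), tril])


def _unpack(theta: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    z0 = theta[:p]
    L = np.zeros((p, p))
    L[np.diag_indices(p)] = np.exp(theta[p:2 * p])
    L[np.tril_indices(p, -1)] = theta[2 * p:]
    return z0, L @ L.T


def fit_model(
    tree: Phylogeny,
    traits: pd.DataFrame | pd.Series,
    model: str = "bm",
    tol: float = 1e-8,
) -> EvoModelFit:
    """ML fit of a trait-evolution model to species-level (log10) traits.

    ``traits`` is a species-indexed DataFrame (columns = traits, NaN allowed);
    species are aligned to the tree by normalized label, and tree tips without
    trait rows are pruned.  Returns an :class:`EvoModelFit` whose ``k``
    counts root states + free entries of R + shape parameters.
    """
    if model not in MODELS:
        raise ParameterError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    tr = _as_matrix(traits)
    tr = tr.loc[tr.notna().any(axis=1)]
    if len(tr) < 3:
        raise ValueError("need >= 3 species with data")
    work = tree.prune_to(list(tr.index))
    C0 = phylo_vcv(work, order=list(tr.index))
    Y = tr.to_numpy(dtype=float)
    mask = ~np.isnan(Y)
    n, p = Y.shape
    depth = work.depth
    n_obs = int(mask.sum())

    if model == "ou-diag":
        # independent single-trait OU fits: diagonal R, one alpha per trait
        z0 = np.zeros(p)
        R = np.zeros((p, p))
        alphas, lnL = [], 0.0
        converged = True
        for j, name in enumerate(tr.columns):
            sub = tr[[name]].dropna()
            subtree = tree.prune_to(list(sub.index))
            Cj = phylo_vcv(subtree, order=list(sub.index))
            Yj = sub.to_numpy(dtype=float)
            zj, Rj, sp, lj, conv = _fit_shared_cov(
                Yj, np.ones_like(Yj, dtype=bool), Cj, "ou", subtree.depth, tol)
            z0[j], R[j, j] = zj[0], Rj[0, 0]
            alphas.append(sp["alpha"])
            lnL += lj
            converged &= conv
        k = 3 * p
        return EvoModelFit(model, list(tr.index), list(tr.columns), z0, R,
                           {"alpha": alphas}, lnL, k, n_obs, converged,
                           {"note": "independent per-trait OU (diagonal R)"})

    z0, R, shape_params, lnL, converged = _fit_shared_cov(Y, mask, C0, model, depth, tol)
    k = p + p * (p + 1) // 2 + (0 if MODELS[model]["shape"] is None else 1)
    fixed = MODELS[model]["fixed"]
    return EvoModelFit(model, list(tr.index), list(tr.columns), z0, R,
                       {**fixed, **shape_params}, lnL, k, n_obs, converged)


def compare_models(fits: Sequence[EvoModelFit]) -> pd.DataFrame:
    """Rank fits by AIC with delta-AIC support labels.

    Delta < 4: comparable support; 4--7: significantly less; 7--10: weak;
    > 10: no support for the worse model.
    """
    if not fits:
        raise ValueError("no fits to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError("fits compare different data (observation counts differ)")
    df = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
        }
    ).sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]

    def label(d: float) -> str:
        if d < 4:
            return "comparable"
        if d <= 7:
            return "significantly less"
        if d <= 10:
            return "weak"
        return "none"

    df["support"] = df["delta_aic"].map(label)
    return df


def lrt_fixed_lambda(fit_lambda1: EvoModelFit, fit_lambda0: EvoModelFit) -> dict:
    """Chi-squared contrast of full phylogenetic signal vs none.

    Both models fix lambda (1 and 0) and have the same free-parameter count,
    so this is a contrast of two fixed hypotheses rather than a nested LRT;
    df = 1 is the adopted convention and is echoed in the result.  Positive
    statistic favours lambda = 1.
    """
    if fit_lambda1.k != fit_lambda0.k:
        raise ValueError("lambda=1 and lambda=0 fits must have equal parameter counts")
    stat = 2.0 * (fit_lambda1.loglik - fit_lambda0.loglik)
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return {"statistic": float(stat), "df": 1, "p": p,
            "favours": "lambda=1" if stat > 0 else "lambda=0"}


# -- ancestral character estimation --------------------------------------


def ace_bm(tree: Phylogeny, trait: pd.Series, fit: EvoModelFit | None = None) -> pd.DataFrame:
    """Ancestral character estimation under Brownian motion.

    Joint ML (equivalently GLS) reconstruction of internal-node states: the
    reconstruction minimizes the sum over branches of squared change divided
    by branch length, a sparse quadratic problem whose normal equations are
    the branch-weighted graph Laplacian.  Node variances are sigma^2 times
    the diagonal of the inverse restricted Laplacian (root uncertainty
    included), and the 95% CI is the estimate +/- 1.96 SD on the log scale;
    ``*_mm3`` columns exponentiate estimate and CI back to volumes.

    ``fit`` supplies the BM rate sigma^2 (ML); when omitted, a single-trait
    BM model is fitted first.  The root row's estimate equals that fit's GLS
    root state.
    """
    trait = trait.dropna().astype(float)
    if fit is None:
        fit = fit_model(tree, trait.to_frame(), "bm")
    else:
        if fit.shape_params.get("lam", fit.shape_params.get("lambda", 1.0)) != 1.0:
            raise ParameterError("ace_bm requires a BM (lambda=1) fit")
        missing = set(fit.taxa) - set(trait.index)
        if missing:
            raise ValueError(f"trait missing for tips the fit used: {sorted(missing)}")
    name = trait.name if trait.name in fit.trait_names else fit.trait_names[0]
    sigma2 = float(fit.rate_matrix[fit.trait_names.index(name), fit.trait_names.index(name)])

    work = tree.prune_to(list(trait.index))
    dtree = work.to_dendropy()
    internal = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    index = {nd: i for i, nd in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros(m)
    tipval = {tr_norm: v for tr_norm, v in
              zip((s for s in trait.index), trait.to_numpy())}
    from .tree import normalize_label
    tipval = {normalize_label(k): v for k, v in tipval.items()}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        w = 1.0 / max(nd.edge.length, 1e-10)
        parent = index[nd.parent_node]
        if nd.is_leaf():
            x = tipval[normalize_label(nd.taxon.label)]
            A[parent, parent] += w
            b[parent] += w * x
        else:
            child = index[nd]
            A[parent, parent] += w
            A[child, child] += w
            A[parent, child] -= w
            A[child, parent] -= w
    Ainv = np.linalg.inv(A)
    est = Ainv @ b
    var = sigma2 * np.diag(Ainv)
    sd = np.sqrt(var)
    labels = []
    for i, nd in enumerate(internal):
        lab = nd.taxon.label if nd.taxon is not None else (nd.label or f"node{i + 1}")
        labels.append(lab)
    out = pd.DataFrame(
        {
            "node": labels,
            "is_root": [nd is dtree.seed_node for nd in internal],
            "estimate": est,
            "variance": var,
            "ci_low": est - 1.96 * sd,
            "ci_high": est + 1.96 * sd,
        }
    )
    out["estimate_mm3"] = 10 ** out["estimate"]
    out["ci_low_mm3"] = 10 ** out["ci_low"]
    out["ci_high_mm3"] = 10 ** out["ci_high"]
    out.attrs["trait"] = str(name)
    out.attrs["sigma2"] = sigma2
    out.attrs["tree_metadata"] = dict(work.metadata)
    return out
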
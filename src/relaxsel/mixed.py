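"""Bayesian multilevel meta-regression with phylogenetic random effects.

The model is the Gaussian mixed model used throughout the analysis:

    y = X beta + sum_l Z_l u_l + e

where ``y`` is a standardized trait mean or an absolute CV, ``X`` holds an
intercept and the trajectory-curve basis covariate (optionally crossed
with a life-history factor), and the random levels ``l`` are any subset of
{study, species, phylogeny, trait_type}.  The phylogenetic level has
``u_phylo ~ N(0, sigma2_phylo * A)`` with ``A`` the Brownian species
correlation matrix; other levels are spherical.  Residuals are
heteroscedastic, ``Var(e_i) = sigma2_e / w_i`` with per-record precision
weights ``w_i`` (by default the sample size).

Inference is by a blocked Gibbs sampler: a flat prior on ``beta`` and
scalar inverse-Wishart priors on every variance — inverse-gamma with
shape nu/2 and scale nu*V/2, the univariate reduction of the
inverse-Wishart(V, nu) prior with the conventional weakly informative
setting V = 1, nu = 0.02.  Model comparison uses DIC computed from the
marginal Gaussian likelihood (random effects integrated out at the
sampled variances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .curves import InverseParams, WeibullParams, weibull_bump

__all__ = [
    "MCMCConfig",
    "Design",
    "GibbsSamples",
    "build_design",
    "run_gibbs",
    "summarize_posterior",
    "compute_dic",
    "rank_models",
    "significance_of_fit",
    "PhyloMetaRegression",
]

RANDOM_LEVELS = ("study", "species", "phylogeny", "trait_type")


@dataclass
class MCMCConfig:
    """Chain settings; defaults follow standard long-chain practice.

    ``n_iter`` counts total Gibbs sweeps including burn-in; retained draws
    number ``(n_iter - burn_in) / thin``.
    """

    n_iter: int = 1_000_000
    burn_in: int = 30_000
    thin: int = 100
    prior_V: float = 1.0
    prior_nu: float = 0.02
    seed: int = 0
    n_chains: int = 5

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_V <= 0 or self.prior_nu <= 0:
            raise ValueError("prior_V and prior_nu must be positive")

    @classmethod
    def scaled_down(cls, seed: int = 0, n_iter: int = 20_000,
                    burn_in: int = 2_000, thin: int = 10) -> "MCMCConfig":
        """Short-chain settings for tests and quick exploration."""
        return cls(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)


@dataclass
class Design:
    """Assembled regression inputs for the Gibbs sampler."""

    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    weights: np.ndarray
    # per level: (record -> group index array, number of groups)
    levels: dict = field(default_factory=dict)
    # phylogeny only: correlation matrix A aligned with that level's groups
    phylo_A: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.y.size


def _basis_covariate(x: np.ndarray, shape_params) -> np.ndarray:
    """The frozen-shape curve covariate entering X.

    For the inverse curve this is ``a**x`` (the decaying regressor whose
    coefficient is the curve's ``k``); for the Weibull curve it is the
    unit-scale bump (the coefficient plays the role of ``a``).
    """
    if isinstance(shape_params, InverseParams):
        return np.power(shape_params.a, x)
    if isinstance(shape_params, WeibullParams):
        unit = WeibullParams(
            y_ini=0.0, a=1.0, k=shape_params.k,
            lam=shape_params.lam, t_min=shape_params.t_min,
        )
        return np.asarray(weibull_bump(x, unit), dtype=float)
    raise TypeError(f"unsupported shape parameter bundle: {type(shape_params)}")


def build_design(
    records: pd.DataFrame,
    shape_params,
    response: str = "standardized_mean",
    group: str | None = None,
    longevity: bool = False,
    random_levels=RANDOM_LEVELS,
    phylo=None,
    lifehistory: pd.DataFrame | None = None,
    drop_aliased: bool = False,
) -> Design:
    """Build the response, fixed-effects matrix and random-level maps.

    Parameters
    ----------
    records : DataFrame
        Standardized records (needs ``generation``, the response column,
        ``weight``, and the id columns for the requested random levels).
    shape_params : InverseParams or WeibullParams
        Frozen curve shape from the CMA-ES stage.
    group : str or sequence of str, optional
        ``"foraging_guild"`` and/or ``"sociality"``.  The first factor is
        coded full-rank one-hot with no global intercept (one intercept and
        one basis slope per level); any additional factor enters in
        reference coding (first level dropped) for both its main effect and
        its basis interaction, keeping the matrix full rank.
    longevity : bool
        Add centred log10 maximum longevity as a continuous covariate.
    random_levels : iterable
        Subset of {study, species, phylogeny, trait_type}.
    phylo : PhyloCorrelationMatrix, optional
        Required when the phylogeny level is requested.
    lifehistory : DataFrame, optional
        Species life-history table (``species_id``, ``foraging_guild``,
        ``sociality``, ``max_longevity``); required for ``group`` or
        ``longevity``.
    """
    records = records.dropna(subset=[response]).reset_index(drop=True)
    if records.empty:
        raise ValueError("no usable records for the requested response")
    x = records["generation"].to_numpy(dtype=float)
    y = records[response].to_numpy(dtype=float)
    w = (
        records["weight"].to_numpy(dtype=float)
        if "weight" in records
        else np.ones_like(y)
    )
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    basis = _basis_covariate(x, shape_params)

    groups = (
        [] if group is None else [group] if isinstance(group, str) else list(group)
    )
    if groups or longevity:
        if lifehistory is None:
            raise ValueError("life-history table required for group/longevity terms")
        lh = lifehistory.set_index("species_id")
        missing = sorted(set(records["species_id"]) - set(lh.index))
        if missing:
            raise ValueError(f"species without life-history data: {missing}")

    cols: list[np.ndarray] = []
    names: list[str] = []
    if not groups:
        cols += [np.ones_like(y), basis]
        names += ["intercept", "basis"]
    else:
        for g_i, g in enumerate(groups):
            gvals = records["species_id"].map(lh[g]).to_numpy()
            levels_ = sorted(pd.unique(gvals))
            # first factor: full one-hot, no global intercept; later factors:
            # reference coding so the design stays full rank
            use = levels_ if g_i == 0 else levels_[1:]
            for lev in use:
                ind = (gvals == lev).astype(float)
                cols.append(ind)
                names.append(f"intercept[{g}={lev}]")
            for lev in use:
                ind = (gvals == lev).astype(float)
                cols.append(ind * basis)
                names.append(f"basis[{g}={lev}]")
    if longevity:
        lon = np.log10(records["species_id"].map(lh["max_longevity"]).to_numpy(float))
        cols.append(lon - lon.mean())
        names.append("log10_longevity")
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if not drop_aliased:
            raise ValueError(
                f"fixed-effects matrix is singular (rank {rank} < {X.shape[1]} "
                f"columns {names}); remove collinear terms"
            )
        # drop aliased columns (QR with pivoting), as standard model fitters do
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        keep_idx = sorted(piv[:rank])
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep_idx]
        warnings.warn(f"dropping aliased fixed-effect columns: {dropped}",
                      stacklevel=2)
        X = X[:, keep_idx]
        names = [names[j] for j in keep_idx]

    level_key = {
        "study": "study_id",
        "species": "species_id",
        "phylogeny": "species_id",
        "trait_type": "trait_class",
    }
    levels: dict = {}
    phylo_A = None
    for lev in random_levels:
        if lev not in RANDOM_LEVELS:
            raise ValueError(f"unknown random level {lev!r}")
        codes, uniques = pd.factorize(records[level_key[lev]], sort=True)
        levels[lev] = (codes.astype(int), len(uniques))
        if lev == "phylogeny":
            if phylo is None:
                raise ValueError("phylogeny level requires a correlation matrix")
            phylo_A = phylo.reorder(list(uniques)).matrix
    return Design(y=y, X=X, colnames=names, weights=w, levels=levels, phylo_A=phylo_A)


@dataclass
class GibbsSamples:
    """Retained posterior draws from one or more chains."""

    beta: np.ndarray  # (n_draws, p)
    colnames: list[str]
    sigma2: dict  # level name (incl. "residual") -> (n_draws,)
    config: MCMCConfig
    chain_id: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def to_frame(self) -> pd.DataFrame:
        d = {f"beta[{c}]": self.beta[:, j] for j, c in enumerate(self.colnames)}
        d.update({f"sigma2[{k}]": v for k, v in self.sigma2.items()})
        return pd.DataFrame(d)


def _sample_invgamma(rng, shape: float, scale: float) -> float:
    # X ~ IG(a, b)  <=>  1/X ~ Gamma(a, rate=b)
    return scale / rng.standard_gamma(shape)


def run_gibbs(design: Design, config: MCMCConfig,
              fix_residual: float | None = None) -> GibbsSamples:
    """Blocked Gibbs sampler for the weighted multilevel Gaussian model.

    Update order per sweep: beta | u, sigma2  ->  each u_l | rest  ->
    each sigma2_l | u_l  ->  sigma2_e | residuals.  Deterministic given
    ``config.seed``.  ``fix_residual`` pins the residual variance instead
    of sampling it (the known-variance special case, where the posterior
    of beta is available in closed form).
    """
    rng = np.random.default_rng(config.seed)
    y, X, w = design.y, design.X, design.weights
    n, p = X.shape
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    try:
        L_fixed = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular fixed-effects matrix") from exc

    level_names = list(design.levels)
    idx = {l: design.levels[l][0] for l in level_names}
    q = {l: design.levels[l][1] for l in level_names}
    wsum = {l: np.bincount(idx[l], weights=w, minlength=q[l]) for l in level_names}
    A_inv = None
    if "phylogeny" in level_names:
        A = design.phylo_A + 1e-10 * np.eye(q["phylogeny"])
        A_inv = np.linalg.inv(A)

    beta = np.linalg.solve(XtWX, Xw.T @ y)
    u = {l: np.zeros(q[l]) for l in level_names}
    s2 = {l: 1.0 for l in level_names}
    s2_e = 1.0 if fix_residual is None else float(fix_residual)
    a0 = config.prior_nu / 2.0
    b0 = config.prior_nu * config.prior_V / 2.0

    n_keep = (config.n_iter - config.burn_in) // config.thin
    beta_out = np.empty((n_keep, p))
    s2_out = {l: np.empty(n_keep) for l in level_names + ["residual"]}
    kept = 0

    total_u = np.zeros(n)

    for it in range(config.n_iter):
        # --- beta | rest ---
        r = y - total_u
        mean_beta = np.linalg.solve(XtWX, Xw.T @ r)
        z = rng.standard_normal(p)
        beta = mean_beta + np.sqrt(s2_e) * np.linalg.solve(L_fixed.T, z)
        xb = X @ beta

        # --- random effects ---
        for l in level_names:
            total_u -= u[l][idx[l]]
            resid = y - xb - total_u
            zw = np.bincount(idx[l], weights=w * resid, minlength=q[l])
            if l == "phylogeny":
                prec = np.diag(wsum[l] / s2_e) + A_inv / s2[l]
                Lp = np.linalg.cholesky(prec)
                mu_u = np.linalg.solve(prec, zw / s2_e)
                u[l] = mu_u + np.linalg.solve(Lp.T, rng.standard_normal(q[l]))
            else:
                prec = wsum[l] / s2_e + 1.0 / s2[l]
                mu_u = (zw / s2_e) / prec
                u[l] = mu_u + rng.standard_normal(q[l]) / np.sqrt(prec)
            total_u += u[l][idx[l]]

        # --- variances ---
        for l in level_names:
            if l == "phylogeny":
                ss = float(u[l] @ A_inv @ u[l])
            else:
                ss = float(u[l] @ u[l])
            s2[l] = _sample_invgamma(rng, a0 + q[l] / 2.0, b0 + ss / 2.0)
        if fix_residual is None:
            e = y - xb - total_u
            s2_e = _sample_invgamma(
                rng, a0 + n / 2.0, b0 + float(e @ (w * e)) / 2.0
            )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            beta_out[kept] = beta
            for l in level_names:
                s2_out[l][kept] = s2[l]
            s2_out["residual"][kept] = s2_e
            kept += 1

    beta_out = beta_out[:kept]
    s2_out = {k: v[:kept] for k, v in s2_out.items()}
    return GibbsSamples(
        beta=beta_out, colnames=list(design.colnames), sigma2=s2_out, config=config
    )


def run_chains(design: Design, config: MCMCConfig) -> GibbsSamples:
    """Run ``config.n_chains`` independent chains and pool the draws."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(config.n_chains) >> 1]
    parts = []
    for s in seeds:
        cfg = MCMCConfig(
            n_iter=config.n_iter, burn_in=config.burn_in, thin=config.thin,
            prior_V=config.prior_V, prior_nu=config.prior_nu,
            seed=s, n_chains=1,
        )
        parts.append(run_gibbs(design, cfg))
    beta = np.vstack([p.beta for p in parts])
    sigma2 = {
        k: np.concatenate([p.sigma2[k] for p in parts]) for k in parts[0].sigma2
    }
    chain_id = np.concatenate(
        [np.full(p.n_draws, i) for i, p in enumerate(parts)]
    )
    return GibbsSamples(
        beta=beta, colnames=parts[0].colnames, sigma2=sigma2,
        config=config, chain_id=chain_id,
    )


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial positive sequence estimator."""
    x = np.asarray(x, float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    tau = 1.0
    for k in range(1, min(n // 2, 1000) - 1, 2):
        pair = acf[k] + acf[k + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(min(n, n / tau))


def summarize_posterior(samples: GibbsSamples, ci: float = 0.95) -> pd.DataFrame:
    """Posterior summary table: mean, equal-tailed CI, pMCMC, ESS, stars.

    pMCMC is twice the smaller tail fraction relative to zero, floored at
    1/n_draws; an effect is flagged significant when its CI excludes 0.
    Variance components are summarized without pMCMC (they are positive by
    construction).
    """
    if samples.n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    for j, name in enumerate(samples.colnames):
        d = samples.beta[:, j]
        lo, hi = np.quantile(d, [lo_q, hi_q])
        frac_pos = np.mean(d > 0)
        pmcmc = max(2 * min(frac_pos, 1 - frac_pos), 1.0 / d.size)
        pmcmc = min(pmcmc, 1.0)
        rows.append(
            {
                "term": name, "kind": "fixed", "post_mean": d.mean(),
                "lower": lo, "upper": hi, "pMCMC": pmcmc,
                "ess": _ess(d), "significant": bool(lo > 0 or hi < 0),
            }
        )
    for lev, d in samples.sigma2.items():
        lo, hi = np.quantile(d, [lo_q, hi_q])
        rows.append(
            {
                "term": f"sigma2[{lev}]", "kind": "variance",
                "post_mean": d.mean(), "lower": lo, "upper": hi,
                "pMCMC": np.nan, "ess": _ess(d), "significant": False,
            }
        )
    out = pd.DataFrame(rows)
    out["stars"] = out.apply(_stars, axis=1)
    return out


def _stars(row) -> str:
    if row["kind"] != "fixed" or not row["significant"]:
        return ""
    p = row["pMCMC"]
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "."


def _marginal_cov_parts(design: Design) -> dict[str, np.ndarray]:
    """Precompute Z_l A_l Z_l' for each level (n x n each)."""
    parts = {}
    for l, (codes, q_l) in design.levels.items():
        if l == "phylogeny":
            parts[l] = design.phylo_A[np.ix_(codes, codes)]
        else:
            parts[l] = (codes[:, None] == codes[None, :]).astype(float)
    return parts


def _gaussian_deviance(y, X, beta, s2_by_level, s2_e, w, cov_parts) -> float:
    n = y.size
    V = np.diag(s2_e / w)
    for l, M in cov_parts.items():
        V = V + s2_by_level[l] * M
    L = np.linalg.cholesky(V)
    r = y - X @ beta
    z = np.linalg.solve(L, r)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(n * np.log(2 * np.pi) + logdet + z @ z)


def compute_dic(samples: GibbsSamples, design: Design, max_draws: int = 500) -> dict:
    """Deviance information criterion from the marginal likelihood.

    ``D = -2 log N(y; X beta, V)`` with ``V = sigma2_e W^-1 + sum_l
    sigma2_l Z_l A_l Z_l'``; DIC = 2 * mean(D) - D(posterior means),
    pD = mean(D) - D(posterior means).  ``max_draws`` caps the number of
    draws scanned (evenly spaced) to bound the n^3 likelihood cost.
    """
    cov_parts = _marginal_cov_parts(design)
    S = samples.n_draws
    take = np.linspace(0, S - 1, min(S, max_draws)).astype(int)
    devs = np.empty(take.size)
    for t, s in enumerate(take):
        s2l = {l: samples.sigma2[l][s] for l in design.levels}
        devs[t] = _gaussian_deviance(
            design.y, design.X, samples.beta[s], s2l,
            samples.sigma2["residual"][s], design.weights, cov_parts,
        )
    mean_dev = float(devs.mean())
    s2l_hat = {l: float(samples.sigma2[l].mean()) for l in design.levels}
    dev_hat = _gaussian_deviance(
        design.y, design.X, samples.beta.mean(axis=0), s2l_hat,
        float(samples.sigma2["residual"].mean()), design.weights, cov_parts,
    )
    pd_eff = mean_dev - dev_hat
    return {"DIC": 2 * mean_dev - dev_hat, "pD": pd_eff, "mean_deviance": mean_dev}


def rank_models(dics, labels=None) -> pd.DataFrame:
    """DIC ranking with Akaike-style model weights.

    ``delta_i = DIC_i - min DIC``; ``weight_i = exp(-delta_i/2)``,
    normalized to sum to 1.  Sorted best first.
    """
    dics = np.asarray([d["DIC"] if isinstance(d, dict) else float(d) for d in dics])
    if dics.size < 1:
        raise ValueError("need at least one model")
    labels = list(labels) if labels is not None else [f"model_{i}" for i in range(dics.size)]
    delta = dics - dics.min()
    wts = np.exp(-delta / 2.0)
    wts = wts / wts.sum()
    out = pd.DataFrame({"model": labels, "DIC": dics, "delta_DIC": delta, "weight": wts})
    return out.sort_values("delta_DIC", kind="stable").reset_index(drop=True)


class PhyloMetaRegression:
    """Scikit-learn-style front end to the multilevel meta-regression.

    Wraps design construction, the Gibbs sampler and posterior
    summarization behind ``fit``/``predict``.

    Parameters
    ----------
    shape_params : InverseParams or WeibullParams
        Frozen curve shape providing the basis covariate.
    response : str
        Column of the records table to model.
    group, longevity, random_levels, phylo, lifehistory
        Passed to :func:`build_design`.
    mcmc : MCMCConfig, optional
        Chain settings (defaults to the scaled-down test configuration).
    pool_chains : bool
        Pool ``mcmc.n_chains`` independent chains instead of running one.

    Attributes
    ----------
    samples_ : GibbsSamples
    summary_ : DataFrame
        Posterior means, credible intervals, pMCMC, ESS per term.
    design_ : Design
    dic_ : dict
        DIC, pD and mean deviance of the fitted model.
    """

    _param_names = (
        "shape_params", "response", "group", "longevity", "random_levels",
        "phylo", "lifehistory", "mcmc", "pool_chains",
    )

    def __init__(self, shape_params, response: str = "standardized_mean",
                 group=None, longevity: bool = False,
                 random_levels=RANDOM_LEVELS, phylo=None, lifehistory=None,
                 mcmc: MCMCConfig | None = None, pool_chains: bool = False):
        self.shape_params = shape_params
        self.response = response
        self.group = group
        self.longevity = longevity
        self.random_levels = random_levels
        self.phylo = phylo
        self.lifehistory = lifehistory
        self.mcmc = mcmc
        self.pool_chains = pool_chains

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, records: pd.DataFrame, y=None):
        levels = self.random_levels
        if self.phylo is None:
            levels = tuple(l for l in levels if l != "phylogeny")
        self.design_ = build_design(
            records, self.shape_params, response=self.response,
            group=self.group, longevity=self.longevity,
            random_levels=levels, phylo=self.phylo,
            lifehistory=self.lifehistory,
        )
        cfg = self.mcmc or MCMCConfig.scaled_down()
        sampler = run_chains if self.pool_chains else run_gibbs
        self.samples_ = sampler(self.design_, cfg)
        self.summary_ = summarize_posterior(self.samples_)
        self.dic_ = compute_dic(self.samples_, self.design_)
        return self

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        """Posterior-mean fixed-effects prediction for new records."""
        if not hasattr(self, "samples_"):
            raise RuntimeError("PhyloMetaRegression is not fitted")
        ref = records.copy()
        if self.response not in ref:
            ref[self.response] = 0.0
        design = build_design(
            ref, self.shape_params, response=self.response,
            group=self.group, longevity=self.longevity,
            random_levels=(), lifehistory=self.lifehistory,
        )
        if design.colnames != self.design_.colnames:
            raise ValueError("new records produce a different fixed design")
        return design.X @ self.samples_.beta.mean(axis=0)


def significance_of_fit(
    records: pd.DataFrame,
    shape_params,
    config: MCMCConfig,
    response: str = "standardized_mean",
    phylo=None,
    random_levels=RANDOM_LEVELS,
    pool_chains: bool = False,
) -> tuple[pd.DataFrame, GibbsSamples, Design]:
    """Bayesian test of a fitted trajectory curve.

    Freezes the curve shape from the CMA-ES stage, regresses the response
    on the curve basis with the full random structure, and summarizes the
    posterior: the basis slope tests the curve's fit, the intercept its
    asymptote/baseline.
    """
    if len(records) == 0:
        raise ValueError("no records supplied")
    if phylo is None:
        random_levels = tuple(l for l in random_levels if l != "phylogeny")
    design = build_design(
        records, shape_params, response=response,
        random_levels=random_levels, phylo=phylo,
    )
    sampler = run_chains if pool_chains else run_gibbs
    samples = sampler(design, config)
    return summarize_posterior(samples), samples, design
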
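"""Multilevel (phylogenetic) meta-analysis and meta-regression.

The model is a Gaussian mixed model on per-observation effect sizes y_i
with known sampling variances v_i:

    y ~ Normal(X beta, V),   V = sum_L sigma2_L Z_L G_L Z_L' + diag(v)

where the random levels L are a subset of {study, species, phylo,
observation}; G is the identity for every level except ``phylo``, whose G
is a species-by-species Brownian-motion correlation matrix from the
phylogeny.  Variance components are estimated by restricted maximum
likelihood (REML) or maximum likelihood (ML) with bounded quasi-Newton
optimization on the log scale and deterministic restarts; fixed effects are
the GLS solution at the optimum, with Wald z inference.

Heterogeneity is summarized by a multilevel I^2: the share of total
variance (variance components plus the typical sampling variance) that is
attributable to true between-effect variation, decomposed across levels.
Model comparison uses small-sample-corrected AIC (AICc), by default on ML
fits because REML criteria are not comparable across fixed-effect
structures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import linalg, optimize, stats

from .phylogeny import PhyloCorrelation

logger = logging.getLogger("isodimorph")

__all__ = [
    "RANDOM_LEVELS",
    "ModelSpec",
    "FittedModel",
    "HeterogeneityReport",
    "fit_multilevel",
    "i_squared",
    "aicc",
    "model_selection_table",
    "predict_with_band",
    "wald_inference",
]

RANDOM_LEVELS = ("study", "species", "phylo", "observation")

_LOG_LB = np.log(1e-10)  # effectively sigma2 = 0


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: formula text, random structure, estimation method.

    ``formula`` is a patsy-style description, e.g.
    ``"value ~ dimorphism * diet_class + mean_size"`` (intercept always
    included).  ``subset`` is an optional pandas query string applied to the
    data first, e.g. ``"gape_limited and diet_class == 'carnivore'"``.
    """

    formula: str = "value ~ 1"
    random_levels: tuple[str, ...] = ("study", "species", "phylo")
    method: str = "REML"
    subset: Optional[str] = None

    def __post_init__(self):
        if self.method not in ("REML", "ML"):
            raise ValueError("method must be REML or ML")
        bad = set(self.random_levels) - set(RANDOM_LEVELS)
        if bad:
            raise ValueError(f"unknown random levels: {sorted(bad)}")


class _Problem:
    """Prepared design: response, fixed design, v_i, and one n x n kernel
    Z G Z' per random level, so each criterion evaluation is a scalar
    combination plus a Cholesky factorization."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec,
                 corr: Optional[PhyloCorrelation]):
        if spec.subset:
            data = data.query(spec.subset)
        data = data.reset_index(drop=True)
        if len(data) < 2:
            raise ValueError("need at least 2 observations after subsetting")
        if "phylo" in spec.random_levels and corr is None:
            raise ValueError("phylo random level requires a PhyloCorrelation")

        ydm, xdm = patsy.dmatrices(spec.formula, data,
                                   return_type="dataframe",
                                   NA_action="raise")
        self.y = np.asarray(ydm).ravel()
        self.X = np.asarray(xdm)
        self.x_names = list(xdm.columns)
        self.design_info = xdm.design_info
        n, p = self.X.shape
        if np.linalg.matrix_rank(self.X) < p:
            aliased = _aliased_columns(self.X, self.x_names)
            raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

        if "sampling_variance" not in data.columns:
            raise ValueError("data must carry a sampling_variance column")
        self.v = np.asarray(data["sampling_variance"], dtype=float)
        if np.any(~np.isfinite(self.v)) or np.any(self.v <= 0):
            raise ValueError("sampling variances must be positive and finite")

        self.data = data
        self.kernels: dict[str, np.ndarray] = {}
        for level in spec.random_levels:
            if level == "observation":
                self.kernels[level] = np.eye(n)
            elif level in ("study", "species"):
                col = {"study": "study_id", "species": "species"}[level]
                codes = pd.factorize(data[col])[0]
                self.kernels[level] = (codes[:, None] == codes[None, :]).astype(float)
            elif level == "phylo":
                missing = sorted(set(data["species"]) - set(corr.species))
                if missing:
                    raise ValueError(
                        f"species absent from phylogenetic correlation: {missing}")
                pos = {s: i for i, s in enumerate(corr.species)}
                idx = np.array([pos[s] for s in data["species"]])
                self.kernels[level] = corr.matrix[np.ix_(idx, idx)]
        self.levels = tuple(self.kernels)

    # -- criterion ---------------------------------------------------------

    def _V(self, sigma2: np.ndarray) -> np.ndarray:
        V = np.diag(self.v.copy())
        for s2, K in zip(sigma2, self.kernels.values()):
            if s2 > 0:
                V += s2 * K
        return V

    def nll(self, sigma2: np.ndarray, method: str) -> float:
        """Negative (restricted) log-likelihood at the given components."""
        n, p = self.X.shape
        V = self._V(sigma2)
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        Vi_X = linalg.cho_solve((c, low), self.X, check_finite=False)
        Vi_y = linalg.cho_solve((c, low), self.y, check_finite=False)
        XtViX = self.X.T @ Vi_X
        try:
            beta = linalg.solve(XtViX, self.X.T @ Vi_y, assume_a="pos")
        except linalg.LinAlgError:
            return np.inf
        r = self.y - self.X @ beta
        quad = r @ linalg.cho_solve((c, low), r, check_finite=False)
        if method == "ML":
            return 0.5 * (n * np.log(2 * np.pi) + logdet_v + quad)
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        _, logdet_xx = np.linalg.slogdet(self.X.T @ self.X)
        return 0.5 * ((n - p) * np.log(2 * np.pi) - logdet_xx
                      + logdet_v + logdet_xvx + quad)

    def gls(self, sigma2: np.ndarray):
        V = self._V(sigma2)
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        Vi_X = linalg.cho_solve((c, low), self.X, check_finite=False)
        XtViX = self.X.T @ Vi_X
        cov_beta = linalg.inv(XtViX)
        beta = cov_beta @ (Vi_X.T @ self.y)
        return beta, cov_beta


def _aliased_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns linearly dependent on their predecessors (by incremental rank)."""
    out, rank = [], 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            out.append(names[j])
        rank = r
    return out


@dataclass
class FittedModel:
    """A fitted multilevel meta-analytic model."""

    spec: ModelSpec
    x_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    zval: np.ndarray
    pval: np.ndarray
    sigma2: dict[str, float]
    fixed_sigma2: dict[str, float]
    loglik: float
    n_obs: int
    n_param: int
    aicc: float
    converged: bool
    cov_beta: np.ndarray
    v: np.ndarray
    problem: Optional[_Problem] = field(default=None, repr=False, compare=False)

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.se,
                "z": self.zval,
                "p": self.pval,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            },
            index=self.x_names,
        )

    def criterion_at(self, sigma2: Mapping[str, float]) -> float:
        """Negative criterion at arbitrary variance components (for profile
        checks); lower is better."""
        vec = np.array([sigma2[lv] for lv in self.problem.levels])
        return self.problem.nll(vec, self.spec.method)

    def to_dict(self) -> dict:
        return {
            "formula": self.spec.formula,
            "method": self.spec.method,
            "random_levels": list(self.spec.random_levels),
            "subset": self.spec.subset,
            "coefficients": {
                name: {
                    "estimate": float(b), "se": float(s), "z": float(z),
                    "p": float(p), "ci_low": float(lo), "ci_high": float(hi),
                }
                for name, b, s, z, p, lo, hi in zip(
                    self.x_names, self.beta, self.se, self.zval, self.pval,
                    self.ci_low, self.ci_high)
            },
            "sigma2": {k: float(x) for k, x in self.sigma2.items()},
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "n_param": int(self.n_param),
            "aicc": float(self.aicc),
            "converged": bool(self.converged),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


@dataclass(frozen=True)
class HeterogeneityReport:
    """Multilevel I^2 decomposition, in percent, plus the typical sampling
    variance v-bar (squared response units)."""

    i2_total: float
    i2_per_level: dict[str, float]
    typical_v: float


def fit_multilevel(
    data: pd.DataFrame,
    spec: ModelSpec,
    corr: Optional[PhyloCorrelation] = None,
    fixed_sigma2: Optional[Mapping[str, float]] = None,
    n_restarts: int = 3,
    tol: float = 1e-8,
) -> FittedModel:
    """Fit the multilevel model by REML or ML.

    ``fixed_sigma2`` pins named components at given values (use 0.0 for all
    levels to get the pure inverse-sampling-variance weighted fit); the
    remaining components are estimated.  Optimization is L-BFGS-B on
    log(sigma2) from ``n_restarts`` deterministic starting points; the best
    criterion wins.  Deterministic given inputs.
    """
    prob = _Problem(data, spec, corr)
    fixed_sigma2 = dict(fixed_sigma2 or {})
    bad = set(fixed_sigma2) - set(prob.levels)
    if bad:
        raise ValueError(f"fixed_sigma2 names unknown levels: {sorted(bad)}")
    free = [lv for lv in prob.levels if lv not in fixed_sigma2]

    n, p = prob.X.shape
    var_y = float(np.var(prob.y, ddof=1)) if n > 1 else 1.0
    total0 = max(var_y - float(np.mean(prob.v)), 0.1 * var_y, 1e-6)

    def pack(free_vals: np.ndarray) -> np.ndarray:
        s2 = np.empty(len(prob.levels))
        it = iter(free_vals)
        for i, lv in enumerate(prob.levels):
            s2[i] = fixed_sigma2[lv] if lv in fixed_sigma2 else next(it)
        return s2

    if free:
        ub = np.log(max(10.0 * var_y, 1.0))
        results = []
        scales = [1.0, 0.1, 10.0][:max(n_restarts, 1)]
        for scale in scales:
            x0 = np.full(len(free), np.log(scale * total0 / len(free)))
            x0 = np.clip(x0, _LOG_LB + 1, ub - 1)
            res = optimize.minimize(
                lambda x: prob.nll(pack(np.exp(x)), spec.method),
                x0,
                method="L-BFGS-B",
                bounds=[(_LOG_LB, ub)] * len(free),
                options={"ftol": tol * 1e-2, "gtol": 1e-10, "maxiter": 500},
            )
            results.append(res)
        best_fun = min(r.fun for r in results)
        # restarts that tie at the optimum: a clean termination wins, so a
        # line-search hiccup in one start does not mask agreement
        tied = [r for r in results if r.fun <= best_fun + 1e-8]
        best = next((r for r in tied if r.success), tied[0])
        sigma2_vec = pack(np.exp(best.x))
        converged = bool(best.success) and np.isfinite(best.fun)
        nll_opt = float(best.fun)
    else:
        sigma2_vec = pack(np.array([]))
        nll_opt = prob.nll(sigma2_vec, spec.method)
        converged = np.isfinite(nll_opt)

    if not converged:
        logger.warning("fit did not converge for %s", spec.formula)

    # components within a whisker of the lower bound are exact zeros
    sigma2_vec = np.where(sigma2_vec <= 1.5e-10, 0.0, sigma2_vec)
    nll_opt = min(nll_opt, prob.nll(sigma2_vec, spec.method))

    beta, cov_beta = prob.gls(sigma2_vec)
    se = np.sqrt(np.diag(cov_beta))
    zval = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    zq = stats.norm.ppf(0.975)
    n_param = p + len(free)
    loglik = -nll_opt
    model = FittedModel(
        spec=spec,
        x_names=prob.x_names,
        beta=beta,
        se=se,
        ci_low=beta - zq * se,
        ci_high=beta + zq * se,
        zval=zval,
        pval=pval,
        sigma2={lv: float(s2) for lv, s2 in zip(prob.levels, sigma2_vec)},
        fixed_sigma2={k: float(v) for k, v in fixed_sigma2.items()},
        loglik=loglik,
        n_obs=n,
        n_param=n_param,
        aicc=(aicc(loglik, n_param, n)
              if n - n_param - 1 > 0 else float("nan")),
        converged=converged,
        cov_beta=cov_beta,
        v=prob.v,
        problem=prob,
    )
    return model


def i_squared(
    model: FittedModel, variances: Optional[Sequence[float]] = None
) -> HeterogeneityReport:
    """Multilevel heterogeneity I^2 from an intercept-only fit.

    The typical sampling variance is

        v_bar = (k - 1) sum(w) / (sum(w)^2 - sum(w^2)),   w_i = 1 / v_i

    and I^2 = 100 * sum(sigma2_L) / (sum(sigma2_L) + v_bar), split across
    levels in proportion to their components.
    """
    if len(model.x_names) != 1:
        raise ValueError("I^2 is defined for intercept-only models")
    v = np.asarray(model.v if variances is None else variances, dtype=float)
    k = len(v)
    if k < 2:
        raise ValueError("need at least 2 observations")
    w = 1.0 / v
    typical_v = (k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
    total_s2 = sum(model.sigma2.values())
    denom = total_s2 + typical_v
    i2_total = 100.0 * total_s2 / denom if denom > 0 else 0.0
    per_level = {
        lv: (100.0 * s2 / denom if denom > 0 else 0.0)
        for lv, s2 in model.sigma2.items()
    }
    return HeterogeneityReport(i2_total, per_level, typical_v)


def aicc(loglik, n_param: Optional[int] = None, n_obs: Optional[int] = None) -> float:
    """Small-sample-corrected AIC: -2 ll + 2p + 2p(p+1)/(n - p - 1)."""
    if isinstance(loglik, FittedModel):
        n_param, n_obs, loglik = loglik.n_param, loglik.n_obs, loglik.loglik
    if not np.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    if n_obs - n_param - 1 <= 0:
        raise ValueError("AICc undefined: n - p - 1 <= 0")
    return (-2.0 * loglik + 2.0 * n_param
            + 2.0 * n_param * (n_param + 1) / (n_obs - n_param - 1))


def model_selection_table(
    formulas: Sequence[str],
    data: pd.DataFrame,
    random_levels: tuple[str, ...] = ("study", "species", "phylo"),
    corr: Optional[PhyloCorrelation] = None,
    method: str = "ML",
    subset: Optional[str] = None,
    tie_tol: float = 0.01,
) -> pd.DataFrame:
    """Fit each formula on the same data and rank ascending by AICc.

    AICc ties closer than ``tie_tol`` share a rank.  The comparison
    criterion (ML vs REML) is recorded in ``df.attrs["method"]``.
    """
    rows = []
    for f in formulas:
        spec = ModelSpec(formula=f, random_levels=random_levels,
                         method=method, subset=subset)
        m = fit_multilevel(data, spec, corr)
        rows.append({
            "formula": f, "n_param": m.n_param, "loglik": m.loglik,
            "aicc": m.aicc, "converged": m.converged,
        })
    df = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    ranks, rank = [], 0
    for i in range(len(df)):
        if i == 0 or df["aicc"].iloc[i] - df["aicc"].iloc[i - 1] >= tie_tol:
            rank = i + 1
        ranks.append(rank)
    df["rank"] = ranks
    df.attrs["method"] = method
    return df


def predict_with_band(model: FittedModel, grid: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect predictions x'beta with Wald 95% bands on a moderator grid."""
    (xg,) = patsy.build_design_matrices([model.problem.design_info], grid,
                                        NA_action="raise")
    X = np.asarray(xg)
    est = X @ model.beta
    var = np.einsum("ij,jk,ik->i", X, model.cov_beta, X)
    if np.any(var < -1e-10):
        raise ValueError("grid outside design column space")
    se = np.sqrt(np.clip(var, 0, None))
    zq = stats.norm.ppf(0.975)
    return pd.DataFrame({
        "estimate": est, "se": se,
        "ci_low": est - zq * se, "ci_high": est + zq * se,
    })


def wald_inference(model: FittedModel) -> pd.DataFrame:
    """Per-coefficient Wald z statistics, two-sided p, and 95% CI."""
    return model.coefficients()[["estimate", "z", "p", "ci_low", "ci_high"]]
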
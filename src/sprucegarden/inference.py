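"""Mixed-model estimation of regional means, multiple comparisons, and
trait-climate association analysis.

The workhorse is a Gaussian linear mixed model with independent random
effects,

    y = X beta + sum_f Z_f u_f + e,      u_f ~ N(0, s2_f I),  e ~ N(0, s2_e I),

fitted by REML. For a provenance trial the fixed effect is the region of
seed origin and the random effects are provenance-within-region, block,
and plot-within-block (or block only for the one-tree-per-provenance-
per-block core sample). Region means are reported as BLUEs (generalized
least squares at the REML variance estimates) with model-based standard
errors, compared pairwise with a studentized-range (Tukey) criterion and
summarized as a compact letter display.

Survival is handled with a binomial logit GLMM fitted by penalized
quasi-likelihood: iteratively reweighted calls into the same REML
machinery on the working response, with estimates mapped back to the
probability scale by the inverse link and delta-method SEs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the optimizer trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# REML linear mixed model
# ---------------------------------------------------------------------------

def _codes(values) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(pd.Series(values), sort=True)
    return codes.astype(int), len(uniques)


@dataclass
class LmmFit:
    """REML fit: fixed-effect estimates, covariance, variance components."""

    beta: np.ndarray
    cov_beta: np.ndarray
    fixed_names: list[str]
    vcomp: dict[str, float]  # per-factor variances, plus "residual"
    loglik_reml: float
    n_obs: int
    df_denom: float  # containment df for fixed-effect comparisons
    converged: bool
    gradient_norm: float
    blups: dict[str, pd.Series] = field(default_factory=dict)


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    random_factors: dict[str, np.ndarray],
    fixed_names: list[str] | None = None,
    weights: np.ndarray | None = None,
    fix_residual: float | None = None,
    start: np.ndarray | None = None,
) -> LmmFit:
    """REML fit of a Gaussian LMM with independent random-intercept factors.

    Parameters
    ----------
    y, X
        Response and fixed-effect design matrix (full column rank).
    random_factors
        Mapping factor name -> level labels per observation. Each factor
        contributes one variance component. Factors with a single level
        are dropped (variance inestimable, clamped to 0) with a warning.
    weights
        Optional known residual precision weights w_i (Var(e_i) = s2_e/w_i),
        used by the PQL working model.
    fix_residual
        If given, the residual variance is fixed at this value instead of
        profiled (not used by default).

    Notes
    -----
    The REML criterion is profiled over the residual variance and
    minimized over log variance ratios with L-BFGS-B; components driven
    to the lower bound are reported as 0 with a warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if fixed_names is None:
        fixed_names = [f"b{j}" for j in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design matrix is rank deficient")
    if weights is not None:
        sw = np.sqrt(np.asarray(weights, dtype=float))
        y = y * sw
        X = X * sw[:, None]

    # build sparse-ish incidence info per factor
    names, Zcols, sizes, level_names = [], [], [], []
    for name, vals in random_factors.items():
        codes, k = _codes(vals)
        if k < 2:
            logger.warning(
                "random factor %r has %d level(s); variance clamped to 0", name, k
            )
            continue
        names.append(name)
        Zcols.append(codes)
        sizes.append(k)
        level_names.append(pd.factorize(pd.Series(vals), sort=True)[1])
    nf = len(names)
    q = int(np.sum(sizes)) if nf else 0
    Z = np.zeros((n, q))
    offs = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    for f in range(nf):
        Z[np.arange(n), offs[f] + Zcols[f]] = 1.0
    if weights is not None and nf:
        Z = Z * sw[:, None]

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    if nf:
        ZtZ = Z.T @ Z
        ZtX = Z.T @ X
        Zty = Z.T @ y

    def crossprods(gamma: np.ndarray):
        """Return logdet(V0), and V0^{-1}-crossproducts via Woodbury."""
        if not nf:
            return 0.0, XtX, Xty, yty, None, None
        g = np.concatenate([np.full(sizes[f], gamma[f]) for f in range(nf)])
        sg = np.sqrt(g)
        B = np.eye(q) + (sg[:, None] * ZtZ * sg[None, :])
        cB = np.linalg.cholesky(B)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cB))))
        # helper: A'V0^{-1}C = A'C - (Z'A)' S B^{-1} S (Z'C)
        SZX = sg[:, None] * ZtX
        SZy = sg * Zty
        t1 = np.linalg.solve(cB, SZX)
        t2 = np.linalg.solve(cB, SZy)
        XtVX = XtX - t1.T @ t1
        XtVy = Xty - t1.T @ t2
        ytVy = yty - float(t2 @ t2)
        return logdet, XtVX, XtVy, ytVy, (cB, sg), g

    # degenerate noiseless data: the REML surface has no interior optimum,
    # so report the exact least-squares fit with all variances zero
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    rss_ols = float(np.sum((y - X @ beta_ols) ** 2))
    if fix_residual is None and rss_ols <= 1e-12 * max(yty, 1.0):
        vcomp0 = {"residual": rss_ols / max(n - p, 1)}
        for name in random_factors:
            vcomp0[name] = 0.0
        return LmmFit(
            beta=beta_ols,
            cov_beta=np.linalg.inv(XtX) * vcomp0["residual"],
            fixed_names=list(fixed_names),
            vcomp=vcomp0,
            loglik_reml=np.nan,
            n_obs=n,
            df_denom=float(max(n - p, 1)),
            converged=True,
            gradient_norm=0.0,
        )

    trace: list = []
    fslice = [slice(offs[f], offs[f + 1]) for f in range(nf)]

    def neg2_reml(delta: np.ndarray, with_grad: bool = False):
        gamma = np.exp(delta)
        logdet, XtVX, XtVy, ytVy, chol_info, _ = crossprods(gamma)
        cXtVX = np.linalg.cholesky(XtVX)
        beta = np.linalg.solve(cXtVX.T, np.linalg.solve(cXtVX, XtVy))
        rss = ytVy - float(beta @ XtVy)
        rss = max(rss, 1e-300)
        logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(cXtVX))))
        if fix_residual is None:
            s2 = rss / (n - p)
            val = (n - p) * (1.0 + np.log(2.0 * np.pi * s2)) + logdet + logdet_xvx
        else:
            s2 = fix_residual
            val = (
                rss / s2 + (n - p) * np.log(2.0 * np.pi * s2)
                + logdet + logdet_xvx
            )
        trace.append((delta.copy(), val))
        if not with_grad:
            return val
        # analytic gradient: dF/dgamma_f = tr(Z_f' P Z_f) - c * ||Z_f' P y||^2
        # with P the REML projector of V0 and c = (n-p)/rss (or 1/s2 fixed)
        cB, sg = chol_info
        SZZ = sg[:, None] * ZtZ  # G^{1/2} Z'Z
        rhs = np.concatenate(
            [SZZ, sg[:, None] * ZtX, (sg * Zty)[:, None]], axis=1
        )
        sol = np.linalg.solve(cB.T, np.linalg.solve(cB, rhs))
        corr = SZZ.T @ sol
        ZtViZ = ZtZ - corr[:, :q]  # Z' V0^{-1} Z
        ZtViX = ZtX - corr[:, q:q + p]  # Z' V0^{-1} X
        ZtViy = Zty - corr[:, -1]
        A = np.linalg.solve(cXtVX.T, np.linalg.solve(cXtVX, ZtViX.T))  # (X'V X)^-1 X'V Z
        ZtPZdiag_blocks = ZtViZ - ZtViX @ A
        ZtPy = ZtViy - ZtViX @ beta
        c = (n - p) / rss if fix_residual is None else 1.0 / s2
        grad = np.empty(nf)
        for f in range(nf):
            sl = fslice[f]
            tr_f = float(np.trace(ZtPZdiag_blocks[sl, sl]))
            quad = float(ZtPy[sl] @ ZtPy[sl])
            grad[f] = gamma[f] * (tr_f - c * quad)
        return val, grad

    if nf:
        bounds = [(-30.0, 15.0)] * nf
        if start is not None:
            starts = [np.clip(start, -30.0, 15.0)]
        else:
            # the profiled surface can have spurious quasi-stationary points;
            # two spread-out starts make the gradient search reliable
            starts = [np.zeros(nf), np.full(nf, -3.0)]
        fg = lambda d: neg2_reml(d, with_grad=True)  # noqa: E731
        results = []
        for x0 in starts:
            # ftol is relative; tighter would chase the numerical noise
            # floor of the Cholesky-based objective
            results.append(
                optimize.minimize(
                    fg, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-5},
                )
            )
        any_success = any(bool(r.success) for r in results)
        best = min(results, key=lambda r: r.fun)
        agree = len(results) < 2 or abs(results[0].fun - results[1].fun) < 1e-4
        if not (any_success and agree):
            # alternate derivative-free polish (escapes line-search stalls on
            # boundaries) with gradient steps until the criterion stabilizes;
            # a plateau within 1e-5 counts as converged
            settled = False
            for _ in range(3):
                polish = optimize.minimize(
                    neg2_reml, np.clip(best.x, -30.0, 15.0),
                    method="Nelder-Mead", bounds=bounds,
                    options={"maxiter": 400, "fatol": 1e-7, "xatol": 1e-6},
                )
                r = optimize.minimize(
                    fg, np.clip(polish.x, -30.0, 15.0), jac=True,
                    method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-5},
                )
                new_best = min([best, polish, r], key=lambda s: s.fun)
                if best.fun - new_best.fun < 1e-5:
                    best = new_best
                    settled = True
                    break
                best = new_best
            if not (settled or any_success or best.success):
                raise ConvergenceError(
                    f"REML did not converge: {best.message}", trace
                )
        delta = best.x
        jac = getattr(best, "jac", None)
        grad_norm = float(np.max(np.abs(jac))) if jac is not None else np.nan
        converged = True
        loglik = -0.5 * float(best.fun)
    else:
        delta = np.array([])
        grad_norm = 0.0
        converged = True
        loglik = -0.5 * neg2_reml(delta)

    gamma = np.exp(delta) if nf else np.array([])
    logdet, XtVX, XtVy, ytVy, chol_info, g_full = crossprods(gamma)
    XtVX_inv = np.linalg.inv(XtVX)
    beta = XtVX_inv @ XtVy
    rss = ytVy - float(beta @ XtVy)
    s2e = rss / (n - p) if fix_residual is None else fix_residual
    cov_beta = XtVX_inv * s2e

    vcomp = {"residual": float(s2e)}
    at_bound = gamma <= np.exp(-30.0) * 1.001
    for f in range(nf):
        v = float(gamma[f] * s2e)
        if at_bound[f]:
            logger.warning("variance component %r at lower bound; reported 0", names[f])
            v = 0.0
        vcomp[names[f]] = v
    for name, vals in random_factors.items():
        if name not in vcomp:
            vcomp[name] = 0.0

    blups: dict[str, pd.Series] = {}
    if nf:
        cB, sg = chol_info
        resid_t = Zty - ZtX @ beta
        t2 = np.linalg.solve(cB.T, np.linalg.solve(cB, sg * resid_t))
        u = sg * t2
        for f in range(nf):
            blups[names[f]] = pd.Series(
                u[offs[f]: offs[f + 1]], index=level_names[f]
            )

    # containment df: observations minus rank of [X, Z-used]
    rank_z = sum(sizes[f] - 1 for f in range(nf) if not at_bound[f])
    df_denom = float(n - p - rank_z)

    return LmmFit(
        beta=beta,
        cov_beta=cov_beta,
        fixed_names=list(fixed_names),
        vcomp=vcomp,
        loglik_reml=loglik,
        n_obs=n,
        df_denom=max(df_denom, 1.0),
        converged=converged,
        gradient_norm=grad_norm,
        blups=blups,
    )


def _vcomp_start(fit: LmmFit, factor_names) -> np.ndarray:
    s2e = max(fit.vcomp.get("residual", 1.0), 1e-12)
    return np.array(
        [np.log(max(fit.vcomp.get(f, 1.0), 1e-10) / s2e) for f in factor_names]
    )


# ---------------------------------------------------------------------------
# Region BLUEs for the trial presets
# ---------------------------------------------------------------------------

#: Model presets: random factors by trait sampling design.
#: "plots"  - 25 trees/provenance in 5-tree row plots: Prov(R), B, Plot(B)
#: "cores"  - 1 tree/provenance/block core sample: B only
PRESETS = {
    "plots": ("provenance", "block", "plot"),
    "cores": ("block",),
}


@dataclass
class RegionEstimates:
    """Per-region estimates, SEs and Tukey letters, plus model metadata."""

    table: pd.DataFrame  # region, estimate, se, letters
    cov: np.ndarray  # covariance of region estimates (link scale for GLMM)
    vcomp: dict[str, float]
    df_denom: float
    response: str
    separation: list[str] = field(default_factory=list)  # GLMM-only flags


def _region_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    regions = sorted(df["region"].unique())
    if len(regions) < 2:
        raise ValueError("need >= 2 regions")
    X = (df["region"].to_numpy()[:, None] == np.array(regions)[None, :]).astype(float)
    return X, regions


def _preset_factors(df: pd.DataFrame, preset: str) -> dict[str, np.ndarray]:
    factors = {}
    for f in PRESETS[preset]:
        if f == "provenance":
            factors["provenance"] = df["provenance_id"].to_numpy()
        elif f == "block":
            factors["block"] = df["block"].to_numpy()
        elif f == "plot":
            # plot nested in block: label by (block, plot)
            factors["plot"] = (
                df["block"].astype(str) + ":" + df["plot"].astype(str)
            ).to_numpy()
    return factors


def fit_lmm_blues(
    df: pd.DataFrame,
    response: str,
    preset: str = "plots",
    alpha: float = 0.05,
) -> RegionEstimates:
    """Regional BLUEs with SEs and Tukey letters for a Gaussian trait.

    Region enters as a cell-means fixed effect so the BLUEs are the region
    means directly; random effects follow the named sampling preset.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    data = df.dropna(subset=[response])
    X, regions = _region_design(data)
    fit = fit_lmm(
        data[response].to_numpy(dtype=float),
        X,
        _preset_factors(data, preset),
        fixed_names=regions,
    )
    letters = tukey_letters(fit.beta, fit.cov_beta, fit.df_denom, alpha=alpha)
    table = pd.DataFrame(
        {
            "region": regions,
            "estimate": fit.beta,
            "se": np.sqrt(np.clip(np.diag(fit.cov_beta), 0.0, None)),
            "letters": letters,
        }
    )
    return RegionEstimates(
        table=table,
        cov=fit.cov_beta,
        vcomp=fit.vcomp,
        df_denom=fit.df_denom,
        response=response,
    )


def fit_glmm_survival(
    df: pd.DataFrame,
    preset: str = "plots",
    alpha: float = 0.05,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> RegionEstimates:
    """Binomial logit GLMM for survival, fitted by PQL; probability scale.

    Regions whose trees all share one outcome (complete separation) are
    flagged: their estimate is reported at the boundary (0 or 1) with an
    infinite SE rather than silently penalized, and they are excluded
    from the letter display.
    """
    data = df.dropna(subset=["survival"])
    y = data["survival"].to_numpy(dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("survival must be 0/1")
    X, regions = _region_design(data)
    factors = _preset_factors(data, preset)

    separated = []
    for j, r in enumerate(regions):
        vals = y[X[:, j] == 1.0]
        if vals.min() == vals.max():
            separated.append(r)
            logger.warning(
                "region %s: complete separation (all survival = %g)", r, vals[0]
            )

    prob = np.full(len(regions), np.nan)
    se_prob = np.full(len(regions), np.nan)
    ci_low = np.full(len(regions), np.nan)
    ci_high = np.full(len(regions), np.nan)
    letters = [""] * len(regions)
    kept = [r for r in regions if r not in separated]

    vcomp: dict[str, float] = {}
    cov = np.zeros((len(regions), len(regions)))
    df_denom = float(len(y))
    if len(kept) >= 2:
        # fit on the non-separated regions only; a separated cell-mean has no
        # finite MLE and would destabilize the working-response iterations
        mask = np.isin(data["region"].to_numpy(), kept)
        yk = y[mask]
        Xk = X[np.ix_(mask, [regions.index(r) for r in kept])]
        fk = {name: vals[mask] for name, vals in factors.items()}
        eta = np.clip(Xk @ np.linalg.lstsq(Xk, (yk - 0.5) * 4, rcond=None)[0], -4, 4)
        fit = None
        start = None
        for _ in range(max_iter):
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            z = eta + (yk - mu) / w
            # dispersion fixed at 1 (binomial); estimating it lets spurious
            # cluster variance soak up working-residual noise on binary data
            fit = fit_lmm(z, Xk, fk, fixed_names=kept, weights=w, start=start,
                          fix_residual=1.0)
            start = _vcomp_start(fit, fit.blups.keys())
            eta_new = Xk @ fit.beta
            for fname, u in fit.blups.items():
                eta_new = eta_new + u.reindex(pd.Series(fk[fname])).to_numpy()
            if np.max(np.abs(eta_new - eta)) < tol:
                break
            eta = eta_new
        assert fit is not None
        se_link = np.sqrt(np.diag(fit.cov_beta))
        p_hat = 1.0 / (1.0 + np.exp(-fit.beta))
        kept_letters = tukey_letters(fit.beta, fit.cov_beta, fit.df_denom,
                                     alpha=alpha)
        for i, r in enumerate(kept):
            j = regions.index(r)
            prob[j] = p_hat[i]
            se_prob[j] = se_link[i] * p_hat[i] * (1.0 - p_hat[i])
            # 2-SE Wald interval on the link scale, back-transformed:
            # near-boundary probabilities get the proper asymmetric interval
            ci_low[j] = 1.0 / (1.0 + np.exp(-(fit.beta[i] - 2.0 * se_link[i])))
            ci_high[j] = 1.0 / (1.0 + np.exp(-(fit.beta[i] + 2.0 * se_link[i])))
            letters[j] = kept_letters[i]
            for i2, r2 in enumerate(kept):
                cov[j, regions.index(r2)] = fit.cov_beta[i, i2]
        vcomp = fit.vcomp
        df_denom = fit.df_denom
    for r in separated:
        j = regions.index(r)
        prob[j] = float(y[X[:, j] == 1.0][0])
        se_prob[j] = np.inf
        ci_low[j], ci_high[j] = 0.0, 1.0
    table = pd.DataFrame(
        {"region": regions, "estimate": prob, "se": se_prob,
         "ci_low": ci_low, "ci_high": ci_high, "letters": letters}
    )
    return RegionEstimates(
        table=table,
        cov=cov,
        vcomp=vcomp,
        df_denom=df_denom,
        response="survival",
        separation=separated,
    )


# ---------------------------------------------------------------------------
# Tukey-adjusted compact letter display
# ---------------------------------------------------------------------------

def tukey_letters(
    estimates: np.ndarray,
    cov: np.ndarray,
    df_denom: float,
    alpha: float = 0.05,
    exclude: list[int] | None = None,
) -> list[str]:
    """Compact letter display from all pairwise studentized-range tests.

    Pair (i, j) differs when |est_i - est_j| / SE_diff exceeds
    q(1-alpha; k, df) / sqrt(2). Letters are assigned with the
    insert-and-absorb algorithm; groups sharing any letter are not
    significantly different at family-wise level alpha.
    """
    estimates = np.asarray(estimates, dtype=float)
    k = len(estimates)
    if k < 2:
        raise ValueError("need >= 2 groups")
    cov = np.asarray(cov, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError("singular or non-finite covariance")
    exclude = set(exclude or [])
    active = [i for i in range(k) if i not in exclude]
    kk = len(active)
    if kk < 2:
        return [""] * k
    qcrit = stats.studentized_range.ppf(1.0 - alpha, kk, df_denom) / math.sqrt(2.0)

    different = set()
    scale = max(1.0, float(np.max(np.abs(estimates))))
    for a, b in itertools.combinations(active, 2):
        var = cov[a, a] + cov[b, b] - 2.0 * cov[a, b]
        se = math.sqrt(max(var, 0.0))
        diff = abs(estimates[a] - estimates[b])
        if se == 0.0:
            # noiseless limit: any real difference is significant
            if diff > 1e-9 * scale:
                different.add((a, b))
        elif diff / se > qcrit:
            different.add((a, b))

    # insert-and-absorb on the active groups
    columns: list[set[int]] = [set(active)]
    for (a, b) in sorted(different):
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb subsets
        new_cols.sort(key=len, reverse=True)
        kept: list[set[int]] = []
        for col in new_cols:
            if not any(col <= other for other in kept):
                kept.append(col)
        columns = kept
    # order letters by the best estimate each column contains, for stable output
    columns.sort(key=lambda col: min(np.argsort(np.argsort(-estimates))[list(col)]))
    letters = [""] * k
    for li, col in enumerate(columns):
        ch = chr(ord("a") + li)
        for i in col:
            letters[i] += ch
    return letters


# ---------------------------------------------------------------------------
# Spearman / Holm association matrix
# ---------------------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a two-sided exact permutation p (small n).

    Conditions on the observed ranks (average ranks for ties) and
    enumerates all permutations of one margin.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(rx)
    obs = float(np.mean(rx * ry))
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (rx[perms] * ry[None, :]).mean(axis=1)
    p = float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))
    return obs, p


#: Cached sorted |rho| draws from the untied permutation null, keyed by n.
_SPEARMAN_NULL_CACHE: dict[int, np.ndarray] = {}
_SPEARMAN_NULL_SIZE = 1_000_000


def _spearman_null_table(n: int) -> np.ndarray:
    """Sorted |rho| under the permutation null for untied samples of size n.

    The null distribution of Spearman's rho for untied data depends only
    on n, so one large Monte-Carlo table (fixed internal stream, so
    p-values are reproducible) is shared by every pair tested at that n.
    """
    tbl = _SPEARMAN_NULL_CACHE.get(n)
    if tbl is None:
        rng = np.random.default_rng(20_170_533 + n)
        r = np.arange(n, dtype=float) - (n - 1) / 2.0
        denom = float(r @ r)
        chunks = []
        remaining = _SPEARMAN_NULL_SIZE
        while remaining > 0:
            m = min(50_000, remaining)
            perms = np.argsort(rng.random((m, n)), axis=1)
            chunks.append(np.abs(r[perms] @ r) / denom)
            remaining -= m
        tbl = np.sort(np.concatenate(chunks))
        _SPEARMAN_NULL_CACHE[n] = tbl
    return tbl


def _spearman_mc_p(n: int, rho: float) -> float:
    """Two-sided Monte-Carlo permutation p, add-one corrected (never 0)."""
    tbl = _spearman_null_table(n)
    count = len(tbl) - np.searchsorted(tbl, abs(rho) - 1e-12, side="left")
    return float((count + 1) / (len(tbl) + 1))


def spearman_with_p(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Exact permutation null for n <= ``exact_max_n``; a shared
    million-permutation Monte-Carlo null for larger untied samples (the
    t-approximation is anti-conservative at these sizes, which would
    inflate the family-wise error of the Holm screen); t-approximation
    only as the fallback when ties invalidate the untied null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    if n <= exact_max_n:
        return _spearman_exact_p(x, y)
    rho, p_t = stats.spearmanr(x, y)
    has_ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if has_ties:
        return float(rho), float(p_t)
    return float(rho), _spearman_mc_p(n, float(rho))


@dataclass
class AssociationMatrix:
    """Spearman rho, raw p, Holm-adjusted p and flags for trait x climate."""

    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_holm: pd.DataFrame
    significant: pd.DataFrame

    def tidy(self) -> pd.DataFrame:
        rows = []
        for t in self.rho.index:
            for c in self.rho.columns:
                rows.append(
                    (t, c, self.rho.loc[t, c], self.p_raw.loc[t, c],
                     self.p_holm.loc[t, c], bool(self.significant.loc[t, c]))
                )
        return pd.DataFrame(
            rows, columns=["trait", "climate", "rho", "p_raw", "p_holm", "significant"]
        )


def spearman_holm(
    traits: pd.DataFrame,
    climate: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "matrix",
) -> AssociationMatrix:
    """Spearman correlations of provenance trait means with origin climate,
    Holm-adjusted for multiple inference.

    ``family`` controls the Holm family: "matrix" (default) adjusts over
    the full trait x climate matrix jointly; "per_trait" adjusts each
    trait's row separately. Rows are matched on the shared index
    (provenance id). Pairs involving a constant column get NaN and are
    excluded from adjustment.
    """
    if family not in ("matrix", "per_trait"):
        raise ValueError("family must be 'matrix' or 'per_trait'")
    common = traits.index.intersection(climate.index)
    if len(common) < 5:
        raise ValueError("need >= 5 provenances with both traits and climate")
    T = traits.loc[common]
    C = climate.loc[common]
    rho = pd.DataFrame(index=T.columns, columns=C.columns, dtype=float)
    p_raw = rho.copy()
    for t in T.columns:
        for c in C.columns:
            r, p = spearman_with_p(T[t].to_numpy(), C[c].to_numpy())
            if np.isnan(r):
                logger.warning("constant column in pair (%s, %s); flagged NaN", t, c)
            rho.loc[t, c] = r
            p_raw.loc[t, c] = p
    p_holm = p_raw.copy()
    if family == "matrix":
        flat = p_raw.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        if ok.any():
            adj[ok] = multipletests(flat[ok], method="holm")[1]
        p_holm.loc[:, :] = adj.reshape(p_raw.shape)
    else:
        for t in p_raw.index:
            row = p_raw.loc[t].to_numpy(dtype=float)
            ok = ~np.isnan(row)
            adj = np.full_like(row, np.nan)
            if ok.any():
                adj[ok] = multipletests(row[ok], method="holm")[1]
            p_holm.loc[t] = adj
    significant = p_holm < alpha
    return AssociationMatrix(
        rho=rho, p_raw=p_raw, p_holm=p_holm, significant=significant
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


# ---------------------------------------------------------------------------
# Climate PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame  # provenances x PCs
    loadings: pd.DataFrame  # variables x PCs, as variable-PC correlations
    variance_fraction: np.ndarray


def climate_pca(climate: pd.DataFrame) -> PcaResult:
    """PCA of the provenance climate table on the correlation matrix.

    Scores are for provenances, loadings are variable-PC correlations
    (eigenvector * sqrt(eigenvalue)), and variance fractions sum to 1.
    Being correlation-based, the result is invariant to affine rescaling
    of any input variable. Eigenvector signs are fixed so the largest
    absolute loading of each PC is positive.
    """
    data = climate.select_dtypes(include=[np.number])
    if data.shape[0] < 3:
        raise ValueError("need >= 3 provenances")
    sd = data.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant climate variable(s): {constant}")
    Zs = (data - data.mean()) / sd
    corr = np.corrcoef(Zs.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] *= -1.0
    pcs = [f"PC{j + 1}" for j in range(len(evals))]
    scores = pd.DataFrame(Zs.to_numpy() @ evecs, index=data.index, columns=pcs)
    loadings = pd.DataFrame(
        evecs * np.sqrt(evals)[None, :], index=data.columns, columns=pcs
    )
    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_fraction=evals / evals.sum(),
    )
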
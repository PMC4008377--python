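"""Mixed-effects models of examiner performance.

The central model is a logistic regression of per-trial correctness with
*crossed* random intercepts for print pair and examiner:

    logit P(correct_ij = 1) = beta0 + x_ij' beta + printID_i + expertID_j

with printID_i ~ N(0, var_print) and expertID_j ~ N(0, var_expert)
independent. The marginal likelihood has no closed form; it is maximized
with a Laplace approximation. Random effects are parameterized spherically
(u = sigma * b, b ~ N(0, I)): for a candidate sigma the fixed effects and
spherical modes are maximized jointly by penalized IRLS, and the Laplace
log-likelihood

    l(sigma) = log f(y | eta_hat) - b_hat'b_hat / 2 - log det(H_bb) / 2

(H_bb the spherical-coordinate block of the penalized Hessian) is optimized
over sigma >= 0 by bounded quasi-Newton. With sigma fixed at zero the fit
reduces exactly to ordinary logistic regression.

Linear mixed models for response time, difficulty and confidence ratings
delegate to :class:`statsmodels.regression.mixed_linear_model.MixedLM`
with variance components emulating the crossed intercepts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist

logger = logging.getLogger(__name__)

RANDOM_FACTORS = {"printID": "pair_id", "expertID": "expert_id"}


class SeparationError(RuntimeError):
    """Quasi-complete separation: a coefficient diverges."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Declaration of one regression model.

    ``fixed`` lists feature-table columns entering as fixed effects (an
    intercept is always included); ``random`` is a subset of
    ``{"printID", "expertID"}``.
    """

    response: str
    fixed: list[str]
    random: list[str] = field(default_factory=lambda: ["printID", "expertID"])
    family: str = "binomial-logit"

    def __post_init__(self) -> None:
        bad = set(self.random) - set(RANDOM_FACTORS)
        if bad:
            raise ValueError(f"unknown random factors {sorted(bad)}")
        if self.family not in ("binomial-logit", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class FittedGLMM:
    """A fitted crossed logistic mixed model."""

    spec: ModelSpec
    beta: pd.Series  # fixed effects incl. "Intercept"
    se: pd.Series
    var_print: float
    var_expert: float
    blups: dict[str, pd.Series]  # factor name -> per-level intercept offset
    blup_se: dict[str, pd.Series]
    loglik: float
    n_obs: int
    converged: bool

    @property
    def z(self) -> pd.Series:
        """Wald z (estimate / SE); p-values from it should be read with caution."""
        return self.beta / self.se

    @property
    def n_params(self) -> int:
        return len(self.beta) + len(self.spec.random)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.n_obs) * self.n_params

    def predict(self, features: pd.DataFrame | pd.Series,
                include_print_blup: bool = False) -> np.ndarray | float:
        return predict_accuracy(self, features, include_print_blup)


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# design assembly


def build_design(
    spec: ModelSpec, trials: pd.DataFrame, features: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, tuple[np.ndarray, pd.Index]]]:
    """Join trials with pair features and assemble y, X and factor codings."""
    feats = features.reset_index() if features.index.name == "pair_id" else features
    missing = [c for c in spec.fixed if c not in feats.columns and c not in trials.columns]
    if missing:
        raise KeyError(f"fixed effects not found in features/trials: {missing}")
    keep = [c for c in trials.columns if c == "pair_id" or c not in feats.columns]
    df = trials[keep].merge(feats, on="pair_id", how="left", validate="many_to_one")
    lost = df[spec.fixed].isna().any(axis=1) if spec.fixed else pd.Series(False, index=df.index)
    if lost.any():
        raise ValueError(
            f"{int(lost.sum())} trial(s) reference pairs without features, "
            f"e.g. {df.loc[lost, 'pair_id'].iloc[0]!r}"
        )
    y = df[spec.response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in spec.fixed])
    names = ["Intercept"] + list(spec.fixed)
    factors: dict[str, tuple[np.ndarray, pd.Index]] = {}
    for fac in spec.random:
        col = RANDOM_FACTORS[fac]
        codes, levels = pd.factorize(df[col], sort=True)
        factors[fac] = (codes, levels)
    return y, X, names, factors


def _factor_matrix(codes: np.ndarray, n_levels: int) -> sparse.csr_matrix:
    n = len(codes)
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


# ---------------------------------------------------------------------------
# Laplace machinery


def _pirls(
    y: np.ndarray,
    A: np.ndarray,
    penalized: np.ndarray,
    coef0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Maximize the penalized Bernoulli log-likelihood over all coefficients.

    ``A`` is the combined design [X, Z*Lambda]; ``penalized`` flags the
    spherical random-effect coordinates (unit ridge). Returns the optimum,
    the final IRLS weights and the penalized log-likelihood.
    """

    def pll(coef: np.ndarray) -> float:
        eta = A @ coef
        return float(y @ eta - np.logaddexp(0.0, eta).sum()
                     - 0.5 * coef[penalized] @ coef[penalized])

    coef = coef0.copy()
    current = pll(coef)
    w = np.empty(len(y))
    for _ in range(max_iter):
        eta = A @ coef
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = A.T @ (y - mu)
        grad[penalized] -= coef[penalized]
        H = (A * w[:, None]).T @ A
        H[penalized, penalized] += 1.0
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving
        alpha, improved = 1.0, False
        for _ in range(30):
            cand = coef + alpha * step
            val = pll(cand)
            if val >= current - 1e-12:
                improved = val > current + tol * (1.0 + abs(current))
                coef, current = cand, val
                break
            alpha *= 0.5
        if not improved:
            break
    return coef, w, current


def _joint_mode(
    y: np.ndarray,
    X: np.ndarray,
    Z: sparse.csr_matrix | None,
    lam: np.ndarray,
    coef0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Joint penalized mode over (beta, b) at per-column scalings ``lam``.

    This profiles the fixed effects on the *joint* penalized likelihood —
    a fast approximation used only to produce starting values for the true
    Laplace optimization (which must treat beta as an outer parameter
    because the log-determinant term depends on it).
    """
    p = X.shape[1]
    if Z is None or Z.shape[1] == 0:
        A = X
        penalized = np.zeros(p, dtype=bool)
    else:
        A = np.hstack([X, Z.toarray() * lam[None, :]])
        penalized = np.concatenate([np.zeros(p, bool), np.ones(Z.shape[1], bool)])
    return _pirls(y, A, penalized, coef0)


class _SphericalDesign:
    """Random-effect bookkeeping: spherical modes, Hessian solves, logdet.

    For one grouping factor the b-block Hessian is diagonal; for two
    crossed factors it is [[D1, C], [C', D2]] with diagonal D's and is
    solved through the Schur complement of the (small) second block.
    """

    def __init__(self, factors: list[tuple[np.ndarray, int]]):
        self.codes = [c for c, _ in factors]
        self.sizes = [s for _, s in factors]
        self.Z = [_factor_matrix(c, s) for c, s in factors]
        self.q = sum(self.sizes)

    def eta_random(self, sigmas: np.ndarray, b: np.ndarray) -> np.ndarray:
        out = 0.0
        off = 0
        for Zf, s, sz in zip(self.Z, sigmas, self.sizes):
            out = out + s * (Zf @ b[off:off + sz])
            off += sz
        return out

    def grad(self, sigmas: np.ndarray, resid: np.ndarray, b: np.ndarray) -> np.ndarray:
        parts = []
        off = 0
        for Zf, s, sz in zip(self.Z, sigmas, self.sizes):
            parts.append(s * (Zf.T @ resid) - b[off:off + sz])
            off += sz
        return np.concatenate(parts) if parts else np.zeros(0)

    def _blocks(self, sigmas: np.ndarray, w: np.ndarray):
        diags = [
            (s * s) * np.bincount(c, weights=w, minlength=sz) + 1.0
            for c, s, sz in zip(self.codes, sigmas, self.sizes)
        ]
        C = None
        if len(self.Z) == 2:
            C = (sigmas[0] * sigmas[1]) * (
                self.Z[0].multiply(w[:, None]).T @ self.Z[1]
            ).toarray()
        return diags, C

    def solve(self, sigmas: np.ndarray, w: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        diags, C = self._blocks(sigmas, w)
        if len(diags) == 1:
            return rhs / diags[0]
        q1 = self.sizes[0]
        r1, r2 = rhs[:q1], rhs[q1:]
        d1 = diags[0]
        S = np.diag(diags[1]) - C.T @ (C / d1[:, None])
        x2 = np.linalg.solve(S, r2 - C.T @ (r1 / d1))
        x1 = (r1 - C @ x2) / d1
        return np.concatenate([x1, x2])

    def logdet(self, sigmas: np.ndarray, w: np.ndarray) -> float:
        diags, C = self._blocks(sigmas, w)
        if len(diags) == 0:
            return 0.0
        if len(diags) == 1:
            return float(np.log(diags[0]).sum())
        d1 = diags[0]
        S = np.diag(diags[1]) - C.T @ (C / d1[:, None])
        sign, ld = np.linalg.slogdet(S)
        if sign <= 0:
            raise ConvergenceError("indefinite Laplace Hessian")
        return float(np.log(d1).sum() + ld)


def _b_mode(
    y: np.ndarray,
    eta_fixed: np.ndarray,
    design: _SphericalDesign,
    sigmas: np.ndarray,
    b0: np.ndarray,
    tol: float = 1e-11,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mode of the spherical random effects given fixed-effect predictor."""

    def pll(b: np.ndarray) -> float:
        eta = eta_fixed + design.eta_random(sigmas, b)
        return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * b @ b)

    b = b0.copy()
    current = pll(b)
    w = np.empty(len(y))
    for _ in range(max_iter):
        eta = eta_fixed + design.eta_random(sigmas, b)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        g = design.grad(sigmas, y - mu, b)
        step = design.solve(sigmas, w, g)
        alpha, improved = 1.0, False
        for _ in range(30):
            cand = b + alpha * step
            val = pll(cand)
            if val >= current - 1e-13:
                improved = val > current + tol * (1.0 + abs(current))
                b, current = cand, val
                break
            alpha *= 0.5
        if not improved:
            break
    eta = eta_fixed + design.eta_random(sigmas, b)
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    return b, w, current


def _laplace_loglik(
    y: np.ndarray,
    X: np.ndarray,
    design: _SphericalDesign,
    beta: np.ndarray,
    sigmas: np.ndarray,
    b0: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Laplace-approximated marginal log-likelihood at (beta, sigmas)."""
    eta_fixed = X @ beta
    b, w, pen_ll = _b_mode(y, eta_fixed, design, sigmas, b0)
    ll = pen_ll - 0.5 * design.logdet(sigmas, w)
    return ll, b, w


def _observed_information_se(
    y: np.ndarray,
    X: np.ndarray,
    design: _SphericalDesign,
    beta: np.ndarray,
    sigmas: np.ndarray,
    b_warm: np.ndarray,
    h: float = 1e-3,
) -> np.ndarray | None:
    """Fixed-effect SEs from the full (beta, sigma) observed information.

    Central second differences of the Laplace log-likelihood; returns None
    when the information matrix is not usably positive definite (e.g. a
    variance estimate on the zero boundary), so the caller can fall back
    to conditional SEs.
    """
    p = X.shape[1]
    x0 = np.concatenate([beta, sigmas])
    d = len(x0)
    warm = {"b": b_warm}

    def f(x: np.ndarray) -> float:
        sig = np.clip(x[p:], 0.0, None)
        ll, b, _ = _laplace_loglik(y, X, design, x[:p], sig, warm["b"])
        warm["b"] = b
        return ll

    H = np.empty((d, d))
    steps = np.maximum(h, h * np.abs(x0))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = steps[i]
            ej = np.zeros(d); ej[j] = steps[j]
            val = (f(x0 + ei + ej) - f(x0 + ei - ej)
                   - f(x0 - ei + ej) + f(x0 - ei - ej)) / (4.0 * steps[i] * steps[j])
            H[i, j] = H[j, i] = val
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return None
    diag = np.diag(cov)[:p]
    if not np.all(np.isfinite(diag)) or np.any(diag <= 0):
        return None
    return np.sqrt(diag)


def fit_glmm(
    spec: ModelSpec,
    trials: pd.DataFrame,
    features: pd.DataFrame,
    sigma0: np.ndarray | None = None,
    beta0: pd.Series | None = None,
    sigma_max: float = 10.0,
    separation_bound: float = 15.0,
    se_method: str = "hessian",
) -> FittedGLMM:
    """Fit the crossed random-intercepts logistic model by Laplace ML.

    With ``spec.random`` empty the same machinery performs an ordinary
    logistic regression. Raises :class:`SeparationError` when a fixed
    effect diverges (e.g. a constant response) and flags non-convergence
    on the result rather than failing silently.

    ``se_method="hessian"`` (default) takes fixed-effect standard errors
    from the inverse of the full numerically-differentiated observed
    information over (beta, sigma), which propagates variance-parameter
    uncertainty; ``"conditional"`` uses the faster Schur complement of the
    joint (beta, b) Hessian, conditional on the variance estimates.
    """
    if spec.family != "binomial-logit":
        raise ValueError("fit_glmm handles the binomial-logit family")
    y, X, names, factors = build_design(spec, trials, features)
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all():
        raise ValueError("response must be binary 0/1")

    p = X.shape[1]
    factor_names = list(factors)
    sizes = [len(factors[f][1]) for f in factor_names]
    design = _SphericalDesign(
        [(factors[f][0], len(factors[f][1])) for f in factor_names]
    )
    q = design.q
    n_sigma = len(factor_names)

    # stage 0: starting fixed effects — warm start if given, else plain GLM
    if beta0 is not None:
        beta = np.array([beta0.get(nm, 0.0) for nm in names], float)
    else:
        beta, _, _ = _pirls(y, X, np.zeros(p, bool), np.zeros(p))

    converged = True
    if n_sigma:

        def lam_vector(sigmas: np.ndarray) -> np.ndarray:
            return np.concatenate(
                [np.full(sz, s) for sz, s in zip(sizes, sigmas)]
            )

        if sigma0 is not None:
            # warm start: trust the supplied scales, skip stage 1
            sig1 = np.clip(np.asarray(sigma0, float), 0.05, sigma_max)
            b_start = np.zeros(q)
        else:
            Z = sparse.hstack([_factor_matrix(c, s) for c, s in
                               zip(design.codes, design.sizes)]).tocsr()
            state = {"coef": np.concatenate([beta, np.zeros(q)])}

            # stage 1: profile the variance scales with beta at the joint
            # penalized mode (fast; starting values for the true objective)
            def stage1(sigmas: np.ndarray) -> float:
                coef, w, _ = _joint_mode(y, X, Z, lam_vector(sigmas), state["coef"])
                state["coef"] = coef
                eta = X @ coef[:p] + Z @ (lam_vector(sigmas) * coef[p:])
                ll = float(y @ eta - np.logaddexp(0.0, eta).sum()
                           - 0.5 * coef[p:] @ coef[p:]
                           - 0.5 * design.logdet(sigmas, w))
                return -2.0 * ll

            if n_sigma == 1:
                res1 = optimize.minimize_scalar(
                    lambda s: stage1(np.array([s])),
                    bounds=(0.0, sigma_max), method="bounded",
                    options={"xatol": 1e-3},
                )
                sig1 = np.array([res1.x])
            else:
                res1 = optimize.minimize(
                    stage1, np.full(n_sigma, 0.7),  # variances 0.5 to start
                    method="Nelder-Mead",
                    options={"xatol": 1e-3, "fatol": 1e-3},
                )
                sig1 = np.clip(np.abs(res1.x), 0.0, sigma_max)
            coef, _, _ = _joint_mode(y, X, Z, lam_vector(sig1), state["coef"])
            beta = coef[:p]
            b_start = coef[p:].copy()

        # stage 2: true Laplace ML over (beta, sigmas) with inner b-mode
        warm = {"b": b_start}

        def objective(x: np.ndarray) -> float:
            ll, b, _ = _laplace_loglik(y, X, design, x[:p], x[p:], warm["b"])
            warm["b"] = b
            return -2.0 * ll

        x0 = np.concatenate([beta, sig1])
        res2 = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            bounds=[(None, None)] * p + [(0.0, sigma_max)] * n_sigma,
            options={"ftol": 1e-11, "gtol": 1e-6, "eps": 1e-5,
                     "maxiter": 500},
        )
        converged = bool(res2.success)
        beta = res2.x[:p]
        sigmas = res2.x[p:]
        loglik, b_hat, w = _laplace_loglik(y, X, design, beta, sigmas, warm["b"])
        coef = np.concatenate([beta, b_hat])
        lam = lam_vector(sigmas)
    else:
        Z = None
        coef, w, _ = _pirls(y, X, np.zeros(p, bool), beta)
        beta = coef
        eta = X @ beta
        loglik = float(y @ eta - np.logaddexp(0.0, eta).sum())
        sigmas = np.zeros(0)
        lam = np.zeros(0)

    beta = coef[:p]
    if np.abs(beta).max() > separation_bound:
        worst = names[int(np.abs(beta).argmax())]
        raise SeparationError(
            f"coefficient for {worst!r} diverged (|beta| > {separation_bound}); "
            "the response is likely separated or constant"
        )

    # SEs conditional on the variance estimates, from the joint Hessian
    if q:
        Z = sparse.hstack([_factor_matrix(c, s) for c, s in
                           zip(design.codes, design.sizes)]).tocsr()
        A = np.hstack([X, Z.toarray() * lam[None, :]])
    else:
        A = X
    H = (A * w[:, None]).T @ A
    if q:
        H[p:, p:][np.diag_indices(q)] += 1.0
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))

    if q and se_method == "hessian":
        full_se = _observed_information_se(y, X, design, beta, sigmas,
                                           coef[p:].copy())
        if full_se is not None:
            se = full_se

    variances = dict(zip(factor_names, sigmas**2))
    blups: dict[str, pd.Series] = {}
    blup_se: dict[str, pd.Series] = {}
    offset = p
    for fac, sz in zip(factor_names, sizes):
        idx = slice(offset, offset + sz)
        s = sigmas[factor_names.index(fac)]
        blups[fac] = pd.Series(s * coef[idx], index=factors[fac][1], name=fac)
        blup_se[fac] = pd.Series(
            s * np.sqrt(np.clip(np.diag(cov)[idx], 0.0, None)), index=factors[fac][1]
        )
        offset += sz

    if not converged:
        logger.warning("variance optimization did not report convergence")
    return FittedGLMM(
        spec=spec,
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        var_print=float(variances.get("printID", 0.0)),
        var_expert=float(variances.get("expertID", 0.0)),
        blups=blups,
        blup_se=blup_se,
        loglik=float(loglik),
        n_obs=len(y),
        converged=converged,
    )


def predict_accuracy(
    fit: FittedGLMM,
    features: pd.DataFrame | pd.Series,
    include_print_blup: bool = False,
) -> np.ndarray | float:
    """Predicted probability of a correct judgment for feature row(s).

    Features must already be on the fit's training scale. For pairs unseen
    during fitting (or with ``include_print_blup=False``) the print offset
    is 0, i.e. a population-level prediction.
    """
    single = isinstance(features, pd.Series)
    df = features.to_frame().T if single else features
    missing = [c for c in fit.spec.fixed if c not in df.columns]
    if missing:
        raise KeyError(f"missing features: {missing}")
    eta = np.full(len(df), fit.beta["Intercept"])
    for col in fit.spec.fixed:
        eta += fit.beta[col] * df[col].to_numpy(float)
    if include_print_blup and "printID" in fit.blups:
        offsets = fit.blups["printID"].reindex(df.index).fillna(0.0).to_numpy()
        eta += offsets
    prob = expit(eta)
    return float(prob[0]) if single else prob


# ---------------------------------------------------------------------------
# inference and selection


def lrt(full: FittedGLMM, null: FittedGLMM) -> LRTResult:
    """Likelihood-ratio test of a null model nested in a full model."""
    if not (set(null.spec.fixed) <= set(full.spec.fixed)
            and set(null.spec.random) <= set(full.spec.random)):
        raise ValueError("null model is not nested in the full model")
    if null.n_obs != full.n_obs:
        raise ValueError("models were fitted to different numbers of observations")
    df = full.n_params - null.n_params
    if df < 1:
        if full.n_params == null.n_params and set(null.spec.fixed) == set(full.spec.fixed):
            return LRTResult(chi2=0.0, df=1, p=1.0)
        raise ValueError("full model has no extra parameters")
    chi2 = max(0.0, 2.0 * (full.loglik - null.loglik))
    if chi2 == 0.0 and df >= 1 and full.spec.fixed == null.spec.fixed \
            and full.spec.random == null.spec.random:
        return LRTResult(chi2=0.0, df=df, p=1.0)
    return LRTResult(chi2=chi2, df=df, p=float(chi2_dist.sf(chi2, df)))


def _interaction_mains(term: str) -> tuple[str, str] | None:
    if term.endswith("_LxK"):
        stem = term[: -len("_LxK")]
        return f"{stem}_L", f"{stem}_K"
    return None


def aic_backward_select(
    spec: ModelSpec,
    trials: pd.DataFrame,
    features: pd.DataFrame,
    hierarchy: bool = True,
) -> tuple[FittedGLMM, list[dict]]:
    """Greedy backward elimination of fixed effects by AIC.

    At each step the single fixed effect whose removal lowers AIC the most
    is dropped; selection stops when no removal lowers AIC. With
    ``hierarchy=True`` (default) a main effect is only removable once no
    surviving interaction involves it. Returns the final fit and the trace
    of ``(step, dropped, aic)``.
    """
    current = fit_glmm(spec, trials, features, se_method="conditional")
    trace: list[dict] = [{"step": 0, "dropped": None, "aic": current.aic}]
    sigma0 = _sigma_from_fit(current)
    step = 0
    while True:
        fixed = current.spec.fixed
        protected: set[str] = set()
        if hierarchy:
            for term in fixed:
                mains = _interaction_mains(term)
                if mains:
                    protected.update(m for m in mains if m in fixed)
        candidates = [t for t in fixed if t not in protected]
        best_fit, best_term = None, None
        for term in candidates:
            sub = replace(current.spec, fixed=[t for t in fixed if t != term])
            try:
                fit = fit_glmm(sub, trials, features, sigma0=sigma0,
                               beta0=current.beta, se_method="conditional")
            except (SeparationError, ConvergenceError) as exc:
                logger.warning("skipping removal of %s: %s", term, exc)
                continue
            if best_fit is None or fit.aic < best_fit.aic:
                best_fit, best_term = fit, term
        if best_fit is None or best_fit.aic >= current.aic:
            break
        step += 1
        current = best_fit
        sigma0 = _sigma_from_fit(current)
        trace.append({"step": step, "dropped": best_term, "aic": current.aic})
        logger.info("AIC step %d: dropped %s (AIC %.2f)", step, best_term, current.aic)
    # candidate fits carry cheap conditional SEs; refit the winner with the
    # full observed-information SEs
    current = fit_glmm(current.spec, trials, features,
                       sigma0=_sigma_from_fit(current), beta0=current.beta)
    return current, trace


def _sigma_from_fit(fit: FittedGLMM) -> np.ndarray:
    return np.sqrt(np.array(
        [fit.var_print if f == "printID" else fit.var_expert for f in fit.spec.random]
    ))


def compare_random_structures(
    trials: pd.DataFrame,
    features: pd.DataFrame,
    fixed: list[str],
    response: str = "correct",
) -> dict:
    """Compare crossed, print-only and expert-only random-intercept models.

    Reports AIC/BIC per structure, the chi2(1) likelihood-ratio test for the
    examiner intercept, and the range of examiner offsets with their SEs —
    the evidence pattern used to decide whether between-examiner variation
    can be dropped (offsets all within 2 SE of zero).
    """
    if trials["expert_id"].nunique() < 2 or trials["pair_id"].nunique() < 2:
        raise ValueError("need at least 2 experts and 2 pairs")
    fits = {}
    for label, random in (
        ("print+expert", ["printID", "expertID"]),
        ("print", ["printID"]),
        ("expert", ["expertID"]),
    ):
        fits[label] = fit_glmm(
            ModelSpec(response=response, fixed=fixed, random=random), trials, features
        )
    test = lrt(fits["print+expert"], fits["print"])
    off = fits["print+expert"].blups["expertID"]
    off_se = fits["print+expert"].blup_se["expertID"]
    within = bool((off.abs() <= 2.0 * off_se + 1e-12).all())
    return {
        "fits": fits,
        "table": pd.DataFrame(
            {
                "loglik": {k: f.loglik for k, f in fits.items()},
                "AIC": {k: f.aic for k, f in fits.items()},
                "BIC": {k: f.bic for k, f in fits.items()},
                "var_print": {k: f.var_print for k, f in fits.items()},
                "var_expert": {k: f.var_expert for k, f in fits.items()},
            }
        ),
        "expert_lrt": test,
        "expert_offset_range": (float(off.min()), float(off.max())),
        "expert_offsets_within_2se": within,
    }


# ---------------------------------------------------------------------------
# linear mixed models (response time, difficulty, confidence)


@dataclass
class FittedLMM:
    """A linear mixed model fitted by REML through statsmodels MixedLM."""

    spec: ModelSpec
    beta: pd.Series
    se: pd.Series
    tvalues: pd.Series
    var_print: float
    var_expert: float
    resid_var: float
    loglik: float
    n_obs: int
    converged: bool


def normalize_response_time(trials: pd.DataFrame, per_expert: bool = True) -> pd.Series:
    """z-score response times, by default within each examiner.

    Examiners differ widely in pace; a per-examiner z-score removes that
    scale difference before modeling. Set ``per_expert=False`` for a single
    global z-score.
    """
    rt = trials["response_time"].astype(float)
    if per_expert:
        def _z(x: pd.Series) -> pd.Series:
            sd = x.std(ddof=0)
            return (x - x.mean()) / sd if sd > 0 else x * 0.0
        return trials.groupby("expert_id")["response_time"].transform(_z)
    sd = rt.std(ddof=0)
    return (rt - rt.mean()) / sd if sd > 0 else rt * 0.0


def fit_lmm(
    spec: ModelSpec,
    trials: pd.DataFrame,
    features: pd.DataFrame,
    rt_normalization: str = "per_expert",
) -> FittedLMM:
    """Fit a Gaussian linear mixed model (REML) for a rating or RT response.

    Ratings models keep both the print and the examiner intercepts, whose
    variances are both of substantive interest. ``response_time`` is
    z-scored (per examiner by default; ``rt_normalization="global"`` for a
    single z-score) before fitting.
    """
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    if spec.family != "gaussian":
        raise ValueError("fit_lmm handles the gaussian family")
    feats = features.reset_index() if features.index.name == "pair_id" else features
    keep = [c for c in trials.columns if c == "pair_id" or c not in feats.columns]
    df = trials[keep].merge(feats, on="pair_id", how="left", validate="many_to_one")
    if spec.response == "response_time":
        df["_y"] = normalize_response_time(df, per_expert=rt_normalization == "per_expert")
    else:
        df["_y"] = df[spec.response].astype(float)
    df = df.dropna(subset=["_y"] + list(spec.fixed))

    y = df["_y"].to_numpy()
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in spec.fixed])
    names = ["Intercept"] + list(spec.fixed)

    if np.std(y) == 0.0:
        zeros = pd.Series(0.0, index=names)
        beta = zeros.copy()
        beta["Intercept"] = float(y[0]) if len(y) else 0.0
        return FittedLMM(spec, beta, zeros.copy(), zeros.copy(), 0.0, 0.0, 0.0,
                         loglik=float("nan"), n_obs=len(y), converged=True)

    exog_vc, vc_names = [], []
    for fac in spec.random:
        col = RANDOM_FACTORS[fac]
        codes, levels = pd.factorize(df[col], sort=True)
        exog_vc.append(_factor_matrix(codes, len(levels)).toarray())
        vc_names.append(fac)
    if not vc_names:
        ols = sm.OLS(y, X).fit()
        return FittedLMM(
            spec, pd.Series(ols.params, index=names), pd.Series(ols.bse, index=names),
            pd.Series(ols.tvalues, index=names), 0.0, 0.0, float(ols.scale),
            float(ols.llf), len(y), True,
        )

    from statsmodels.regression.mixed_linear_model import VCSpec

    spec_vc = VCSpec(
        names=vc_names,
        colnames=[[f"{n}_{i}" for i in range(m.shape[1])] for n, m in zip(vc_names, exog_vc)],
        mats=[[m] for m in exog_vc],
    )
    groups = np.zeros(len(df))  # single group: crossed effects live in the VCs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups, exog_vc=spec_vc)
        result = model.fit(reml=True, method="lbfgs")
    vcomp = dict(zip(vc_names, result.vcomp))
    return FittedLMM(
        spec=spec,
        beta=pd.Series(result.fe_params, index=names),
        se=pd.Series(result.bse_fe, index=names),
        tvalues=pd.Series(result.fe_params / result.bse_fe, index=names),
        var_print=float(vcomp.get("printID", 0.0)),
        var_expert=float(vcomp.get("expertID", 0.0)),
        resid_var=float(result.scale),
        loglik=float(result.llf),
        n_obs=len(y),
        converged=bool(result.converged),
    )
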
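"""Count regressions of incidence with a log population offset.

Four families: Poisson, negative binomial (NB2, variance mu + mu^2/theta),
and their zero-inflated extensions, in which a logistic component models
structural zeros with probability pi_i = logistic(gamma . z_i) and the
observed count is zero with probability pi_i + (1 - pi_i) f(0) and equals
y > 0 with probability (1 - pi_i) f(y). The count mean is always

    log mu_i = alpha + sum_k beta_k x_ik + log e_i

with the dog population e_i entering as an offset, so coefficients act
multiplicatively on the incidence *rate*. Covariates are deliberately not
centered so a coefficient reads directly in the covariate's own units.

Fits are maximum likelihood with analytic gradients (L-BFGS-B, fixed
initialization and tolerances, hence deterministic): the Poisson solution
initializes the richer families, the NB dispersion starts at a
method-of-moments value, and zero-inflation coefficients start at zero.
Wald standard errors come from the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln, digamma
from scipy.stats import norm

__all__ = [
    "ModelSpec",
    "CountModelFit",
    "FitError",
    "log_likelihood",
    "fit",
    "multiplicative_effect",
    "sqvif",
    "deviance_reduction",
    "select_zi_covariates",
]

FAMILIES = ("poisson", "zip", "negbin", "zinb")
_NB_FAMILIES = ("negbin", "zinb")
_ZI_FAMILIES = ("zip", "zinb")

# box constraints guarding the optimizer against numerical escape; generous
# relative to any plausible effect on these covariate scales
_COEF_BOUND = 50.0
_LOG_THETA_BOUNDS = (-12.0, 15.0)
_GAMMA_BOUND = 30.0


class FitError(RuntimeError):
    """Maximum-likelihood fit failed; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    count_covariates: tuple[str, ...] = ()
    zi_covariates: tuple[str, ...] = ()
    offset_name: str = "e"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.zi_covariates and self.family not in _ZI_FAMILIES:
            raise ValueError("zi_covariates must be empty for non-zero-inflated families")
        object.__setattr__(self, "count_covariates", tuple(self.count_covariates))
        object.__setattr__(self, "zi_covariates", tuple(self.zi_covariates))

    @property
    def has_theta(self) -> bool:
        return self.family in _NB_FAMILIES

    @property
    def zero_inflated(self) -> bool:
        return self.family in _ZI_FAMILIES

    @property
    def n_params(self) -> int:
        k = 1 + len(self.count_covariates)
        if self.has_theta:
            k += 1
        if self.zero_inflated:
            k += 1 + len(self.zi_covariates)
        return k


@dataclass
class CountModelFit:
    """A fitted count model in Table-3 layout: estimate / SE / p per term."""

    spec: ModelSpec
    alpha: float
    beta: dict[str, float]
    theta: float | None
    gamma: dict[str, float]  # 'intercept' + zi covariate names; empty if not ZI
    se: dict[str, float]
    p: dict[str, float]
    loglik: float
    aic: float
    deviance: float
    n_params: int
    nobs: int
    converged: bool = True
    optimizer: dict = field(default_factory=dict, repr=False)
    data_fingerprint: tuple = ()  # (nobs, sum y, sum e) for same-data checks

    def params_vector(self) -> np.ndarray:
        v = [self.alpha] + [self.beta[c] for c in self.spec.count_covariates]
        if self.spec.has_theta:
            v.append(np.log(self.theta))
        if self.spec.zero_inflated:
            v += [self.gamma["intercept"]] + [
                self.gamma[c] for c in self.spec.zi_covariates]
        return np.asarray(v, dtype=float)

    def coefficient_table(self) -> pd.DataFrame:
        """Long-format table: component, term, estimate, se, p."""
        rows = [("count", "intercept", self.alpha, self.se.get("alpha"),
                 self.p.get("alpha"))]
        for c in self.spec.count_covariates:
            rows.append(("count", c, self.beta[c], self.se.get(c), self.p.get(c)))
        if self.theta is not None:
            rows.append(("dispersion", "theta", self.theta, self.se.get("theta"),
                         np.nan))
        if self.spec.zero_inflated:
            rows.append(("zero_inflation", "intercept", self.gamma["intercept"],
                         self.se.get("zi_intercept"), self.p.get("zi_intercept")))
            for c in self.spec.zi_covariates:
                rows.append(("zero_inflation", c, self.gamma[c],
                             self.se.get(f"zi_{c}"), self.p.get(f"zi_{c}")))
        return pd.DataFrame(rows, columns=["component", "term", "estimate", "se", "p"])


def _design(spec: ModelSpec, table: pd.DataFrame):
    y = table["y"].to_numpy(float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("outcome y must contain non-negative integers")
    e = table[spec.offset_name].to_numpy(float)
    if np.any(e <= 0):
        raise ValueError("offset e must be positive for all rows")
    cols = [np.ones(len(table))]
    for c in spec.count_covariates:
        cols.append(table[c].to_numpy(float))
    X = np.column_stack(cols)
    Z = None
    if spec.zero_inflated:
        zcols = [np.ones(len(table))]
        for c in spec.zi_covariates:
            zcols.append(table[c].to_numpy(float))
        Z = np.column_stack(zcols)
    return y, X, Z, np.log(e)


def _softplus(w):
    return np.logaddexp(0.0, w)


def _nll_grad(spec: ModelSpec, psi: np.ndarray, y, X, Z, log_e, theta_log=True):
    """Negative log-likelihood and gradient.

    ``psi`` packs [count coefs, log(theta) if NB family, gamma if ZI];
    with ``theta_log=False`` the dispersion slot holds theta itself (used
    for the observed-information Hessian on the natural scale).
    """
    p = X.shape[1]
    b = psi[:p]
    i = p
    theta = None
    if spec.has_theta:
        theta = np.exp(psi[i]) if theta_log else psi[i]
        i += 1
    gam = psi[i:] if spec.zero_inflated else None

    eta = np.clip(X @ b + log_e, -500.0, 30.0)
    mu = np.exp(eta)
    pos = y > 0

    if spec.family in ("poisson", "zip"):
        base_ll = y * eta - mu - gammaln(y + 1.0)
        dbase_deta = y - mu
        log_f0 = -mu
        dlogf0_deta = -mu
        dbase_dth = None
        dlogf0_dth = None
    else:
        tm = theta + mu
        base_ll = (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
                   + theta * (np.log(theta) - np.log(tm)) + y * (eta - np.log(tm)))
        dbase_deta = (y - mu) * theta / tm
        log_f0 = theta * (np.log(theta) - np.log(tm))
        dlogf0_deta = -theta * mu / tm
        dbase_dth = (digamma(y + theta) - digamma(theta) + np.log(theta / tm)
                     + 1.0 - (y + theta) / tm)
        dlogf0_dth = np.log(theta / tm) + mu / tm

    if not spec.zero_inflated:
        ll = base_ll.sum()
        grad = [X.T @ dbase_deta]
        if spec.has_theta:
            g = dbase_dth.sum()
            grad.append(np.array([g * theta if theta_log else g]))
        return -ll, -np.concatenate(grad)

    w = Z @ gam
    pi = expit(w)
    # y = 0: log(pi + (1-pi) f0);  y > 0: log(1-pi) + log f(y)
    ll0 = np.logaddexp(w, log_f0) - _softplus(w)
    ll = np.where(pos, base_ll - _softplus(w), ll0).sum()

    q = expit(w - log_f0)  # e^w / (e^w + f0), share of the zero mass that is structural
    r = 1.0 - q
    deta = np.where(pos, dbase_deta, r * dlogf0_deta)
    grad = [X.T @ deta]
    if spec.has_theta:
        g = np.where(pos, dbase_dth, r * dlogf0_dth).sum()
        grad.append(np.array([g * theta if theta_log else g]))
    dw = np.where(pos, -pi, q - pi)
    grad.append(Z.T @ dw)
    return -ll, -np.concatenate(grad)


def log_likelihood(spec: ModelSpec, params, table: pd.DataFrame) -> float:
    """Log-likelihood of a parameter set on a unit table.

    ``params`` is a mapping with keys ``alpha``, ``beta`` (dict by
    covariate), ``theta`` (NB families) and ``gamma`` (dict with
    ``'intercept'`` + zi covariates). ``gamma`` entries may be ``-inf``/
    ``+inf`` to evaluate the degenerate no-inflation / all-zero limits;
    all other parameters must be finite.
    """
    y, X, Z, log_e = _design(spec, table)
    b = [float(params["alpha"])] + [float(params["beta"][c])
                                    for c in spec.count_covariates]
    psi = list(b)
    if spec.has_theta:
        theta = float(params["theta"])
        if not (np.isfinite(theta) and theta > 0):
            raise ValueError("theta must be finite and positive")
        psi.append(np.log(theta))
    if not np.all(np.isfinite(b)):
        raise ValueError("count-component parameters must be finite")
    if spec.zero_inflated:
        gam = [float(params["gamma"]["intercept"])] + [
            float(params["gamma"][c]) for c in spec.zi_covariates]
        if np.any(np.isnan(gam)):
            raise ValueError("gamma parameters must not be NaN")
        psi.extend(gam)
    with np.errstate(invalid="ignore"):
        nll, _ = _nll_grad(spec, np.asarray(psi, float), y, X, Z, log_e)
    return -float(nll)


def _saturated_loglik(family: str, y: np.ndarray, theta: float | None) -> float:
    """Log-likelihood of the saturated model (one mean per observation).

    For zero-inflated families a zero observation attains probability one
    (pi -> 1) and a positive observation is best served by pi = 0 and
    mu = y, so only positive counts contribute; theta is held at the
    fitted value. This fixes the deviance convention used throughout.
    """
    yp = y[y > 0]
    if family in ("poisson", "zip"):
        return float((yp * np.log(yp) - yp - gammaln(yp + 1.0)).sum())
    t = theta
    return float((gammaln(yp + t) - gammaln(t) - gammaln(yp + 1.0)
                  + t * np.log(t / (t + yp)) + yp * np.log(yp / (t + yp))).sum())


def _standardize(M: np.ndarray):
    """Center/scale non-intercept columns; returns (scaled, means, sds).

    An exact affine reparameterization used only inside the optimizer for
    conditioning; fitted coefficients are transformed back to the
    original (uncentered) covariate scale afterwards.
    """
    Ms = M.copy()
    m = np.zeros(M.shape[1])
    s = np.ones(M.shape[1])
    for j in range(1, M.shape[1]):
        m[j] = M[:, j].mean()
        sd = M[:, j].std()
        s[j] = sd if sd > 0 else 1.0
        Ms[:, j] = (M[:, j] - m[j]) / s[j]
    return Ms, m, s


def _start_values(spec: ModelSpec, y, X, Z, log_e) -> np.ndarray:
    """Fixed initialization: Poisson solution -> MoM theta -> gamma = 0."""
    p = X.shape[1]
    base = ModelSpec("poisson", spec.count_covariates, (), spec.offset_name)
    b0 = np.zeros(p)
    b0[0] = np.log(max(y.sum(), 0.5) / np.exp(log_e).sum())
    res = optimize.minimize(
        lambda v: _nll_grad(base, v, y, X, None, log_e), b0, jac=True,
        method="L-BFGS-B", bounds=[(-_COEF_BOUND, _COEF_BOUND)] * p,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-08},
    )
    start = [res.x]
    if spec.has_theta:
        mu = np.exp(np.clip(X @ res.x + log_e, -500, 30))
        denom = max(((y - mu) ** 2 - mu).sum(), 1e-8)
        theta0 = float(np.clip((mu ** 2).sum() / denom, 0.05, 50.0))
        start.append(np.array([np.log(theta0)]))
    if spec.zero_inflated:
        start.append(np.zeros(Z.shape[1]))
    return np.concatenate(start)


def _hessian(fun_grad, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Observed information by central differences of the analytic gradient."""
    k = len(x)
    H = np.empty((k, k))
    for j in range(k):
        h = step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        _, gp = fun_grad(xp)
        _, gm = fun_grad(xm)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit(spec: ModelSpec, table: pd.DataFrame) -> CountModelFit:
    """Maximum-likelihood fit of a count model on a unit table.

    Deterministic given the data: fixed initialization (see
    ``_start_values``), L-BFGS-B with gradient tolerance 1e-8 and a fixed
    iteration cap. Raises ``FitError`` with optimizer diagnostics on
    non-convergence or a degenerate design (constant covariate columns,
    fewer rows than parameters).
    """
    for c in spec.count_covariates + spec.zi_covariates:
        col = table[c].to_numpy(float)
        if np.ptp(col) == 0.0:
            raise FitError(f"covariate {c!r} is constant; degenerate design")
    if len(table) <= spec.n_params:
        raise FitError(f"{len(table)} rows cannot identify {spec.n_params} parameters")

    y, X, Z, log_e = _design(spec, table)
    # optimize in a centered/scaled parameterization for conditioning; the
    # reported coefficients are transformed back to the original scale
    Xs, xm, xs = _standardize(X)
    if Z is not None:
        Zs, zm, zs = _standardize(Z)
    else:
        Zs = None
    psi0 = _start_values(spec, y, Xs, Zs, log_e)

    p = X.shape[1]
    bounds = [(-_COEF_BOUND, _COEF_BOUND)] * p
    if spec.has_theta:
        bounds.append(_LOG_THETA_BOUNDS)
    if spec.zero_inflated:
        bounds += [(-_GAMMA_BOUND, _GAMMA_BOUND)] * Z.shape[1]

    obj = lambda v: _nll_grad(spec, v, y, Xs, Zs, log_e)  # noqa: E731
    opts = {"maxiter": 2000, "maxfun": 20000, "ftol": 1e-14, "gtol": 1e-08}
    res = optimize.minimize(obj, psi0, jac=True, method="L-BFGS-B",
                            bounds=bounds, options=opts)
    if spec.zero_inflated:
        # second deterministic start near the no-inflation boundary, so the
        # ZI optimum can never fall below its base family's optimum
        alt = psi0.copy()
        alt[-Z.shape[1]:] = 0.0
        alt[-Z.shape[1]] = -5.0
        res_alt = optimize.minimize(obj, alt, jac=True, method="L-BFGS-B",
                                    bounds=bounds, options=opts)
        if res_alt.fun < res.fun:
            res = res_alt
    nll, grad = obj(res.x)
    grad_ok = np.max(np.abs(grad)) < 1e-4 * max(1.0, abs(nll))
    at_bound = any(
        np.isclose(x, lo) or np.isclose(x, hi) for x, (lo, hi) in zip(res.x, bounds))
    if not (res.success or grad_ok or at_bound):
        raise FitError(
            f"{spec.family} fit did not converge: {res.message}",
            diagnostics={"status": res.status, "nit": res.nit,
                         "grad_inf_norm": float(np.max(np.abs(grad)))},
        )

    # back-transform to the original covariate scale
    psi_s = res.x
    k = spec.n_params
    i = p
    theta = float(np.exp(psi_s[i])) if spec.has_theta else None
    if spec.has_theta:
        i += 1
    bs = psi_s[:p]
    b = bs / xs
    b[0] = bs[0] - np.sum(bs[1:] * xm[1:] / xs[1:])
    if spec.zero_inflated:
        gs = psi_s[i:]
        gam = gs / zs
        gam[0] = gs[0] - np.sum(gs[1:] * zm[1:] / zs[1:])
    else:
        gam = np.array([])
    psi = np.concatenate([b, [np.log(theta)] if spec.has_theta else [], gam])

    # observed information in the scaled space (well conditioned), then an
    # exact Jacobian transform to the natural parameters (theta, not log theta)
    H = _hessian(obj, psi_s)
    T = np.zeros((k, k))
    T[0, 0] = 1.0
    T[0, 1:p] = -xm[1:] / xs[1:]
    for j in range(1, p):
        T[j, j] = 1.0 / xs[j]
    off = p
    if spec.has_theta:
        T[off, off] = theta  # d theta / d log theta
        off += 1
    if spec.zero_inflated:
        q = Z.shape[1]
        T[off, off] = 1.0
        T[off, off + 1:off + q] = -zm[1:] / zs[1:]
        for j in range(1, q):
            T[off + j, off + j] = 1.0 / zs[j]
    try:
        cov_s = np.linalg.inv(H)
        cov = T @ cov_s @ T.T
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
    except np.linalg.LinAlgError:
        warnings.warn("observed information singular; using pseudo-inverse SEs",
                      stacklevel=2)
        cov = T @ np.linalg.pinv(H) @ T.T
    se_vec = np.sqrt(np.abs(np.diag(cov)))

    names = ["alpha", *spec.count_covariates]
    if spec.has_theta:
        names.append("theta")
    if spec.zero_inflated:
        names += ["zi_intercept"] + [f"zi_{c}" for c in spec.zi_covariates]
    se = dict(zip(names, se_vec))
    phi = np.concatenate([b, [theta] if spec.has_theta else [], gam])
    est_nat = dict(zip(names, phi))
    pvals = {
        n: float(2.0 * norm.sf(abs(est_nat[n] / se[n]))) if se[n] > 0 else np.nan
        for n in names if n != "theta"
    }

    ll = -float(nll)
    dev = 2.0 * (_saturated_loglik(spec.family, y, theta) - ll)
    return CountModelFit(
        spec=spec,
        alpha=float(psi[0]),
        beta={c: float(psi[1 + j]) for j, c in enumerate(spec.count_covariates)},
        theta=theta,
        gamma=({"intercept": float(gam[0]),
                **{c: float(gam[1 + j]) for j, c in enumerate(spec.zi_covariates)}}
               if spec.zero_inflated else {}),
        se=se,
        p=pvals,
        loglik=ll,
        aic=2.0 * k - 2.0 * ll,
        deviance=float(dev),
        n_params=k,
        nobs=len(y),
        converged=True,
        optimizer={"nit": int(res.nit), "message": str(res.message),
                   "grad_inf_norm": float(np.max(np.abs(grad)))},
        data_fingerprint=(len(y), float(y.sum()), float(np.exp(log_e).sum())),
    )


def multiplicative_effect(coefficient: float, decimals: int | None = 1) -> float:
    """Percent change in the rate per unit covariate increase: 100(e^b - 1).

    Negative values are decreases. Applied to a zero-inflation
    coefficient the same formula gives the percent change in the odds of
    a structural zero. Rounded to one decimal by default
    (``decimals=None`` returns the raw value).
    """
    val = 100.0 * np.expm1(coefficient)
    return float(val) if decimals is None else float(np.round(val, decimals))


def sqvif(table: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Square-root variance inflation factors of the covariate set.

    VIF_k = 1 / (1 - R^2_k) from regressing covariate k on the others
    (with intercept). Values of sqrt(VIF) >= 2.0 flag critical
    collinearity. Raises on perfectly collinear or constant columns.
    """
    if len(covariates) < 2:
        raise ValueError("need at least two covariates")
    M = table[list(covariates)].to_numpy(float)
    n = len(M)
    rows = []
    for j, name in enumerate(covariates):
        xj = M[:, j]
        sst = ((xj - xj.mean()) ** 2).sum()
        if sst == 0:
            raise ValueError(f"covariate {name!r} is constant")
        others = np.column_stack([np.ones(n), np.delete(M, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
        ssr = ((xj - others @ coef) ** 2).sum()
        one_minus_r2 = ssr / sst
        if one_minus_r2 < 1e-10:
            raise ValueError(f"covariate {name!r} is perfectly collinear with the others")
        sq = float(np.sqrt(1.0 / one_minus_r2))
        rows.append({"covariate": name, "sqvif": sq, "ok": sq < 2.0})
    return pd.DataFrame(rows).set_index("covariate")


def deviance_reduction(
    spec: ModelSpec, table: pd.DataFrame, full_fit: CountModelFit
) -> pd.DataFrame:
    """Drop-one deviance reduction per covariate, as percent of null deviance.

    For covariate k: DR_k = 100 (dev(model without k) - dev(full)) /
    dev(null), with the null the same family with intercept-only count
    and zero-inflation components. Zero-inflation covariates are dropped
    from the logistic component analogously. Raises naming the covariate
    if a refit fails.
    """
    null_spec = ModelSpec(spec.family, (), (), spec.offset_name)
    dev_null = fit(null_spec, table).deviance
    rows = []
    for c in spec.count_covariates:
        reduced = ModelSpec(
            spec.family,
            tuple(x for x in spec.count_covariates if x != c),
            spec.zi_covariates, spec.offset_name)
        try:
            f = fit(reduced, table)
        except FitError as err:
            raise FitError(f"drop-one refit without {c!r} failed: {err}") from err
        rows.append({"component": "count", "covariate": c,
                     "deviance_reduction_pct":
                         100.0 * (f.deviance - full_fit.deviance) / dev_null})
    for c in spec.zi_covariates:
        reduced = ModelSpec(
            spec.family, spec.count_covariates,
            tuple(x for x in spec.zi_covariates if x != c), spec.offset_name)
        try:
            f = fit(reduced, table)
        except FitError as err:
            raise FitError(f"drop-one refit without zi {c!r} failed: {err}") from err
        rows.append({"component": "zero_inflation", "covariate": c,
                     "deviance_reduction_pct":
                         100.0 * (f.deviance - full_fit.deviance) / dev_null})
    return pd.DataFrame(rows)


def select_zi_covariates(
    table: pd.DataFrame,
    candidates: list[str],
    alpha: float = 0.05,
    family: str = "zinb",
    count_covariates: tuple[str, ...] | None = None,
) -> list[str]:
    """Backward elimination on the zero-inflation component.

    Starts from the full candidate set, repeatedly drops the least
    significant zero-inflation covariate with Wald p >= alpha and refits,
    until every retained candidate is significant (possibly none,
    leaving an intercept-only logistic component). Count-component
    covariates are untouched. Deterministic: ties resolve to the first
    candidate in current order.
    """
    if count_covariates is None:
        count_covariates = tuple(candidates)
    retained = list(candidates)
    while retained:
        f = fit(ModelSpec(family, count_covariates, tuple(retained)), table)
        pvals = {c: f.p[f"zi_{c}"] for c in retained}
        worst = max(retained, key=lambda c: pvals[c])
        if pvals[worst] < alpha:
            break
        retained.remove(worst)
    return retained
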
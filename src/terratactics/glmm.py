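"""Binomial-logit mixed models with random intercepts.

Maximum-likelihood fitting via the Laplace approximation, in the style of
``lme4::glmer``:

* random effects are reparametrized spherically, ``u_f = sigma_f * b_f``
  with ``b_f ~ N(0, I)``, so variance parameters live on ``sigma_f >= 0``
  and the boundary ``sigma_f = 0`` is an ordinary point of the objective;
* for given ``(beta, sigma)`` the mode ``b_hat`` is found by penalized
  IRLS (Newton) and the Laplace log-likelihood is
  ``loglik(eta_hat) - |b_hat|^2 / 2 - log det(Zt W Z + I) / 2``;
* a fast first stage folds ``beta`` into the inner Newton step and
  optimizes ``sigma`` alone (the nAGQ=0 shortcut); a second stage refines
  ``(beta, sigma)`` against the true Laplace objective.

Inference follows the likelihood-ratio convention: the full-null comparison
and per-term p-values come from refitting nested models (``drop1``), not
from Wald statistics, though Wald z and normal CIs are reported for table
parity.  Effect sizes use the Nakagawa variance decomposition with the
logit-link distribution-specific variance pi^2 / 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

LOGIT_RESID_VAR = np.pi ** 2 / 3


class SeparationError(RuntimeError):
    """Raised when the likelihood diverges (complete or quasi-separation)."""


class NotConvergedError(RuntimeError):
    pass


def _as_term(t):
    return (t,) if isinstance(t, str) else tuple(t)


@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random structure plus the transform plan.

    ``terms`` are tuples of column names; a singleton is a main effect, a
    longer tuple an interaction (the elementwise product of its transformed
    components).  Every interaction's main effects must be present.
    ``controls`` are terms exempt from model reduction.  ``z_cols`` are
    z-scored (after ``ln_cols`` are log-transformed) using the modeling
    table's own mean/SD.
    """

    response: str
    terms: tuple
    random: tuple
    z_cols: tuple = ()
    ln_cols: tuple = ()
    controls: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(_as_term(t) for t in self.terms))
        object.__setattr__(self, "controls", tuple(_as_term(t) for t in self.controls))
        object.__setattr__(self, "random", tuple(self.random))
        object.__setattr__(self, "z_cols", tuple(self.z_cols))
        object.__setattr__(self, "ln_cols", tuple(self.ln_cols))
        have = set(self.terms)
        for t in self.terms:
            if len(t) > 1:
                for c in t:
                    if (c,) not in have:
                        raise ValueError(
                            f"interaction {t} lacks main effect for {c!r}")

    def term_names(self):
        return ["(Intercept)"] + [":".join(t) for t in self.terms]

    def droppable(self):
        """Terms eligible for drop1: not controls, not marginal to a
        retained higher-order interaction."""
        out = []
        for t in self.terms:
            if t in self.controls:
                continue
            if any(set(t) < set(o) for o in self.terms if o != t):
                continue
            out.append(t)
        return out

    def without(self, term):
        term = _as_term(term)
        if term not in self.terms:
            raise ValueError(f"term {term} not in spec")
        return replace(self, terms=tuple(t for t in self.terms if t != term))


def transform_data(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Apply the ln-then-z transform plan using the table's own moments."""
    df = data.copy()
    for c in spec.ln_cols:
        v = df[c].astype(float)
        if (v <= 0).any():
            raise ValueError(f"ln-transform of non-positive values in {c!r}")
        df[c] = np.log(v)
    for c in spec.z_cols:
        v = df[c].astype(float)
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"cannot z-transform constant column {c!r}")
        df[c] = (v - v.mean()) / sd
    return df


def build_design(spec: ModelSpec, data: pd.DataFrame, transformed: bool = False):
    """(y, X, column names, random-factor codes dict) for a modeling table."""
    df = data if transformed else transform_data(spec, data)
    y = df[spec.response].to_numpy(float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("response must be binary 0/1")
    n = len(df)
    cols = [np.ones(n)]
    for t in spec.terms:
        v = np.ones(n)
        for c in t:
            v = v * df[c].to_numpy(float)
        cols.append(v)
    X = np.column_stack(cols)
    codes = {}
    for f in spec.random:
        cat = pd.Categorical(df[f])
        codes[f] = (np.asarray(cat.codes), len(cat.categories),
                    list(cat.categories))
    return y, X, spec.term_names(), codes


@dataclass
class ModelResult:
    spec: ModelSpec
    params: pd.DataFrame          # estimate, se, z, p_wald, ci_lo, ci_hi per term
    re_sd: dict                   # factor -> sigma_hat
    llf: float
    n: int
    converged: bool
    fitted: np.ndarray            # conditional probabilities
    fitted_marginal: np.ndarray   # probabilities at b = 0
    beta: np.ndarray
    vcov_beta: np.ndarray
    b_modes: dict                 # factor -> (levels, u_hat on natural scale)
    n_fixed: int

    @property
    def estimates(self) -> pd.Series:
        return self.params["estimate"]


class _LaplaceFitter:
    """One modeling table; evaluates the Laplace objective and its pieces."""

    def __init__(self, y, X, codes, max_sigma=15.0):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.factors = list(codes)
        self.codes = [codes[f][0] for f in self.factors]
        self.sizes = [codes[f][1] for f in self.factors]
        self.levels = {f: codes[f][2] for f in self.factors}
        self.q = int(sum(self.sizes))
        self.offsets = np.cumsum([0] + self.sizes[:-1])
        self.max_sigma = max_sigma
        self._b = np.zeros(self.q)

    # -- linear algebra helpers -------------------------------------------

    def _zb(self, sigma, b):
        out = np.zeros(self.n)
        for s, c, off, sz in zip(sigma, self.codes, self.offsets, self.sizes):
            out += s * b[off:off + sz][c]
        return out

    def _zt(self, sigma, v):
        """Z~' v for the scaled RE design."""
        out = np.empty(self.q)
        for s, c, off, sz in zip(sigma, self.codes, self.offsets, self.sizes):
            out[off:off + sz] = s * np.bincount(c, weights=v, minlength=sz)
        return out

    def _ztwz(self, sigma, w):
        """Dense Z~' W Z~ (q x q)."""
        H = np.zeros((self.q, self.q))
        k = len(self.factors)
        for a in range(k):
            ca, oa, sa = self.codes[a], self.offsets[a], self.sizes[a]
            diag = np.bincount(ca, weights=w, minlength=sa)
            H[oa:oa + sa, oa:oa + sa] += np.diag(diag * sigma[a] ** 2)
            for bfi in range(a + 1, k):
                cb, ob, sb = self.codes[bfi], self.offsets[bfi], self.sizes[bfi]
                M = np.zeros((sa, sb))
                np.add.at(M, (ca, cb), w)
                M *= sigma[a] * sigma[bfi]
                H[oa:oa + sa, ob:ob + sb] += M
                H[ob:ob + sb, oa:oa + sa] += M.T
        return H

    def _ztwx(self, sigma, w):
        M = np.empty((self.q, self.p))
        for s, c, off, sz in zip(sigma, self.codes, self.offsets, self.sizes):
            for j in range(self.p):
                M[off:off + sz, j] = s * np.bincount(
                    c, weights=w * self.X[:, j], minlength=sz)
        return M

    @staticmethod
    def _loglik(y, eta):
        # Bernoulli log-likelihood, stable for large |eta|
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    # -- inner solves ------------------------------------------------------

    def pirls_u(self, sigma, beta, tol=1e-10, max_iter=60):
        """Mode of b given (sigma, beta); returns (b, eta, chol(H_bb))."""
        xb = self.X @ beta
        b = self._b.copy()
        if not np.all(np.isfinite(b)):
            b = np.zeros(self.q)
        pen_old = -np.inf
        for _ in range(max_iter):
            eta = xb + self._zb(sigma, b)
            mu = special.expit(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            g = self._zt(sigma, self.y - mu) - b
            H = self._ztwz(sigma, w)
            H[np.diag_indices_from(H)] += 1.0
            cf = linalg.cho_factor(H, lower=True)
            step = linalg.cho_solve(cf, g)
            # step-halving on the penalized objective
            pen0 = self._loglik(self.y, eta) - 0.5 * b @ b
            t = 1.0
            for _ in range(30):
                b_new = b + t * step
                eta_n = xb + self._zb(sigma, b_new)
                pen = self._loglik(self.y, eta_n) - 0.5 * b_new @ b_new
                if pen >= pen0 - 1e-12:
                    break
                t *= 0.5
            b = b_new
            if abs(pen - pen_old) < tol * (1 + abs(pen)):
                pen_old = pen
                break
            pen_old = pen
        self._b = b
        eta = xb + self._zb(sigma, b)
        mu = special.expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = self._ztwz(sigma, w)
        H[np.diag_indices_from(H)] += 1.0
        cf = linalg.cho_factor(H, lower=True)
        return b, eta, cf

    def laplace_ll(self, sigma, beta):
        if self.q == 0:
            eta = self.X @ beta
            return self._loglik(self.y, eta)
        b, eta, cf = self.pirls_u(sigma, beta)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return self._loglik(self.y, eta) - 0.5 * b @ b - 0.5 * logdet

    def pirls_joint(self, sigma, beta0, tol=1e-10, max_iter=80):
        """Joint penalized mode over (beta, b) for fixed sigma (nAGQ0)."""
        beta = beta0.copy()
        b = self._b.copy()
        if not np.all(np.isfinite(b)):
            b = np.zeros(self.q)
        pen_old = -np.inf
        for _ in range(max_iter):
            eta = self.X @ beta + self._zb(sigma, b)
            mu = special.expit(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            r = self.y - mu
            gb = self.X.T @ r
            gu = self._zt(sigma, r) - b
            Hxx = (self.X * w[:, None]).T @ self.X
            Hxu = self._ztwx(sigma, w).T
            Huu = self._ztwz(sigma, w)
            Huu[np.diag_indices_from(Huu)] += 1.0
            H = np.block([[Hxx, Hxu], [Hxu.T, Huu]])
            g = np.concatenate([gb, gu])
            try:
                step = linalg.cho_factor(H + 1e-10 * np.eye(len(H)))
                d = linalg.cho_solve(step, g)
            except linalg.LinAlgError:
                d = linalg.lstsq(H, g)[0]
            pen0 = self._loglik(self.y, eta) - 0.5 * b @ b
            t = 1.0
            for _ in range(30):
                beta_n = beta + t * d[:self.p]
                b_n = b + t * d[self.p:]
                eta_n = self.X @ beta_n + self._zb(sigma, b_n)
                pen = self._loglik(self.y, eta_n) - 0.5 * b_n @ b_n
                if pen >= pen0 - 1e-12:
                    break
                t *= 0.5
            beta, b = beta_n, b_n
            if np.abs(eta_n).max() > 30.0 and np.abs(beta).max() > 100.0:
                raise SeparationError(
                    "likelihood diverges: complete or quasi-complete separation")
            if abs(pen - pen_old) < tol * (1 + abs(pen)):
                break
            pen_old = pen
        self._b = b
        return beta, b


def _wald_table(names, beta, vcov):
    se = np.sqrt(np.diag(vcov))
    z = np.where(se > 0, beta / se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "estimate": beta, "se": se, "z": z, "p_wald": p,
        "ci_lo": beta - 1.96 * se, "ci_hi": beta + 1.96 * se,
    }, index=names)


def fit(spec: ModelSpec, data: pd.DataFrame, transformed: bool = False,
        refine: bool = True) -> ModelResult:
    """Fit a binomial-logit random-intercept model by ML (Laplace).

    Two stages: a fast profile over the variance parameters with fixed
    effects folded into the inner Newton step, then (``refine=True``) a
    joint refinement of ``(beta, sigma)`` against the Laplace objective.
    Deterministic given the data (fixed starting point: beta from an
    unpenalized logistic fit approximation, random effects at zero).
    """
    if len(data) == 0:
        raise ValueError("empty modeling table")
    y, X, names, codes = build_design(spec, data, transformed=transformed)
    if y.min() == y.max():
        raise SeparationError(f"response {spec.response!r} is constant")
    # drop random factors with a single level (nothing to estimate)
    codes = {f: v for f, v in codes.items() if v[1] > 1}
    fitter = _LaplaceFitter(y, X, codes)
    k = len(fitter.factors)
    p = fitter.p

    # stage A: sigma-profile with joint inner Newton
    beta0 = np.zeros(p)
    beta0[0] = special.logit(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    beta_hold = [beta0]

    def nagq0_obj(sig):
        sig = np.abs(sig)
        beta_hold[0], _ = fitter.pirls_joint(sig, beta_hold[0])
        return -fitter.laplace_ll(sig, beta_hold[0])

    if k:
        res0 = optimize.minimize(nagq0_obj, x0=np.full(k, 0.5),
                                 method="Powell",
                                 bounds=[(0.0, fitter.max_sigma)] * k,
                                 options={"xtol": 1e-3, "ftol": 1e-7})
        sigma = np.abs(res0.x)
        beta = beta_hold[0]
        conv = bool(res0.success)
    else:
        beta, _ = fitter.pirls_joint(np.zeros(0), beta0)
        sigma = np.zeros(0)
        conv = True

    if refine and k:
        def lap_obj(par):
            bb, ss = par[:p], np.abs(par[p:])
            return -fitter.laplace_ll(ss, bb)

        res1 = optimize.minimize(
            lap_obj, x0=np.concatenate([beta, sigma]), method="L-BFGS-B",
            bounds=[(None, None)] * p + [(0.0, fitter.max_sigma)] * k,
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-7})
        if np.isfinite(res1.fun) and res1.fun <= -fitter.laplace_ll(sigma, beta) + 1e-9:
            beta, sigma = res1.x[:p], np.abs(res1.x[p:])
            conv = conv or bool(res1.success)
    eta_chk = X @ beta
    if np.abs(eta_chk).max() > 30.0 and np.abs(beta).max() > 100.0:
        j = int(np.argmax(np.abs(beta)))
        raise SeparationError(
            f"separation suspected: estimate for {names[j]!r} diverges")

    llf = fitter.laplace_ll(sigma, beta)
    # conditional covariance of beta (RE-profiled observed information)
    b, eta, cf = (fitter.pirls_u(sigma, beta) if k
                  else (np.zeros(0), X @ beta, None))
    mu = special.expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    Hxx = (X * w[:, None]).T @ X
    if k:
        Hxu = fitter._ztwx(sigma, w).T
        Hxx = Hxx - Hxu @ linalg.cho_solve(cf, Hxu.T)
    vcov = np.linalg.pinv(Hxx)

    re_sd = {f: float(s) for f, s in zip(fitter.factors, sigma)}
    b_modes = {}
    for f, s, off, sz in zip(fitter.factors, sigma, fitter.offsets, fitter.sizes):
        b_modes[f] = (fitter.levels[f], s * b[off:off + sz])
    return ModelResult(
        spec=spec, params=_wald_table(names, beta, vcov), re_sd=re_sd,
        llf=float(llf), n=fitter.n, converged=conv, fitted=mu,
        fitted_marginal=special.expit(X @ beta), beta=beta, vcov_beta=vcov,
        b_modes=b_modes, n_fixed=p,
    )


# ---------------------------------------------------------------------------
# inference


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float


def lrt(full: ModelResult, null: ModelResult) -> LRTResult:
    """Likelihood-ratio test of two nested fits."""
    if set(null.spec.terms) - set(full.spec.terms):
        raise ValueError("null model terms are not nested in the full model")
    if tuple(null.spec.random) != tuple(full.spec.random):
        raise ValueError("nested models must share the random structure")
    df = full.n_fixed - null.n_fixed
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    p = stats.chi2.sf(chi2, df) if df > 0 else float("nan")
    return LRTResult(chi2=float(chi2), df=int(df), p=float(p))


lrt_full_null = lrt


def null_spec(spec: ModelSpec) -> ModelSpec:
    """Control-only counterpart of a spec (same randoms and transforms)."""
    return replace(spec, terms=spec.controls, controls=spec.controls)


def drop1(spec: ModelSpec, data: pd.DataFrame,
          fitted: ModelResult | None = None) -> pd.DataFrame:
    """Per-term LRT p-values by single-term deletion, respecting marginality."""
    df_t = transform_data(spec, data)
    if fitted is None:
        fitted = fit(spec, df_t, transformed=True)
    rows = []
    for t in spec.droppable():
        red = fit(spec.without(t), df_t, transformed=True)
        r = lrt(fitted, red)
        rows.append({"term": ":".join(t), "chi2": r.chi2, "df": r.df, "p": r.p})
    return pd.DataFrame(rows).set_index("term")


def reduce(spec: ModelSpec, data: pd.DataFrame, alpha: float = 0.05):
    """Iteratively remove nonsignificant interactions, highest order first.

    Main effects and controls are never removed.  Returns
    ``(reduced_spec, fitted ModelResult)``.
    """
    cur = spec
    fitted = None
    while True:
        df_t = transform_data(cur, data)
        fitted = fit(cur, df_t, transformed=True)
        cand = [t for t in cur.droppable() if len(t) > 1]
        if not cand:
            break
        tab = drop1(cur, data, fitted=fitted)
        cand_p = [(tab.loc[":".join(t), "p"], len(t), t) for t in cand]
        nonsig = [c for c in cand_p if c[0] >= alpha]
        if not nonsig:
            break
        nonsig.sort(key=lambda c: (-c[1], -c[0]))
        cur = cur.without(nonsig[0][2])
    return cur, fitted


def r2(result: ModelResult) -> tuple:
    """Nakagawa marginal and conditional R^2 for the binomial-logit model."""
    # variance on the link scale explained by the fixed effects
    eta_fix = special.logit(np.clip(result.fitted_marginal, 1e-12, 1 - 1e-12))
    var_f = float(np.var(eta_fix))
    var_r = float(sum(s ** 2 for s in result.re_sd.values()))
    denom = var_f + var_r + LOGIT_RESID_VAR
    return var_f / denom, (var_f + var_r) / denom


def vif(spec: ModelSpec, data: pd.DataFrame) -> pd.Series:
    """Variance inflation factors from the main-effects-only linear design."""
    df_t = transform_data(spec, data)
    mains = [t for t in spec.terms if len(t) == 1]
    M = np.column_stack([df_t[t[0]].to_numpy(float) for t in mains])
    names = [t[0] for t in mains]
    out = {}
    ones = np.ones((len(M), 1))
    for j in range(M.shape[1]):
        yj = M[:, j]
        Xj = np.hstack([ones, np.delete(M, j, axis=1)])
        betaj, _, _, _ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ betaj
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[names[j]] = float("nan")
        elif ss_res / ss_tot < 1e-12:
            out[names[j]] = float("inf")
        else:
            out[names[j]] = 1.0 / (ss_res / ss_tot)
    return pd.Series(out, name="vif")


def simulate_response(result: ModelResult, data: pd.DataFrame,
                      rng: np.random.Generator,
                      transformed: bool = False) -> np.ndarray:
    """Parametric simulation: new random intercepts + Bernoulli response."""
    _, X, _, codes = build_design(result.spec, data, transformed=transformed)
    eta = X @ result.beta
    for f, (c, sz, _levels) in codes.items():
        s = result.re_sd.get(f, 0.0)
        u = rng.normal(0.0, s, size=sz)
        eta = eta + u[c]
    return (rng.random(len(eta)) < special.expit(eta)).astype(float)


def bootstrap_ci(spec: ModelSpec, data: pd.DataFrame, n: int = 1000,
                 seed: int = 0, fitted: ModelResult | None = None,
                 level: float = 0.95) -> pd.DataFrame:
    """Parametric-bootstrap percentile CIs for the fixed effects."""
    if n <= 0:
        raise ValueError("bootstrap replicate count must be positive")
    df_t = transform_data(spec, data)
    if fitted is None:
        fitted = fit(spec, df_t, transformed=True)
    rng = np.random.default_rng(seed)
    draws = []
    failures = 0
    sim_df = df_t.copy()
    for _ in range(n):
        sim_df[spec.response] = simulate_response(fitted, df_t, rng,
                                                  transformed=True)
        try:
            res = fit(spec, sim_df, transformed=True, refine=False)
            draws.append(res.beta)
        except (SeparationError, linalg.LinAlgError):
            failures += 1
    if failures > 0.1 * n:
        warnings.warn(f"bootstrap: only {n - failures}/{n} replicates converged")
    D = np.array(draws)
    a = (1 - level) / 2
    lo = np.percentile(D, 100 * a, axis=0)
    hi = np.percentile(D, 100 * (1 - a), axis=0)
    return pd.DataFrame({"ci_lo": lo, "ci_hi": hi},
                        index=fitted.params.index)


def stability(spec: ModelSpec, data: pd.DataFrame,
              fitted: ModelResult | None = None) -> pd.DataFrame:
    """Leave-one-level-out ranges of the fixed estimates.

    Refits the model once per level of each random factor, excluding that
    level's rows; reports the min/max of every fixed-effect estimate.
    """
    df_t = transform_data(spec, data)
    if fitted is None:
        fitted = fit(spec, df_t, transformed=True)
    ests = []
    for f in spec.random:
        levels = pd.unique(df_t[f])
        if len(levels) < 2:
            raise ValueError(f"random factor {f!r} has a single level")
        for lev in levels:
            sub = df_t[df_t[f] != lev]
            try:
                res = fit(spec, sub, transformed=True, refine=False)
                ests.append(res.beta)
            except SeparationError:
                continue
    E = np.array(ests)
    return pd.DataFrame({
        "estimate": fitted.beta, "min": E.min(axis=0), "max": E.max(axis=0),
    }, index=fitted.params.index)


def overdispersion(result: ModelResult, data: pd.DataFrame | None = None) -> float:
    """Pearson dispersion: sum of squared Pearson residuals over residual df."""
    if result.n == 0:
        raise ValueError("empty fit")
    if data is not None and len(data) == 0:
        raise ValueError("empty data")
    y = None
    if data is not None:
        y = data[result.spec.response].to_numpy(float)
    if y is None or len(y) != result.n:
        raise ValueError("overdispersion needs the modeling table the fit used")
    mu = result.fitted
    pear = (y - mu) / np.sqrt(np.clip(mu * (1 - mu), 1e-12, None))
    dof = result.n - result.n_fixed - len(result.re_sd)
    return float((pear ** 2).sum() / dof)
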
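"""Residual autocorrelation diagnostics and the temporal autocorrelation term.

Minute-resolution behavioral data are serially dependent.  Two tools manage
this:

* ``diagnostics`` — the descriptive check: within each pairing unit, the
  Pearson correlation between pairwise absolute residual differences
  |r_i - r_j| and the pairwise time lags (temporal) or metric distances
  (spatial), averaged over units.  Correlated residuals make |Δr| grow
  with lag, so a positive coefficient flags autocorrelation.
* ``ac_term`` / ``fit_sigma`` — the correction: each row receives a
  Gaussian-weighted average of all *other* same-group residuals,
  ``value_i = Σ_j φ(t_i − t_j; σ) r_j / Σ_j φ(...)``, entered (z-scored)
  as an extra fixed effect; the weighting SD σ is chosen by maximizing the
  refit model's likelihood over a log-spaced grid with golden-section
  refinement.

Residuals are response-scale (observed minus conditionally fitted
probability) from the model *without* the term; the scheme is one-shot by
default with an optional single re-iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import glmm


@dataclass
class ACDiagnostics:
    mean_temporal: float
    mean_spatial: float
    per_unit: pd.DataFrame


def _pair_corr(vals: np.ndarray, resid: np.ndarray) -> float:
    """Correlation of |Δresid| with Δvals over all pairs (vals 1-D)."""
    n = len(resid)
    iu = np.triu_indices(n, 1)
    dr = np.abs(resid[:, None] - resid[None, :])[iu]
    dv = np.abs(vals[:, None] - vals[None, :])[iu]
    if dr.std() == 0 or dv.std() == 0:
        return float("nan")
    return float(stats.pearsonr(dv, dr)[0])


def _pair_corr_xy(xy: np.ndarray, resid: np.ndarray) -> float:
    n = len(resid)
    iu = np.triu_indices(n, 1)
    dr = np.abs(resid[:, None] - resid[None, :])[iu]
    dd = np.hypot(xy[:, None, 0] - xy[None, :, 0],
                  xy[:, None, 1] - xy[None, :, 1])[iu]
    if dr.std() == 0 or dd.std() == 0:
        return float("nan")
    return float(stats.pearsonr(dd, dr)[0])


def diagnostics(residuals, times, xys=None, unit_keys=None,
                max_unit_size: int = 2000) -> ACDiagnostics:
    """Per-unit |Δresidual|-vs-lag correlations and their means.

    ``times`` in minutes (any numeric scale), ``xys`` an (n, 2) array of
    projected meters or None to skip the spatial check, ``unit_keys`` the
    pairing unit per row (typically day:group for the diagnostics — all
    pairs across a multi-year study would be quadratic); None pools all
    rows into one unit.
    """
    residuals = np.asarray(residuals, float)
    times = np.asarray(times, float)
    if unit_keys is None:
        unit_keys = np.zeros(len(residuals))
    unit_keys = np.asarray(unit_keys)
    rows = []
    for u in pd.unique(unit_keys):
        m = unit_keys == u
        if m.sum() < 3 or m.sum() > max_unit_size:
            continue
        r_t = _pair_corr(times[m], residuals[m])
        r_s = (_pair_corr_xy(np.asarray(xys)[m], residuals[m])
               if xys is not None else float("nan"))
        rows.append({"unit": u, "n": int(m.sum()), "r_temporal": r_t,
                     "r_spatial": r_s})
    per_unit = pd.DataFrame(rows)
    if len(per_unit) == 0:
        raise ValueError("no unit with >= 3 rows")
    return ACDiagnostics(
        mean_temporal=float(per_unit["r_temporal"].mean(skipna=True)),
        mean_spatial=float(per_unit["r_spatial"].mean(skipna=True)),
        per_unit=per_unit,
    )


def ac_term(residuals, times, group_keys, sigma: float) -> np.ndarray:
    """Gaussian-weighted average of other same-group residuals per row.

    Weight of row j on row i is exp(-(t_i - t_j)^2 / (2 sigma^2)); weights
    renormalize within the group excluding i itself.  Rows whose group has
    no partner get NaN.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    residuals = np.asarray(residuals, float)
    times = np.asarray(times, float)
    group_keys = np.asarray(group_keys)
    out = np.full(len(residuals), np.nan)
    for g in pd.unique(group_keys):
        m = np.flatnonzero(group_keys == g)
        if len(m) < 2:
            continue
        t = times[m]
        r = residuals[m]
        # log-space weights avoid underflow at small sigma / long lags
        logw = -0.5 * ((t[:, None] - t[None, :]) / sigma) ** 2
        np.fill_diagonal(logw, -np.inf)
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        out[m] = (w @ r) / w.sum(axis=1)
    return out


def _with_ac(spec: glmm.ModelSpec) -> glmm.ModelSpec:
    return replace(spec, terms=spec.terms + (("ac_term",),),
                   controls=spec.controls + (("ac_term",),),
                   z_cols=tuple(spec.z_cols) + ("ac_term",))


@dataclass
class SigmaFit:
    sigma: float
    result: "glmm.ModelResult"
    profile: pd.DataFrame   # sigma, llf over the evaluated candidates
    spec: glmm.ModelSpec
    data: pd.DataFrame
    base_spec: glmm.ModelSpec | None = None
    data_ac: pd.DataFrame | None = None     # transformed table incl. ac_term
    times: np.ndarray | None = None
    group_keys: np.ndarray | None = None


def fit_sigma(spec: glmm.ModelSpec, data: pd.DataFrame, times, group_keys,
              sigma_grid=None, base: "glmm.ModelResult | None" = None,
              refine: bool = True, iterate: int = 0) -> SigmaFit:
    """Choose the AC-term weighting SD by maximizing the refit likelihood.

    The base model (without the term) supplies response-scale residuals;
    for each candidate sigma the weighted-residual term is computed,
    z-scored, added as a fixed effect (kept as a control), and the model is
    refit; the sigma with the highest Laplace log-likelihood wins and a
    golden-section pass refines it between its grid neighbours.
    ``iterate=1`` recomputes residuals from the winning fit once and
    repeats the search.
    """
    if sigma_grid is None:
        sigma_grid = np.geomspace(5.0, 24 * 60.0, 25)
    sigma_grid = np.asarray(sigma_grid, float)
    times = np.asarray(times, float)
    group_keys = np.asarray(group_keys)
    df_t = glmm.transform_data(spec, data)
    if base is None:
        base = glmm.fit(spec, df_t, transformed=True)
    resid = df_t[spec.response].to_numpy(float) - base.fitted
    spec_ac = _with_ac(spec)

    def eval_sigma(s, return_table=False):
        term = ac_term(resid, times, group_keys, s)
        if not np.isfinite(term).all():
            keep = np.isfinite(term)
            sub = df_t[keep].copy()
            sub["ac_term"] = term[keep]
        else:
            sub = df_t.copy()
            sub["ac_term"] = term
        sub["ac_term"] = ((sub["ac_term"] - sub["ac_term"].mean())
                          / sub["ac_term"].std(ddof=1))
        res = glmm.fit(replace(spec_ac, z_cols=spec.z_cols), sub,
                       transformed=True, refine=False)
        return (res, sub) if return_table else res

    records = []
    best = (None, -np.inf, None)
    for s in sigma_grid:
        try:
            res = eval_sigma(s)
        except (glmm.SeparationError, np.linalg.LinAlgError):
            continue
        records.append({"sigma": float(s), "llf": res.llf})
        if res.llf > best[1]:
            best = (float(s), res.llf, res)
    if best[0] is None:
        raise RuntimeError("model failed to converge at every candidate sigma")

    if refine and len(sigma_grid) > 2:
        i = int(np.argmin(np.abs(sigma_grid - best[0])))
        lo = sigma_grid[max(i - 1, 0)]
        hi = sigma_grid[min(i + 1, len(sigma_grid) - 1)]
        if hi > lo:
            r = optimize.minimize_scalar(
                lambda s: -eval_sigma(float(s)).llf,
                bounds=(float(lo), float(hi)), method="bounded",
                options={"xatol": 0.02 * best[0]})
            if np.isfinite(r.fun) and -r.fun > best[1]:
                res = eval_sigma(float(r.x))
                records.append({"sigma": float(r.x), "llf": res.llf})
                best = (float(r.x), res.llf, res)

    if iterate > 0:
        resid2 = None
        fitdata = best[2]
        # recompute residuals from the AC-inclusive fit, restricted to rows kept
        term = ac_term(resid, times, group_keys, best[0])
        keep = np.isfinite(term)
        resid2 = df_t[spec.response].to_numpy(float)[keep] - fitdata.fitted
        full = np.full(len(df_t), np.nan)
        full[keep] = resid2
        resid = np.where(np.isfinite(full), full, resid)
        return fit_sigma(spec, data, times, group_keys, sigma_grid=sigma_grid,
                         base=base, refine=refine, iterate=iterate - 1)

    profile = pd.DataFrame(records).sort_values("sigma").reset_index(drop=True)
    _, best_table = eval_sigma(best[0], return_table=True)
    return SigmaFit(sigma=best[0], result=best[2], profile=profile,
                    spec=spec_ac, data=data, base_spec=spec,
                    data_ac=best_table, times=times, group_keys=group_keys)


def bootstrap_ci_ac(sf: SigmaFit, n_boot: int = 200, seed: int = 0,
                    level: float = 0.95) -> tuple:
    """Procedure-level parametric bootstrap CI for the AC-term coefficient.

    The AC covariate is a *generated regressor* (a function of the same
    data's residuals), so the refit model's Wald SE understates the
    procedure's sampling variance and a plain normal CI is anticonservative.
    Each bootstrap replicate therefore re-runs the construction: simulate
    the response from the AC-inclusive fit, refit the base model, rebuild
    the weighted-residual term at the selected sigma, z-score, refit, and
    record the coefficient.  Returns the percentile interval.
    """
    if sf.data_ac is None or sf.base_spec is None:
        raise ValueError("SigmaFit lacks bootstrap context (rerun fit_sigma)")
    rng = np.random.default_rng(seed)
    df = sf.data_ac
    keep = np.ones(len(sf.times), dtype=bool)
    if len(df) != len(sf.times):
        term0 = ac_term(np.zeros(len(sf.times)), sf.times, sf.group_keys,
                        sf.sigma)
        keep = np.isfinite(term0)
    t_k, g_k = sf.times[keep], sf.group_keys[keep]
    base_spec = sf.base_spec
    gammas = []
    for _ in range(n_boot):
        sim = df.copy()
        sim[base_spec.response] = glmm.simulate_response(
            sf.result, df, rng, transformed=True)
        try:
            base_b = glmm.fit(base_spec, sim, transformed=True, refine=False)
        except (glmm.SeparationError, np.linalg.LinAlgError):
            continue
        resid_b = sim[base_spec.response].to_numpy(float) - base_b.fitted
        term = ac_term(resid_b, t_k, g_k, sf.sigma)
        m = np.isfinite(term)
        sim2 = sim[m].copy()
        sim2["ac_term"] = (term[m] - term[m].mean()) / term[m].std(ddof=1)
        try:
            res_b = glmm.fit(sf.result.spec, sim2, transformed=True,
                             refine=False)
        except (glmm.SeparationError, np.linalg.LinAlgError):
            continue
        gammas.append(float(res_b.params.loc["ac_term", "estimate"]))
    a = 100 * (1 - level) / 2
    lo, hi = np.percentile(gammas, [a, 100 - a])
    return float(lo), float(hi)
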
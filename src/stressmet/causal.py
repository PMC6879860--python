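"""Causal effect estimation for continuous regulatory exposures.

Four stages, mirroring the analysis pipeline:

* covariate-balancing weights for a continuous exposure (entropy
  balancing: minimum divergence from uniform weights subject to zero
  weighted association between the exposure, its square, and every
  covariate moment);
* weighted log-log regression average causal effects (elasticities) with
  robust sandwich standard errors;
* a simulated-confounder sensitivity scan yielding the diagonal
  robustness parameters tau1 (estimate crosses zero) and tau2
  (significance lost);
* natural-effects mediation with a joint mediator set: counterfactual
  expansion with inverse conditional-exposure-density weights, an
  outcome-model imputation step, and a weighted natural-effects
  regression whose coefficients are the natural direct (psi_d) and
  indirect (psi_i) effects, with psi_t = psi_d + psi_i by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .stats import CohortTable, adjust_fdr

__all__ = [
    "BalanceError",
    "BalancingWeights",
    "CausalResult",
    "MediationDesign",
    "SensitivityResult",
    "encode_covariates",
    "balancing_weights",
    "average_causal_effect",
    "ace_panel",
    "sensitivity_scan",
    "expand_counterfactuals",
    "natural_effects_fit",
    "joint_mediation",
]


class BalanceError(RuntimeError):
    """Balancing constraints are infeasible or the solver failed."""


@dataclass
class BalancingWeights:
    """Positive per-sample weights summing to n, with a balance audit."""

    weights: np.ndarray
    balance_report: pd.DataFrame
    effective_sample_size: float

    @property
    def n(self) -> int:
        return len(self.weights)


@dataclass
class CausalResult:
    """Point estimate with uncertainty and robustness parameters."""

    effect: float | dict[str, float]
    se: float | dict[str, float]
    ci_95: tuple[float, float] | dict[str, tuple[float, float]]
    p: float | dict[str, float]
    q: float | None = None
    tau1: float | None = None
    tau2: float | None = None


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode non-numeric columns; passthrough numeric ones."""
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).rename(col))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    out = pd.concat(parts, axis=1)
    # drop constant columns (cannot be balanced, carry no information)
    keep = out.std(ddof=0) > 0
    return out.loc[:, keep]


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (a - a.mean()) / sd


def balancing_weights(
    exposure: Sequence[float],
    covariates: pd.DataFrame,
    moments: Sequence[int] = (1, 2),
    tol: float = 1e-8,
    max_iter: int = 500,
) -> BalancingWeights:
    """Entropy-balancing weights for a continuous exposure.

    Finds weights minimizing Kullback-Leibler divergence from uniform
    subject to: weighted means of the standardized exposure and of every
    covariate column equal zero, and weighted cross-moments between the
    exposure (moment 1) and centered squared exposure (moment 2) and
    every covariate equal zero. Solved through the unconstrained convex
    dual (log-sum-exp).
    """
    x = np.asarray(exposure, dtype=float)
    Z = encode_covariates(covariates)
    n, k = len(x), Z.shape[1]
    xs = _standardize(x)
    Zs = np.column_stack([_standardize(Z[c].to_numpy()) for c in Z.columns])

    cols: list[np.ndarray] = [xs]
    names: list[str] = ["exposure"]
    for j, c in enumerate(Z.columns):
        cols.append(Zs[:, j])
        names.append(str(c))
    if 1 in moments:
        for j, c in enumerate(Z.columns):
            cols.append(xs * Zs[:, j])
            names.append(f"exposure*{c}")
    if 2 in moments:
        x2c = xs**2 - (xs**2).mean()
        for j, c in enumerate(Z.columns):
            cols.append(x2c * Zs[:, j])
            names.append(f"exposure^2*{c}")
    # constraint columns with target 0: weighted means of the standardized
    # exposure/covariates vanish and so do the weighted cross moments
    C = np.column_stack(cols)
    m = C.shape[1]
    if n <= m:
        raise BalanceError(
            f"{m} balance constraints for {n} samples; reduce moments"
        )

    def dual_parts(lam: np.ndarray):
        eta = C @ lam
        shift = eta.max()
        w = np.exp(eta - shift)
        s = w.sum()
        f = np.log(s / n) + shift
        p = w / s
        g = p @ C
        return f, g, p

    # damped Newton on the convex log-sum-exp dual
    lam = np.zeros(m)
    f, g, p = dual_parts(lam)
    for _ in range(max_iter):
        if np.abs(g).max() < tol:
            break
        H = (C.T * p) @ C - np.outer(g, g)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(m), -g)
        except np.linalg.LinAlgError:
            step = -g
        t_step = 1.0
        for _ in range(60):
            f_new, g_new, p_new = dual_parts(lam + t_step * step)
            if f_new <= f + 1e-4 * t_step * (g @ step):
                lam = lam + t_step * step
                f, g, p = f_new, g_new, p_new
                break
            t_step /= 2.0
        else:
            break
    eta = C @ lam
    eta -= eta.max()
    w = np.exp(eta)
    w = w / w.sum() * n
    achieved = np.abs(w @ C) / n
    if not np.all(np.isfinite(w)) or achieved.max() > 1e-6:
        raise BalanceError(
            "balancing constraints appear infeasible "
            f"(max residual {achieved.max():.2e}); a covariate may be "
            "collinear with the exposure - try moments=(1,)"
        )
    ess = float(w.sum() ** 2 / (w**2).sum())
    if ess < n / 5:
        warnings.warn(
            f"extreme balancing weights: effective sample size {ess:.1f} < n/5",
            stacklevel=2,
        )
    report = pd.DataFrame({"constraint": names, "weighted_moment": w @ C / n})
    return BalancingWeights(
        weights=w, balance_report=report, effective_sample_size=ess
    )


def _wls_slope_sandwich(
    y: np.ndarray, x: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """Weighted LS slope of y on [1, x] with an HC1-style sandwich se."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    XtW = X.T * w
    bread = np.linalg.inv(XtW @ X)
    beta = bread @ (XtW @ y)
    e = y - X @ beta
    meat = (X.T * (w**2 * e**2)) @ X
    V = bread @ meat @ bread * (n / (n - 2))
    return float(beta[1]), float(np.sqrt(V[1, 1]))


def average_causal_effect(
    outcome: Sequence[float],
    exposure: Sequence[float],
    w: BalancingWeights | np.ndarray,
    alpha: float = 0.05,
) -> CausalResult:
    """Weighted least-squares elasticity of log-outcome on log-exposure.

    Inputs are expected already on the log scale; the slope gamma is the
    percent change in outcome per percent change in exposure.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    ww = w.weights if isinstance(w, BalancingWeights) else np.asarray(w, dtype=float)
    if x.std(ddof=0) == 0:
        raise ValueError("exposure has zero variance")
    gamma, se = _wls_slope_sandwich(y, x, ww)
    df = len(y) - 2
    tval = gamma / se
    p = 2 * sps.t.sf(abs(tval), df)
    crit = sps.t.ppf(1 - alpha / 2, df)
    return CausalResult(
        effect=gamma, se=se, ci_95=(gamma - crit * se, gamma + crit * se), p=float(p)
    )


def ace_panel(
    table: pd.DataFrame,
    exposure: str,
    outcomes: Sequence[str],
    covariates: Sequence[str],
    log: bool = True,
    moments: Sequence[int] = (1, 2),
) -> pd.DataFrame:
    """Balanced ACE of one exposure on a panel of outcomes, with q-values."""
    x = table[exposure].to_numpy(dtype=float)
    if log:
        x = np.log(x)
    try:
        w = balancing_weights(x, table[list(covariates)], moments=moments)
    except BalanceError:
        if tuple(moments) == (1,):
            raise
        warnings.warn(
            "second-moment balance infeasible at this sample size; "
            "falling back to first-moment constraints",
            stacklevel=2,
        )
        w = balancing_weights(x, table[list(covariates)], moments=(1,))
    rows = []
    for out in outcomes:
        y = table[out].to_numpy(dtype=float)
        if log:
            y = np.log(y)
        r = average_causal_effect(y, x, w)
        rows.append(
            {"outcome": out, "gamma": r.effect, "se": r.se,
             "ci_lo": r.ci_95[0], "ci_hi": r.ci_95[1], "p": r.p}
        )
    frame = pd.DataFrame(rows)
    frame["q"] = adjust_fdr(frame["p"].to_numpy())
    return frame


# ---------------------------------------------------------------------------
# sensitivity analysis


@dataclass
class SensitivityResult:
    grid: np.ndarray
    surface: np.ndarray  # estimates, shape (len(grid), len(grid)): [i_t, i_y]
    diagonal: pd.DataFrame  # zeta, estimate, se, p
    base: CausalResult
    tau1: float | None
    tau2: float | None
    tau1_censored: bool = False
    tau2_censored: bool = False


def _ols_coef_se(y: np.ndarray, X: np.ndarray, j: int) -> tuple[float, float]:
    """OLS coefficient j (0-based within X) with classical se."""
    n, k = X.shape
    Xa = np.column_stack([np.ones(n), X])
    XtX = Xa.T @ Xa
    beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    e = y - Xa @ beta
    s2 = e @ e / (n - k - 1)
    V = s2 * np.linalg.pinv(XtX)
    return float(beta[j + 1]), float(np.sqrt(V[j + 1, j + 1]))


def _interp_crossing(z: np.ndarray, v: np.ndarray, level: float) -> float | None:
    """First crossing of v through `level` along z, linearly interpolated."""
    for i in range(1, len(z)):
        a, b = v[i - 1] - level, v[i] - level
        if a == 0:
            return float(z[i - 1])
        if a * b < 0:
            return float(z[i - 1] + (z[i] - z[i - 1]) * a / (a - b))
    if v[-1] - level == 0:
        return float(z[-1])
    return None


def sensitivity_scan(
    outcome: Sequence[float],
    exposure: Sequence[float],
    covariates: pd.DataFrame | None = None,
    grid: np.ndarray | None = None,
    n_draws: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
) -> SensitivityResult:
    """Robustness of an effect to a simulated unmeasured confounder.

    Over a lattice of (zeta_t, zeta_y) in [0,1]^2, a latent standard
    normal confounder with association zeta_t to the exposure and zeta_y
    to the outcome residual is simulated (``n_draws`` draws, averaged)
    and the exposure effect re-estimated adjusting for it. All data are
    standardized. tau1 is the x=y diagonal crossing where the estimate
    reaches 0; tau2 where two-sided p exceeds alpha. The zero-confounding
    corner reproduces the unperturbed estimate exactly.
    """
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 11)
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 5:
        warnings.warn("sensitivity grid coarser than 5x5", stacklevel=2)
    y = _standardize(np.asarray(outcome, dtype=float))
    x = _standardize(np.asarray(exposure, dtype=float))
    if covariates is not None and covariates.shape[1] > 0:
        Zenc = encode_covariates(covariates)
        Z = np.column_stack([_standardize(Zenc[c].to_numpy()) for c in Zenc.columns])
    else:
        Z = np.empty((len(y), 0))
    n = len(y)

    X0 = np.column_stack([x, Z]) if Z.size else x[:, None]
    g0, se0 = _ols_coef_se(y, X0, 0)
    df0 = n - X0.shape[1] - 1
    p0 = 2 * sps.t.sf(abs(g0 / se0), df0)
    base = CausalResult(
        effect=g0, se=se0, p=float(p0),
        ci_95=(g0 - 1.96 * se0, g0 + 1.96 * se0),
    )
    # outcome residual direction for constructing the confounder
    beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), X0]), y, rcond=None)
    e = y - np.column_stack([np.ones(n), X0]) @ beta
    e = e / e.std(ddof=0)
    # orient the confounder's outcome association against the observed
    # estimate so increasing confounding explains the effect away
    e *= np.sign(g0) if g0 != 0 else 1.0

    est = np.zeros((len(grid), len(grid)))
    sem = np.zeros_like(est)
    for i, zt in enumerate(grid):
        for j, zy in enumerate(grid):
            if zt == 0.0 and zy == 0.0:
                est[i, j], sem[i, j] = g0, se0
                continue
            # clamp so the confounder never reproduces the exposure exactly
            zt_e, zy_e = min(zt, 0.99), min(zy, 0.99)
            c2 = max(0.0, 1.0 - zt_e**2 - zy_e**2)
            gs, ss = [], []
            for _ in range(n_draws):
                u = zt_e * x + zy_e * e + np.sqrt(c2) * rng.standard_normal(n)
                Xu = np.column_stack([x, u, Z]) if Z.size else np.column_stack([x, u])
                g, s = _ols_coef_se(y, Xu, 0)
                gs.append(g)
                ss.append(s)
            est[i, j] = np.mean(gs)
            sem[i, j] = np.mean(ss)

    diag_est = np.array([est[i, i] for i in range(len(grid))])
    diag_se = np.array([sem[i, i] for i in range(len(grid))])
    dfd = n - (X0.shape[1] + 2)
    diag_p = 2 * sps.t.sf(np.abs(diag_est / diag_se), dfd)
    diag = pd.DataFrame(
        {"zeta": grid, "estimate": diag_est, "se": diag_se, "p": diag_p}
    )

    # locate crossings on a finely interpolated diagonal so that a loss
    # of significance between two grid nodes is still detected
    zf = np.linspace(grid[0], grid[-1], 2001)
    est_f = np.interp(zf, grid, diag_est)
    se_f = np.interp(zf, grid, diag_se)
    tau1 = _interp_crossing(zf, est_f, 0.0)
    tau1_cens = tau1 is None
    if tau1_cens:
        tau1 = float(grid[-1])
    tau2 = None
    tau2_cens = False
    if p0 < alpha:
        crit = sps.t.ppf(1 - alpha / 2, dfd)
        tau2 = _interp_crossing(zf, np.abs(est_f) - crit * se_f, 0.0)
        tau2_cens = tau2 is None
        if tau2_cens:
            tau2 = float(grid[-1])
        elif tau2 > tau1:
            tau2 = tau1
    return SensitivityResult(
        grid=grid, surface=est, diagonal=diag, base=base,
        tau1=tau1, tau2=tau2, tau1_censored=tau1_cens, tau2_censored=tau2_cens,
    )


# ---------------------------------------------------------------------------
# natural-effects mediation


@dataclass
class MediationDesign:
    """Exposure -> joint mediators -> outcome design with adjustments."""

    exposure: str = "cortisol_suppression"
    mediators: tuple[str, ...] = ("HOMA_IR", "hsCRP", "GGT", "hypoxanthine")
    outcomes: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    extra_controls: tuple[str, ...] = ()
    group_col: str | None = "group"

    def __post_init__(self) -> None:
        med = set(self.mediators)
        if self.exposure in med:
            raise ValueError("exposure cannot be a mediator")
        bad = med & set(self.outcomes)
        if bad or self.exposure in set(self.outcomes):
            raise ValueError(f"outcomes overlap exposure/mediators: {sorted(bad)}")


def expand_counterfactuals(
    x: Sequence[float],
    covariates: pd.DataFrame | None,
    delta: float = 0.01,
    truncate: tuple[float, float] = (1.0, 99.0),
) -> pd.DataFrame:
    """Replicate samples over hypothetical exposure levels with IP weights.

    Each sample yields two rows with hypothetical exposure at its
    observed level -/+ ``delta`` (log-scale shift). Weights are the
    reciprocal of a Gaussian conditional exposure density (linear in the
    covariates), truncated at the given percentiles and normalized to
    mean one.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if covariates is not None and covariates.shape[1] > 0:
        Zenc = encode_covariates(covariates)
        X = np.column_stack([np.ones(n), Zenc.to_numpy(dtype=float)])
    else:
        X = np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    mu = X @ beta
    resid = x - mu
    sigma = max(resid.std(ddof=X.shape[1]), 1e-12)
    dens = sps.norm.pdf(x, loc=mu, scale=sigma)
    w = 1.0 / np.maximum(dens, 1e-300)
    lo, hi = np.percentile(w, truncate)
    w = np.clip(w, lo, hi)
    w = w / w.mean()
    rows = {
        "idx": np.repeat(np.arange(n), 2),
        "x_hyp": np.column_stack([x - delta, x + delta]).ravel(),
        "x_act": np.repeat(x, 2),
        "weight": np.repeat(w, 2),
    }
    return pd.DataFrame(rows)


def _natural_effects_point(
    y: np.ndarray,
    x: np.ndarray,
    M: np.ndarray,
    Z: np.ndarray,
    delta: float,
    covariates_frame: pd.DataFrame | None,
) -> tuple[float, float, float]:
    """One-shot natural-effects estimate (psi_d, psi_i, psi_t)."""
    n = len(y)
    # stage 1: outcome model on observed data
    X1 = np.column_stack([np.ones(n), x, M, Z]) if Z.size else np.column_stack(
        [np.ones(n), x, M]
    )
    b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    exp_df = expand_counterfactuals(x, covariates_frame, delta=delta)
    idx = exp_df["idx"].to_numpy()
    xh = exp_df["x_hyp"].to_numpy()
    xa = exp_df["x_act"].to_numpy()
    w = exp_df["weight"].to_numpy()
    # imputed counterfactual outcome at (x_hyp, M observed)
    Mx = M[idx]
    Zx = Z[idx] if Z.size else np.empty((len(idx), 0))
    parts = [np.ones(len(idx)), xh, Mx]
    if Zx.size:
        parts.append(Zx)
    ytil = np.column_stack(parts) @ b1
    # stage 2: natural-effects regression, parametrized as (d, x_act)
    d = xh - xa
    parts2 = [np.ones(len(idx)), d, xa]
    if Zx.size:
        parts2.append(Zx)
    X2 = np.column_stack(parts2)
    sw = np.sqrt(w)
    b2, *_ = np.linalg.lstsq(X2 * sw[:, None], ytil * sw, rcond=None)
    psi_d = float(b2[1])
    psi_t = float(b2[2])
    return psi_d, psi_t - psi_d, psi_t


def natural_effects_fit(
    y: Sequence[float],
    x: Sequence[float],
    mediators: pd.DataFrame | np.ndarray,
    covariates: pd.DataFrame | None = None,
    delta: float = 0.01,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CausalResult:
    """Natural direct/indirect/total effects with bootstrap inference.

    The point estimates come from an outcome-model imputation of nested
    counterfactuals over the expanded (hypothetical, actual) exposure
    pairs, weighted by reciprocal conditional exposure density; psi_t =
    psi_d + psi_i holds exactly on every fit. CIs bootstrap over samples
    (not expanded rows).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    M = mediators.to_numpy(dtype=float) if isinstance(mediators, pd.DataFrame) else np.asarray(mediators, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if covariates is not None and covariates.shape[1] > 0:
        Zenc = encode_covariates(covariates)
        Z = Zenc.to_numpy(dtype=float)
    else:
        Zenc = None
        Z = np.empty((len(y), 0))
    # aliasing check
    X1 = np.column_stack([np.ones(len(y)), x, M, Z])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("singular mediation design: aliased columns among "
                         "exposure/mediators/covariates")

    pd_, pi_, pt_ = _natural_effects_point(y, x, M, Z, delta, Zenc)
    rng = np.random.default_rng(seed)
    n = len(y)
    boots = np.empty((n_boot, 3))
    for b in range(n_boot):
        ii = rng.integers(0, n, n)
        Zb = Zenc.iloc[ii].reset_index(drop=True) if Zenc is not None else None
        boots[b] = _natural_effects_point(
            y[ii], x[ii], M[ii], Z[ii] if Z.size else Z, delta, Zb
        )
    se = boots.std(axis=0, ddof=1)
    lo = np.percentile(boots, 100 * alpha / 2, axis=0)
    hi = np.percentile(boots, 100 * (1 - alpha / 2), axis=0)
    est = np.array([pd_, pi_, pt_])
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = 2 * sps.norm.sf(np.abs(est / se))
    keys = ("psi_d", "psi_i", "psi_t")
    return CausalResult(
        effect=dict(zip(keys, est.tolist())),
        se=dict(zip(keys, se.tolist())),
        ci_95={k: (float(l), float(h)) for k, l, h in zip(keys, lo, hi)},
        p=dict(zip(keys, pvals.tolist())),
    )


def joint_mediation(
    design: MediationDesign,
    data: CohortTable | pd.DataFrame,
    log: bool = True,
    delta: float = 0.01,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-outcome natural-effects panel with the joint mediator complex.

    Population-level estimates control for the group label (disease
    status) plus covariates and extra controls; q-values are computed
    across the outcome panel for each effect type.
    """
    df = data.data if isinstance(data, CohortTable) else data
    need = [design.exposure, *design.mediators, *design.outcomes,
            *design.covariates, *design.extra_controls]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"design columns missing from table: {missing}")
    df = df.dropna(subset=need).reset_index(drop=True)

    def tolog(col: str) -> np.ndarray:
        v = df[col].to_numpy(dtype=float)
        return np.log(v) if log else v

    x = tolog(design.exposure)
    M = np.column_stack([tolog(m) for m in design.mediators])
    cov_cols = list(design.covariates) + list(design.extra_controls)
    cov = df[cov_cols].copy() if cov_cols else pd.DataFrame(index=df.index)
    if design.group_col and design.group_col in df.columns:
        cov = cov.copy()
        cov["_group"] = (df[design.group_col] == "PTSD").astype(float)

    rows = []
    for i, out in enumerate(design.outcomes):
        res = natural_effects_fit(
            tolog(out), x, M, cov if cov.shape[1] else None,
            delta=delta, n_boot=n_boot, seed=seed + i,
        )
        rows.append(
            {
                "outcome": out,
                "psi_d": res.effect["psi_d"],
                "psi_i": res.effect["psi_i"],
                "psi_t": res.effect["psi_t"],
                "se_d": res.se["psi_d"],
                "se_i": res.se["psi_i"],
                "se_t": res.se["psi_t"],
                "ci_i_lo": res.ci_95["psi_i"][0],
                "ci_i_hi": res.ci_95["psi_i"][1],
                "p_d": res.p["psi_d"],
                "p_i": res.p["psi_i"],
                "p_t": res.p["psi_t"],
            }
        )
    frame = pd.DataFrame(rows)
    for kind in ("d", "i", "t"):
        frame[f"q_{kind}"] = adjust_fdr(frame[f"p_{kind}"].to_numpy())
    return frame
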
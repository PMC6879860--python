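"""Cohort feature-table preprocessing and group statistics.

Implements the metabolomics-style preprocessing (natural-log transform
plus per-sample median centering), two-group nonparametric testing with
exact small-sample enumeration, Storey q-value multiplicity adjustment
with a Benjamini-Hochberg fallback, Cohen's d effect sizes, Spearman
correlation maps with pairwise-complete observations, and between-group
correlation fold changes with magnitude capping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import UnivariateSpline

__all__ = [
    "CohortTable",
    "GroupDiffResult",
    "preprocess",
    "mannwhitney_u",
    "cohen_d",
    "group_difference",
    "group_differences",
    "adjust_fdr",
    "correlation_map",
    "correlation_fold_change",
]

GROUP_LEVELS = ("PTSD", "control")


@dataclass
class CohortTable:
    """Samples x features with group labels and preprocessing provenance.

    ``data`` must carry ``sample_id`` and ``group`` columns; feature
    columns are numeric. ``metabolites`` names the metabolite subset used
    for the per-sample normalization reference.
    """

    data: pd.DataFrame
    metabolites: list[str]
    group_col: str = "group"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "sample_id" not in self.data.columns:
            raise ValueError("cohort table requires a 'sample_id' column")
        if self.data["sample_id"].duplicated().any():
            dups = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        if self.group_col not in self.data.columns:
            raise ValueError(f"cohort table requires a {self.group_col!r} column")
        levels = set(self.data[self.group_col].unique())
        if not levels <= set(GROUP_LEVELS):
            raise ValueError(
                f"group labels must be among {GROUP_LEVELS}, got {sorted(levels)}"
            )
        missing = [m for m in self.metabolites if m not in self.data.columns]
        if missing:
            raise ValueError(f"metabolite columns missing from table: {missing}")

    def groups(self) -> dict[str, pd.DataFrame]:
        return {g: d for g, d in self.data.groupby(self.group_col, observed=True)}

    def subset(self, which: Literal["all", "PTSD", "control"]) -> pd.DataFrame:
        if which == "all":
            return self.data
        return self.data[self.data[self.group_col] == which]


def preprocess(
    raw: CohortTable,
    features: Sequence[str] | None = None,
    center: Literal["sample", "feature"] = "sample",
) -> CohortTable:
    """Natural-log transform and median-normalize feature columns.

    ``center='sample'`` (default) subtracts each sample's median over the
    log metabolite features from that sample's log values; ``'feature'``
    centers each feature column at its own median instead. Missing values
    are preserved; nonpositive values raise with the offending
    feature/sample named.
    """
    feats = list(features) if features is not None else list(raw.metabolites)
    df = raw.data.copy()
    for f in feats:
        col = pd.to_numeric(df[f], errors="coerce")
        bad = df.loc[col.notna() & (col <= 0), "sample_id"].tolist()
        if bad:
            raise ValueError(
                f"feature {f!r} has nonpositive values for samples {bad}; "
                "log transform undefined"
            )
        df[f] = np.log(col)
    if center == "sample":
        ref = df[list(raw.metabolites)].median(axis=1, skipna=True)
        df[feats] = df[feats].sub(ref, axis=0)
        note = "log + per-sample median centering (reference: metabolites)"
    elif center == "feature":
        df[feats] = df[feats].sub(df[feats].median(axis=0, skipna=True), axis=1)
        note = "log + per-feature median centering"
    else:
        raise ValueError(f"unknown centering mode {center!r}")
    return replace(raw, data=df, provenance=raw.provenance + [note])


# ---------------------------------------------------------------------------
# Mann-Whitney


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x via midranks (handles ties with the 0.5 convention)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def mannwhitney_u(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 20,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses full enumeration of group assignments when the combined sample
    size is at most ``exact_max_n`` (valid under ties via midranks),
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    m, n = len(x), len(y)
    u1 = _u_statistic(x, y)
    if m + n <= exact_max_n:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        offset = m * (m + 1) / 2.0
        center = m * n / 2.0
        obs_dev = abs(u1 - center)
        total = 0
        hits = 0
        for comb in itertools.combinations(range(m + n), m):
            u = ranks[list(comb)].sum() - offset
            total += 1
            if abs(u - center) >= obs_dev - 1e-9:
                hits += 1
        return u1, hits / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u1, float(res.pvalue)


def cohen_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with pooled (n-1) standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        return float("nan")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


@dataclass
class GroupDiffResult:
    feature: str
    u: float
    p: float
    cohen_d: float
    direction: int  # sign of PTSD - control median
    q: float | None = None
    significance_class: str | None = None

    def classify(self, q: float) -> None:
        self.q = q
        if self.p < 0.05 and q < 0.1:
            self.significance_class = "significant"
        elif 0.05 < self.p < 0.1:
            self.significance_class = "trend"
        else:
            self.significance_class = "ns"


def group_difference(t: CohortTable, feature: str) -> GroupDiffResult:
    """Mann-Whitney + Cohen's d for one feature (PTSD vs control)."""
    groups = t.groups()
    for g in GROUP_LEVELS:
        if g not in groups or groups[g][feature].dropna().empty:
            raise ValueError(f"group {g!r} empty for feature {feature!r}")
    case = groups["PTSD"][feature].dropna().to_numpy(dtype=float)
    ctrl = groups["control"][feature].dropna().to_numpy(dtype=float)
    u, p = mannwhitney_u(case, ctrl)
    d = cohen_d(case, ctrl)
    med = np.median(case) - np.median(ctrl)
    return GroupDiffResult(
        feature=feature,
        u=u,
        p=p,
        cohen_d=d,
        direction=int(np.sign(med)),
    )


def group_differences(t: CohortTable, features: Sequence[str]) -> pd.DataFrame:
    """Per-feature group tests with q-values across the panel."""
    results = [group_difference(t, f) for f in features]
    qs = adjust_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.classify(float(q))
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "U": [r.u for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "cohen_d": [r.cohen_d for r in results],
            "direction": [r.direction for r in results],
            "significance_class": [r.significance_class for r in results],
        }
    )


# ---------------------------------------------------------------------------
# q-values


def _storey_pi0(p: np.ndarray) -> float:
    """Smoother estimate of the null proportion pi0; 1.0 when degenerate."""
    m = len(p)
    lambdas = np.arange(0.05, 0.96, 0.05)
    if m < 100:  # too few tests for a stable smoother
        return 1.0
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    try:
        spl = UnivariateSpline(lambdas, pi0_l, k=3)
        pi0 = float(spl(lambdas[-1]))
    except Exception:
        return 1.0
    if not np.isfinite(pi0) or pi0 <= 0 or pi0 > 1:
        return 1.0
    return pi0


def adjust_fdr(pvals: Sequence[float], pi0: float | None = None) -> np.ndarray:
    """Storey q-values; with pi0=1 this is the Benjamini-Hochberg step-up.

    ``pi0=None`` uses the smoother estimate, falling back to 1 when the
    estimate is degenerate (including small panels).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = _storey_pi0(p)
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# correlations


def correlation_map(
    t: CohortTable,
    components: Sequence[str],
    metabolites: Sequence[str] | None = None,
    subset: Literal["all", "PTSD", "control"] = "all",
    alpha: float = 0.05,
    min_pairs: int = 4,
) -> dict[str, pd.DataFrame]:
    """Spearman rho/p matrices (components x metabolites), pairwise-complete.

    Entries with fewer than ``min_pairs`` complete observations are NaN
    and flagged in the ``missing`` mask. ``significant`` masks p < alpha.
    """
    mets = list(metabolites) if metabolites is not None else list(t.metabolites)
    df = t.subset(subset)
    if df.empty:
        raise ValueError(f"subset {subset!r} is empty")
    rho = pd.DataFrame(np.nan, index=list(components), columns=mets)
    pmat = pd.DataFrame(np.nan, index=list(components), columns=mets)
    missing = pd.DataFrame(False, index=list(components), columns=mets)
    for c in components:
        xc = pd.to_numeric(df[c], errors="coerce")
        for m in mets:
            ym = pd.to_numeric(df[m], errors="coerce")
            ok = xc.notna() & ym.notna()
            if ok.sum() < min_pairs:
                missing.loc[c, m] = True
                continue
            r, p = sps.spearmanr(xc[ok], ym[ok])
            rho.loc[c, m] = r
            pmat.loc[c, m] = p
    return {
        "rho": rho,
        "p": pmat,
        "significant": pmat < alpha,
        "missing": missing,
    }


def correlation_fold_change(
    rho_case: pd.DataFrame,
    rho_control: pd.DataFrame,
    cap: float = 4.0,
    control_floor: float = 1e-8,
) -> dict[str, pd.DataFrame]:
    """Elementwise rho_case / rho_control with magnitude capping.

    Ratios with |value| > ``cap`` are set to +/-cap. Sign-flipped pairs
    (opposite-sign correlations) are not ratioed: their fold entry is NaN
    and they are flagged in ``sign_flip``. Near-zero control entries are
    reported as capped and flagged in ``capped``.
    """
    if not rho_case.shape == rho_control.shape:
        raise ValueError("correlation matrices must be conformable")
    case = rho_case.to_numpy(dtype=float)
    ctrl = rho_control.to_numpy(dtype=float)
    fold = np.full_like(case, np.nan)
    flip = np.zeros_like(case, dtype=bool)
    capped = np.zeros_like(case, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(case.shape[0]):
            for j in range(case.shape[1]):
                a, b = case[i, j], ctrl[i, j]
                if np.isnan(a) or np.isnan(b):
                    continue
                if a * b < 0:
                    flip[i, j] = True
                    continue
                if abs(b) < control_floor:
                    fold[i, j] = np.sign(a) * cap if a != 0 else np.nan
                    capped[i, j] = True
                    continue
                r = a / b
                if abs(r) > cap:
                    r = np.sign(r) * cap
                    capped[i, j] = True
                fold[i, j] = r
    idx, cols = rho_case.index, rho_case.columns
    return {
        "fold": pd.DataFrame(fold, index=idx, columns=cols),
        "sign_flip": pd.DataFrame(flip, index=idx, columns=cols),
        "capped": pd.DataFrame(capped, index=idx, columns=cols),
    }
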
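"""Finite-perturbation control analysis of steady-state concentrations.

Computes metabolite concentration response coefficients (normalized
sensitivities of steady-state concentrations to parameter rescaling),
screens parameters against per-feature and cumulative thresholds,
matches direction-of-change signatures, and emits trichotomized
regulatory-state matrices.

For a parameter rescaled by ``fold``, the finite response coefficient

    [(C(fold*P) - C(P)) / ((fold - 1) * P)] * P / C(P)
      = (C(fold*P)/C(P) - 1) / (fold - 1)

is evaluated between steady states computed under the same clamp set
(glycogen clamped by default). Net coefficients average the 0.5-fold and
1.5-fold values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    ModelSpec,
    SteadyState,
    derived_ratios,
    find_steady_state,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MDSignature",
    "MCRCMatrix",
    "SignatureMatch",
    "mcrc",
    "mca_scan",
    "screen_parameters",
    "match_signature",
    "regulatory_state_matrix",
    "DEFAULT_FOLDS",
    "DEFAULT_CLAMPS",
]

DEFAULT_FOLDS = (0.5, 1.5)
DEFAULT_CLAMPS = ("glycogen",)

# 12-feature core of the dysfunction signature; ffa stands for long-chain
# fatty acids, carnitine for the carnitine pool.
CORE_12 = (
    "glucose",
    "pyruvate",
    "lactate",
    "citrate",
    "alanine",
    "glutamine",
    "ffa",
    "triglycerides",
    "carnitine",
    "arginine",
    "ornithine",
    "insulin",
)
EXTENSION_4 = ("il6", "tnf", "acth", "cortisol")

# Stated direction defaults: citrate -, pyruvate +, lactate +, alanine +,
# ornithine +, arginine -, fatty acids -, triglycerides +, carnitines +.
# glucose/glutamine/insulin directions are configurable; defaults chosen
# to match the elevated glucose/insulin/glutamine group pattern.
DEFAULT_SIGNS = {
    "glucose": +1,
    "pyruvate": +1,
    "lactate": +1,
    "citrate": -1,
    "alanine": +1,
    "glutamine": +1,
    "ffa": -1,
    "triglycerides": +1,
    "carnitine": +1,
    "arginine": -1,
    "ornithine": +1,
    "insulin": +1,
    "il6": +1,
    "tnf": +1,
    "acth": +1,
    "cortisol": +1,
}


@dataclass
class MDSignature:
    """Ordered feature list with expected direction-of-change signs."""

    features: tuple[str, ...]
    signs: dict[str, int]

    def __post_init__(self) -> None:
        for f in self.features:
            if f not in self.signs:
                raise ValueError(f"signature feature {f!r} has no sign")
            if self.signs[f] not in (-1, 1):
                raise ValueError(f"sign for {f!r} must be +1 or -1")

    @classmethod
    def core_12(cls, overrides: Mapping[str, int] | None = None) -> "MDSignature":
        signs = {f: DEFAULT_SIGNS[f] for f in CORE_12}
        if overrides:
            signs.update(overrides)
        return cls(features=CORE_12, signs=signs)

    @classmethod
    def extended_16(cls, overrides: Mapping[str, int] | None = None) -> "MDSignature":
        feats = CORE_12 + EXTENSION_4
        signs = {f: DEFAULT_SIGNS[f] for f in feats}
        if overrides:
            signs.update(overrides)
        return cls(features=feats, signs=signs)


@dataclass
class MCRCMatrix:
    """Response coefficients per parameter x feature at both folds."""

    params: list[str]
    metabolites: list[str]
    coeff_down: pd.DataFrame  # at fold 0.5
    coeff_up: pd.DataFrame  # at fold 1.5
    baseline: SteadyState | None = None
    failures: list[dict] = field(default_factory=list)

    @property
    def coeff_net(self) -> pd.DataFrame:
        return (self.coeff_down + self.coeff_up) / 2.0

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        net = self.coeff_net
        for p in self.params:
            for m in self.metabolites:
                rows.append(
                    {
                        "param": p,
                        "metabolite": m,
                        "coeff_down": self.coeff_down.loc[p, m],
                        "coeff_up": self.coeff_up.loc[p, m],
                        "coeff_net": net.loc[p, m],
                    }
                )
        return pd.DataFrame(rows)


def _feature_value(ss: SteadyState, feature: str) -> float:
    if feature in ss.concentrations:
        return ss.concentrations[feature]
    if feature in ss.derived_ratios:
        return ss.derived_ratios[feature]
    raise KeyError(f"feature {feature!r} is neither a species nor a derived ratio")


def _perturbed_ss(
    model: ModelSpec,
    param: str,
    fold: float,
    base: SteadyState,
    clamps: Sequence[str],
    tol: float,
    t_max: float,
) -> SteadyState:
    if param not in model.parameters:
        raise KeyError(f"unknown parameter {param!r}")
    pars = {param: model.parameters[param] * fold}
    return find_steady_state(
        model,
        initial=base.concentrations,
        params=pars,
        extra_clamps=[c for c in clamps if c not in model.clamps],
        tol=tol,
        t_max=t_max,
    )


def mcrc(
    model: ModelSpec,
    param: str,
    metabolite: str,
    fold: float,
    base: SteadyState | None = None,
    clamps: Sequence[str] = DEFAULT_CLAMPS,
    tol: float = 1e-8,
    t_max: float = 5000.0,
) -> float:
    """Single finite-perturbation response coefficient.

    Raises :class:`RuntimeError` when either steady state fails to
    converge (never silently returns zero).
    """
    if not (fold > 0) or fold == 1.0:
        raise ValueError("fold must be positive and != 1")
    clamps = [c for c in clamps if c in model.species_ids()]
    if base is None:
        base = find_steady_state(
            model, extra_clamps=[c for c in clamps if c not in model.clamps],
            tol=tol, t_max=t_max,
        )
    if not base.converged:
        raise RuntimeError("baseline steady state did not converge")
    pert = _perturbed_ss(model, param, fold, base, clamps, tol, t_max)
    if not pert.converged:
        raise RuntimeError(
            f"perturbed steady state did not converge for {param!r} at fold {fold}"
        )
    c0 = _feature_value(base, metabolite)
    c1 = _feature_value(pert, metabolite)
    if c0 == 0:
        return float("nan")
    return (c1 / c0 - 1.0) / (fold - 1.0)


def mca_scan(
    model: ModelSpec,
    params: Sequence[str],
    signature: MDSignature | Sequence[str],
    folds: tuple[float, float] = DEFAULT_FOLDS,
    clamps: Sequence[str] = DEFAULT_CLAMPS,
    tol: float = 1e-8,
    t_max: float = 5000.0,
    partial: MCRCMatrix | None = None,
) -> MCRCMatrix:
    """Scan parameters x signature features at both folds.

    Deterministic order; per-entry convergence failures are collected in
    ``failures`` and surface as NaN rows, never as silent zeros. Passing
    ``partial`` resumes a previous scan, skipping already-computed rows.
    """
    features = list(signature.features) if isinstance(signature, MDSignature) else list(signature)
    params = list(params)
    clamps = [c for c in clamps if c in model.species_ids()]
    base = find_steady_state(
        model, extra_clamps=[c for c in clamps if c not in model.clamps],
        tol=tol, t_max=t_max,
    )
    if not base.converged:
        raise RuntimeError("baseline steady state did not converge")

    down = pd.DataFrame(np.nan, index=params, columns=features, dtype=float)
    up = pd.DataFrame(np.nan, index=params, columns=features, dtype=float)
    failures: list[dict] = []
    for p in params:
        if (
            partial is not None
            and p in partial.coeff_down.index
            and not partial.coeff_down.loc[p].isna().any()
            and set(features) <= set(partial.coeff_down.columns)
        ):
            down.loc[p] = partial.coeff_down.loc[p, features]
            up.loc[p] = partial.coeff_up.loc[p, features]
            continue
        for fold, frame in zip(folds, (down, up)):
            try:
                pert = _perturbed_ss(model, p, fold, base, clamps, tol, t_max)
            except Exception as exc:
                failures.append({"param": p, "fold": fold, "error": str(exc)})
                continue
            if not pert.converged:
                failures.append(
                    {"param": p, "fold": fold, "error": "steady state not converged"}
                )
                continue
            for m in features:
                c0 = _feature_value(base, m)
                c1 = _feature_value(pert, m)
                frame.loc[p, m] = (c1 / c0 - 1.0) / (fold - 1.0) if c0 else np.nan
        logger.info("mca_scan: parameter %s done", p)
    return MCRCMatrix(
        params=params,
        metabolites=features,
        coeff_down=down,
        coeff_up=up,
        baseline=base,
        failures=failures,
    )


def screen_parameters(
    m: MCRCMatrix,
    per_metabolite_min: float = 0.001,
    cumulative_min: float = 0.1,
) -> pd.DataFrame:
    """Keep parameters passing both magnitude thresholds.

    A parameter is kept when |net coefficient| >= ``per_metabolite_min``
    for every signature feature and the sum of |net coefficients| over
    features is >= ``cumulative_min``. Returns a frame ranked by
    cumulative magnitude (descending); parameters with missing entries
    are excluded with a warning.
    """
    net = m.coeff_net
    rows = []
    for p in m.params:
        r = net.loc[p]
        if r.isna().any():
            logger.warning("screen_parameters: %s excluded (missing entries)", p)
            continue
        absr = r.abs()
        cumulative = float(absr.sum())
        if bool((absr >= per_metabolite_min).all()) and cumulative >= cumulative_min:
            rows.append({"param": p, "cumulative_mcrc": cumulative})
    out = pd.DataFrame(rows, columns=["param", "cumulative_mcrc"])
    out = out.sort_values(
        ["cumulative_mcrc", "param"], ascending=[False, True]
    ).reset_index(drop=True)
    out.index.name = "rank"
    return out


@dataclass
class SignatureMatch:
    match: bool
    per_feature_signs: dict[str, int]
    mismatches: list[str]


def match_signature(
    model: ModelSpec,
    param: str | Mapping[str, float],
    fold: float,
    signature: MDSignature,
    rel_tol: float = 0.01,
    clamps: Sequence[str] = DEFAULT_CLAMPS,
    tol: float = 1e-8,
    t_max: float = 5000.0,
) -> SignatureMatch:
    """Compare steady-state direction-of-change against a signature.

    ``param`` may be a single parameter id (rescaled by ``fold``) or a
    mapping of parameter id -> fold for joint perturbations. A relative
    change below ``rel_tol`` counts as no change (sign 0), which fails
    any +/- expectation.
    """
    clamps = [c for c in clamps if c in model.species_ids()]
    extra = [c for c in clamps if c not in model.clamps]
    base = find_steady_state(model, extra_clamps=extra, tol=tol, t_max=t_max)
    if not base.converged:
        raise RuntimeError("baseline steady state did not converge")
    if isinstance(param, str):
        folds = {param: fold}
    else:
        folds = dict(param)
    for p in folds:
        if p not in model.parameters:
            raise KeyError(f"unknown parameter {p!r}")
    pars = {p: model.parameters[p] * f for p, f in folds.items()}
    pert = find_steady_state(
        model, initial=base.concentrations, params=pars,
        extra_clamps=extra, tol=tol, t_max=t_max,
    )
    if not pert.converged:
        raise RuntimeError("perturbed steady state did not converge")

    signs: dict[str, int] = {}
    mismatches: list[str] = []
    for f in signature.features:
        c0 = _feature_value(base, f)
        c1 = _feature_value(pert, f)
        rel = (c1 - c0) / abs(c0) if c0 else np.inf
        s = 0 if abs(rel) < rel_tol else (1 if rel > 0 else -1)
        signs[f] = s
        if s != signature.signs[f]:
            mismatches.append(f)
    return SignatureMatch(match=not mismatches, per_feature_signs=signs, mismatches=mismatches)


def regulatory_state_matrix(
    model: ModelSpec,
    matched_params: Sequence[str | Mapping[str, float]],
    components: Sequence[str],
    fold: float = 1.5,
    rel_tol: float = 0.01,
    clamps: Sequence[str] = DEFAULT_CLAMPS,
    tol: float = 1e-8,
    t_max: float = 5000.0,
) -> pd.DataFrame:
    """Trichotomized perturbation-state matrix.

    Rows are perturbations (single parameter ids or joint fold maps),
    columns are species or derived-ratio names; entries are
    ``increased`` / ``decreased`` / ``small`` at the 1% threshold.
    """
    clamps = [c for c in clamps if c in model.species_ids()]
    extra = [c for c in clamps if c not in model.clamps]
    base = find_steady_state(model, extra_clamps=extra, tol=tol, t_max=t_max)
    if not base.converged:
        raise RuntimeError("baseline steady state did not converge")

    labels = []
    rows = []
    for spec in matched_params:
        folds = {spec: fold} if isinstance(spec, str) else dict(spec)
        pars = {p: model.parameters[p] * f for p, f in folds.items()}
        label = "+".join(f"{p}x{f:g}" for p, f in folds.items())
        pert = find_steady_state(
            model, initial=base.concentrations, params=pars,
            extra_clamps=extra, tol=tol, t_max=t_max,
        )
        if not pert.converged:
            raise RuntimeError(f"perturbed steady state did not converge for {label}")
        row = {}
        for comp in components:
            c0 = _feature_value(base, comp)
            c1 = _feature_value(pert, comp)
            rel = (c1 - c0) / abs(c0) if c0 else np.inf
            if abs(rel) < rel_tol:
                row[comp] = "small"
            elif rel > 0:
                row[comp] = "increased"
            else:
                row[comp] = "decreased"
        labels.append(label)
        rows.append(row)
    return pd.DataFrame(rows, index=labels, columns=list(components))
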
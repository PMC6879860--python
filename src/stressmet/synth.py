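"""Synthetic cohorts and toy models with known ground truth.

The cohort generator draws a linear-Gaussian structure on the log scale:

    covariates -> exposure -> mediators -> outcomes

plus direct exposure->outcome paths and two-group mean shifts. Every
causal estimand then has a closed form (path products of the generating
loadings), recorded in the accompanying :class:`TruthReport`. Metabolite
features are exponentiated (log-normal), so they are strictly positive
and survive the log preprocessing without error.

Toy model generators return small :class:`~stressmet.model.ModelSpec`
instances with closed-form steady states for oracle tests of the control
analysis machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    CompartmentDef,
    ModelSpec,
    ReactionDef,
    RegulatorDef,
    SpeciesDef,
    SubstrateDef,
)
from .stats import CohortTable

__all__ = [
    "CohortConfig",
    "TruthReport",
    "generate_cohort",
    "generate_md_cohort",
    "generate_toy_model",
    "MEDIATOR_NAMES",
    "COVARIATE_COLUMNS",
]

MEDIATOR_NAMES = ("HOMA_IR", "hsCRP", "GGT", "hypoxanthine")
EXPOSURE_NAME = "cortisol_suppression"
# 8 covariate groups: age, BMI, education, race, ethnicity, medications
# (10 indicators), smoking, alcohol use.
COVARIATE_COLUMNS = (
    ["age", "bmi", "education", "alcohol", "smoking"]
    + [f"med_{i:02d}" for i in range(1, 11)]
    + ["race", "ethnicity"]
)


def _default_direct(n: int) -> np.ndarray:
    pattern = np.array([0.3, 0.0, -0.2, 0.15, 0.0, 0.25, -0.1, 0.0])
    return np.resize(pattern, n)


def _default_b(n: int) -> np.ndarray:
    base = np.array(
        [[0.4, 0.2, 0.0, 0.3],
         [0.0, 0.0, 0.0, 0.0],
         [-0.3, 0.0, 0.2, 0.0],
         [0.2, -0.2, 0.1, 0.0],
         [0.0, 0.3, 0.0, -0.2]]
    )
    return np.resize(base, (n, 4))


@dataclass
class CohortConfig:
    """Generating configuration for a two-group synthetic cohort."""

    n_case: int = 83
    n_control: int = 82
    n_outcomes: int = 35
    # exposure model (log scale)
    exposure_cov_loadings: tuple[float, ...] = (0.3, 0.25, -0.2, 0.1, 0.15)
    exposure_group_shift: float = 0.3
    exposure_noise: float = 0.5
    # mediator models
    mediator_a: tuple[float, float, float, float] = (0.5, 0.4, 0.3, 0.35)
    mediator_cov_loading: float = 0.08
    mediator_group_shift: float = 0.1
    mediator_noise: float = 0.4
    # outcome models
    outcome_direct: tuple[float, ...] | None = None
    outcome_b: np.ndarray | None = None
    outcome_cov_loading: float = 0.08
    outcome_group_shift: float = 0.1
    outcome_noise: float = 0.5
    heavy_tails: bool = False

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")
        for name in ("exposure_noise", "mediator_noise", "outcome_noise"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.outcome_direct is None:
            self.outcome_direct = tuple(_default_direct(self.n_outcomes))
        if len(self.outcome_direct) != self.n_outcomes:
            raise ValueError("outcome_direct length must equal n_outcomes")
        if self.outcome_b is None:
            self.outcome_b = _default_b(self.n_outcomes)
        self.outcome_b = np.asarray(self.outcome_b, dtype=float)
        if self.outcome_b.shape != (self.n_outcomes, 4):
            raise ValueError("outcome_b must have shape (n_outcomes, 4)")
        if not np.all(np.isfinite(self.outcome_b)) or not np.all(
            np.isfinite(self.outcome_direct)
        ):
            raise ValueError("loadings must be finite")

    @classmethod
    def null(cls, **kw) -> "CohortConfig":
        """All exposure->mediator->outcome paths zero (null DGP)."""
        kw.setdefault("n_outcomes", 35)
        n = kw["n_outcomes"]
        kw.setdefault("outcome_direct", tuple([0.0] * n))
        kw.setdefault("outcome_b", np.zeros((n, 4)))
        kw.setdefault("mediator_a", (0.0, 0.0, 0.0, 0.0))
        return cls(**kw)


@dataclass
class TruthReport:
    """Closed-form estimands implied by the generating loadings."""

    gamma: dict[str, float]
    psi_d: dict[str, float]
    psi_i: dict[str, float]
    psi_t: dict[str, float]
    group_direction: dict[str, int]
    seed: int


def _draw_noise(rng: np.random.Generator, size, heavy: bool) -> np.ndarray:
    if heavy:
        return rng.standard_t(df=4, size=size) / np.sqrt(2.0)  # unit variance
    return rng.standard_normal(size)


def _covariate_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "age": rng.normal(38.0, 8.0, n).clip(20, 60),
            "bmi": rng.normal(27.0, 4.0, n).clip(17, 45),
            "education": rng.integers(12, 21, n).astype(float),
            "alcohol": rng.gamma(2.0, 2.0, n),
            "smoking": rng.binomial(1, 0.35, n).astype(float),
        }
    )
    for i in range(1, 11):
        df[f"med_{i:02d}"] = rng.binomial(1, 0.15, n).astype(float)
    df["race"] = rng.choice(["white", "black", "asian", "other"], n, p=[0.5, 0.25, 0.15, 0.1])
    df["ethnicity"] = rng.choice(["hispanic", "non-hispanic", "unknown"], n, p=[0.3, 0.65, 0.05])
    return df[list(COVARIATE_COLUMNS)]


def _loading_matrix(cov: pd.DataFrame, loadings: Sequence[float]) -> np.ndarray:
    """Standardized numeric design columns hit by the exposure loadings."""
    cols = ["age", "bmi", "education", "alcohol", "smoking"]
    Z = np.column_stack(
        [
            (cov[c].to_numpy(dtype=float) - cov[c].to_numpy(dtype=float).mean())
            / max(cov[c].to_numpy(dtype=float).std(), 1e-12)
            for c in cols
        ]
    )
    lam = np.zeros(len(cols))
    lam[: len(loadings)] = loadings[: len(cols)]
    return Z @ lam, Z


def generate_cohort(
    cfg: CohortConfig, seed: int = 0
) -> tuple[CohortTable, TruthReport]:
    """Draw a cohort with known direct/indirect effects.

    Deterministic given ``seed``. Feature values are exponentiated from
    the generated log scale, so all metabolite/mediator/exposure columns
    are strictly positive.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_case + cfg.n_control
    group = np.array(["PTSD"] * cfg.n_case + ["control"] * cfg.n_control)
    g = (group == "PTSD").astype(float)
    cov = _covariate_frame(rng, n)
    zx, Zstd = _loading_matrix(cov, cfg.exposure_cov_loadings)

    x = zx + cfg.exposure_group_shift * g + cfg.exposure_noise * _draw_noise(
        rng, n, cfg.heavy_tails
    )
    a = np.asarray(cfg.mediator_a)
    M = np.empty((n, 4))
    zcov = Zstd[:, :3] @ np.full(3, cfg.mediator_cov_loading)
    for k in range(4):
        M[:, k] = (
            a[k] * x
            + zcov
            + cfg.mediator_group_shift * g
            + cfg.mediator_noise * _draw_noise(rng, n, cfg.heavy_tails)
        )
    c = np.asarray(cfg.outcome_direct)
    B = cfg.outcome_b
    zy = Zstd[:, :4] @ np.full(4, cfg.outcome_cov_loading)
    names = [f"met_{j + 1:02d}" for j in range(cfg.n_outcomes)]
    Y = np.empty((n, cfg.n_outcomes))
    for j in range(cfg.n_outcomes):
        Y[:, j] = (
            c[j] * x
            + M @ B[j]
            + zy
            + cfg.outcome_group_shift * g
            + cfg.outcome_noise * _draw_noise(rng, n, cfg.heavy_tails)
        )

    data = pd.DataFrame({"sample_id": [f"S{i + 1:04d}" for i in range(n)], "group": group})
    data = pd.concat([data, cov.reset_index(drop=True)], axis=1)
    data[EXPOSURE_NAME] = np.exp(x)
    for k, m in enumerate(MEDIATOR_NAMES):
        data[m] = np.exp(M[:, k])
    for j, nm in enumerate(names):
        data[nm] = np.exp(Y[:, j])

    psi_i = B @ a
    gamma = c + psi_i
    truth = TruthReport(
        gamma={nm: float(v) for nm, v in zip(names, gamma)},
        psi_d={nm: float(v) for nm, v in zip(names, c)},
        psi_i={nm: float(v) for nm, v in zip(names, psi_i)},
        psi_t={nm: float(v) for nm, v in zip(names, gamma)},
        group_direction={nm: int(np.sign(cfg.outcome_group_shift)) for nm in names},
        seed=seed,
    )
    table = CohortTable(data=data, metabolites=names)
    return table, truth


def generate_md_cohort(
    cfg: CohortConfig,
    signature,
    effect_size: float = 0.5,
    seed: int = 0,
) -> CohortTable:
    """Cohort whose features carry group shifts matching a signature.

    Each signature feature is log-normal with a case-group mean shift of
    ``sign * effect_size`` standard deviations, enabling end-to-end
    recovery tests of the group-difference machinery.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_case + cfg.n_control
    group = np.array(["PTSD"] * cfg.n_case + ["control"] * cfg.n_control)
    g = (group == "PTSD").astype(float)
    data = pd.DataFrame({"sample_id": [f"S{i + 1:04d}" for i in range(n)], "group": group})
    sigma = 1.0
    for f in signature.features:
        shift = signature.signs[f] * effect_size * sigma
        data[f] = np.exp(rng.standard_normal(n) * sigma + shift * g)
    return CohortTable(data=data, metabolites=list(signature.features))


def generate_toy_model(kind: str) -> ModelSpec:
    """Small models with closed-form steady states for oracle tests.

    * ``linear_chain``: constant source -> a -> b -> sink, all linear;
      steady state a* = v_in/k_ab, b* = v_in/k_out (response of both to
      v_in is exactly +1).
    * ``feedback_loop``: hormone production under Hill negative feedback
      from its induced inhibitor (HPA-like central feedback); exponent
      parameter ``n_fb``.
    * ``clamp_demo``: clamped glycogen-like source feeding a product.
    """
    if kind == "linear_chain":
        return ModelSpec(
            name="linear_chain",
            species=[
                SpeciesDef(id="a", initial=1.0),
                SpeciesDef(id="b", initial=1.0),
            ],
            compartments=[CompartmentDef(id="plasma", volume=1.0)],
            parameters={"v_in": 2.0, "k_ab": 1.0, "k_out": 0.5},
            reactions=[
                ReactionDef(id="source", vmax="v_in", products={"a": 1}),
                ReactionDef(
                    id="a_to_b",
                    vmax="k_ab",
                    substrates=[SubstrateDef(species="a", km=None)],
                    products={"b": 1},
                ),
                ReactionDef(
                    id="b_out",
                    vmax="k_out",
                    substrates=[SubstrateDef(species="b", km=None)],
                ),
            ],
        )
    if kind == "feedback_loop":
        return ModelSpec(
            name="feedback_loop",
            species=[
                SpeciesDef(id="input", initial=1.0, role="signaling"),
                SpeciesDef(id="hormone", initial=1.0, role="hormone"),
                SpeciesDef(id="inhibitor", initial=1.0, role="transcription_factor"),
            ],
            compartments=[CompartmentDef(id="plasma", volume=1.0)],
            parameters={
                "v_h": 2.0,
                "kd_h": 1.0,
                "k_input": 0.5,
                "k_fb": 1.0,
                "n_fb": 2.0,
                "v_i": 1.0,
                "kd_i": 1.0,
                "k_act": 1.0,
            },
            clamps=["input"],
            reactions=[
                ReactionDef(
                    id="hormone_synthesis",
                    vmax="v_h",
                    products={"hormone": 1},
                    regulators=[
                        RegulatorDef(species="input", mode="activate", k_half="k_input"),
                        RegulatorDef(
                            species="inhibitor",
                            mode="deactivate",
                            k_half="k_fb",
                            hill_n="n_fb",
                        ),
                    ],
                ),
                ReactionDef(
                    id="hormone_decay",
                    vmax="kd_h",
                    substrates=[SubstrateDef(species="hormone", km=None)],
                ),
                ReactionDef(
                    id="inhibitor_synthesis",
                    vmax="v_i",
                    products={"inhibitor": 1},
                    regulators=[
                        RegulatorDef(species="hormone", mode="activate", k_half="k_act")
                    ],
                ),
                ReactionDef(
                    id="inhibitor_decay",
                    vmax="kd_i",
                    substrates=[SubstrateDef(species="inhibitor", km=None)],
                ),
            ],
        )
    if kind == "clamp_demo":
        return ModelSpec(
            name="clamp_demo",
            species=[
                SpeciesDef(id="glycogen", initial=5.0),
                SpeciesDef(id="product", initial=1.0),
            ],
            compartments=[CompartmentDef(id="plasma", volume=1.0)],
            parameters={"k_release": 0.4, "k_clear": 1.0},
            clamps=["glycogen"],
            reactions=[
                ReactionDef(
                    id="release",
                    vmax="k_release",
                    substrates=[SubstrateDef(species="glycogen", km=None)],
                    products={"product": 1},
                ),
                ReactionDef(
                    id="clear",
                    vmax="k_clear",
                    substrates=[SubstrateDef(species="product", km=None)],
                ),
            ],
        )
    raise ValueError(f"unknown toy model kind {kind!r}")
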
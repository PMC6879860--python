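"""Semi-empirical rate-law building blocks.

Pure functions evaluating the saturating Michaelis-Menten / Hill factors
that compose every reaction rate in the network models: substrate
saturation, allosteric activation / deactivation / product inhibition,
and multiplicative signaling / transcriptional regulation.

All factors are dimensionless fractions in [0, 1] except the combined
signaling multiplier, which is bounded by ``weight * (1 + n_activators)``.
Concentrations are clipped at zero before evaluation so that rate laws
remain defined under small integrator under-shoot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "KineticsError",
    "InvalidParameterError",
    "MissingRegulatorError",
    "SaturationTerm",
    "AllostericSpec",
    "RegulatorEdge",
    "TransportSpec",
    "saturation_term",
    "allosteric_factors",
    "hill_activation",
    "hill_inhibition",
    "sigtrans_factor",
    "reaction_rate",
    "transport_rate",
]


class KineticsError(ValueError):
    """Base class for rate-law evaluation errors."""


class InvalidParameterError(KineticsError):
    """A kinetic constant violates its positivity constraint."""


class MissingRegulatorError(KineticsError):
    """A regulatory edge references a species absent from the state."""


def _clip0(x: float) -> float:
    """Clip a concentration at zero (guards integrator under-shoot)."""
    x = float(x)
    if x < 0.0:
        return 0.0
    return x


@dataclass(frozen=True)
class SaturationTerm:
    """Substrate half-saturation factor ``c / (c + km)``."""

    metabolite_conc: float
    km: float

    def value(self) -> float:
        return saturation_term(self.metabolite_conc, self.km)


@dataclass(frozen=True)
class AllostericSpec:
    """Allosteric activator / inhibitor context for one reaction.

    ``k_act`` is the activator half-effect constant, ``k_inh`` the
    inhibitor half-effect constant and ``k_prod`` the product-inhibition
    constant. Any of the concentrations may be ``None`` meaning the
    corresponding factor is absent (evaluates to 1).
    """

    activator_conc: float | None = None
    inhibitor_conc: float | None = None
    k_act: float = 1.0
    k_inh: float = 1.0
    k_prod: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_act", "k_inh", "k_prod"):
            v = getattr(self, name)
            if not (v > 0):
                raise InvalidParameterError(f"{name} must be > 0, got {v!r}")
        for name in ("activator_conc", "inhibitor_conc"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class RegulatorEdge:
    """One signaling or transcriptional regulatory edge onto a reaction."""

    regulator_id: str
    mode: Literal["activate", "deactivate"]
    k_half: float
    hill_n: float = 1.0
    layer: Literal["signaling", "transcription"] = "signaling"

    def __post_init__(self) -> None:
        if self.mode not in ("activate", "deactivate"):
            raise InvalidParameterError(f"unknown regulator mode {self.mode!r}")
        if self.layer not in ("signaling", "transcription"):
            raise InvalidParameterError(f"unknown regulator layer {self.layer!r}")
        if not (self.k_half > 0):
            raise InvalidParameterError(f"k_half must be > 0, got {self.k_half!r}")
        if not (self.hill_n >= 1):
            raise InvalidParameterError(f"hill_n must be >= 1, got {self.hill_n!r}")


@dataclass(frozen=True)
class TransportSpec:
    """Passive or facilitated blood<->tissue transport parameters."""

    kind: Literal["passive", "facilitated"]
    epsilon: float | None = None
    t_max: float | None = None
    k_blood: float | None = None
    k_tissue: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "passive":
            if self.epsilon is None or not (self.epsilon > 0):
                raise InvalidParameterError(
                    f"passive transport requires epsilon > 0, got {self.epsilon!r}"
                )
        elif self.kind == "facilitated":
            for name in ("t_max", "k_blood", "k_tissue"):
                v = getattr(self, name)
                if v is None or not (v > 0):
                    raise InvalidParameterError(
                        f"facilitated transport requires {name} > 0, got {v!r}"
                    )
        else:
            raise KineticsError(f"unknown transport kind {self.kind!r}")


def saturation_term(conc: float, km: float) -> float:
    """Hyperbolic substrate saturation ``conc / (conc + km)``.

    Monotone increasing in ``conc``, equals 0.5 at ``conc == km``.
    """
    if not (km > 0):
        raise InvalidParameterError(f"km must be > 0, got {km!r}")
    c = _clip0(conc)
    return c / (c + km)


def allosteric_factors(spec: AllostericSpec) -> dict[str, float]:
    """Evaluate allosteric activation, deactivation and product inhibition.

    Returns ``f_act = A/(A+k_act)``, ``f_deact = k_inh/(I+k_inh)`` and
    ``f_pi = A/(A+k_inh) * 1/(1 + I/k_prod)``. Absent concentrations give
    unit factors.
    """
    out = {"f_act": 1.0, "f_deact": 1.0, "f_pi": 1.0}
    a = spec.activator_conc
    i = spec.inhibitor_conc
    if a is not None:
        a = _clip0(a)
        out["f_act"] = a / (a + spec.k_act)
    if i is not None:
        i = _clip0(i)
        out["f_deact"] = spec.k_inh / (i + spec.k_inh)
    if a is not None:
        # product inhibition: hyperbolic decrease with inhibitor I
        pi = a / (a + spec.k_inh)
        if i is not None:
            pi *= 1.0 / (1.0 + i / spec.k_prod)
        out["f_pi"] = pi
    return out


def hill_activation(s: float, k: float, n: float) -> float:
    """Hill activation ``s^n / (s^n + k^n)``; reduces to saturation at n=1."""
    if not (k > 0):
        raise InvalidParameterError(f"k must be > 0, got {k!r}")
    s = _clip0(s)
    if s == 0.0:
        return 0.0
    # log-space ratio form, stable for large n and extreme s/k
    t = n * (math.log(k) - math.log(s))
    if t > 700.0:
        return 0.0
    if t < -700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(t))


def hill_inhibition(i: float, k: float, n: float) -> float:
    """Hill inhibition ``k^n / (i^n + k^n)``; equals 1 - hill_activation."""
    return 1.0 - hill_activation(i, k, n)


def sigtrans_factor(
    edges: Sequence[RegulatorEdge],
    state: Mapping[str, float],
    weight: float = 1.0,
) -> float:
    """Combined signaling/transcription multiplier for a reaction.

    ``weight * (1 + sum of activator Hill terms) * (product of inhibitor
    Hill terms)``. With no edges this reduces to ``weight``.
    """
    if not (weight > 0):
        raise InvalidParameterError(f"weight must be > 0, got {weight!r}")
    act_sum = 0.0
    inh_prod = 1.0
    for e in edges:
        if e.regulator_id not in state:
            raise MissingRegulatorError(
                f"regulator species {e.regulator_id!r} not present in state"
            )
        conc = state[e.regulator_id]
        if e.mode == "activate":
            act_sum += hill_activation(conc, e.k_half, e.hill_n)
        else:
            inh_prod *= hill_inhibition(conc, e.k_half, e.hill_n)
    return weight * (1.0 + act_sum) * inh_prod


def reaction_rate(
    vmax: float,
    substrates: Iterable[SaturationTerm] = (),
    allosteric: AllostericSpec | None = None,
    regulation: Sequence[RegulatorEdge] = (),
    state: Mapping[str, float] | None = None,
    weight: float = 1.0,
) -> float:
    """Full reaction rate: vmax x saturation x allosteric x regulation."""
    if vmax < 0:
        raise InvalidParameterError(f"vmax must be >= 0, got {vmax!r}")
    rate = float(vmax)
    for s in substrates:
        rate *= s.value()
    if allosteric is not None:
        f = allosteric_factors(allosteric)
        rate *= f["f_act"] * f["f_deact"] * f["f_pi"]
    if regulation:
        rate *= sigtrans_factor(regulation, state or {}, weight)
    elif weight != 1.0:
        rate *= weight
    return rate


def transport_rate(spec: TransportSpec, c_blood: float, c_tissue: float) -> float:
    """Signed blood->tissue transport rate.

    Positive values move material from blood into tissue.
    """
    cb = _clip0(c_blood)
    ct = _clip0(c_tissue)
    if spec.kind == "passive":
        return spec.epsilon * (cb - ct)
    if spec.kind == "facilitated":
        return spec.t_max * (
            cb / (spec.k_blood + cb) - ct / (spec.k_tissue + ct)
        )
    raise KineticsError(f"unknown transport kind {spec.kind!r}")
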
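"""Declarative network models and ODE assembly.

A :class:`ModelSpec` declares species, compartments, reactions built from
the rate-law grammar in :mod:`stressmet.kinetics`, blood/tissue transports
and named parameters. The module assembles the mass-balance right-hand
side

    dM_i/dt * V = sum(producing rates) - sum(consuming rates) +/- transport

integrates it to steady state with a stiff-capable scheme plus a
root-polish step, and runs qualitative scenario checks. Clamped species
have identically zero derivatives (used e.g. for the glycogen clamp
during control analysis).

Models are written as plain-text YAML documents; numeric fields may
reference named parameters so that perturbation scans can rescale them
without re-parsing. A reaction substrate with ``km: null`` contributes a
linear (mass-action) factor, the Km -> infinity limit of the saturating
form with the 1/Km absorbed into vmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .kinetics import hill_activation, hill_inhibition

__all__ = [
    "ModelError",
    "UnresolvedReferenceError",
    "ConvergenceError",
    "SpeciesDef",
    "CompartmentDef",
    "SubstrateDef",
    "RegulatorDef",
    "AllostericDef",
    "ReactionDef",
    "TransportDef",
    "ModelSpec",
    "SteadyState",
    "StepInput",
    "load_model",
    "loads_model",
    "model_to_yaml",
    "assemble_rhs",
    "find_steady_state",
    "simulate",
    "qualitative_check",
    "reference_model",
    "DERIVED_RATIOS",
    "derived_ratios",
    "SCENARIOS",
]


class ModelError(ValueError):
    """Invalid model specification."""


class UnresolvedReferenceError(ModelError):
    """A reaction or regulator references an unknown species/parameter."""


class ConvergenceError(RuntimeError):
    """Integration blew up or the steady-state search failed hard."""


SPECIES_ROLES = {"metabolite", "signaling", "transcription_factor", "hormone", "cytokine"}


@dataclass
class SpeciesDef:
    id: str
    compartment: str = "plasma"
    initial: float = 1.0
    role: str = "metabolite"


@dataclass
class CompartmentDef:
    id: str
    volume: float = 1.0


@dataclass
class SubstrateDef:
    """A rate factor: saturating if km given, linear if km is None.

    ``stoich`` is the consumed stoichiometry (0 = pure kinetic modifier).
    """

    species: str
    km: float | str | None = None
    stoich: float = 1.0


@dataclass
class RegulatorDef:
    species: str
    mode: str  # activate | deactivate
    k_half: float | str = 1.0
    hill_n: float | str = 1.0
    layer: str = "signaling"


@dataclass
class AllostericDef:
    activator: str | None = None
    inhibitor: str | None = None
    k_act: float | str = 1.0
    k_inh: float | str = 1.0
    k_prod: float | str = 1.0


@dataclass
class ReactionDef:
    id: str
    vmax: float | str = 1.0
    substrates: list[SubstrateDef] = field(default_factory=list)
    products: dict[str, float] = field(default_factory=dict)
    regulators: list[RegulatorDef] = field(default_factory=list)
    allosteric: AllostericDef | None = None
    weight: float | str = 1.0


@dataclass
class TransportDef:
    id: str
    kind: str  # passive | facilitated
    blood: str
    tissue: str
    epsilon: float | str | None = None
    t_max: float | str | None = None
    k_blood: float | str | None = None
    k_tissue: float | str | None = None


@dataclass
class ModelSpec:
    """Fully resolved declarative model."""

    name: str = "model"
    species: list[SpeciesDef] = field(default_factory=list)
    compartments: list[CompartmentDef] = field(default_factory=list)
    reactions: list[ReactionDef] = field(default_factory=list)
    transports: list[TransportDef] = field(default_factory=list)
    parameters: dict[str, float] = field(default_factory=dict)
    clamps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- resolution helpers -------------------------------------------------
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial for s in self.species], dtype=float)

    def volume_of(self, species_id: str) -> float:
        comp = {c.id: c.volume for c in self.compartments}
        sp = {s.id: s for s in self.species}[species_id]
        return comp.get(sp.compartment, 1.0)

    def validate(self) -> None:
        if not self.species:
            raise ModelError("model declares an empty species list")
        ids = self.species_ids()
        if len(set(ids)) != len(ids):
            raise ModelError("duplicate species ids")
        known = set(ids)
        comp_ids = {c.id for c in self.compartments}
        for c in self.compartments:
            if not (c.volume > 0):
                raise ModelError(f"compartment {c.id!r} volume must be > 0")
        for s in self.species:
            if comp_ids and s.compartment not in comp_ids:
                raise UnresolvedReferenceError(
                    f"species {s.id!r} placed in unknown compartment {s.compartment!r}"
                )
        for r in self.reactions:
            for sub in r.substrates:
                if sub.species not in known:
                    raise UnresolvedReferenceError(
                        f"reaction {r.id!r} cites unknown species {sub.species!r}"
                    )
            for pid in r.products:
                if pid not in known:
                    raise UnresolvedReferenceError(
                        f"reaction {r.id!r} produces unknown species {pid!r}"
                    )
            for reg in r.regulators:
                if reg.species not in known:
                    raise UnresolvedReferenceError(
                        f"reaction {r.id!r} regulated by unknown species {reg.species!r}"
                    )
            if r.allosteric is not None:
                for a in (r.allosteric.activator, r.allosteric.inhibitor):
                    if a is not None and a not in known:
                        raise UnresolvedReferenceError(
                            f"reaction {r.id!r} allosteric cites unknown species {a!r}"
                        )
            self._check_param_refs(r)
        for t in self.transports:
            for sp in (t.blood, t.tissue):
                if sp not in known:
                    raise UnresolvedReferenceError(
                        f"transport {t.id!r} cites unknown species {sp!r}"
                    )
        for c in self.clamps:
            if c not in known:
                raise UnresolvedReferenceError(f"clamp cites unknown species {c!r}")

    def _check_param_refs(self, r: ReactionDef) -> None:
        def chk(v: Any, ctx: str) -> None:
            if isinstance(v, str) and v not in self.parameters:
                raise UnresolvedReferenceError(
                    f"reaction {r.id!r}: {ctx} references unknown parameter {v!r}"
                )

        chk(r.vmax, "vmax")
        chk(r.weight, "weight")
        for sub in r.substrates:
            chk(sub.km, "km")
        for reg in r.regulators:
            chk(reg.k_half, "k_half")
            chk(reg.hill_n, "hill_n")


@dataclass
class SteadyState:
    concentrations: dict[str, float]
    residual_norm: float
    converged: bool
    derived_ratios: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.concentrations[key]


@dataclass
class StepInput:
    """Clamp ``species`` at ``value`` during [t_start, t_end]."""

    species: str
    value: float
    t_start: float
    t_end: float


# Derived regulatory-state ratios reported alongside steady states.
DERIVED_RATIOS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "ATP/ADP": (("atp",), ("adp",)),
    "NADH/NAD": (("nadh",), ("nad",)),
    "glycolytic_ratio": (("pyruvate", "lactate"), ("citrate",)),
    "GABR": (("arginine",), ("ornithine", "citrulline")),
}


def derived_ratios(conc: Mapping[str, float]) -> dict[str, float]:
    """Compute the derived ratios available in a concentration map."""
    out: dict[str, float] = {}
    for name, (num, den) in DERIVED_RATIOS.items():
        if all(s in conc for s in num) and all(s in conc for s in den):
            d = sum(conc[s] for s in den)
            out[name] = sum(conc[s] for s in num) / d if d > 0 else math.inf
    return out


# ---------------------------------------------------------------------------
# parsing


def _parse_reaction(d: Mapping[str, Any]) -> ReactionDef:
    subs = []
    for s in d.get("substrates", []) or []:
        subs.append(
            SubstrateDef(
                species=s["species"],
                km=s.get("km"),
                stoich=float(s.get("stoich", 1.0)),
            )
        )
    regs = []
    for g in d.get("regulators", []) or []:
        regs.append(
            RegulatorDef(
                species=g["species"],
                mode=g["mode"],
                k_half=g.get("k_half", 1.0),
                hill_n=g.get("hill_n", 1.0),
                layer=g.get("layer", "signaling"),
            )
        )
    allo = None
    if d.get("allosteric"):
        a = d["allosteric"]
        allo = AllostericDef(
            activator=a.get("activator"),
            inhibitor=a.get("inhibitor"),
            k_act=a.get("k_act", 1.0),
            k_inh=a.get("k_inh", 1.0),
            k_prod=a.get("k_prod", 1.0),
        )
    return ReactionDef(
        id=d["id"],
        vmax=d.get("vmax", 1.0),
        substrates=subs,
        products={k: float(v) for k, v in (d.get("products") or {}).items()},
        regulators=regs,
        allosteric=allo,
        weight=d.get("weight", 1.0),
    )


def loads_model(text: str) -> ModelSpec:
    """Parse a YAML model document into a validated :class:`ModelSpec`."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough context
        raise ModelError(f"model config does not parse: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ModelError("model config must be a YAML mapping")
    species = [
        SpeciesDef(
            id=s["id"],
            compartment=s.get("compartment", "plasma"),
            initial=float(s.get("initial", 1.0)),
            role=s.get("role", "metabolite"),
        )
        for s in doc.get("species", []) or []
    ]
    comps = [
        CompartmentDef(id=c["id"], volume=float(c.get("volume", 1.0)))
        for c in doc.get("compartments", []) or []
    ] or [CompartmentDef(id="plasma", volume=1.0)]
    reactions = [_parse_reaction(r) for r in doc.get("reactions", []) or []]
    transports = [
        TransportDef(
            id=t["id"],
            kind=t["kind"],
            blood=t["blood"],
            tissue=t["tissue"],
            epsilon=t.get("epsilon"),
            t_max=t.get("t_max"),
            k_blood=t.get("k_blood"),
            k_tissue=t.get("k_tissue"),
        )
        for t in doc.get("transports", []) or []
    ]
    return ModelSpec(
        name=doc.get("name", "model"),
        species=species,
        compartments=comps,
        reactions=reactions,
        transports=transports,
        parameters={k: float(v) for k, v in (doc.get("parameters") or {}).items()},
        clamps=list(doc.get("clamps", []) or []),
    )


def load_model(path: str) -> ModelSpec:
    """Load and validate a model config file."""
    with open(path) as fh:
        return loads_model(fh.read())


def model_to_yaml(model: ModelSpec) -> str:
    """Serialize a ModelSpec back to its YAML document form."""
    doc: dict[str, Any] = {
        "name": model.name,
        "compartments": [{"id": c.id, "volume": c.volume} for c in model.compartments],
        "parameters": dict(model.parameters),
        "species": [
            {"id": s.id, "compartment": s.compartment, "initial": s.initial, "role": s.role}
            for s in model.species
        ],
        "clamps": list(model.clamps),
        "reactions": [],
        "transports": [],
    }
    for r in model.reactions:
        rd: dict[str, Any] = {"id": r.id, "vmax": r.vmax}
        if r.substrates:
            rd["substrates"] = [
                {"species": s.species, "km": s.km, "stoich": s.stoich} for s in r.substrates
            ]
        if r.products:
            rd["products"] = dict(r.products)
        if r.regulators:
            rd["regulators"] = [
                {
                    "species": g.species,
                    "mode": g.mode,
                    "k_half": g.k_half,
                    "hill_n": g.hill_n,
                    "layer": g.layer,
                }
                for g in r.regulators
            ]
        if r.allosteric:
            a = r.allosteric
            rd["allosteric"] = {
                "activator": a.activator,
                "inhibitor": a.inhibitor,
                "k_act": a.k_act,
                "k_inh": a.k_inh,
                "k_prod": a.k_prod,
            }
        if r.weight != 1.0:
            rd["weight"] = r.weight
        doc["reactions"].append(rd)
    for t in model.transports:
        doc["transports"].append(
            {
                "id": t.id,
                "kind": t.kind,
                "blood": t.blood,
                "tissue": t.tissue,
                "epsilon": t.epsilon,
                "t_max": t.t_max,
                "k_blood": t.k_blood,
                "k_tissue": t.k_tissue,
            }
        )
    return yaml.safe_dump(doc, sort_keys=False)


# ---------------------------------------------------------------------------
# RHS assembly


def _resolver(params: Mapping[str, float]) -> Callable[[Any], float]:
    def res(v: Any) -> float:
        if isinstance(v, str):
            try:
                return float(params[v])
            except KeyError:
                raise UnresolvedReferenceError(f"unknown parameter {v!r}") from None
        return float(v)

    return res


def assemble_rhs(
    model: ModelSpec,
    params: Mapping[str, float] | None = None,
    extra_clamps: Sequence[str] = (),
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the mass-balance derivative function for a model.

    ``params`` overrides entries of ``model.parameters`` (used by
    perturbation scans). ``extra_clamps`` adds clamped species on top of
    those declared by the model.
    """
    merged = dict(model.parameters)
    if params:
        merged.update(params)
    res = _resolver(merged)
    idx = model.index()
    n = len(model.species)
    inv_vol = np.array([1.0 / model.volume_of(s.id) for s in model.species])

    compiled = []
    for r in model.reactions:
        vmax = res(r.vmax)
        if vmax < 0:
            raise ModelError(f"reaction {r.id!r}: vmax must be >= 0")
        weight = res(r.weight)
        subs = [
            (idx[s.species], None if s.km is None else res(s.km), s.stoich)
            for s in r.substrates
        ]
        prods = [(idx[p], st) for p, st in r.products.items()]
        regs = [
            (idx[g.species], g.mode == "activate", res(g.k_half), res(g.hill_n))
            for g in r.regulators
        ]
        allo = None
        if r.allosteric is not None:
            a = r.allosteric
            allo = (
                idx[a.activator] if a.activator else -1,
                idx[a.inhibitor] if a.inhibitor else -1,
                res(a.k_act),
                res(a.k_inh),
                res(a.k_prod),
            )
        compiled.append((vmax, weight, subs, prods, regs, allo))

    transports = []
    for t in model.transports:
        if t.kind == "passive":
            transports.append(("p", idx[t.blood], idx[t.tissue], res(t.epsilon), 0.0, 0.0))
        elif t.kind == "facilitated":
            transports.append(
                ("f", idx[t.blood], idx[t.tissue], res(t.t_max), res(t.k_blood), res(t.k_tissue))
            )
        else:
            raise ModelError(f"transport {t.id!r}: unknown kind {t.kind!r}")

    clamp_idx = np.array(
        sorted({idx[c] for c in list(model.clamps) + list(extra_clamps)}), dtype=int
    )

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        yc = np.maximum(y, 0.0)  # guard integrator under-shoot
        dy = np.zeros(n)
        for vmax, weight, subs, prods, regs, allo in compiled:
            rate = vmax
            for si, km, _ in subs:
                c = yc[si]
                rate *= c if km is None else c / (c + km)
                if rate == 0.0:
                    break
            if rate > 0.0 and allo is not None:
                ai, ii, ka, ki, kp = allo
                if ai >= 0:
                    a = yc[ai]
                    rate *= a / (a + ka)  # activation
                    pi = a / (a + ki)  # product inhibition base
                    if ii >= 0:
                        pi *= 1.0 / (1.0 + yc[ii] / kp)
                    rate *= pi
                if ii >= 0:
                    rate *= ki / (yc[ii] + ki)  # deactivation
            if rate > 0.0 and (regs or weight != 1.0):
                act = 0.0
                inh = 1.0
                for ri, is_act, k, hn in regs:
                    h = hill_activation(yc[ri], k, hn)
                    if is_act:
                        act += h
                    else:
                        inh *= 1.0 - h
                rate *= weight * (1.0 + act) * inh
            for si, km, st in subs:
                if st:
                    dy[si] -= st * rate
            for pi_, st in prods:
                dy[pi_] += st * rate
        for kind, bi, ti, p1, p2, p3 in transports:
            if kind == "p":
                tr = p1 * (yc[bi] - yc[ti])
            else:
                tr = p1 * (yc[bi] / (p2 + yc[bi]) - yc[ti] / (p3 + yc[ti]))
            dy[bi] -= tr
            dy[ti] += tr
        dy *= inv_vol
        if clamp_idx.size:
            dy[clamp_idx] = 0.0
        return dy

    return rhs


# ---------------------------------------------------------------------------
# steady state and simulation


def find_steady_state(
    model: ModelSpec,
    initial: np.ndarray | Mapping[str, float] | None = None,
    t_max: float = 5000.0,
    tol: float = 1e-6,
    params: Mapping[str, float] | None = None,
    extra_clamps: Sequence[str] = (),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SteadyState:
    """Integrate to steady state and root-polish the result.

    Non-convergence is flagged on the returned object, never silent.
    """
    rhs = assemble_rhs(model, params=params, extra_clamps=extra_clamps)
    y = _coerce_state(model, initial)
    if np.any(y < 0):
        raise ModelError("initial state must be nonnegative")
    idx = model.index()
    clamped = {idx[c] for c in list(model.clamps) + list(extra_clamps)}
    free = np.array([i for i in range(len(y)) if i not in clamped], dtype=int)

    t0, chunk = 0.0, max(t_max / 8.0, 1.0)
    converged = False
    while t0 < t_max:
        t1 = min(t0 + chunk, t_max)
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise ConvergenceError(
                f"integrator failed on {model.name!r}: {sol.message}"
            )
        y = sol.y[:, -1]
        if not np.all(np.isfinite(y)):
            bad = [model.species[i].id for i in np.where(~np.isfinite(y))[0]]
            raise ConvergenceError(f"integration blew up for species {bad}")
        if np.max(np.abs(rhs(0.0, y))) < tol:
            converged = True
            break
        t0 = t1

    # root-polish the free species at the integration endpoint
    if free.size:
        def fun(z: np.ndarray) -> np.ndarray:
            full = y.copy()
            full[free] = z
            return rhs(0.0, full)[free]

        try:
            polish = root(fun, y[free], method="hybr", tol=1e-12)
            cand = y.copy()
            cand[free] = polish.x
            if np.all(cand[free] >= -1e-12):
                cand = np.maximum(cand, 0.0)
                if np.max(np.abs(rhs(0.0, cand))) <= np.max(np.abs(rhs(0.0, y))):
                    y = cand
        except Exception:
            pass  # keep the integrated state

    residual = float(np.max(np.abs(rhs(0.0, y))))
    converged = residual < tol
    conc = {s.id: float(v) for s, v in zip(model.species, y)}
    return SteadyState(
        concentrations=conc,
        residual_norm=residual,
        converged=converged,
        derived_ratios=derived_ratios(conc),
    )


def _coerce_state(
    model: ModelSpec, initial: np.ndarray | Mapping[str, float] | None
) -> np.ndarray:
    if initial is None:
        return model.initial_state()
    if isinstance(initial, Mapping):
        y = model.initial_state()
        idx = model.index()
        for k, v in initial.items():
            y[idx[k]] = v
        return y
    return np.asarray(initial, dtype=float).copy()


def simulate(
    model: ModelSpec,
    t_span: tuple[float, float],
    initial: np.ndarray | Mapping[str, float] | None = None,
    inputs: Sequence[StepInput] = (),
    params: Mapping[str, float] | None = None,
    n_points: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Simulate a trajectory, honouring clamped species and step inputs.

    Returns a tidy wide table: a ``time`` column plus one column per
    species.
    """
    if not (t_span[1] > t_span[0]):
        raise ModelError("t_span must be increasing")
    idx = model.index()
    for s in inputs:
        if s.species not in idx:
            raise UnresolvedReferenceError(f"input overrides unknown species {s.species!r}")

    # breakpoints where the active override set changes
    cuts = {t_span[0], t_span[1]}
    for s in inputs:
        if t_span[0] < s.t_start < t_span[1]:
            cuts.add(s.t_start)
        if t_span[0] < s.t_end < t_span[1]:
            cuts.add(s.t_end)
    cuts = sorted(cuts)

    y = _coerce_state(model, initial)
    times = np.linspace(t_span[0], t_span[1], n_points)
    rows: list[np.ndarray] = []
    out_t: list[float] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        active = [s for s in inputs if s.t_start < b and s.t_end > a]
        for s in active:
            y[idx[s.species]] = s.value
        rhs = assemble_rhs(model, params=params, extra_clamps=[s.species for s in active])
        seg_t = times[(times >= a) & (times <= b)]
        t_eval = np.unique(np.concatenate([[a], seg_t, [b]]))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise ConvergenceError(f"integrator failed: {sol.message}")
        for tv, col in zip(sol.t, sol.y.T):
            if tv in seg_t and (not out_t or tv > out_t[-1]):
                out_t.append(float(tv))
                rows.append(col.copy())
        y = sol.y[:, -1]
        for s in active:  # restore pre-step level when the step ends at b
            if s.t_end <= b and s.t_end < t_span[1]:
                y[idx[s.species]] = model.initial_state()[idx[s.species]] if initial is None \
                    else _coerce_state(model, initial)[idx[s.species]]
    frame = pd.DataFrame(rows, columns=model.species_ids())
    frame.insert(0, "time", out_t)
    return frame


# ---------------------------------------------------------------------------
# qualitative scenarios

_REL_TOL = 0.01


def _sign(base: float, new: float, rel_tol: float = _REL_TOL) -> str:
    if base == 0:
        return "+" if new > 0 else ("-" if new < 0 else "0")
    rel = (new - base) / abs(base)
    if rel > rel_tol:
        return "+"
    if rel < -rel_tol:
        return "-"
    return "0"


@dataclass
class QualitativeReport:
    scenario: str
    assertions: list[dict[str, Any]]

    @property
    def passed(self) -> bool:
        return all(a["ok"] for a in self.assertions)


# scenario -> (param overrides, state overrides, expected signs)
SCENARIOS: dict[str, dict[str, Any]] = {
    "null": {"params": {}, "state": {}, "expect": {}},
    "stress_step": {"params": {}, "state": {"stress": 3.0}, "expect": {"cortisol": "+"}},
    "glucose_load": {"params": {}, "state": {"glucose": 2.0}, "expect": {"insulin": "+"}},
    "cytokine_challenge": {"params": {}, "state": {"il6": 3.0}, "expect": {"cortisol": "+"}},
    "gr_sensitization": {
        "params": {"n_gr_central": 1.5, "nx_gr_cytokine": 1.5},  # fold factors
        "state": {},
        "expect": {"il6": "+", "tnf": "+"},
    },
}


def qualitative_check(
    model: ModelSpec,
    scenario: str,
    tol: float = 1e-6,
    t_max: float = 5000.0,
) -> QualitativeReport:
    """Run a named directional scenario against the model's baseline."""
    if scenario not in SCENARIOS:
        raise ModelError(
            f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}"
        )
    cfg = SCENARIOS[scenario]
    base = find_steady_state(model, tol=tol, t_max=t_max)

    params = {
        k: model.parameters[k] * fold for k, fold in cfg["params"].items()
        if k in model.parameters
    }
    state_over = {
        k: base.concentrations[k] * mult for k, mult in cfg["state"].items()
        if k in base.concentrations
    }
    extra = list(state_over)
    pert = find_steady_state(
        model,
        initial={**base.concentrations, **state_over},
        params=params or None,
        extra_clamps=extra,
        tol=tol,
        t_max=t_max,
    )
    assertions = []
    expect = dict(cfg["expect"])
    if not expect:  # null scenario: everything should stay put
        for sid in base.concentrations:
            s = _sign(base.concentrations[sid], pert.concentrations[sid])
            assertions.append({"feature": sid, "expected": "0", "observed": s, "ok": s == "0"})
    for feat, exp in expect.items():
        if feat not in base.concentrations:
            assertions.append({"feature": feat, "expected": exp, "observed": "absent", "ok": False})
            continue
        s = _sign(base.concentrations[feat], pert.concentrations[feat])
        assertions.append({"feature": feat, "expected": exp, "observed": s, "ok": s == exp})
    return QualitativeReport(scenario=scenario, assertions=assertions)


def reference_model() -> ModelSpec:
    """Load the shipped reduced integrated reference model."""
    text = resources.files("stressmet").joinpath("models/reference.yaml").read_text()
    return loads_model(text)
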
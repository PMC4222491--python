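"""Data model for hierarchically regulated metabolic pathways.

A :class:`PathwayModel` combines three layers:

* a metabolic network — :class:`Species` with role ``metabolite`` converted by
  :class:`Reaction` objects, each carrying a :class:`RateLaw` and optionally
  catalysed by an enzyme species;
* a gene-expression layer — :class:`GeneExpressionUnit` objects that synthesise
  one or more enzymes (an operon shares a single mRNA), driven by a
  transcription rate law in a single regulator metabolite, and degraded by the
  sum of a first-order term (dilution ``mu`` plus first-order proteolysis) and
  a zero-order proteolysis term;
* bookkeeping — moiety-conservation sums (e.g. ATP + ADP = C), a partition of
  processes into supply/demand/protein-synthesis(a)/protein-degradation(b)
  blocks, and designations of controlled and manipulated variables.

:func:`assemble_rhs` turns a model into an ODE right-hand side
``dX/dt = N · v(X, E)`` (plus the mRNA/enzyme dynamics) that the solvers in
:mod:`hiersd.dynamics` integrate.  Concentrations and time are in arbitrary
consistent units; boundary species are clamped rather than removed.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import yaml

SCHEMA_VERSION = 1

ROLES = ("metabolite", "enzyme", "mrna")
RATE_LAW_KINDS = (
    "mass_action",
    "irreversible_saturable",
    "hill_inhibited",
    "hill_activated",
    "linear_demand",
    "constant",
)
MODIFIER_EFFECTS = ("inhibitor", "activator")
BLOCK_LABELS = ("supply", "demand", "a", "b")

#: Hard switch below which the zero-order protein degradation term is dropped
#: (degradation cannot consume protein that is not there).  A negative
#: zero-order coefficient represents constant synthesis and is never gated.
ENZYME_GUARD = 1e-12

_GENE_SCALARS = (
    "k_RD",
    "k_Trnl",
    "mu",
    "k_proteolysis1",
    "k_proteolysis0",
    "transcription_scale",
    "synthesis_scale",
    "degradation_scale",
)


class ModelError(ValueError):
    """Raised for malformed or inconsistent model definitions."""


def dilution_rate(doubling_time: float) -> float:
    """Specific growth (dilution) rate ``mu = ln 2 / T`` for doubling time T.

    For steadily growing cells the dominant first-order loss of a stable
    protein is dilution by growth; T in seconds gives mu in 1/s.
    """
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    return math.log(2.0) / doubling_time


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Species:
    """A chemical species: metabolite, enzyme or mRNA.

    ``clamped`` marks boundary species (pathway substrate, external product)
    whose concentration is held fixed by the environment.
    """

    id: str
    role: str = "metabolite"
    initial_value: float = 0.0
    clamped: bool = False


@dataclass
class RateLaw:
    """A kinetic rate law.

    ``kind`` selects the functional form applied to the reaction's substrates:

    ``mass_action``
        ``k * prod(S_i^n_i)``
    ``irreversible_saturable``
        ``k_cat * S / (K_m + S)`` (single substrate)
    ``linear_demand``
        ``k * S`` (single substrate; the canonical demand block)
    ``hill_inhibited`` / ``hill_activated``
        mass action times a Hill regulation factor in the modifier species
    ``constant``
        ``k``

    ``modifiers`` lists ``(species_id, effect)`` pairs; each inhibitor
    contributes ``1/(1+(x/K_I)^h)`` and each activator
    ``(x/K_A)^h/(1+(x/K_A)^h)``.
    """

    kind: str
    parameters: dict[str, float] = field(default_factory=dict)
    modifiers: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Reaction:
    id: str
    rate_law: RateLaw
    substrates: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)
    enzyme: str | None = None
    #: dimensionless process-activity multiplier; perturbing it is the
    #: canonical way control coefficients probe a step's activity.
    activity_scale: float = 1.0


@dataclass
class GeneExpressionUnit:
    """Synthesis and degradation of one or more enzymes (an operon).

    With ``explicit_mrna`` the unit follows two-step dynamics

    ``dR/dt = g_Trsc(x) - k_RD * R``,
    ``dE/dt = k_Trnl * R - k_proteolysis0 - k_ED * E``,

    where ``x`` is the regulator concentration and ``k_ED = mu +
    k_proteolysis1``.  Without it the two steps collapse to
    ``dE/dt = g(x) - k_proteolysis0 - k_ED * E``.  The zero-order proteolysis
    constant doubles as the reference signal r of the control loop.
    """

    id: str
    enzyme_targets: list[str] = field(default_factory=list)
    transcription: RateLaw = field(default_factory=lambda: RateLaw("constant", {"k": 0.0}))
    regulator: str | None = None
    mrna: str | None = None
    explicit_mrna: bool = False
    k_RD: float = 0.0
    k_Trnl: float = 0.0
    mu: float = 0.0
    k_proteolysis1: float = 0.0
    k_proteolysis0: float = 0.0
    transcription_scale: float = 1.0
    synthesis_scale: float = 1.0
    degradation_scale: float = 1.0

    @property
    def k_ED(self) -> float:
        """First-order protein loss: dilution plus first-order proteolysis."""
        return self.mu + self.k_proteolysis1


@dataclass
class Moiety:
    """A conserved sum ``sum_i coeff_i * [species_i] = total``."""

    name: str
    coefficients: dict[str, float] = field(default_factory=dict)
    total: float | None = None


@dataclass
class PathwayModel:
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    gene_units: list[GeneExpressionUnit] = field(default_factory=list)
    moieties: list[Moiety] = field(default_factory=list)
    partition: dict[str, str] = field(default_factory=dict)
    designations: dict[str, list[str]] = field(default_factory=dict)

    # -- lookups ----------------------------------------------------------
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise ModelError(f"unknown species {sid!r}")

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise ModelError(f"unknown reaction {rid!r}")

    def get_gene_unit(self, gid: str) -> GeneExpressionUnit:
        for u in self.gene_units:
            if u.id == gid:
                return u
        raise ModelError(f"unknown gene unit {gid!r}")

    def process_ids(self) -> list[str]:
        """All elementary process identifiers (reactions + gene sub-processes)."""
        out = [r.id for r in self.reactions]
        for u in self.gene_units:
            if u.explicit_mrna:
                out.append(f"{u.id}.transcription")
                out.append(f"{u.id}.mrna_decay")
            out.append(f"{u.id}.synthesis")
            out.append(f"{u.id}.degradation")
        return out

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_value for s in self.species], dtype=float)

    def copy(self) -> "PathwayModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# rate evaluation
# ---------------------------------------------------------------------------


def _hill_factor(x: float, K: float, h: float, effect: str) -> float:
    x = max(x, 0.0)  # guard tiny negative solver excursions
    ratio = (x / K) ** h
    if effect == "inhibitor":
        return 1.0 / (1.0 + ratio)
    return ratio / (1.0 + ratio)


def _modifier_factor(law: RateLaw, conc: Mapping[str, float]) -> float:
    fac = 1.0
    p = law.parameters
    for sid, effect in law.modifiers:
        h = p.get("h", 1.0)
        K = p["K_I"] if effect == "inhibitor" else p["K_A"]
        fac *= _hill_factor(conc[sid], K, h, effect)
    return fac


def reaction_rate(rxn: Reaction, conc: Mapping[str, float]) -> float:
    """Rate of a reaction at the given concentrations (activity scale included)."""
    law = rxn.rate_law
    p = law.parameters
    kind = law.kind
    if kind == "constant":
        base = p["k"]
    elif kind == "irreversible_saturable":
        (sid, _nu), = rxn.substrates
        s = conc[sid]
        base = p["k_cat"] * s / (p["K_m"] + s)
    elif kind == "linear_demand":
        (sid, _nu), = rxn.substrates
        base = p["k"] * conc[sid]
    elif kind in ("mass_action", "hill_inhibited", "hill_activated"):
        base = p["k"] if "k" in p else p["k_cat"]
        for sid, nu in rxn.substrates:
            base *= conc[sid] ** nu
    else:  # pragma: no cover - rejected at load time
        raise ModelError(f"unknown rate-law kind {kind!r}")
    base *= _modifier_factor(law, conc)
    if rxn.enzyme is not None:
        base *= conc[rxn.enzyme]
    return rxn.activity_scale * base


def transcription_rate(unit: GeneExpressionUnit, conc: Mapping[str, float]) -> float:
    """Transcription rate g(x) as a univariate function of the regulator.

    For ``mass_action``/``linear_demand`` kinds g is first order in the
    regulator (g = k*x); ``constant`` ignores it; the Hill kinds apply their
    saturation/repression curve to the regulator.  The unit's
    ``transcription_scale`` is *not* applied here (callers choose).
    """
    law = unit.transcription
    p = law.parameters
    kind = law.kind
    if kind == "constant":
        return p["k"]
    if unit.regulator is None:
        raise ModelError(f"gene unit {unit.id!r}: transcription law {kind!r} needs a regulator")
    x = conc[unit.regulator]
    if kind in ("mass_action", "linear_demand"):
        return p["k"] * x
    if kind == "hill_inhibited":
        return p["k"] * _hill_factor(x, p["K_I"], p.get("h", 1.0), "inhibitor")
    if kind == "hill_activated":
        return p["k"] * _hill_factor(x, p["K_A"], p.get("h", 1.0), "activator")
    raise ModelError(f"unknown rate-law kind {kind!r}")


def _zero_order_term(k0: float, e: float) -> float:
    # positive k0 is saturated proteolysis: switched off when no protein left;
    # negative k0 is a constant synthesis contribution, never gated.
    if k0 > 0.0 and e <= ENZYME_GUARD:
        return 0.0
    return k0


def gene_unit_rates(unit: GeneExpressionUnit, conc: Mapping[str, float]) -> dict[str, float]:
    """Elementary process rates of one gene-expression unit.

    Returns transcription, mrna_decay (explicit-mRNA units only), synthesis
    (per enzyme target, identical), and degradation per enzyme target.
    """
    out: dict[str, float] = {}
    g = unit.transcription_scale * transcription_rate(unit, conc)
    if unit.explicit_mrna:
        r = conc[unit.mrna]
        out["transcription"] = g
        out["mrna_decay"] = unit.k_RD * r
        syn = unit.synthesis_scale * unit.k_Trnl * r
    else:
        syn = unit.synthesis_scale * g
    out["synthesis"] = syn
    for tgt in unit.enzyme_targets:
        e = conc[tgt]
        out[f"degradation:{tgt}"] = unit.degradation_scale * (
            unit.k_ED * e + _zero_order_term(unit.k_proteolysis0, e)
        )
    return out


class RHSEvaluator:
    """Callable ``f(t, y) -> dy/dt`` assembled from a :class:`PathwayModel`.

    Clamped species get derivative zero; moiety conservation holds to machine
    precision by construction because every reaction's stoichiometry respects
    the declared conservation sums.
    """

    def __init__(self, model: PathwayModel):
        self.model = model
        self.ids = model.species_ids()
        self.index = model.species_index()
        self.n = len(self.ids)
        self.clamped = np.array([s.clamped for s in model.species], dtype=bool)
        m = len(model.reactions)
        N = np.zeros((self.n, m))
        for j, rxn in enumerate(model.reactions):
            for sid, nu in rxn.substrates:
                N[self.index[sid], j] -= nu
            for sid, nu in rxn.products:
                N[self.index[sid], j] += nu
        self.N = N
        self.N_dyn = N.copy()
        self.N_dyn[self.clamped, :] = 0.0
        touched = np.abs(N).sum(axis=1) > 0
        for u in model.gene_units:
            if u.explicit_mrna and u.mrna is not None:
                touched[self.index[u.mrna]] = True
            for tgt in u.enzyme_targets:
                touched[self.index[tgt]] = True
        #: species whose derivative can be nonzero (drives the reduced system)
        self.touched = touched

    # -- helpers ----------------------------------------------------------
    def conc(self, y: np.ndarray) -> dict[str, float]:
        return dict(zip(self.ids, y))

    def reaction_rates(self, y: np.ndarray) -> np.ndarray:
        conc = self.conc(y)
        return np.array([reaction_rate(r, conc) for r in self.model.reactions])

    def process_rate(
        self,
        process: str,
        conc: Mapping[str, float],
        enzyme_target: str | None = None,
    ) -> float:
        """Rate of one elementary process (reaction or gene sub-process).

        Gene sub-processes are addressed as ``"<unit>.synthesis"``,
        ``"<unit>.degradation"``, ``"<unit>.transcription"`` and
        ``"<unit>.mrna_decay"``; for multi-enzyme operons ``enzyme_target``
        selects which copy of the (identical-form) degradation process.
        """
        for rxn in self.model.reactions:
            if rxn.id == process:
                return reaction_rate(rxn, conc)
        if "." in process:
            gid, sub = process.rsplit(".", 1)
            unit = self.model.get_gene_unit(gid)
            rates = gene_unit_rates(unit, conc)
            if sub == "degradation":
                tgt = enzyme_target or unit.enzyme_targets[0]
                return rates[f"degradation:{tgt}"]
            if sub in rates:
                return rates[sub]
        raise ModelError(f"unknown process {process!r}")

    def rate_scale(self, y: np.ndarray) -> np.ndarray:
        """Per-species sum of absolute rate contributions.

        Used to express steady-state residuals on the natural scale of each
        balance: a residual of 1e-10 on a balance of O(1e6) opposing terms is
        converged to float precision even though it is not small absolutely.
        """
        conc = self.conc(y)
        v = np.abs(self.reaction_rates(y))
        scale = np.abs(self.N_dyn) @ v
        for u in self.model.gene_units:
            rates = gene_unit_rates(u, conc)
            if u.explicit_mrna:
                i = self.index[u.mrna]
                scale[i] += abs(rates["transcription"]) + abs(rates["mrna_decay"])
            for tgt in u.enzyme_targets:
                i = self.index[tgt]
                scale[i] += abs(rates["synthesis"]) + abs(rates[f"degradation:{tgt}"])
        scale[self.clamped] = 0.0
        return scale

    # -- evaluation -------------------------------------------------------
    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        conc = self.conc(y)
        v = np.array([reaction_rate(r, conc) for r in self.model.reactions])
        dy = self.N_dyn @ v if v.size else np.zeros(self.n)
        for u in self.model.gene_units:
            g = u.transcription_scale * transcription_rate(u, conc)
            if u.explicit_mrna:
                i = self.index[u.mrna]
                r = conc[u.mrna]
                if not self.clamped[i]:
                    dy[i] += g - u.k_RD * r
                syn = u.synthesis_scale * u.k_Trnl * r
            else:
                syn = u.synthesis_scale * g
            for tgt in u.enzyme_targets:
                i = self.index[tgt]
                if self.clamped[i]:
                    continue
                e = conc[tgt]
                deg = u.degradation_scale * (
                    u.k_ED * e + _zero_order_term(u.k_proteolysis0, e)
                )
                dy[i] += syn - deg
        dy[self.clamped] = 0.0
        return dy


def assemble_rhs(model: PathwayModel) -> RHSEvaluator:
    """Build the state-derivative evaluator for a validated model."""
    return RHSEvaluator(model)


# ---------------------------------------------------------------------------
# parameter paths and process activity scales
# ---------------------------------------------------------------------------


def resolve_parameter(model: PathwayModel, path: str) -> tuple[Callable[[], float], Callable[[float], None]]:
    """Return (getter, setter) for a dotted parameter path.

    Supported forms::

        reactions.<id>.activity
        reactions.<id>.<param>            (rate-law parameter)
        reactions.<id>.params.<param>
        gene_units.<id>.<scalar>          (k_RD, k_Trnl, mu, k_proteolysis0, ...)
        gene_units.<id>.transcription.<param>
    """
    tokens = path.split(".")
    try:
        if tokens[0] == "reactions" and len(tokens) >= 3:
            rxn = model.get_reaction(tokens[1])
            rest = tokens[2:]
            if rest == ["activity"]:
                return (lambda: rxn.activity_scale,
                        lambda v: setattr(rxn, "activity_scale", v))
            if rest[0] == "params":
                rest = rest[1:]
            (pname,) = rest
            if pname not in rxn.rate_law.parameters:
                raise ModelError(f"{path}: reaction {rxn.id!r} has no parameter {pname!r}")
            return (lambda: rxn.rate_law.parameters[pname],
                    lambda v: rxn.rate_law.parameters.__setitem__(pname, v))
        if tokens[0] == "gene_units" and len(tokens) >= 3:
            unit = model.get_gene_unit(tokens[1])
            rest = tokens[2:]
            if rest[0] == "transcription":
                sub = rest[1:]
                if sub and sub[0] == "params":
                    sub = sub[1:]
                (pname,) = sub
                if pname not in unit.transcription.parameters:
                    raise ModelError(f"{path}: no transcription parameter {pname!r}")
                return (lambda: unit.transcription.parameters[pname],
                        lambda v: unit.transcription.parameters.__setitem__(pname, v))
            (attr,) = rest
            if attr not in _GENE_SCALARS:
                raise ModelError(f"{path}: unknown gene-unit attribute {attr!r}")
            return (lambda: getattr(unit, attr), lambda v: setattr(unit, attr, v))
    except ModelError:
        raise
    except (ValueError, IndexError) as exc:
        raise ModelError(f"cannot resolve parameter path {path!r}") from exc
    raise ModelError(f"cannot resolve parameter path {path!r}")


def process_activity(model: PathwayModel, process: str) -> tuple[Callable[[], float], Callable[[float], None]]:
    """(getter, setter) for the activity scale of a process.

    Reactions expose ``activity_scale``; gene sub-processes expose the unit's
    transcription/synthesis/degradation scales.
    """
    for rxn in model.reactions:
        if rxn.id == process:
            return (lambda: rxn.activity_scale,
                    lambda v: setattr(rxn, "activity_scale", v))
    if "." in process:
        gid, sub = process.rsplit(".", 1)
        unit = model.get_gene_unit(gid)
        attr = {"transcription": "transcription_scale",
                "synthesis": "synthesis_scale",
                "degradation": "degradation_scale"}.get(sub)
        if attr is not None:
            return (lambda: getattr(unit, attr), lambda v: setattr(unit, attr, v))
    raise ModelError(f"process {process!r} has no activity scale")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _law_to_dict(law: RateLaw) -> dict:
    return {
        "kind": law.kind,
        "params": {k: float(v) for k, v in law.parameters.items()},
        "modifiers": [[sid, eff] for sid, eff in law.modifiers],
    }


def _law_from_dict(d: dict, path: str) -> RateLaw:
    kind = d.get("kind")
    if kind not in RATE_LAW_KINDS:
        raise ModelError(f"{path}.kind: unknown rate-law kind {kind!r}")
    params = {str(k): float(v) for k, v in (d.get("params") or {}).items()}
    for name, value in params.items():
        if name == "h":
            if value <= 0:
                raise ModelError(f"{path}.params.h: Hill coefficient must be > 0, got {value}")
        elif value < 0:
            raise ModelError(f"{path}.params.{name}: negative parameter {value}")
    modifiers = []
    for m in d.get("modifiers") or []:
        sid, eff = m
        if eff not in MODIFIER_EFFECTS:
            raise ModelError(f"{path}.modifiers: unknown effect {eff!r}")
        modifiers.append((str(sid), str(eff)))
    return RateLaw(kind=kind, parameters=params, modifiers=modifiers)


def model_to_dict(model: PathwayModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "species": [
            {"id": s.id, "role": s.role, "initial_value": float(s.initial_value),
             "clamped": bool(s.clamped)}
            for s in model.species
        ],
        "reactions": [
            {"id": r.id,
             "substrates": [[sid, float(nu)] for sid, nu in r.substrates],
             "products": [[sid, float(nu)] for sid, nu in r.products],
             "enzyme": r.enzyme,
             "activity_scale": float(r.activity_scale),
             "rate_law": _law_to_dict(r.rate_law)}
            for r in model.reactions
        ],
        "gene_units": [
            {"id": u.id,
             "enzyme_targets": list(u.enzyme_targets),
             "regulator": u.regulator,
             "mrna": u.mrna,
             "explicit_mrna": bool(u.explicit_mrna),
             "transcription": _law_to_dict(u.transcription),
             "k_RD": float(u.k_RD), "k_Trnl": float(u.k_Trnl),
             "mu": float(u.mu),
             "k_proteolysis1": float(u.k_proteolysis1),
             "k_proteolysis0": float(u.k_proteolysis0)}
            for u in model.gene_units
        ],
        "moieties": [
            {"name": m.name,
             "coefficients": {k: float(v) for k, v in m.coefficients.items()},
             "total": None if m.total is None else float(m.total)}
            for m in model.moieties
        ],
        "partition": dict(model.partition),
        "designations": {k: list(v) for k, v in model.designations.items()},
    }


def model_from_dict(d: dict) -> PathwayModel:
    if d.get("schema_version") != SCHEMA_VERSION:
        raise ModelError(f"unsupported schema_version {d.get('schema_version')!r}")
    species = []
    seen: set[str] = set()
    for i, sd in enumerate(d.get("species") or []):
        sid = str(sd["id"])
        if sid in seen:
            raise ModelError(f"species[{i}]: duplicate id {sid!r}")
        seen.add(sid)
        role = sd.get("role", "metabolite")
        if role not in ROLES:
            raise ModelError(f"species[{i}].role: unknown role {role!r}")
        init = float(sd.get("initial_value", 0.0))
        if init < 0:
            raise ModelError(f"species[{i}].initial_value: negative value {init}")
        species.append(Species(id=sid, role=role, initial_value=init,
                               clamped=bool(sd.get("clamped", False))))
    ids = {s.id: s for s in species}

    def check_ref(sid, path):
        if sid not in ids:
            raise ModelError(f"{path}: unknown species {sid!r}")

    reactions = []
    for i, rd in enumerate(d.get("reactions") or []):
        path = f"reactions[{i}]"
        law = _law_from_dict(rd.get("rate_law") or {}, f"{path}.rate_law")
        subs, prods = [], []
        for key, target in (("substrates", subs), ("products", prods)):
            for pair in rd.get(key) or []:
                sid, nu = str(pair[0]), float(pair[1])
                check_ref(sid, f"{path}.{key}")
                if nu <= 0:
                    raise ModelError(f"{path}.{key}: stoichiometric coefficient must be positive")
                target.append((sid, nu))
        for sid, _eff in law.modifiers:
            check_ref(sid, f"{path}.rate_law.modifiers")
        enzyme = rd.get("enzyme")
        if enzyme is not None:
            check_ref(enzyme, f"{path}.enzyme")
            if ids[enzyme].role != "enzyme":
                raise ModelError(f"{path}.enzyme: species {enzyme!r} does not have role 'enzyme'")
        reactions.append(Reaction(
            id=str(rd["id"]), rate_law=law, substrates=subs, products=prods,
            enzyme=enzyme, activity_scale=float(rd.get("activity_scale", 1.0))))

    gene_units = []
    for i, gd in enumerate(d.get("gene_units") or []):
        path = f"gene_units[{i}]"
        law = _law_from_dict(gd.get("transcription") or {}, f"{path}.transcription")
        targets = [str(t) for t in gd.get("enzyme_targets") or []]
        for t in targets:
            check_ref(t, f"{path}.enzyme_targets")
            if ids[t].role != "enzyme":
                raise ModelError(f"{path}.enzyme_targets: {t!r} is not an enzyme")
        regulator = gd.get("regulator")
        if regulator is not None:
            check_ref(regulator, f"{path}.regulator")
        mrna = gd.get("mrna")
        explicit = bool(gd.get("explicit_mrna", False))
        if explicit:
            if mrna is None:
                raise ModelError(f"{path}.mrna: explicit_mrna unit needs an mrna species")
            check_ref(mrna, f"{path}.mrna")
            if ids[mrna].role != "mrna":
                raise ModelError(f"{path}.mrna: {mrna!r} is not an mrna species")
        unit = GeneExpressionUnit(
            id=str(gd["id"]), enzyme_targets=targets, transcription=law,
            regulator=regulator, mrna=mrna, explicit_mrna=explicit,
            k_RD=float(gd.get("k_RD", 0.0)), k_Trnl=float(gd.get("k_Trnl", 0.0)),
            mu=float(gd.get("mu", 0.0)),
            k_proteolysis1=float(gd.get("k_proteolysis1", 0.0)),
            k_proteolysis0=float(gd.get("k_proteolysis0", 0.0)))
        for attr in ("k_RD", "k_Trnl", "mu", "k_proteolysis1"):
            if getattr(unit, attr) < 0:
                raise ModelError(f"{path}.{attr}: negative rate constant")
        gene_units.append(unit)

    moieties = []
    for i, md in enumerate(d.get("moieties") or []):
        coeffs = {str(k): float(v) for k, v in (md.get("coefficients") or {}).items()}
        for sid in coeffs:
            check_ref(sid, f"moieties[{i}].coefficients")
        total = md.get("total")
        moieties.append(Moiety(name=str(md.get("name", f"moiety{i}")),
                               coefficients=coeffs,
                               total=None if total is None else float(total)))

    partition = {str(k): str(v) for k, v in (d.get("partition") or {}).items()}
    for pid, label in partition.items():
        if label not in BLOCK_LABELS:
            raise ModelError(f"partition[{pid!r}]: unknown block label {label!r}")

    designations = {str(k): [str(x) for x in v]
                    for k, v in (d.get("designations") or {}).items()}
    for key, lst in designations.items():
        for sid in lst:
            check_ref(sid, f"designations.{key}")

    model = PathwayModel(species=species, reactions=reactions,
                         gene_units=gene_units, moieties=moieties,
                         partition=partition, designations=designations)
    known = set(model.process_ids())
    for pid in partition:
        if pid not in known:
            raise ModelError(f"partition: unknown process {pid!r}")
    return model


def save_model(model: PathwayModel) -> str:
    """Canonical, key-sorted YAML rendering (diff-stable round trips)."""
    return yaml.safe_dump(model_to_dict(model), sort_keys=True, default_flow_style=False)


def load_model(config_text: str) -> PathwayModel:
    """Parse and validate a model configuration (YAML, which subsumes JSON)."""
    try:
        data = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ModelError(f"config does not parse: {exc}") from exc
    if not isinstance(data, dict):
        raise ModelError("config must be a mapping")
    return model_from_dict(data)


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------


@dataclass
class Check:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[Check] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks.append(Check(name, bool(passed), detail))


def _moiety_vector(model: PathwayModel, moiety: Moiety) -> np.ndarray:
    idx = model.species_index()
    m = np.zeros(len(model.species))
    for sid, c in moiety.coefficients.items():
        m[idx[sid]] = c
    return m


def validate_model(model: PathwayModel, grid_points: int = 25) -> ValidationReport:
    """Structural and qualitative sanity checks; failures are reported, not raised.

    Checks performed: each declared moiety vector is a left null vector of the
    stoichiometry matrix restricted to non-clamped species; the process
    partition covers every process exactly once; for end-product templates the
    supply intersection function (first-reaction rate times relative enzyme
    abundance) is monotone decreasing and the demand rate monotone increasing
    in the end metabolite, sampled on a grid.
    """
    report = ValidationReport()
    rhs = RHSEvaluator(model)
    free = ~rhs.clamped
    for moiety in model.moieties:
        vec = _moiety_vector(model, moiety)
        if model.reactions:
            resid = float(np.max(np.abs(vec[free] @ rhs.N[free, :])))
        else:
            resid = 0.0
        report.add(f"moiety:{moiety.name}:null_vector", resid < 1e-12,
                   f"max |m.N| = {resid:g}")
        if moiety.total is not None:
            got = float(vec @ model.initial_state())
            report.add(f"moiety:{moiety.name}:total", abs(got - moiety.total) < 1e-9,
                       f"initial sum {got:g} vs declared {moiety.total:g}")

    procs = model.process_ids()
    missing = [p for p in procs if p not in model.partition]
    extra = [p for p in model.partition if p not in procs]
    report.add("partition:complete", not missing and not extra,
               f"missing={missing} unknown={extra}")

    template = match_end_product_template(model)
    if template is not None:
        r1, demand, unit, x_n = template
        conc = rhs.conc(model.initial_state())
        x0 = max(conc.get(x_n, 1.0), 1e-3)
        grid = np.linspace(0.2 * x0, 5.0 * x0, grid_points)

        def supply_curve(x):
            c = dict(conc)
            c[x_n] = x
            g = unit.transcription_scale * transcription_rate(unit, c)
            e1 = unit.synthesis_scale * g / (unit.degradation_scale * unit.k_ED)
            c[r1.enzyme] = e1
            return reaction_rate(r1, c)

        def demand_curve(x):
            c = dict(conc)
            c[x_n] = x
            return reaction_rate(demand, c)

        sup = np.array([supply_curve(x) for x in grid])
        dem = np.array([demand_curve(x) for x in grid])
        report.add("end_product:supply_monotone_decreasing",
                   bool(np.all(np.diff(sup) <= 1e-12)),
                   "f1*g/k_ED sampled on grid")
        report.add("end_product:demand_monotone_increasing",
                   bool(np.all(np.diff(dem) >= -1e-12)),
                   "f_n sampled on grid")
    return report


def match_end_product_template(model: PathwayModel):
    """Detect the end-product template used by the intersection construction.

    Requires a single collapsed (no explicit mRNA) gene unit with pure
    first-order protein degradation, regulating the enzyme of a first reaction
    whose rate depends only on clamped species and the end metabolite, plus an
    enzyme-free demand reaction consuming that metabolite.  Returns
    ``(first_reaction, demand_reaction, unit, x_n)`` or None.
    """
    if len(model.gene_units) != 1:
        return None
    unit = model.gene_units[0]
    if unit.explicit_mrna or unit.k_proteolysis0 != 0 or unit.k_ED <= 0:
        return None
    if unit.regulator is None:
        return None
    x_n = unit.regulator
    sp = {s.id: s for s in model.species}
    if x_n not in sp or sp[x_n].clamped:
        return None
    r1 = None
    for rxn in model.reactions:
        if rxn.enzyme in unit.enzyme_targets:
            r1 = rxn
            break
    if r1 is None:
        return None
    allowed = {sid for sid, s in sp.items() if s.clamped} | {x_n}
    deps = {sid for sid, _ in r1.substrates} | {sid for sid, _ in r1.rate_law.modifiers}
    if not deps <= allowed:
        return None
    demand = None
    for rxn in model.reactions:
        if rxn is r1:
            continue
        if x_n in [sid for sid, _ in rxn.substrates]:
            if model.partition.get(rxn.id) == "demand" or demand is None:
                demand = rxn
    if demand is None or demand.enzyme is not None:
        return None
    ddeps = {sid for sid, _ in demand.substrates} | {sid for sid, _ in demand.rate_law.modifiers}
    if not ddeps <= allowed:
        return None
    return r1, demand, unit, x_n
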
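"""Elasticities, control coefficients, robustness and fragility.

Direct elasticities are scaled local sensitivities of one isolated process
rate to one variable (everything else clamped).  Control coefficients are
scaled steady-state sensitivities of a system flux or concentration to a
process activity; the scope decides what counts as "the system":

``metabolic``
    classical metabolic control analysis — enzyme and mRNA levels frozen at
    their steady values, only the metabolic relaxation responds;
``hierarchical``
    the full model including gene-expression adjustment of enzyme levels;
``local``
    a declared block (supply chain, gene-expression unit, ...) in isolation,
    its boundary species clamped.

Fragility is identical to the (hierarchical) control coefficient; robustness
is its reciprocal, reported as infinite below ``ZERO_TOL``.  Theorem-based
shortcuts for supply-demand systems and local linear chains are provided and
are cross-checked against the numeric route in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    ModelError,
    PathwayModel,
    RHSEvaluator,
    process_activity,
)
from .dynamics import SteadyState, find_steady_state

#: |coefficient| below which fragility counts as zero / robustness as infinite
ZERO_TOL = 1e-8
#: relative log-perturbation for control coefficients
DELTA_CONTROL = 1e-4
#: relative step for elasticity log-differences (Richardson-extrapolated once)
DELTA_ELASTICITY = 1e-5


@dataclass
class ElasticitySet:
    """Collected elasticities: direct (process, variable) and overall (block, variable)."""

    direct: dict[tuple[str, str], float] = field(default_factory=dict)
    overall: dict[tuple[str, str], float] = field(default_factory=dict)
    provenance: str = "numeric"

    def to_frame(self):
        import pandas as pd

        rows = [{"process": p, "variable": v, "elasticity": e, "kind": "direct"}
                for (p, v), e in self.direct.items()]
        rows += [{"process": b, "variable": v, "elasticity": e, "kind": "overall"}
                 for (b, v), e in self.overall.items()]
        return pd.DataFrame(rows)


@dataclass
class CoefficientReport:
    scope: str
    target: str
    entries: dict[str, float] = field(default_factory=dict)
    method: str = "numeric"

    @property
    def fragility(self) -> dict[str, float]:
        return dict(self.entries)

    @property
    def robustness(self) -> dict[str, float]:
        return {p: (math.inf if abs(c) < ZERO_TOL else 1.0 / c)
                for p, c in self.entries.items()}

    def to_dict(self) -> dict:
        rob = {p: (None if math.isinf(r) else r) for p, r in self.robustness.items()}
        return {"scope": self.scope, "target": self.target, "method": self.method,
                "coefficients": self.entries, "fragility": self.fragility,
                "robustness": rob}


# ---------------------------------------------------------------------------
# elasticities
# ---------------------------------------------------------------------------


def _moiety_partners(model: PathwayModel, variable: str) -> list[tuple[str, float]]:
    """Compensating species for a variable bound in moiety-conservation sums.

    Varying a conserved-cycle member only makes sense along the conservation
    (e.g. the demand rate k_d*[ATP] seen as k_d*(C - [ADP])), so for each
    moiety containing the variable one partner absorbs the change: the member
    with the largest coefficient (the variable itself excluded).  Returns
    ``(partner_id, d partner / d variable)`` pairs.
    """
    partners = []
    for moiety in model.moieties:
        if variable not in moiety.coefficients:
            continue
        others = [(sid, c) for sid, c in moiety.coefficients.items() if sid != variable]
        if not others:
            continue
        pid, pc = max(enumerate(others), key=lambda t: (abs(t[1][1]), t[0]))[1]
        partners.append((pid, -moiety.coefficients[variable] / pc))
    return partners


def direct_elasticity(
    model: PathwayModel,
    ss: SteadyState,
    process: str,
    variable: str,
    *,
    enzyme_target: str | None = None,
    rel_step: float = DELTA_ELASTICITY,
    respect_moieties: bool = True,
) -> float:
    """d ln v / d ln x of one isolated process rate at a steady state.

    Central log-difference with all other rate arguments clamped at the
    steady state, Richardson-extrapolated once.  Exact zeros (variable absent
    from the law) come out as exactly 0.  With ``respect_moieties`` the
    variation moves along declared conservation sums (see
    :func:`_moiety_partners`), which is what makes the demand elasticity of a
    conserved cycle come out as ``-X/(C-X)``.
    """
    rhs = RHSEvaluator(model)
    base = dict(ss.state)
    x0 = base.get(variable)
    if x0 is None:
        raise ModelError(f"unknown variable {variable!r}")
    if x0 <= 0:
        raise ModelError(f"elasticity w.r.t. {variable!r} undefined: value {x0:g} at steady state")
    v0 = rhs.process_rate(process, base, enzyme_target)
    if v0 == 0:
        raise ModelError(f"elasticity of {process!r} undefined: zero rate at steady state")
    partners = _moiety_partners(model, variable) if respect_moieties else []

    def at(x: float) -> dict[str, float]:
        c = dict(base)
        c[variable] = x
        for pid, slope in partners:
            c[pid] = base[pid] + slope * (x - x0)
        return c

    def eps(h: float) -> float:
        vp = rhs.process_rate(process, at(x0 * (1.0 + h)), enzyme_target)
        vm = rhs.process_rate(process, at(x0 * (1.0 - h)), enzyme_target)
        if vp == vm:
            return 0.0
        return (math.log(vp) - math.log(vm)) / (math.log1p(h) - math.log1p(-h))

    e1 = eps(rel_step)
    e2 = eps(rel_step / 2.0)
    return (4.0 * e2 - e1) / 3.0


def overall_elasticity(
    eps_direct: float,
    eps_enzyme: float,
    eps_x_synthesis: float,
    eps_e_degradation: float,
    eps_e_synthesis: float = 0.0,
) -> float:
    """Block elasticity including the indirect gene-expression route.

    ``*eps = eps_direct + eps_enzyme * c_a * eps_x_synthesis`` where the local
    control of synthesis over the enzyme level is
    ``c_a = 1/(eps_e_degradation - eps_e_synthesis)``.  ``eps_enzyme`` is the
    elasticity of the block rate w.r.t. the enzyme (1 for rates proportional
    to enzyme concentration).  When the local gene control is singular
    (degradation and synthesis orders equal) the indirect term is infinite and
    ``math.inf`` (signed by the numerator) is returned rather than raising.
    """
    denom = eps_e_degradation - eps_e_synthesis
    numer = eps_enzyme * eps_x_synthesis
    if denom == 0.0:
        if numer == 0.0:
            return eps_direct
        return math.copysign(math.inf, numer)
    return eps_direct + numer / denom


def local_gene_control(eps_e_degradation: float, eps_e_synthesis: float = 0.0) -> float:
    """Local control of the synthesis process over the enzyme level, 1/(eps_b - eps_a)."""
    denom = eps_e_degradation - eps_e_synthesis
    if denom == 0.0:
        return math.inf
    return 1.0 / denom


# ---------------------------------------------------------------------------
# numeric control coefficients
# ---------------------------------------------------------------------------


def _scoped_model(model: PathwayModel, base: SteadyState, scope: str, block) -> PathwayModel:
    work = model.copy()
    for sp in work.species:
        sp.initial_value = base.state[sp.id]
    if scope == "hierarchical":
        return work
    if scope == "metabolic":
        for sp in work.species:
            if sp.role in ("enzyme", "mrna"):
                sp.clamped = True
        return work
    if scope == "local":
        if block is None:
            raise ModelError("local scope needs a block label (or set of labels)")
        labels = {block} if isinstance(block, str) else set(block)
        rhs = RHSEvaluator(work)
        touched_in: set[str] = set()
        touched_out: set[str] = set()
        for rxn in work.reactions:
            tgt = touched_in if work.partition.get(rxn.id) in labels else touched_out
            for sid, _nu in rxn.substrates + rxn.products:
                tgt.add(sid)
        for u in work.gene_units:
            pid = f"{u.id}.synthesis"
            tgt = touched_in if work.partition.get(pid) in labels else touched_out
            for sid in u.enzyme_targets:
                tgt.add(sid)
            if u.explicit_mrna:
                tgt.add(u.mrna)
        for sp in work.species:
            if sp.id not in touched_in or sp.id in touched_out:
                sp.clamped = True
        return work
    raise ModelError(f"unknown scope {scope!r}")


def _target_value(ss: SteadyState, target: str) -> float:
    if target.startswith("flux:"):
        return ss.fluxes[target.split(":", 1)[1]]
    return ss.state[target]


def control_coefficients_numeric(
    model: PathwayModel,
    targets: list[str],
    process: str,
    scope: str = "hierarchical",
    *,
    block=None,
    delta: float = DELTA_CONTROL,
    base: SteadyState | None = None,
) -> dict[str, float]:
    """Control coefficients of several targets w.r.t. one process activity.

    Scales the process activity symmetrically to ``1 - delta`` and
    ``1 + delta``, re-solves the steady state on each side (relaxation from
    the unperturbed state keeps degenerate systems on their physical branch)
    and returns ``d ln(target) / d ln(activity)`` for every target.  Targets
    are species ids or ``"flux:<reaction>"``.
    """
    if base is None:
        base = find_steady_state(model)
    if not base.stable:
        raise RuntimeError("base steady state is not stable")
    work = _scoped_model(model, base, scope, block)
    get, set_ = process_activity(work, process)
    e0 = get()
    sides = {}
    for sign in (-1.0, +1.0):
        set_(e0 * (1.0 + sign * delta))
        try:
            ss = find_steady_state(work, guess=base)
        except Exception as exc:
            raise RuntimeError(
                f"perturbed steady state lost for process {process!r} "
                f"(scope {scope}, side {sign:+g}): {exc}") from exc
        sides[sign] = ss
        set_(e0)
    dln_e = math.log1p(delta) - math.log1p(-delta)
    out: dict[str, float] = {}
    for target in targets:
        vp = _target_value(sides[+1.0], target)
        vm = _target_value(sides[-1.0], target)
        if vp <= 0 or vm <= 0:
            raise ModelError(f"target {target!r} hit zero; coefficient undefined")
        out[target] = (math.log(vp) - math.log(vm)) / dln_e
    return out


def control_coefficient_numeric(
    model: PathwayModel,
    target: str,
    process: str,
    scope: str = "hierarchical",
    *,
    block=None,
    delta: float = DELTA_CONTROL,
    base: SteadyState | None = None,
) -> float:
    """Single-target convenience wrapper around :func:`control_coefficients_numeric`."""
    return control_coefficients_numeric(
        model, [target], process, scope, block=block, delta=delta, base=base)[target]


def coefficient_report(
    model: PathwayModel,
    target: str,
    processes: list[str] | None = None,
    scope: str = "hierarchical",
    *,
    block=None,
    delta: float = DELTA_CONTROL,
) -> CoefficientReport:
    """Control coefficients of one target w.r.t. many processes."""
    base = find_steady_state(model)
    procs = processes if processes is not None else [r.id for r in model.reactions]
    entries = {}
    for p in procs:
        entries[p] = control_coefficient_numeric(
            model, target, p, scope, block=block, delta=delta, base=base)
    return CoefficientReport(scope=scope, target=target, entries=entries)


# ---------------------------------------------------------------------------
# theorem-based shortcuts
# ---------------------------------------------------------------------------


def supply_demand_from_elasticities(eps_s: float, eps_d: float) -> dict[str, float]:
    """The four control coefficients of a supply->X->demand system.

    From the summation and connectivity theorems:
    ``C_s^x = 1/(eps_d - eps_s)``, ``C_d^x = -C_s^x``,
    ``C_s^J = -eps_d/(eps_s - eps_d)``, ``C_d^J = eps_s/(eps_s - eps_d)``.
    """
    if eps_s == eps_d:
        raise ModelError("singular supply-demand system: eps_s == eps_d")
    c_s_x = 1.0 / (eps_d - eps_s)
    c_s_j = -eps_d / (eps_s - eps_d)
    c_d_j = eps_s / (eps_s - eps_d)
    out = {"C_s_x": c_s_x, "C_d_x": -c_s_x, "C_s_J": c_s_j, "C_d_J": c_d_j}
    assert abs(out["C_s_J"] + out["C_d_J"] - 1.0) < 1e-12
    assert abs(out["C_s_x"] + out["C_d_x"]) < 1e-12
    return out


def local_chain_flux_control(elasticity_pairs: list[tuple[float, float]]) -> np.ndarray:
    """Local flux control coefficients of an unbranched chain.

    ``elasticity_pairs[i]`` holds ``(eps_{x_{i+1}}^{v_i}, eps_{x_{i+1}}^{v_{i+1}})``
    for each internal metabolite of the chain; the returned vector of length
    ``len(pairs) + 1`` solves the summation row plus one connectivity row per
    metabolite.  Raises for singular systems, citing the condition number.
    """
    m = len(elasticity_pairs) + 1
    A = np.zeros((m, m))
    b = np.zeros(m)
    A[0, :] = 1.0
    b[0] = 1.0
    for i, (e_lower, e_upper) in enumerate(elasticity_pairs):
        A[i + 1, i] = e_lower
        A[i + 1, i + 1] = e_upper
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise ModelError(f"singular local-chain system (condition number {cond:.3g})")
    c = np.linalg.solve(A, b)
    resid = float(np.max(np.abs(A @ c - b)))
    if resid > 1e-12:
        raise ModelError(f"local-chain solve residual {resid:g} too large")
    return c


def hierarchical_supply_demand_coefficient(
    eps_x_s: float,
    eps_x_d: float,
    eps_es_s: float,
    eps_x_a: float,
    eps_es_a: float,
    eps_es_b: float,
) -> tuple[float, float]:
    """Hierarchical control of the linking metabolite by supply (and demand).

    ``H_s^X = 1 / (eps_X^d - eps_X^s - eps_Es^s * eps_X^a / (eps_Es^b - eps_Es^a))``
    and ``H_d^X = -H_s^X``.  Zero-order enzyme turnover
    (``eps_Es^b = eps_Es^a = 0``) makes the indirect term infinite and the
    control exactly zero: gene expression absorbs the perturbation completely.
    A vanishing denominator is flagged as infinite control rather than raised.
    """
    gene_denom = eps_es_b - eps_es_a
    numer = eps_es_s * eps_x_a
    if gene_denom == 0.0:
        if numer != 0.0:
            return 0.0, 0.0
        indirect = 0.0
    else:
        indirect = numer / gene_denom
    denom = eps_x_d - eps_x_s - indirect
    if denom == 0.0:
        return math.inf, -math.inf
    h_s = 1.0 / denom
    return h_s, -h_s


# ---------------------------------------------------------------------------
# robustness and fragility
# ---------------------------------------------------------------------------


def robustness_and_fragility(
    model: PathwayModel,
    target: str,
    process: str,
    *,
    zero_tol: float = ZERO_TOL,
    base: SteadyState | None = None,
) -> tuple[float, float]:
    """(robustness, fragility) of a target w.r.t. a process activity.

    Fragility equals the hierarchical control coefficient; robustness is its
    reciprocal, +inf when the fragility is numerically zero.
    """
    f = control_coefficient_numeric(model, target, process, "hierarchical", base=base)
    r = math.inf if abs(f) < zero_tol else 1.0 / f
    return r, f
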
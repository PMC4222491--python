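"""Perfect-adaptation, reference-tracking and control-loop classification.

A gene-expression feedback loop behaves like the integral controller of
control engineering exactly insofar as the elasticity of total enzyme
degradation w.r.t. the enzyme concentration vanishes: the loop then keeps
integrating the deviation of the sensed metabolite until the deviation is
gone (perfect adaptation), and the mRNA level tracks the zero-order
proteolysis constant, which plays the role of a reference signal.  With
first-order degradation the integration is leaky and adaptation imperfect.
These experiments make the correspondence quantitative on any model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelError, PathwayModel, RHSEvaluator
from .coefficients import ZERO_TOL, direct_elasticity
from .dynamics import SteadyState, apply_step_perturbation, find_steady_state

#: relative deviation below which a controlled variable counts as perfectly adapted
ADAPT_TOL = 1e-6


@dataclass
class AdaptationReport:
    perturbation: tuple[str, float]
    deviations: dict[str, float]
    controlled_ok: dict[str, bool]
    manipulated_shift: dict[str, float]
    verdict: str
    adapt_tol: float = ADAPT_TOL

    def to_dict(self) -> dict:
        return {
            "perturbation": {"parameter": self.perturbation[0],
                             "relative_change": self.perturbation[1]},
            "deviations": self.deviations,
            "controlled_ok": self.controlled_ok,
            "manipulated_shift": self.manipulated_shift,
            "verdict": self.verdict,
            "adapt_tol": self.adapt_tol,
        }


@dataclass
class TrackingReport:
    reference_path: str
    reference_old: float
    reference_new: float
    tracked_variable: str
    predicted: float          # ideal-integral prediction r/k_Trnl
    predicted_full: float     # (k_ED * E_ss + r)/k_Trnl, an identity at steady state
    achieved: float
    tracking_error: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("reference_path", "reference_old", "reference_new",
                 "tracked_variable", "predicted", "predicted_full",
                 "achieved", "tracking_error")}


@dataclass
class ControlLoopClassification:
    category: str             # ideal_integral | pseudo_integral | direct_only
    eps_e_b: float | None     # degree of integralness (0 = ideal)
    gene_unit: str | None


@dataclass
class LinearDecomposition:
    """Jacobian blocks of the linearized closed loop at a steady state.

    ``proportional`` is the metabolite-by-metabolite block (direct/metabolic
    response with enzyme levels frozen), ``coupling`` the sensitivity of the
    metabolite balances to the enzyme levels, and ``integral_gain`` the
    sensitivity of the gene-expression balances to the metabolites — the gain
    of the integral path.  ``consistency_error`` is the difference between the
    proportional block and an independent enzyme-frozen recomputation.
    """

    metabolites: list[str]
    gene_species: list[str]
    proportional: np.ndarray
    coupling: np.ndarray
    integral_gain: np.ndarray
    gene_block: np.ndarray
    consistency_error: float


# ---------------------------------------------------------------------------


def adaptation_report(
    model: PathwayModel,
    parameter_path: str,
    relative_change: float,
    *,
    adapt_tol: float = ADAPT_TOL,
) -> AdaptationReport:
    """Step a parameter and judge adaptation of the controlled variables."""
    res = apply_step_perturbation(model, parameter_path, relative_change,
                                  include_trajectory=False)
    controlled = model.designations.get("controlled_variables", [])
    manipulated = model.designations.get("manipulated_variables", [])
    if not controlled:
        raise ModelError("model designates no controlled variables")
    ok = {c: bool(abs(res.deviations.get(c, math.inf)) < adapt_tol) for c in controlled}
    verdict = "perfect" if all(ok.values()) else "imperfect"
    return AdaptationReport(
        perturbation=(parameter_path, relative_change),
        deviations=res.deviations,
        controlled_ok=ok,
        manipulated_shift={m: res.deviations.get(m, 0.0) for m in manipulated},
        verdict=verdict,
        adapt_tol=adapt_tol,
    )


def tracking_report(
    model: PathwayModel,
    new_reference_value: float,
    gene_unit: str | None = None,
) -> TrackingReport:
    """Step the reference signal (zero-order proteolysis) and check mRNA tracking.

    An ideal integral loop (k_ED = 0) forces the steady mRNA level to
    ``r / k_Trnl``: the mRNA follows the reference exactly.  With leaky
    integration the mRNA settles at ``(k_ED * E_ss + r) / k_Trnl`` and moves
    less than the reference.
    """
    unit = None
    if gene_unit is not None:
        unit = model.get_gene_unit(gene_unit)
    else:
        for u in model.gene_units:
            if u.k_proteolysis0 > 0:
                unit = u
                break
    if unit is None:
        raise ModelError("no gene unit with a positive zero-order proteolysis "
                         "(reference) constant")
    if not unit.explicit_mrna:
        raise ModelError("reference tracking needs an explicit-mRNA gene unit")
    if unit.k_Trnl <= 0:
        raise ModelError("reference tracking needs k_Trnl > 0")
    path = f"gene_units.{unit.id}.k_proteolysis0"
    r_old = unit.k_proteolysis0
    rc = new_reference_value / r_old - 1.0
    if rc == 0.0:
        pre = find_steady_state(model)
        achieved = pre.state[unit.mrna]
        e_ss = pre.state[unit.enzyme_targets[0]]
    else:
        res = apply_step_perturbation(model, path, rc, include_trajectory=False)
        achieved = res.post.state[unit.mrna]
        e_ss = res.post.state[unit.enzyme_targets[0]]
    predicted = new_reference_value / unit.k_Trnl
    predicted_full = (unit.k_ED * e_ss + new_reference_value) / unit.k_Trnl
    err = abs(achieved - predicted) / abs(predicted)
    return TrackingReport(
        reference_path=path, reference_old=r_old,
        reference_new=new_reference_value,
        tracked_variable=unit.mrna, predicted=predicted,
        predicted_full=predicted_full, achieved=achieved, tracking_error=err)


def classify_control_loop(
    model: PathwayModel,
    gene_unit: str | None = None,
    *,
    zero_tol: float = ZERO_TOL,
    ss: SteadyState | None = None,
) -> ControlLoopClassification:
    """Classify a gene-expression loop by the kinetic order of enzyme degradation.

    The category is decided by the elasticity of total enzyme degradation
    w.r.t. the enzyme at steady state: zero order means the loop is an ideal
    integrator (``ideal_integral``); a positive order on a loop that senses a
    system variable is a leaky, pseudo-integral controller; absence of a
    gene-expression loop acting on a system variable leaves only direct
    (metabolic/proportional) regulation.
    """
    if gene_unit is not None:
        unit = model.get_gene_unit(gene_unit)
    elif model.gene_units:
        unit = model.gene_units[0]
    else:
        return ControlLoopClassification("direct_only", None, None)
    regulator = unit.regulator
    senses_variable = (regulator is not None
                       and not model.get_species(regulator).clamped
                       and regulator not in unit.enzyme_targets
                       and unit.transcription.kind != "constant")
    if not senses_variable:
        return ControlLoopClassification("direct_only", None, unit.id)
    if ss is None:
        ss = find_steady_state(model)
    eps_b = direct_elasticity(model, ss, f"{unit.id}.degradation",
                              unit.enzyme_targets[0])
    category = "ideal_integral" if abs(eps_b) < zero_tol else "pseudo_integral"
    return ControlLoopClassification(category, eps_b, unit.id)


def linear_decomposition(model: PathwayModel, ss: SteadyState | None = None) -> LinearDecomposition:
    """Split the moiety-reduced Jacobian into proportional and integral parts.

    Computed by central finite differences.  The proportional block is also
    recomputed independently with enzyme and mRNA levels frozen; the maximal
    discrepancy between the two routes is returned as ``consistency_error``
    (a self-check of the decomposition, expected below ~1e-8 on well-scaled
    models).
    """
    from .dynamics import _ReducedSystem  # reuse the reduction bookkeeping

    if ss is None:
        ss = find_steady_state(model)
    rhs = RHSEvaluator(model)
    y = ss.as_array(model)
    red = _ReducedSystem(model, rhs, y)
    J = red.jacobian(y[red.free], y)
    roles = {s.id: s.role for s in model.species}
    ids = model.species_ids()
    met_pos = [k for k, i in enumerate(red.free) if roles[ids[i]] == "metabolite"]
    gene_pos = [k for k, i in enumerate(red.free) if roles[ids[i]] != "metabolite"]
    met_ids = [ids[red.free[k]] for k in met_pos]
    gene_ids = [ids[red.free[k]] for k in gene_pos]
    prop = J[np.ix_(met_pos, met_pos)]
    coupling = J[np.ix_(met_pos, gene_pos)]
    gain = J[np.ix_(gene_pos, met_pos)]
    gene_block = J[np.ix_(gene_pos, gene_pos)]

    frozen = model.copy()
    for sp in frozen.species:
        sp.initial_value = ss.state[sp.id]
        if sp.role in ("enzyme", "mrna"):
            sp.clamped = True
    frhs = RHSEvaluator(frozen)
    fred = _ReducedSystem(frozen, frhs, y)
    Jf = fred.jacobian(y[fred.free], y)
    fmet = [k for k, i in enumerate(fred.free) if roles[ids[i]] == "metabolite"]
    order = {ids[fred.free[k]]: k for k in fmet}
    perm = [order[m] for m in met_ids]
    prop_frozen = Jf[np.ix_(perm, perm)]
    err = float(np.max(np.abs(prop - prop_frozen))) if prop.size else 0.0

    return LinearDecomposition(
        metabolites=met_ids, gene_species=gene_ids,
        proportional=prop, coupling=coupling, integral_gain=gain,
        gene_block=gene_block, consistency_error=err)
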
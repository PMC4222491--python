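"""Closed-form analysis of the two-step ATP/ADP module.

The module interconverts ADP and ATP (conserved sum C) through a supply
reaction ``k_s * E * ADP`` catalysed by an enzyme E whose gene expression is
activated by ADP (synthesis ``k_a * ADP``), and a demand reaction
``k_d * (C - ADP)``.  Enzyme degradation is ``k_b * E + k_0`` — a first-order
and a zero-order part.  Everything of interest (steady state, hierarchical
control coefficients, robustness and fragility) has a closed form here, which
makes this module the analytic oracle against which the numeric machinery in
:mod:`hiersd.coefficients` is verified.

Calibration convention: the cell is assumed to need a particular steady ADP
level, so the parameterization fixes ``ADP_ss`` and derives either ``k_0``
(from ``k_a``) or ``k_a`` (from ``k_0``) through the enzyme balance
``k_a * ADP_ss = k_b * E_ss + k_0``.  When sweeping ``k_b`` with ``k_a`` held
fixed the derived ``k_0`` eventually turns negative; a negative zero-order
degradation constant is the same bookkeeping as a constant protein-synthesis
term (the zero-order term can be moved freely between the synthesis and
degradation sides of the enzyme balance), so sweeps admit it explicitly via
``allow_negative_k0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd


class InconsistentParameterizationError(ValueError):
    """The requested (k_s, k_d, k_a, k_b, k_0, C, ADP_ss) set has no steady state."""


@dataclass(frozen=True)
class AtpParams:
    """Parameterization of the ATP module.

    Exactly one of ``k_0`` and ``k_a`` may be None; it is then derived from
    the enzyme balance at the target steady state.  A derived negative ``k_0``
    is rejected unless ``allow_negative_k0`` is set (see module docstring).
    """

    k_s: float = 1.0
    k_d: float = 1.0
    C: float = 1.0
    adp_ss: float = 0.5
    k_b: float = 0.25
    k_a: float | None = 1.0
    k_0: float | None = None
    allow_negative_k0: bool = False


@dataclass(frozen=True)
class AtpSteadyState:
    adp_ss: float
    e_ss: float
    k_a: float
    k_0: float


def atp_steady_state(params: AtpParams) -> AtpSteadyState:
    """Resolve the steady state and the derived rate constant.

    ``E_ss = k_d (C - ADP_ss) / (k_s ADP_ss)`` from the metabolic balance and
    ``k_0 = k_a ADP_ss - k_b E_ss`` (or the inverse for ``k_a``) from the
    enzyme balance.
    """
    p = params
    for name in ("k_s", "k_d", "k_b"):
        if getattr(p, name) < 0:
            raise InconsistentParameterizationError(f"{name} must be non-negative")
    if p.C <= 0:
        raise InconsistentParameterizationError("C must be positive")
    if not 0.0 < p.adp_ss < p.C:
        raise InconsistentParameterizationError(
            f"ADP_ss must lie strictly inside (0, C); got {p.adp_ss} with C={p.C}")
    if p.k_s == 0 or p.k_d == 0:
        raise InconsistentParameterizationError("k_s and k_d must be positive")
    e_ss = p.k_d * (p.C - p.adp_ss) / (p.k_s * p.adp_ss)
    if p.k_0 is None and p.k_a is not None:
        if p.k_a < 0:
            raise InconsistentParameterizationError("k_a must be non-negative")
        k_a = p.k_a
        k_0 = k_a * p.adp_ss - p.k_b * e_ss
        if k_0 < 0 and not p.allow_negative_k0:
            raise InconsistentParameterizationError(
                f"derived k_0 = {k_0:g} < 0; either lower k_b, raise k_a, or "
                "opt in to allow_negative_k0 (constant-synthesis bookkeeping)")
    elif p.k_a is None and p.k_0 is not None:
        k_0 = p.k_0
        k_a = (k_0 + p.k_b * e_ss) / p.adp_ss
        if k_a <= 0:
            raise InconsistentParameterizationError(f"derived k_a = {k_a:g} <= 0")
    elif p.k_a is not None and p.k_0 is not None:
        k_a, k_0 = p.k_a, p.k_0
        gap = k_a * p.adp_ss - p.k_b * e_ss - k_0
        if abs(gap) > 1e-9 * max(1.0, abs(k_0), k_a * p.adp_ss):
            raise InconsistentParameterizationError(
                f"k_a and k_0 both given but inconsistent (enzyme balance off by {gap:g})")
    else:
        raise InconsistentParameterizationError("one of k_a, k_0 must be given")
    return AtpSteadyState(adp_ss=p.adp_ss, e_ss=e_ss, k_a=k_a, k_0=k_0)


def _phi(params: AtpParams, ss: AtpSteadyState) -> float:
    """The dimensionless gene-expression gain ratio k_s ADP^2 k_a / (k_d C k_b)."""
    return params.k_s * ss.adp_ss**2 * ss.k_a / (params.k_d * params.C * params.k_b)


def atp_hierarchical_coefficients(params: AtpParams) -> tuple[float, float]:
    """Hierarchical control of the enzyme level and of the flux by the demand.

    ``H^E = 1 - 1/(1 + phi)`` and ``H^J = 1 - (ADP_ss/C)/(1 + phi)`` with
    ``phi = k_s ADP_ss^2 k_a / (k_d C k_b)``.  Zero-order degradation
    (k_b = 0) is the exact limit (1, 1): the enzyme tracks the demand
    activity perfectly and the flux tracks the perturbation perfectly.
    """
    ss = atp_steady_state(params)
    if params.k_b == 0.0:
        return 1.0, 1.0
    phi = _phi(params, ss)
    h_e = 1.0 - 1.0 / (1.0 + phi)
    h_j = 1.0 - (ss.adp_ss / params.C) / (1.0 + phi)
    return h_e, h_j


def atp_fragility(params: AtpParams) -> tuple[float, float]:
    """Fragility F of the ADP concentration w.r.t. the demand, and robustness 1/F.

    ``F = (C - ADP_ss) / (C + ADP_ss^2 k_s k_a / (k_d k_b))``; zero (infinitely
    robust) when enzyme degradation is zero order, saturating towards the
    ATP/(ADP+ATP) ratio as k_b grows with k_a fixed.
    """
    ss = atp_steady_state(params)
    if params.k_b == 0.0:
        return 0.0, math.inf
    f = (params.C - ss.adp_ss) / (
        params.C + ss.adp_ss**2 * params.k_s * ss.k_a / (params.k_d * params.k_b))
    return f, (math.inf if f == 0 else 1.0 / f)


def atp_half_max_kb(params: AtpParams) -> float:
    """First-order degradation constant at which fragility is half maximal.

    ``k_b(1/2) = (ADP_ss^2 / C) * k_s k_a / k_d`` with k_a held fixed.  At this
    k_b the enzyme-level control H^E equals 1/2.  Self-checks the hyperbolic
    identity to 1e-12.
    """
    if params.k_a is None:
        raise InconsistentParameterizationError("half-max k_b needs k_a fixed")
    kb_half = params.adp_ss**2 / params.C * params.k_s * params.k_a / params.k_d
    p_half = replace(params, k_b=kb_half, k_0=None, allow_negative_k0=True)
    f_half, _ = atp_fragility(p_half)
    f_max = (params.C - params.adp_ss) / params.C
    assert abs(f_half - 0.5 * f_max) < 1e-12 * max(1.0, f_max)
    return kb_half


def atp_elasticities(params: AtpParams) -> dict[str, float]:
    """Direct elasticities of the module at its steady state.

    Supply is first order in both ADP and E (elasticities 1), enzyme synthesis
    is first order in ADP and independent of E, demand has elasticity
    ``-ADP/(C-ADP)`` w.r.t. ADP, and the enzyme-degradation elasticity w.r.t.
    E is ``k_b E / (k_b E + k_0)`` — the quantity whose vanishing defines
    ideal integral control.
    """
    ss = atp_steady_state(params)
    deg = params.k_b * ss.e_ss + ss.k_0
    eps_e_b = 0.0 if params.k_b == 0.0 else params.k_b * ss.e_ss / deg
    return {
        "eps_adp_s": 1.0,
        "eps_adp_a": 1.0,
        "eps_e_s": 1.0,
        "eps_e_a": 0.0,
        "eps_adp_d": -ss.adp_ss / (params.C - ss.adp_ss),
        "eps_e_b": eps_e_b,
    }


def atp_robustness_from_elasticities(params: AtpParams) -> float:
    """Robustness 1/H_d^ADP from the elasticity decomposition.

    ``1/H_d^ADP = C/(C - ADP_ss) + 1/eps_E^b``: the metabolic contribution plus
    the reciprocal kinetic order of enzyme degradation.  Infinite when the
    degradation is zero order.  Must equal the robustness from
    :func:`atp_fragility` exactly (an identity, verified in the test suite to
    1e-12).
    """
    ss = atp_steady_state(params)
    eps = atp_elasticities(params)
    if eps["eps_e_b"] == 0.0:
        return math.inf
    return params.C / (params.C - ss.adp_ss) + 1.0 / eps["eps_e_b"]


def atp_kb_sweep(kb_values, base: AtpParams | None = None, recalibrate: bool = True) -> pd.DataFrame:
    """Evaluate the closed forms over a range of k_b values.

    With ``recalibrate`` (the default, appropriate for sweeps) the target
    ADP_ss and k_a are held and k_0 is re-derived from the enzyme balance at
    each k_b, going negative where the balance requires constant synthesis.
    Without it the base k_0 is kept and k_a is re-derived instead.
    """
    base = base or AtpParams()
    rows = []
    for kb in kb_values:
        if recalibrate:
            p = replace(base, k_b=float(kb), k_0=None, allow_negative_k0=True)
        else:
            k0 = base.k_0 if base.k_0 is not None else atp_steady_state(base).k_0
            p = replace(base, k_b=float(kb), k_a=None, k_0=k0)
        ss = atp_steady_state(p)
        h_e, h_j = atp_hierarchical_coefficients(p)
        f, r = atp_fragility(p)
        rows.append({"k_b": float(kb), "k_a": ss.k_a, "k_0": ss.k_0,
                     "E_ss": ss.e_ss, "F": f, "R": r, "H_E": h_e, "H_J": h_j})
    return pd.DataFrame(rows)
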
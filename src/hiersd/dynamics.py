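"""Time integration, steady-state solving and step-perturbation experiments.

Steady states are found by relaxation (stiff-capable integration until the
scaled residual is small) followed by a root polish, and carry a stability
flag computed from the moiety-reduced Jacobian.  Step perturbations scale one
parameter at a given time and report pre/post steady states together with the
relative deviation of every free species — the raw material for the
adaptation and control-coefficient analyses built on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .model_core import (
    ModelError,
    PathwayModel,
    RHSEvaluator,
    match_end_product_template,
    reaction_rate,
    resolve_parameter,
    transcription_rate,
)

#: steady-state residual tolerance (scaled max-norm, see RHSEvaluator.rate_scale)
TOL_SS = 1e-10
#: relaxation stops and hands over to the root polish below this residual
RELAX_TOL = 1e-6
#: integration budget before declaring non-convergence
T_BUDGET = 1e6
#: eigenvalue real parts below this count as non-positive (neutral modes of
#: degenerate ideal-integral fixtures are tolerated)
STABILITY_TOL = 1e-7


class ConvergenceError(RuntimeError):
    """Steady-state search did not converge within its budget."""


class DivergenceError(RuntimeError):
    """The state diverged (grew without bound) during relaxation."""


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced an inadmissible state."""


@dataclass
class SteadyState:
    state: dict[str, float]
    fluxes: dict[str, float]
    residual_norm: float
    stable: bool
    eigenvalues: np.ndarray | None = None

    def as_array(self, model: PathwayModel) -> np.ndarray:
        return np.array([self.state[sid] for sid in model.species_ids()])


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (time, species)
    species_ids: list[str]
    fluxes: np.ndarray  # (time, reactions)
    reaction_ids: list[str]
    event_times: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times}
        for j, sid in enumerate(self.species_ids):
            data[sid] = self.states[:, j]
        for j, rid in enumerate(self.reaction_ids):
            data[f"flux:{rid}"] = self.fluxes[:, j]
        return pd.DataFrame(data)


@dataclass
class PerturbationResult:
    parameter_path: str
    relative_change: float
    pre: SteadyState
    post: SteadyState
    deviations: dict[str, float]
    trajectory: Trajectory | None = None

    def to_dict(self) -> dict:
        return {
            "parameter_path": self.parameter_path,
            "relative_change": self.relative_change,
            "pre_state": self.pre.state,
            "post_state": self.post.state,
            "deviations": self.deviations,
        }


# ---------------------------------------------------------------------------
# reduced coordinates (clamped species fixed, one species per moiety eliminated)
# ---------------------------------------------------------------------------


class _ReducedSystem:
    def __init__(self, model: PathwayModel, rhs: RHSEvaluator, base: np.ndarray):
        self.rhs = rhs
        idx = model.species_index()
        candidates = [i for i in range(rhs.n) if not rhs.clamped[i] and rhs.touched[i]]
        self.eliminated: list[tuple[int, float, list[tuple[int, float]], float]] = []
        taken: set[int] = set()
        for moiety in model.moieties:
            members = [(idx[sid], c) for sid, c in moiety.coefficients.items()
                       if idx[sid] in candidates and idx[sid] not in taken]
            if not members:
                continue
            # eliminate the member with the largest coefficient (last on ties,
            # which keeps the earlier-declared, usually controlled, species free)
            elim_i, elim_c = max(enumerate(members), key=lambda t: (abs(t[1][1]), t[0]))[1]
            others = [(i, c) for i, c in
                      ((idx[sid], c) for sid, c in moiety.coefficients.items())
                      if i != elim_i]
            total = moiety.total
            if total is None:
                vec = np.zeros(rhs.n)
                for sid, c in moiety.coefficients.items():
                    vec[idx[sid]] = c
                total = float(vec @ base)
            self.eliminated.append((elim_i, elim_c, others, total))
            taken.add(elim_i)
        self.free = [i for i in candidates if i not in taken]
        self.active = sorted(set(self.free) | taken)

    def embed(self, y_red: np.ndarray, base: np.ndarray) -> np.ndarray:
        full = base.copy()
        full[self.free] = y_red
        for elim_i, elim_c, others, total in self.eliminated:
            acc = total
            for j, c in others:
                acc -= c * full[j]
            full[elim_i] = acc / elim_c
        return full

    def residual(self, y_red: np.ndarray, base: np.ndarray) -> np.ndarray:
        full = self.embed(y_red, base)
        return self.rhs(0.0, full)[self.free]

    def scaled_norm(self, y_full: np.ndarray) -> float:
        if not self.active:
            return 0.0
        dy = self.rhs(0.0, y_full)
        scale = np.maximum(self.rhs.rate_scale(y_full), 1.0)
        return float(np.max(np.abs(dy[self.active]) / scale[self.active]))

    def jacobian(self, y_red: np.ndarray, base: np.ndarray) -> np.ndarray:
        n = len(y_red)
        J = np.zeros((n, n))
        for k in range(n):
            h = 1e-6 * max(abs(y_red[k]), 1.0)
            yp = y_red.copy(); yp[k] += h
            ym = y_red.copy(); ym[k] -= h
            J[:, k] = (self.residual(yp, base) - self.residual(ym, base)) / (2 * h)
        return J


def _as_state_array(model: PathwayModel, state) -> np.ndarray:
    if state is None:
        return model.initial_state()
    if isinstance(state, SteadyState):
        return state.as_array(model)
    if isinstance(state, dict):
        return np.array([state[sid] for sid in model.species_ids()])
    arr = np.asarray(state, dtype=float)
    if arr.shape != (len(model.species),):
        raise ModelError(
            f"state vector length {arr.shape} does not match {len(model.species)} species")
    return arr


def _fluxes(model: PathwayModel, rhs: RHSEvaluator, y: np.ndarray) -> dict[str, float]:
    conc = rhs.conc(y)
    return {r.id: reaction_rate(r, conc) for r in model.reactions}


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------


def find_steady_state(
    model: PathwayModel,
    guess=None,
    *,
    tol_ss: float = TOL_SS,
    relax_tol: float = RELAX_TOL,
    t_budget: float = T_BUDGET,
    method: str = "auto",
) -> SteadyState:
    """Locate a steady state by relaxation followed by a root polish.

    ``method`` selects ``"auto"`` (relax until the scaled residual drops below
    ``relax_tol``, then polish), ``"relax"`` (integration only, to ``relax_tol``)
    or ``"newton"`` (root solve straight from the guess).  The stability flag
    reports whether all eigenvalues of the moiety-reduced Jacobian have real
    part below a small tolerance; neutral modes (exact zero eigenvalues of
    degenerate ideal-integral systems) count as stable.
    """
    rhs = RHSEvaluator(model)
    y = _as_state_array(model, guess)
    red = _ReducedSystem(model, rhs, y)
    if not red.free:
        return SteadyState(state={k: float(v) for k, v in rhs.conc(y).items()},
                           fluxes={k: float(v) for k, v in _fluxes(model, rhs, y).items()},
                           residual_norm=red.scaled_norm(y), stable=True,
                           eigenvalues=np.zeros(0))

    if method not in ("auto", "relax", "newton"):
        raise ValueError(f"unknown method {method!r}")

    if method in ("auto", "relax"):
        target = relax_tol if method == "auto" else max(tol_ss, relax_tol)
        t_done, t_chunk = 0.0, 10.0
        history: list[tuple[float, float]] = []
        while red.scaled_norm(y) > target:
            if t_done >= t_budget:
                raise ConvergenceError(
                    f"no convergence within t={t_budget:g}: scaled residual "
                    f"{red.scaled_norm(y):g} > {target:g}")
            # cap the work per chunk: sliding modes at the zero-order
            # degradation switch can otherwise stall the integrator
            budget = [300_000]

            def counted(t, state):
                budget[0] -= 1
                if budget[0] <= 0:
                    raise ConvergenceError(
                        "relaxation stalled: rhs evaluation budget exceeded "
                        f"(scaled residual {red.scaled_norm(state):g})")
                return rhs(t, state)

            sol = solve_ivp(counted, (0.0, t_chunk), y, method="LSODA",
                            rtol=1e-9, atol=1e-12)
            if not sol.success:
                raise IntegrationError(f"relaxation integration failed: {sol.message}")
            y = sol.y[:, -1]
            if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > 1e12:
                raise DivergenceError("state diverged during relaxation")
            t_done += t_chunk
            t_chunk = min(t_chunk * 10.0, 1e5)
            res = red.scaled_norm(y)
            history.append((t_done, res))
            # a residual that has not dropped over a decade of relaxation time
            # signals drift (e.g. a missing sink), not slow convergence
            if t_done >= 1e4:
                ref = max(r for t, r in history if t <= t_done / 10.0)
                if res > 0.5 * ref:
                    raise ConvergenceError(
                        f"relaxation stalled at scaled residual {res:g} "
                        f"(no decade-scale decrease by t={t_done:g})")

    if method in ("auto", "newton"):
        base = y.copy()
        yred = y[red.free]
        sol = root(lambda z: red.residual(z, base), yred, method="lm",
                   options={"xtol": 1e-14, "ftol": 1e-14, "maxiter": 2000})
        y_new = red.embed(sol.x, base)
        if red.scaled_norm(y_new) > tol_ss:
            sol = root(lambda z: red.residual(z, base), yred, method="hybr",
                       options={"xtol": 1e-14})
            y_new = red.embed(sol.x, base)
        if red.scaled_norm(y_new) > tol_ss:
            raise ConvergenceError(
                f"root polish stalled at scaled residual {red.scaled_norm(y_new):g}")
        y = y_new

    residual = red.scaled_norm(y)
    if residual > max(tol_ss, relax_tol):
        raise ConvergenceError(f"residual {residual:g} above tolerance")
    J = red.jacobian(y[red.free], y)
    eig = np.linalg.eigvals(J)
    stable = bool(np.max(eig.real) < STABILITY_TOL) if eig.size else True
    return SteadyState(state={k: float(v) for k, v in rhs.conc(y).items()},
                       fluxes={k: float(v) for k, v in _fluxes(model, rhs, y).items()},
                       residual_norm=residual, stable=stable, eigenvalues=eig)


# ---------------------------------------------------------------------------
# simulation with parameter-step events
# ---------------------------------------------------------------------------


def simulate(
    model: PathwayModel,
    initial_state=None,
    t_end: float = 100.0,
    events: Iterable[tuple[float, str, float]] = (),
    *,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model, applying parameter steps by integrator restart.

    ``events`` is an iterable of ``(t, parameter_path, relative_change)``; at
    each event time the integrator stops, the parameter is scaled by
    ``1 + relative_change`` and integration restarts.  The input model is not
    mutated.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    work = model.copy()
    y = _as_state_array(work, initial_state)
    if np.any(y < 0):
        raise ValueError("initial_state must be non-negative")
    evs = sorted(events, key=lambda e: e[0])
    for t, _p, _rc in evs:
        if not 0.0 < t < t_end:
            raise ValueError(f"event time {t} outside (0, {t_end})")

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    fluxes: list[np.ndarray] = []
    t0 = 0.0
    segments = [(t, (p, rc)) for t, p, rc in evs] + [(t_end, None)]
    for t1, action in segments:
        rhs = RHSEvaluator(work)
        sol = solve_ivp(rhs, (t0, t1), y, method=method, rtol=rtol, atol=atol,
                        dense_output=False)
        if not sol.success:
            raise IntegrationError(f"integration failed at t={sol.t[-1]:g}: {sol.message}")
        seg_states = sol.y.T
        floor = -1e-9 * max(1.0, float(np.max(np.abs(seg_states))))
        if np.min(seg_states) < floor:
            raise IntegrationError(
                f"negative-state excursion {np.min(seg_states):g} beyond tolerance")
        times.append(sol.t)
        states.append(seg_states)
        fluxes.append(np.array([[reaction_rate(r, rhs.conc(row))
                                 for r in work.reactions] for row in seg_states]))
        y = seg_states[-1]
        t0 = t1
        if action is not None:
            path, rc = action
            get, set_ = resolve_parameter(work, path)
            set_(get() * (1.0 + rc))

    return Trajectory(
        times=np.concatenate(times),
        states=np.vstack(states),
        species_ids=work.species_ids(),
        fluxes=np.vstack(fluxes) if model.reactions else np.zeros((0, 0)),
        reaction_ids=[r.id for r in work.reactions],
        event_times=[t for t, _a in segments[:-1]],
    )


# ---------------------------------------------------------------------------
# end-product intersection construction
# ---------------------------------------------------------------------------


def solve_end_product_intersection(model: PathwayModel, bracket=None, xtol: float = 1e-12) -> float:
    """Steady end-metabolite concentration of an end-product template.

    Solves ``f1(x1_bar, x_n) * g(x_n) / k_ED = f_n(x_n)`` — the supply rate
    with the first enzyme at its gene-expression steady level against the
    demand rate — by bracketing and bisection.  Both sides depend only on the
    end metabolite (and clamped boundary species), so when the supply side is
    monotone decreasing and the demand side increasing the root is unique.
    """
    template = match_end_product_template(model)
    if template is None:
        raise ModelError(
            "model does not match the end-product template "
            "(see validate_model for the structural requirements)")
    r1, demand, unit, x_n = template
    rhs = RHSEvaluator(model)
    base = rhs.conc(model.initial_state())

    def gap(x: float) -> float:
        c = dict(base)
        c[x_n] = x
        g = unit.transcription_scale * transcription_rate(unit, c)
        c[r1.enzyme] = unit.synthesis_scale * g / (unit.degradation_scale * unit.k_ED)
        return reaction_rate(r1, c) - reaction_rate(demand, c)

    if bracket is not None:
        lo, hi = bracket
    else:
        lo = 1e-9
        hi = max(2.0 * base.get(x_n, 1.0), 1.0)
        while gap(hi) > 0:
            hi *= 10.0
            if hi > 1e9:
                raise ModelError("no sign change found: supply/demand curves "
                                 "do not intersect (monotonicity violated?)")
    if gap(lo) <= 0 or gap(hi) >= 0:
        raise ModelError(
            f"no sign change in bracket ({lo:g}, {hi:g}); run validate_model "
            "to check the monotonicity assumptions")
    return float(brentq(gap, lo, hi, xtol=xtol))


# ---------------------------------------------------------------------------
# step perturbations
# ---------------------------------------------------------------------------


def apply_step_perturbation(
    model: PathwayModel,
    parameter_path: str,
    relative_change: float,
    t_step: float = 50.0,
    t_end: float | None = None,
    *,
    include_trajectory: bool = True,
) -> PerturbationResult:
    """Step a parameter by a relative amount and compare steady states.

    The pre-perturbation steady state must exist and be stable.  Deviations
    are relative to the pre-perturbation steady state, ``(new - old)/old``.
    """
    if relative_change <= -1.0:
        raise ValueError("relative_change must be > -1 (rates stay non-negative)")
    pre = find_steady_state(model)
    if not pre.stable:
        raise RuntimeError("pre-perturbation steady state is not stable")

    work = model.copy()
    get, set_ = resolve_parameter(work, parameter_path)
    set_(get() * (1.0 + relative_change))
    try:
        post = find_steady_state(work, guess=pre)
    except DivergenceError:
        raise DivergenceError(
            f"post-perturbation state diverged for {parameter_path} "
            f"{relative_change:+.0%}")

    trajectory = None
    if include_trajectory:
        horizon = t_end if t_end is not None else 3.0 * t_step
        trajectory = simulate(model, initial_state=pre, t_end=horizon,
                              events=[(t_step, parameter_path, relative_change)])

    deviations: dict[str, float] = {}
    for sp in model.species:
        if sp.clamped:
            continue
        old = pre.state[sp.id]
        new = post.state[sp.id]
        if old != 0.0:
            deviations[sp.id] = (new - old) / old
        else:
            deviations[sp.id] = 0.0 if new == 0.0 else float("inf")
    return PerturbationResult(parameter_path=parameter_path,
                              relative_change=relative_change,
                              pre=pre, post=post, deviations=deviations,
                              trajectory=trajectory)
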
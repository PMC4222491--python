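"""Built-in, fully parameterized fixture models.

Four regulatory archetypes ship as ready-to-run models:

* :func:`make_atp_module` — the two-step ATP/ADP energy module with
  gene-expression regulation of the supply enzyme;
* :func:`make_end_product_operon` — a linear S -> x1 -> x2 -> x3 -> P pathway
  whose three enzymes sit on one operon repressed by the end product, which
  also inhibits the first enzyme allosterically;
* :func:`make_initial_product_module` — feed-forward activation: the enzyme
  consuming the initial product is gene-activated by that same product;
* :func:`make_leucine_skeleton` — a three-step biosynthetic skeleton
  (pyruvate -> aIPM -> bIPM -> leucine) combining end-product inhibition of
  the committed step with gene-expression activation of the downstream
  enzymes by the first intermediate, and dilution-only enzyme turnover.

All kinetic parameter values here are this package's own synthetic choices,
selected to give stable, strictly positive steady states with O(1)
concentrations; they are not taken from any published model.  Hill forms with
coefficient 2 implement the required monotone regulation without switch-like
steepness.  Every constructor verifies stability and positivity of the
default steady state and stores that steady state as the model's initial
condition.
"""

from __future__ import annotations

import numpy as np

from .atp_oracle import AtpParams, atp_steady_state
from .dynamics import find_steady_state
from .model_core import (
    GeneExpressionUnit,
    ModelError,
    Moiety,
    PathwayModel,
    RateLaw,
    Reaction,
    Species,
)


def _verify(model: PathwayModel, name: str, check: bool = True) -> PathwayModel:
    if not check:
        return model
    try:
        ss = find_steady_state(model)
    except Exception as exc:
        raise ModelError(f"fixture {name!r}: no steady state with these "
                         f"parameters ({exc})") from exc
    if not ss.stable:
        raise ModelError(f"fixture {name!r}: default steady state is unstable")
    for sp in model.species:
        val = ss.state[sp.id]
        if not sp.clamped and val <= 0:
            raise ModelError(f"fixture {name!r}: non-positive steady value "
                             f"{sp.id}={val:g}")
        sp.initial_value = float(val)
    return model


def make_atp_module(
    k_s: float = 1.0,
    k_d: float = 1.0,
    C: float = 1.0,
    k_a: float | None = 1.0,
    k_b: float = 0.25,
    adp_ss: float = 0.5,
    k_0: float | None = None,
    *,
    allow_negative_k0: bool = True,
    check: bool = True,
) -> PathwayModel:
    """Two-step ATP/ADP module with gene-expression regulation of the supply.

    Defaults (k_s = k_d = C = k_a = 1, ADP_ss = 0.5, k_b = 0.25) derive
    k_0 = 0.25 and a steady state (ADP, E) = (0.5, 1).  Setting ``k_b=0``
    yields the ideal-integral variant.  One of ``k_a``/``k_0`` may be None and
    is derived from the enzyme balance; for large k_b the derived k_0 is
    negative (a constant synthesis contribution), which sweeps rely on.
    """
    params = AtpParams(k_s=k_s, k_d=k_d, C=C, adp_ss=adp_ss, k_b=k_b,
                       k_a=k_a, k_0=k_0, allow_negative_k0=allow_negative_k0)
    ss = atp_steady_state(params)
    model = PathwayModel(
        species=[
            Species("ADP", "metabolite", adp_ss),
            Species("ATP", "metabolite", C - adp_ss),
            Species("E", "enzyme", ss.e_ss),
        ],
        reactions=[
            Reaction("supply", RateLaw("mass_action", {"k": k_s}),
                     substrates=[("ADP", 1.0)], products=[("ATP", 1.0)],
                     enzyme="E"),
            Reaction("demand", RateLaw("mass_action", {"k": k_d}),
                     substrates=[("ATP", 1.0)], products=[("ADP", 1.0)]),
        ],
        gene_units=[
            GeneExpressionUnit(
                id="gene_E", enzyme_targets=["E"],
                transcription=RateLaw("mass_action", {"k": ss.k_a}),
                regulator="ADP",
                k_proteolysis1=k_b, k_proteolysis0=ss.k_0),
        ],
        moieties=[Moiety("adenine", {"ADP": 1.0, "ATP": 1.0}, total=C)],
        partition={"supply": "supply", "demand": "demand",
                   "gene_E.synthesis": "a", "gene_E.degradation": "b"},
        designations={"controlled_variables": ["ADP"],
                      "manipulated_variables": ["E"]},
    )
    return _verify(model, "atp", check)


def make_end_product_operon(
    k_ED: float = 0.2,
    *,
    explicit_mrna: bool = True,
    k_proteolysis0: float = 0.5,
    k_cat: tuple[float, float, float] = (1.0, 1.0, 1.0),
    k_dem: float = 1.0,
    S: float = 1.0,
    K_I: float = 1.0,
    h: float = 2.0,
    k_trsc: float = 1.0,
    K_T: float = 1.0,
    h_T: float = 2.0,
    k_RD: float = 1.0,
    k_Trnl: float = 1.0,
    check: bool = True,
) -> PathwayModel:
    """Linear end-product pathway, three enzymes on one operon.

    The end product x3 inhibits the first reaction allosterically (Hill,
    K_I, h) and represses transcription of the shared mRNA (Hill, K_T, h_T).
    ``k_ED`` is the first-order protein loss: 0 gives the ideal-integral
    variant (then x3 = 1, mRNA = 0.5, E = 2 at steady state with the
    defaults); 0.2 and 0.4 give progressively leakier integration.
    """
    species = [
        Species("S", "metabolite", S, clamped=True),
        Species("x1", "metabolite", 0.5),
        Species("x2", "metabolite", 0.5),
        Species("x3", "metabolite", 1.0),
        Species("P", "metabolite", 0.0, clamped=True),
        Species("E1", "enzyme", 2.0),
        Species("E2", "enzyme", 2.0),
        Species("E3", "enzyme", 2.0),
    ]
    if explicit_mrna:
        species.append(Species("mR", "mrna", 0.5))
    reactions = [
        Reaction("r1", RateLaw("hill_inhibited", {"k": k_cat[0], "K_I": K_I, "h": h},
                               modifiers=[("x3", "inhibitor")]),
                 substrates=[("S", 1.0)], products=[("x1", 1.0)], enzyme="E1"),
        Reaction("r2", RateLaw("mass_action", {"k": k_cat[1]}),
                 substrates=[("x1", 1.0)], products=[("x2", 1.0)], enzyme="E2"),
        Reaction("r3", RateLaw("mass_action", {"k": k_cat[2]}),
                 substrates=[("x2", 1.0)], products=[("x3", 1.0)], enzyme="E3"),
        Reaction("demand", RateLaw("linear_demand", {"k": k_dem}),
                 substrates=[("x3", 1.0)], products=[("P", 1.0)]),
    ]
    unit = GeneExpressionUnit(
        id="operon", enzyme_targets=["E1", "E2", "E3"],
        transcription=RateLaw("hill_inhibited", {"k": k_trsc, "K_I": K_T, "h": h_T}),
        regulator="x3",
        mrna="mR" if explicit_mrna else None,
        explicit_mrna=explicit_mrna,
        k_RD=k_RD, k_Trnl=k_Trnl,
        k_proteolysis1=k_ED, k_proteolysis0=k_proteolysis0)
    partition = {"r1": "supply", "r2": "supply", "r3": "supply",
                 "demand": "demand",
                 "operon.synthesis": "a", "operon.degradation": "b"}
    if explicit_mrna:
        partition["operon.transcription"] = "a"
        partition["operon.mrna_decay"] = "b"
    model = PathwayModel(
        species=species, reactions=reactions, gene_units=[unit],
        partition=partition,
        designations={"controlled_variables": ["x3"],
                      "manipulated_variables": ["E1", "E2", "E3"]},
    )
    return _verify(model, "end_product", check)


def make_initial_product_module(
    k_ED: float = 0.2,
    *,
    v0: float = 1.0,
    k_cat: float = 1.0,
    k_dem: float = 1.0,
    k_trsc: float = 0.4,
    K_A: float = 1.0,
    h: float = 2.0,
    check: bool = True,
) -> PathwayModel:
    """Feed-forward activation: E1 consumes x1 and is gene-activated by x1.

    A constant input v0 feeds x1; enzyme E1 (x1 -> x2) is synthesised at rate
    ``k_trsc * (x1/K_A)^h / (1 + (x1/K_A)^h)`` and degraded first order
    (k_ED).  The defaults give the steady state x1 = x2 = E1 = 1.  Although
    wired as feed-forward activation, the loop acts as negative feedback:
    raising E1 depletes x1, which lowers E1 synthesis.
    """
    if k_ED <= 0:
        raise ModelError("initial-product module needs first-order degradation k_ED > 0")
    model = PathwayModel(
        species=[
            Species("S0", "metabolite", 1.0, clamped=True),
            Species("x1", "metabolite", 1.0),
            Species("x2", "metabolite", 1.0),
            Species("P", "metabolite", 0.0, clamped=True),
            Species("E1", "enzyme", 1.0),
        ],
        reactions=[
            Reaction("src", RateLaw("mass_action", {"k": v0}),
                     substrates=[("S0", 1.0)], products=[("x1", 1.0)]),
            Reaction("r1", RateLaw("mass_action", {"k": k_cat}),
                     substrates=[("x1", 1.0)], products=[("x2", 1.0)],
                     enzyme="E1"),
            Reaction("demand", RateLaw("linear_demand", {"k": k_dem}),
                     substrates=[("x2", 1.0)], products=[("P", 1.0)]),
        ],
        gene_units=[
            GeneExpressionUnit(
                id="gene_E1", enzyme_targets=["E1"],
                transcription=RateLaw("hill_activated", {"k": k_trsc, "K_A": K_A, "h": h}),
                regulator="x1", k_proteolysis1=k_ED),
        ],
        partition={"src": "supply", "r1": "demand", "demand": "demand",
                   "gene_E1.synthesis": "a", "gene_E1.degradation": "b"},
        designations={"controlled_variables": ["x1"],
                      "manipulated_variables": ["E1"]},
    )
    return _verify(model, "initial_product", check)


def make_leucine_skeleton(
    mu: float = 1e-2,
    *,
    k_proteolysis0: float = 0.0,
    kcat_u: float = 1.0,
    k1: float = 1.0,
    k2: float = 1.0,
    k_dem: float = 1.0,
    K_I: float = 1.0,
    h: float = 2.0,
    k_trsc: float = 2e-2,
    K_A: float = 1.0,
    h_A: float = 2.0,
    E_u: float = 1.0,
    check: bool = True,
) -> PathwayModel:
    """Simplified leucine-biosynthesis skeleton with feed-forward gene activation.

    Pyruvate (clamped) is converted by the committed enzyme E_u — inhibited by
    the end product leucine — to the intermediate I1 (aIPM), then by E1 to I2
    (bIPM) and by E2 to leucine, which is consumed by a linear demand.  I1
    activates transcription of E1 and E2 (two independent single-enzyme
    units), whose only first-order loss is dilution at rate ``mu``
    (default 1e-2, slow compared with metabolic turnover).  E_u itself is
    constant (clamped).  Parameters are synthetic; they give a stable steady
    state with all concentrations of order one.
    """
    trsc = {"k": k_trsc, "K_A": K_A, "h": h_A}
    model = PathwayModel(
        species=[
            Species("PYR", "metabolite", 1.0, clamped=True),
            Species("I1", "metabolite", 0.83),
            Species("I2", "metabolite", 0.83),
            Species("LEU", "metabolite", 0.68),
            Species("SINK", "metabolite", 0.0, clamped=True),
            Species("E_u", "enzyme", E_u, clamped=True),
            Species("E1", "enzyme", 0.8),
            Species("E2", "enzyme", 0.8),
        ],
        reactions=[
            Reaction("ru", RateLaw("hill_inhibited", {"k": kcat_u, "K_I": K_I, "h": h},
                                   modifiers=[("LEU", "inhibitor")]),
                     substrates=[("PYR", 1.0)], products=[("I1", 1.0)],
                     enzyme="E_u"),
            Reaction("r1", RateLaw("mass_action", {"k": k1}),
                     substrates=[("I1", 1.0)], products=[("I2", 1.0)],
                     enzyme="E1"),
            Reaction("r2", RateLaw("mass_action", {"k": k2}),
                     substrates=[("I2", 1.0)], products=[("LEU", 1.0)],
                     enzyme="E2"),
            Reaction("demand", RateLaw("linear_demand", {"k": k_dem}),
                     substrates=[("LEU", 1.0)], products=[("SINK", 1.0)]),
        ],
        gene_units=[
            GeneExpressionUnit(id="gene_E1", enzyme_targets=["E1"],
                               transcription=RateLaw("hill_activated", dict(trsc)),
                               regulator="I1", mu=mu,
                               k_proteolysis0=k_proteolysis0),
            GeneExpressionUnit(id="gene_E2", enzyme_targets=["E2"],
                               transcription=RateLaw("hill_activated", dict(trsc)),
                               regulator="I1", mu=mu,
                               k_proteolysis0=k_proteolysis0),
        ],
        partition={"ru": "supply", "r1": "demand", "r2": "demand",
                   "demand": "demand",
                   "gene_E1.synthesis": "a", "gene_E1.degradation": "b",
                   "gene_E2.synthesis": "a", "gene_E2.degradation": "b"},
        designations={"controlled_variables": ["I1", "I2"],
                      "manipulated_variables": ["E1", "E2"]},
    )
    return _verify(model, "leucine", check)


FIXTURES = {
    "atp": make_atp_module,
    "atp_integral": lambda **kw: make_atp_module(k_b=0.0, **kw),
    "end_product": make_end_product_operon,
    "end_product_integral": lambda **kw: make_end_product_operon(k_ED=0.0, **kw),
    "initial_product": make_initial_product_module,
    "leucine": make_leucine_skeleton,
}


def list_fixtures() -> list[str]:
    return sorted(FIXTURES)


def get_fixture(name: str, **overrides) -> PathwayModel:
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise ModelError(f"unknown fixture {name!r}; choose from {list_fixtures()}")
    return builder(**overrides)


def randomized_atp_module(seed: int) -> PathwayModel:
    """ATP module with log-uniform parameter multipliers in [0.5, 2].

    Multipliers apply to k_s, k_d and k_b; the target ADP_ss and k_a stay
    fixed and k_0 is re-derived, so the steady state remains by construction.
    Used by property tests; the seed makes draws reproducible.
    """
    rng = np.random.default_rng(seed)
    m = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=3))
    return make_atp_module(k_s=float(m[0]), k_d=float(m[1]), k_b=0.25 * float(m[2]))


def randomized_end_product(seed: int, k_ED: float = 0.2) -> PathwayModel:
    """End-product operon with log-uniform multipliers in [0.5, 2] on the kinetics."""
    rng = np.random.default_rng(seed)
    m = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=5))
    return make_end_product_operon(
        k_ED=k_ED,
        k_cat=(float(m[0]), float(m[1]), float(m[2])),
        k_dem=float(m[3]), k_trsc=float(m[4]))
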
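"""Synthetic desk-scale metabolic models with known engineering targets.

The generated network mimics, at ~15 reactions, the structure that makes
comparative flux sampling informative on a real genome-scale model: a single
carbon source feeds a precursor node from which a biomass branch, a
heterologous product branch and a gene-bearing overflow (degradation) branch
compete.  ATP couples biomass and product synthesis but keeps its own slack
through a free maintenance drain, so the overflow branch is *not* a pure
function of growth — exactly the situation the slow-growth control must
distinguish from biomass-component reactions.

Expected target labels are not hard-coded: :func:`expected_labels` derives
them from flux-variability intervals of the growth and production scenarios
(disjoint intervals imply a forced flux change).
"""

from __future__ import annotations

from dataclasses import dataclass

import cobra
from cobra import Metabolite, Model, Reaction

from .model_prep import MetabolicNetwork
from .scenarios import ConstrainedModel

__all__ = ["ToyGemSpec", "make_toy_gem", "fva_oracle", "expected_labels"]


@dataclass(frozen=True)
class ToyGemSpec:
    """Topology and yields of the synthetic model.

    ``uptake_max`` mmol/gDW/h substrate uptake; each unit of substrate gives
    one precursor and one ATP.  Biomass costs 1 precursor + ``atp_biosyn``
    ATP in precursor assembly + ``atp_growth`` ATP at the growth reaction;
    product costs 1 precursor + 1 ATP.  Optional motifs: an isoenzyme pair on
    glycolysis, a two-reaction futile cycle on the precursor, a gene-less
    dead-end (blocked) reaction, extra linear steps in the uptake pathway.
    """

    uptake_max: float = 10.0
    atp_biosyn: float = 2.0
    atp_growth: float = 0.5
    maintenance_lb: float = 0.1
    n_linear_steps: int = 1
    isoenzyme_pair: bool = False
    futile_cycle: bool = False
    blocked_branch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.uptake_max <= 0:
            raise ValueError("uptake_max must be positive")
        if self.atp_biosyn + self.atp_growth <= 0:
            raise ValueError("biomass must cost ATP (zero yield is infeasible)")
        if self.n_linear_steps < 1:
            raise ValueError("need at least one glycolytic step")


def make_toy_gem(spec: ToyGemSpec = ToyGemSpec()) -> MetabolicNetwork:
    """Build the synthetic network; deterministic for a given spec."""
    m = Model(f"toy_gem_seed{spec.seed}")
    m.compartments = {"c": "cytosol", "e": "extracellular"}

    def met(mid: str) -> Metabolite:
        return Metabolite(mid, compartment=mid.rsplit("_", 1)[-1])

    S_e, S_c = met("S_e"), met("S_c")
    P_c, ATP_c, BM_c = met("P_c"), met("ATP_c"), met("BM_c")
    PRE_c, NAR_c, NAR_e = met("PRE_c"), met("NAR_c"), met("NAR_e")
    W_c, W_e = met("W_c"), met("W_e")

    def rxn(rid, stoich, lb, ub, gpr=""):
        r = Reaction(rid)
        r.bounds = (lb, ub)
        r.add_metabolites(stoich)
        m.add_reactions([r])
        if gpr:
            r.gene_reaction_rule = gpr
        return r

    rxn("EX_S", {S_e: -1}, -spec.uptake_max, 1000.0)
    rxn("T_S", {S_e: -1, S_c: 1}, 0.0, 1000.0, gpr="g_ts")

    # glycolysis: S_c -> P_c + ATP_c, optionally via intermediates
    prev = S_c
    for k in range(spec.n_linear_steps - 1):
        nxt = met(f"I{k + 1}_c")
        rxn(f"GLYC{k + 1}", {prev: -1, nxt: 1}, 0.0, 1000.0, gpr=f"g_glyc{k + 1}")
        prev = nxt
    gpr_last = "g_glyA or g_glyB" if spec.isoenzyme_pair else "g_gly"
    rxn("GLYC", {prev: -1, P_c: 1, ATP_c: 1}, 0.0, 1000.0, gpr=gpr_last)

    # biomass branch
    rxn(
        "BIOSYN",
        {P_c: -1, ATP_c: -spec.atp_biosyn, BM_c: 1},
        0.0,
        1000.0,
        gpr="g_bio",
    )
    rxn("BIOMASS", {BM_c: -1, ATP_c: -spec.atp_growth}, 0.0, 1000.0)
    rxn("ATPM", {ATP_c: -1}, spec.maintenance_lb, 1000.0)

    # product branch
    rxn("PP1", {P_c: -1, PRE_c: 1}, 0.0, 1000.0, gpr="g_pp1")
    rxn("PP2", {PRE_c: -1, ATP_c: -1, NAR_c: 1}, 0.0, 1000.0, gpr="g_pp2")
    rxn("NARt", {NAR_c: -1, NAR_e: 1}, -1000.0, 1000.0, gpr="g_nart")
    rxn("EX_NAR", {NAR_e: -1}, 0.0, 1000.0)

    # overflow / degradation branch competing for the precursor
    rxn("DEG", {P_c: -1, W_c: 1}, 0.0, 1000.0, gpr="g_deg")
    rxn("T_W", {W_c: -1, W_e: 1}, 0.0, 1000.0, gpr="g_tw")
    rxn("EX_W", {W_e: -1}, 0.0, 1000.0)

    if spec.futile_cycle:
        Q_c = met("Q_c")
        rxn("FCF", {P_c: -1, Q_c: 1}, 0.0, 1000.0, gpr="g_fc1")
        rxn("FCB", {Q_c: -1, P_c: 1}, 0.0, 1000.0, gpr="g_fc2")

    if spec.blocked_branch:
        X_c, Y_c = met("X_c"), met("Y_c")
        rxn("ORPH", {X_c: -1, Y_c: 1}, 0.0, 1000.0)  # dead-end, gene-less

    m.objective = "BIOMASS"
    return MetabolicNetwork(
        model=m,
        biomass_reaction_id="BIOMASS",
        maintenance_reaction_ids=["ATPM"],
        product_reaction_id="EX_NAR",
    )


def fva_oracle(cm: ConstrainedModel, tol: float = 1e-9) -> dict[str, tuple[float, float]]:
    """Exact per-reaction flux ranges under a scenario's constraints.

    Independent of the sampler: each reaction is minimised and maximised by a
    dedicated LP on the constrained model (including any total-flux cap held
    in the solver).  Every valid sample must fall inside its interval; the
    box is a relaxation of the polytope, so containment is necessary, not
    sufficient.
    """
    model = cm.model
    ranges: dict[str, tuple[float, float]] = {}
    for rxn in model.reactions:
        vals = []
        for direction in ("min", "max"):
            with model:
                model.objective = rxn.id
                model.objective_direction = direction
                v = model.slim_optimize(error_value=float("nan"))
            if v != v:
                raise RuntimeError(
                    f"FVA oracle infeasible for {rxn.id} in {cm.scenario}"
                )
            vals.append(v)
        ranges[rxn.id] = (vals[0] - tol, vals[1] + tol)
    return ranges


def expected_labels(
    growth: ConstrainedModel,
    production: ConstrainedModel,
    margin: float = 1e-6,
) -> dict[str, str]:
    """Derive expected target directions from scenario FVA intervals.

    A reaction whose production-scenario interval lies strictly above
    (below) its growth-scenario interval in absolute value must increase
    (decrease) to reach the production phenotype: expected over-expression
    (down-regulation).  Overlapping intervals give no expectation.
    """
    g = fva_oracle(growth)
    p = fva_oracle(production)
    labels: dict[str, str] = {}
    for rid in g:
        g_lo, g_hi = g[rid]
        p_lo, p_hi = p[rid]
        if p_lo > g_hi + margin:
            labels[rid] = "over_expression"
        elif p_hi < g_lo - margin:
            labels[rid] = "down_regulation"
    return labels
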
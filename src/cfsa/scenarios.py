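"""Scenario construction: growth, production and slow-growth models.

The three scenarios bracket the phenotypes compared by the workflow:

* **growth** — biomass lower-bounded at ``optimality`` x FBA maximum growth;
  the flux polytope of a well-growing cell.
* **production** — product exchange lower-bounded at ``optimality`` x FBA
  maximum production, plus a parsimonious total-flux cap: the sum of absolute
  fluxes may not exceed ``flux_fraction`` x the pFBA minimum at maximal
  growth.  The cap is a proteome-burden proxy that suppresses futile cycles.
* **slow_growth** — a negative control: biomass is *upper*-bounded at the
  highest growth rate compatible with the required minimal production rate,
  but production itself is left unconstrained during sampling.  Reactions
  whose flux drops in the production scenario merely because growth is slow
  look the same here, which later unmasks them as false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
from optlang.symbolics import Zero

from .model_prep import MetabolicNetwork

__all__ = [
    "ScenarioSpec",
    "ConstrainedModel",
    "InfeasibleScenarioError",
    "optimum_flux",
    "min_total_flux",
    "build_scenario",
    "TOTAL_FLUX_CAP_NAME",
]

SCENARIO_NAMES = ("growth", "production", "slow_growth")
TOTAL_FLUX_CAP_NAME = "total_flux_cap"

#: outward rounding applied to derived bounds so the interior stays non-empty
BOUND_SLACK = 1e-9


class InfeasibleScenarioError(RuntimeError):
    pass


@dataclass
class ScenarioSpec:
    """Parameters defining one sampling scenario.

    ``optimality`` is the fraction of the FBA optimum (growth or production)
    enforced as a lower bound; ``flux_fraction`` (>= 1) scales the pFBA
    minimum total flux into the cap applied in the production and slow-growth
    scenarios.  ``min_production_rate`` (mmol/gDW/h) is the production level
    the slow-growth scenario must remain compatible with; by default it equals
    the minimum production enforced in the production scenario
    (``optimality`` x max production).
    """

    name: str
    optimality: float = 0.9
    flux_fraction: float = 1.25
    min_production_rate: float | None = None

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"scenario name must be one of {SCENARIO_NAMES}")
        if not 0.0 <= self.optimality <= 1.0:
            raise ValueError("optimality must be in [0, 1]")
        if self.flux_fraction < 1.0:
            raise ValueError("flux_fraction must be >= 1")


@dataclass
class ConstrainedModel:
    """A scenario-constrained copy of the network, ready for sampling."""

    network: MetabolicNetwork
    scenario: str
    #: optima and derived bounds actually applied, for the run log
    records: dict[str, float] = field(default_factory=dict)

    @property
    def model(self) -> cobra.Model:
        return self.network.model

    @property
    def total_flux_cap(self) -> float | None:
        return self.records.get("total_flux_cap")


def optimum_flux(net: MetabolicNetwork, reaction_id: str) -> float:
    """FBA maximum of one reaction under the network's current bounds."""
    model = net.model
    with model:
        model.objective = reaction_id
        model.objective_direction = "max"
        value = model.slim_optimize(error_value=float("nan"))
    if value != value:
        raise InfeasibleScenarioError(
            f"FBA maximisation of {reaction_id!r} is infeasible"
        )
    return value


def min_total_flux(
    net: MetabolicNetwork, fixed: dict[str, tuple[float, float]] | None = None
) -> float:
    """Parsimonious minimum of the total absolute flux.

    Minimises sum_r |v_r| subject to the model and the ``fixed`` bound
    overrides (typically biomass fixed at its maximum).  Absolute values are
    linearised through each reaction's nonnegative forward and reverse
    solver variables.
    """
    model = net.model
    with model:
        for rid, bounds in (fixed or {}).items():
            model.reactions.get_by_id(rid).bounds = bounds
        model.objective = model.problem.Objective(Zero, direction="min")
        model.objective.set_linear_coefficients(
            {
                var: 1.0
                for rxn in model.reactions
                for var in (rxn.forward_variable, rxn.reverse_variable)
            }
        )
        value = model.slim_optimize(error_value=float("nan"))
    if value != value:
        raise InfeasibleScenarioError(
            "total-flux minimisation infeasible under the fixed constraints"
        )
    return value


def _add_total_flux_cap(model: cobra.Model, cap: float) -> None:
    expr = Zero
    constraint = model.problem.Constraint(Zero, ub=cap, name=TOTAL_FLUX_CAP_NAME)
    model.add_cons_vars([constraint])
    model.solver.update()
    constraint.set_linear_coefficients(
        {
            var: 1.0
            for rxn in model.reactions
            for var in (rxn.forward_variable, rxn.reverse_variable)
        }
    )


def _assert_feasible(cm: ConstrainedModel) -> None:
    model = cm.model
    with model:
        model.objective = cm.network.biomass_reaction_id
        value = model.slim_optimize(error_value=float("nan"))
    if value != value:
        raise InfeasibleScenarioError(
            f"{cm.scenario} scenario is infeasible after applying derived bounds"
        )


def _diagnose_zero_production(net: MetabolicNetwork) -> str:
    """Name pathway steps unable to carry flux when max production is zero."""
    from cobra.flux_analysis import flux_variability_analysis

    msg = (
        f"maximum production through {net.product_reaction_id!r} is zero; "
        "the pathway cannot carry flux."
    )
    candidates = net.pathway_reaction_ids or []
    if candidates:
        try:
            fva = flux_variability_analysis(
                net.model,
                reaction_list=[
                    r for r in candidates if r in {x.id for x in net.model.reactions}
                ],
                fraction_of_optimum=0.0,
            )
            blocked = [
                rid
                for rid, row in fva.iterrows()
                if abs(row["minimum"]) < 1e-9 and abs(row["maximum"]) < 1e-9
            ]
            if blocked:
                msg += f" Blocked pathway steps: {', '.join(blocked)}."
        except Exception:
            pass
    return msg


def build_scenario(net: MetabolicNetwork, spec: ScenarioSpec) -> ConstrainedModel:
    """Build one scenario-constrained model copy.

    growth: biomass.lb = optimality x max growth, no total-flux cap.
    production: product.lb = optimality x max production; cap =
    flux_fraction x pFBA minimum at maximal growth.  slow_growth: biomass.ub =
    max growth at product >= min_production_rate; product unconstrained; same
    cap.  All optima used are recorded on the returned model.
    """
    max_growth = optimum_flux(net, net.biomass_reaction_id)
    if max_growth <= 0:
        raise InfeasibleScenarioError("model does not grow on the applied medium")

    work = net.copy()
    records: dict[str, float] = {"max_growth": max_growth}

    # outward rounding is only needed when a derived bound sits exactly on
    # the optimum (optimality 1 / flux fraction 1), where it would otherwise
    # leave an empty interior to sample
    lb_slack = BOUND_SLACK if spec.optimality >= 1.0 else 0.0
    cap_slack = BOUND_SLACK if spec.flux_fraction <= 1.0 else 0.0

    if spec.name == "growth":
        lb = spec.optimality * max_growth
        work.biomass_reaction.lower_bound = max(lb - lb_slack, 0.0)
        records["biomass_lower_bound"] = work.biomass_reaction.lower_bound
        cm = ConstrainedModel(network=work, scenario="growth", records=records)
        _assert_feasible(cm)
        return cm

    # production and slow growth share the parsimonious cap, referenced to
    # the minimum total flux compatible with maximal growth
    pfba_min = min_total_flux(
        net, fixed={net.biomass_reaction_id: (max_growth * (1 - 1e-9), 1000.0)}
    )
    cap = spec.flux_fraction * pfba_min + cap_slack
    records["pfba_min_total_flux"] = pfba_min
    records["total_flux_cap"] = cap

    max_production = optimum_flux(net, net.product_reaction_id)
    records["max_production"] = max_production
    if max_production <= 0:
        raise InfeasibleScenarioError(_diagnose_zero_production(net))

    if spec.name == "production":
        lb = spec.optimality * max_production
        work.product_reaction.lower_bound = max(lb - lb_slack, 0.0)
        records["product_lower_bound"] = work.product_reaction.lower_bound
        _add_total_flux_cap(work.model, cap)
        cm = ConstrainedModel(network=work, scenario="production", records=records)
        _assert_feasible(cm)
        return cm

    # slow growth
    min_rate = (
        spec.min_production_rate
        if spec.min_production_rate is not None
        else spec.optimality * max_production
    )
    records["min_production_rate"] = min_rate
    probe = net.copy()
    probe.product_reaction.lower_bound = min_rate
    slow_max_growth = optimum_flux(probe, net.biomass_reaction_id)
    records["biomass_upper_bound"] = slow_max_growth + BOUND_SLACK
    work.biomass_reaction.upper_bound = slow_max_growth + BOUND_SLACK
    _add_total_flux_cap(work.model, cap)
    cm = ConstrainedModel(network=work, scenario="slow_growth", records=records)
    _assert_feasible(cm)
    return cm


def build_all_scenarios(
    net: MetabolicNetwork,
    optimality: float = 0.9,
    flux_fraction: float = 1.25,
    min_production_rate: float | None = None,
) -> dict[str, ConstrainedModel]:
    """Convenience: the three scenario models with shared parameters."""
    return {
        name: build_scenario(
            net,
            ScenarioSpec(
                name=name,
                optimality=optimality,
                flux_fraction=flux_fraction,
                min_production_rate=min_production_rate,
            ),
        )
        for name in SCENARIO_NAMES
    }
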
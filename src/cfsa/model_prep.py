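"""Model loading and preparation.

Everything downstream of this module operates on a :class:`MetabolicNetwork`:
a genome-scale metabolic model (GEM) together with the identity of its biomass
reaction, its maintenance reaction(s) and, once a production pathway has been
chosen, the product exchange reaction.  This module loads the model, applies a
growth medium, inserts a heterologous pathway, screens genes and reactions for
essentiality and assigns every reaction to the seven categories used by the
target filters: *required*, *not_biological*, *blocked*, *no_gene*,
*essential*, *has_essential_gene* and *transport*.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import cobra
from cobra import Metabolite, Reaction
from cobra.flux_analysis import flux_variability_analysis

__all__ = [
    "MetabolicNetwork",
    "MediaSpec",
    "PathwaySpec",
    "PathwayReaction",
    "EssentialityResult",
    "ReactionCategories",
    "ConfigurationError",
    "load_model",
    "apply_media",
    "add_pathway",
    "assess_essentiality",
    "categorize_reactions",
    "parse_equation",
]

CATEGORY_NAMES = (
    "required",
    "not_biological",
    "blocked",
    "no_gene",
    "essential",
    "has_essential_gene",
    "transport",
)

#: default identifiers recognised as non-growth ATP maintenance
DEFAULT_MAINTENANCE_IDS = ("ATPM", "ATPM_c", "r_4046", "RM00001", "NGAM")


class ConfigurationError(ValueError):
    """Raised when a model/config combination cannot be resolved."""


@dataclass
class MetabolicNetwork:
    """A GEM plus the reaction identities the workflow needs.

    Wraps a :class:`cobra.Model`; the stoichiometry, bounds, compartments and
    gene-protein-reaction (GPR) rules live in the wrapped model.
    """

    model: cobra.Model
    biomass_reaction_id: str
    maintenance_reaction_ids: list[str] = field(default_factory=list)
    product_reaction_id: str | None = None
    #: reactions inserted by :func:`add_pathway` (used for diagnostics)
    pathway_reaction_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {r.id for r in self.model.reactions}
        if self.biomass_reaction_id not in ids:
            raise ConfigurationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        for rid in self.maintenance_reaction_ids:
            if rid not in ids:
                raise ConfigurationError(f"maintenance reaction {rid!r} not in model")
        for rxn in self.model.reactions:
            if rxn.lower_bound > rxn.upper_bound:
                raise ConfigurationError(
                    f"reaction {rxn.id}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}"
                )

    @property
    def biomass_reaction(self) -> Reaction:
        return self.model.reactions.get_by_id(self.biomass_reaction_id)

    @property
    def product_reaction(self) -> Reaction:
        if self.product_reaction_id is None:
            raise ConfigurationError("product_reaction_id is not set")
        return self.model.reactions.get_by_id(self.product_reaction_id)

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.model.reactions]

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            model=self.model.copy(),
            biomass_reaction_id=self.biomass_reaction_id,
            maintenance_reaction_ids=list(self.maintenance_reaction_ids),
            product_reaction_id=self.product_reaction_id,
            pathway_reaction_ids=list(self.pathway_reaction_ids),
        )


@dataclass
class MediaSpec:
    """Exchange-reaction bounds defining a growth medium.

    ``bounds`` maps exchange reaction ids to ``(lower, upper)`` in
    mmol/gDW/h (uptake negative by convention).  ``aerobic`` resolves into the
    oxygen exchange bound: ``False`` closes uptake, ``True`` leaves it to the
    listed/current bound.  ``unlisted_uptake`` controls exchanges absent from
    ``bounds``: ``"close"`` (minimal-medium semantics; secretion stays open)
    or ``"keep"`` for models shipped with curated media.
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    aerobic: bool | None = None
    oxygen_exchange_id: str = "EX_o2_e"
    unlisted_uptake: str = "close"  # "close" | "keep"

    def __post_init__(self) -> None:
        for rid, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise ConfigurationError(f"media bound for {rid}: {lb} > {ub}")
        if self.unlisted_uptake not in ("close", "keep"):
            raise ConfigurationError(
                f"unlisted_uptake must be 'close' or 'keep', got {self.unlisted_uptake!r}"
            )


@dataclass
class PathwayReaction:
    id: str
    equation: str
    gpr: str = ""
    name: str = ""


@dataclass
class PathwaySpec:
    """Heterologous pathway: ordered reactions plus new-metabolite declarations.

    ``metabolites`` maps metabolite id -> compartment for species not already
    in the model; undeclared new metabolites get their compartment guessed
    from an ``_c`` / ``[c]`` style suffix.  ``product_exchange_id`` names the
    exchange reaction draining the product (it must be one of ``reactions``).
    """

    reactions: list[PathwayReaction] = field(default_factory=list)
    metabolites: dict[str, str] = field(default_factory=dict)
    product_exchange_id: str | None = None


_ARROWS = (
    ("<=>", True),
    ("<->", True),
    ("↔", True),
    ("-->", False),
    ("->", False),
    ("→", False),
)


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse a reaction equation string into stoichiometry and reversibility.

    Accepts ``-->``, ``->``, ``→`` (irreversible) and ``<=>``, ``<->``, ``↔``
    (reversible) arrows, ``+``-separated terms and decimal coefficients
    (``3.0 MaCoA_c``).  Either side may be empty (exchange/demand reactions).
    Returns ``(stoichiometry, reversible)`` with substrates negative.
    """
    arrow = None
    reversible = False
    for token, rev in _ARROWS:
        if token in equation:
            arrow, reversible = token, rev
            break
    if arrow is None:
        raise ConfigurationError(f"no reaction arrow found in {equation!r}")
    left, right = equation.split(arrow, 1)
    stoich: dict[str, float] = {}

    def _add(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        # split on '+' only when space-surrounded: species names may contain
        # '+' themselves (protons: "H+_c")
        for term in re.split(r"(?:^|\s)\+(?:\s|$)", side):
            term = term.strip()
            if not term:
                raise ConfigurationError(f"empty term in equation {equation!r}")
            m = re.match(r"^(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+(\S.*)$", term)
            if m:
                coeff = float(m.group(1))
                met = m.group(2).strip()
            else:
                coeff, met = 1.0, term
            if coeff <= 0:
                raise ConfigurationError(f"non-positive coefficient in {equation!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    _add(left, -1.0)
    _add(right, +1.0)
    # species on both sides cancel; drop exact zeros
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise ConfigurationError(f"equation {equation!r} has no net stoichiometry")
    return stoich, reversible


def strip_compartment(met_id: str, compartment: str | None = None) -> str:
    """Base metabolite id with its compartment tag removed.

    Handles ``glc__D_c``, ``glc__D[c]`` and, when ``compartment`` is given,
    arbitrary ``<base>_<compartment>`` / ``<base>[<compartment>]`` suffixes.
    """
    if compartment:
        for suffix in (f"_{compartment}", f"[{compartment}]"):
            if met_id.endswith(suffix):
                return met_id[: -len(suffix)]
    m = re.match(r"^(.*)\[[^\[\]]+\]$", met_id)
    if m:
        return m.group(1)
    m = re.match(r"^(.*)_[a-zA-Z0-9]{1,3}$", met_id)
    if m:
        return m.group(1)
    return met_id


def _guess_compartment(met_id: str) -> str:
    m = re.match(r"^.*\[([^\[\]]+)\]$", met_id)
    if m:
        return m.group(1)
    m = re.match(r"^.*_([a-zA-Z0-9]{1,3})$", met_id)
    if m:
        return m.group(1)
    return "c"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def load_model(
    path: str,
    format: str | None = None,
    biomass_reaction_id: str | None = None,
    maintenance_reaction_ids: Iterable[str] | None = None,
) -> MetabolicNetwork:
    """Load an SBML (Level 3 FBC) or constraint-model JSON file.

    The biomass reaction is taken from ``biomass_reaction_id`` when given,
    otherwise from the model's objective annotation; failing both is a
    configuration error.  Maintenance reactions default to common
    ATP-maintenance ids present in the model.
    """
    if format is None:
        format = "json" if str(path).endswith(".json") else "sbml"
    if format == "sbml":
        model = cobra.io.read_sbml_model(str(path))
    elif format == "json":
        model = cobra.io.load_json_model(str(path))
    else:
        raise ConfigurationError(f"unknown model format {format!r}")

    if biomass_reaction_id is None:
        objective_rxns = [
            r.id for r in model.reactions if r.objective_coefficient != 0
        ]
        if len(objective_rxns) != 1:
            raise ConfigurationError(
                "cannot resolve biomass reaction: no biomass_reaction_id given "
                f"and model objective names {len(objective_rxns)} reactions"
            )
        biomass_reaction_id = objective_rxns[0]

    if maintenance_reaction_ids is None:
        model_ids = {r.id for r in model.reactions}
        maintenance_reaction_ids = [
            rid for rid in DEFAULT_MAINTENANCE_IDS if rid in model_ids
        ]

    return MetabolicNetwork(
        model=model,
        biomass_reaction_id=biomass_reaction_id,
        maintenance_reaction_ids=list(maintenance_reaction_ids),
    )


def save_model(net: MetabolicNetwork, path: str) -> None:
    """Write the (curated) model back out for provenance (SBML or JSON)."""
    if str(path).endswith(".json"):
        cobra.io.save_json_model(net.model, str(path))
    else:
        cobra.io.write_sbml_model(net.model, str(path))


def apply_media(net: MetabolicNetwork, media: MediaSpec) -> MetabolicNetwork:
    """Return a copy of the network with medium bounds applied.

    Listed exchange bounds are assigned verbatim.  Unlisted boundary reactions
    have their uptake (lower bound) closed to zero under the default
    ``"close"`` policy; secretion is never touched.  The ``aerobic`` flag
    overrides the oxygen exchange lower bound (0 when anaerobic).
    """
    out = net.copy()
    model = out.model
    boundary_ids = {r.id for r in model.boundary}
    for rid in media.bounds:
        if rid not in boundary_ids:
            raise ConfigurationError(
                f"media id {rid!r} is not an exchange/boundary reaction of the model"
            )
    if media.unlisted_uptake == "close":
        for rxn in model.boundary:
            if rxn.id not in media.bounds:
                rxn.lower_bound = max(rxn.lower_bound, 0.0)
    for rid, (lb, ub) in media.bounds.items():
        model.reactions.get_by_id(rid).bounds = (lb, ub)
    if media.aerobic is False and media.oxygen_exchange_id in boundary_ids:
        model.reactions.get_by_id(media.oxygen_exchange_id).lower_bound = 0.0
    return out


def add_pathway(net: MetabolicNetwork, pathway: PathwaySpec) -> MetabolicNetwork:
    """Return a copy of the network with the heterologous pathway inserted.

    New metabolites are created from the declarations (or from compartment
    suffixes), reactions are appended with their GPRs and bounds follow the
    equation arrow (reversible: -1000..1000, irreversible: 0..1000).  When
    ``product_exchange_id`` is declared the returned network has
    ``product_reaction_id`` set.
    """
    out = net.copy()
    model = out.model
    existing = {r.id for r in model.reactions}
    for prxn in pathway.reactions:
        if prxn.id in existing:
            raise ConfigurationError(f"duplicate reaction id {prxn.id!r}")
    for prxn in pathway.reactions:
        stoich, reversible = parse_equation(prxn.equation)
        rxn = Reaction(prxn.id, name=prxn.name or prxn.id)
        rxn.bounds = (-1000.0, 1000.0) if reversible else (0.0, 1000.0)
        met_map: dict[Metabolite, float] = {}
        for met_id, coeff in stoich.items():
            if met_id in model.metabolites:
                met = model.metabolites.get_by_id(met_id)
            else:
                comp = pathway.metabolites.get(met_id, _guess_compartment(met_id))
                met = Metabolite(met_id, compartment=comp)
            met_map[met] = coeff
        rxn.add_metabolites(met_map)
        model.add_reactions([rxn])
        if prxn.gpr:
            rxn.gene_reaction_rule = prxn.gpr
        out.pathway_reaction_ids.append(prxn.id)
    if pathway.product_exchange_id is not None:
        if pathway.product_exchange_id not in {r.id for r in model.reactions}:
            raise ConfigurationError(
                f"product exchange {pathway.product_exchange_id!r} not among "
                "pathway or model reactions"
            )
        out.product_reaction_id = pathway.product_exchange_id
    return out


@dataclass
class EssentialityResult:
    essential_genes: set[str]
    essential_reactions: set[str]
    wild_type_growth: float
    growth_cutoff_fraction: float


def _knockout_growth_gene(model: cobra.Model, gene_id: str) -> float:
    with model:
        model.genes.get_by_id(gene_id).knock_out()
        value = model.slim_optimize(error_value=float("nan"))
    return 0.0 if value != value else value  # NaN (infeasible) counts as no growth


def _knockout_growth_reaction(model: cobra.Model, rxn_id: str) -> float:
    with model:
        model.reactions.get_by_id(rxn_id).bounds = (0.0, 0.0)
        value = model.slim_optimize(error_value=float("nan"))
    return 0.0 if value != value else value


def assess_essentiality(
    net: MetabolicNetwork, growth_cutoff_fraction: float = 0.01
) -> EssentialityResult:
    """Single-deletion essentiality screen for genes and reactions.

    A gene is essential iff knocking it out (GPR rules evaluated with the gene
    set to false; reactions whose rule becomes false get zero bounds) drops
    the FBA growth maximum below ``growth_cutoff_fraction`` x wild type.  A
    reaction is essential iff forcing its bounds to zero does the same.
    Results do not depend on gene order (each deletion is independent).
    """
    model = net.model
    with model:
        model.objective = net.biomass_reaction_id
        wild_type = model.slim_optimize(error_value=float("nan"))
    if wild_type != wild_type or wild_type <= 0:
        raise ConfigurationError(
            "wild-type model does not grow on the applied medium; "
            "essentiality is undefined"
        )
    cutoff = growth_cutoff_fraction * wild_type

    with model:
        model.objective = net.biomass_reaction_id
        essential_genes = {
            g.id for g in model.genes if _knockout_growth_gene(model, g.id) < cutoff
        }
        essential_reactions = {
            r.id
            for r in model.reactions
            if _knockout_growth_reaction(model, r.id) < cutoff
        }
    return EssentialityResult(
        essential_genes=essential_genes,
        essential_reactions=essential_reactions,
        wild_type_growth=wild_type,
        growth_cutoff_fraction=growth_cutoff_fraction,
    )


@dataclass
class ReactionCategories:
    """Category sets per reaction id; every model reaction is a key."""

    categories: dict[str, set[str]]

    def of(self, rxn_id: str) -> set[str]:
        return self.categories[rxn_id]

    def never_target(self, rxn_id: str) -> bool:
        """Reactions excluded from targeting outright."""
        cats = self.categories[rxn_id]
        return bool(cats & {"required", "not_biological", "blocked", "no_gene"})


def _is_transport(rxn: Reaction) -> bool:
    base_by_comp: dict[str, set[str]] = {}
    for met in rxn.metabolites:
        base = strip_compartment(met.id, met.compartment)
        base_by_comp.setdefault(base, set()).add(met.compartment)
    return any(len(comps) >= 2 for comps in base_by_comp.values())


def categorize_reactions(
    net: MetabolicNetwork,
    essentials: EssentialityResult,
    blocked_tol: float = 1e-9,
) -> ReactionCategories:
    """Assign the seven filter categories to every reaction.

    required: biomass + maintenance; not_biological: boundary (exchange, sink,
    demand); blocked: FVA min = max = 0 under the current medium; no_gene:
    empty GPR; essential / has_essential_gene from the essentiality screen;
    transport: same base metabolite in two or more compartments.
    """
    model = net.model
    cats: dict[str, set[str]] = {r.id: set() for r in model.reactions}

    cats[net.biomass_reaction_id].add("required")
    for rid in net.maintenance_reaction_ids:
        cats[rid].add("required")
    for rxn in model.boundary:
        cats[rxn.id].add("not_biological")

    with model:
        model.objective = net.biomass_reaction_id
        fva = flux_variability_analysis(model, fraction_of_optimum=0.0)
    for rid, row in fva.iterrows():
        if abs(row["minimum"]) < blocked_tol and abs(row["maximum"]) < blocked_tol:
            cats[rid].add("blocked")

    for rxn in model.reactions:
        if not rxn.genes:
            cats[rxn.id].add("no_gene")
        if rxn.id in essentials.essential_reactions:
            cats[rxn.id].add("essential")
        if any(g.id in essentials.essential_genes for g in rxn.genes):
            cats[rxn.id].add("has_essential_gene")
        if _is_transport(rxn):
            cats[rxn.id].add("transport")

    return ReactionCategories(categories=cats)
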
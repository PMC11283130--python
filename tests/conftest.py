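"""Shared fixtures: one toy network, its scenarios and one sampled triple.

The expensive pieces (essentiality screen, scenario LPs, sampling) are
session-scoped; tests must treat them as read-only and copy before mutating.
"""

from __future__ import annotations

import numpy as np
import pytest

from cfsa.analysis import compare_scenarios
from cfsa.model_prep import assess_essentiality, categorize_reactions
from cfsa.sampling import (
    convergence_filter,
    familywise_z_threshold,
    sample_scenario,
    validate_samples,
)
from cfsa.scenarios import build_all_scenarios
from cfsa.toys import ToyGemSpec, make_toy_gem

SAMPLE_N = 1000
SAMPLE_THINNING = 10
SAMPLE_SEED = 11


@pytest.fixture(scope="session")
def toy_net():
    return make_toy_gem(ToyGemSpec())


@pytest.fixture(scope="session")
def toy_essentials(toy_net):
    return assess_essentiality(toy_net)


@pytest.fixture(scope="session")
def toy_categories(toy_net, toy_essentials):
    return categorize_reactions(toy_net, toy_essentials)


@pytest.fixture(scope="session")
def scenario_models(toy_net):
    return build_all_scenarios(toy_net)


@pytest.fixture(scope="session")
def sampled_triple(scenario_models):
    """Validated, convergence-screened SampleSets for the three scenarios."""
    n_rxn = len(scenario_models["growth"].model.reactions)
    z_cut = familywise_z_threshold(n_rxn * 3)
    out = {}
    for name, cm in scenario_models.items():
        ss = sample_scenario(
            cm, n_samples=SAMPLE_N, thinning=SAMPLE_THINNING, seed=SAMPLE_SEED
        )
        ss = validate_samples(ss, cm)
        out[name] = convergence_filter(ss, z_threshold=z_cut)
    return out


@pytest.fixture(scope="session")
def toy_comparisons(sampled_triple, toy_net):
    return compare_scenarios(
        sampled_triple["growth"],
        sampled_triple["production"],
        sampled_triple["slow_growth"],
        toy_net.biomass_reaction_id,
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def ecdf_sup_distance(a, b) -> float:
    """Brute-force two-sample KS statistic: sup |ECDF_a - ECDF_b| over all
    observed breakpoints."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.abs(fa - fb).max())


def eval_gpr(rule: str, deleted: set[str]) -> bool:
    """Boolean GPR evaluation with deleted genes set to false.

    Independent of cobra's GPR machinery: gene ids are substituted into the
    and/or expression and evaluated as Python booleans.  An empty rule means
    the reaction needs no gene (always active).
    """
    if not rule.strip():
        return True
    tokens = rule.replace("(", " ( ").replace(")", " ) ").split()
    expr = " ".join(
        tok
        if tok in ("and", "or", "(", ")")
        else ("False" if tok in deleted else "True")
        for tok in tokens
    )
    return bool(eval(expr))  # noqa: S307 - tokens restricted to booleans/operators


def linprog_optimum(model, objective_id: str, sense: str = "max", extra_bounds=None):
    """LP optimum of one reaction flux via scipy.linprog (independent of
    cobra's solver path): maximise/minimise c.v s.t. S.v = 0 and bounds."""
    from cobra.util.array import create_stoichiometric_matrix
    from scipy.optimize import linprog

    S = create_stoichiometric_matrix(model)
    rxns = list(model.reactions)
    bounds = [(r.lower_bound, r.upper_bound) for r in rxns]
    if extra_bounds:
        for rid, bd in extra_bounds.items():
            bounds[[r.id for r in rxns].index(rid)] = bd
    c = np.zeros(len(rxns))
    c[[r.id for r in rxns].index(objective_id)] = -1.0 if sense == "max" else 1.0
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs"
    )
    if not res.success:
        return None
    return -res.fun if sense == "max" else res.fun
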
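"""Flux sampling, sample validation and convergence screening.

Samples are drawn with cobrapy's OptGP sampler (a parallel artificially
centred hit-and-run variant).  Each retained sample must satisfy steady
state, the reaction bounds and every scenario-derived constraint; rows that
do not are discarded.  Per-reaction chains are then screened for
stationarity with the Geweke diagnostic, and non-converged reactions are
excluded from the downstream comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra.sampling import OptGPSampler
from cobra.util.array import create_stoichiometric_matrix

from .scenarios import ConstrainedModel

__all__ = [
    "SampleSet",
    "sample_scenario",
    "validate_samples",
    "geweke_z",
    "convergence_filter",
    "familywise_z_threshold",
]

STEADY_STATE_TOL = 1e-6
CONSTRAINT_TOL = 1e-6
GEWEKE_FIRST_FRAC = 0.1
GEWEKE_LAST_FRAC = 0.5
GEWEKE_Z_THRESHOLD = 1.96


@dataclass
class SampleSet:
    """Sampled fluxes for one scenario.

    ``fluxes`` is n_samples x n_reactions (mmol/gDW/h), columns in model
    reaction order.  ``valid`` flags rows that passed constraint replay;
    ``geweke_z`` / ``converged`` are per-reaction chain diagnostics.
    """

    scenario: str
    fluxes: pd.DataFrame
    seed: int
    thinning: int
    processes: int = 1
    valid: np.ndarray | None = None
    geweke_z: pd.Series | None = None
    converged: pd.Series | None = None
    n_discarded: int = 0

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.fluxes.columns)

    def valid_fluxes(self) -> pd.DataFrame:
        if self.valid is None:
            return self.fluxes
        return self.fluxes.loc[self.valid]

    def converged_reactions(self) -> list[str]:
        if self.converged is None:
            return self.reaction_ids
        return list(self.converged.index[self.converged])


def sample_scenario(
    cm: ConstrainedModel,
    n_samples: int = 10_000,
    thinning: int = 100,
    seed: int = 0,
    processes: int = 1,
) -> SampleSet:
    """Draw ``n_samples`` flux vectors from the scenario polytope.

    Keeps every ``thinning``-th hit-and-run step to decorrelate samples.
    Reruns with identical inputs and ``processes=1`` are bitwise identical;
    with more processes each chain is seeded deterministically from ``seed``
    by the sampler.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    try:
        sampler = OptGPSampler(
            cm.model, thinning=thinning, processes=processes, seed=seed
        )
        fluxes = sampler.sample(n_samples)
    except Exception as exc:  # pragma: no cover - solver-dependent message
        raise RuntimeError(f"sampling failed in scenario {cm.scenario!r}: {exc}") from exc
    return SampleSet(
        scenario=cm.scenario,
        fluxes=fluxes,
        seed=seed,
        thinning=thinning,
        processes=processes,
    )


def validate_samples(
    ss: SampleSet, cm: ConstrainedModel, tol: float = CONSTRAINT_TOL
) -> SampleSet:
    """Replay every constraint against every sample and drop violators.

    Checks, independently of the sampler: steady state (|S.v|_inf <= tol),
    the reaction bounds of the constrained model (which already carry the
    optimality bound and the slow-growth cap) and, when present, the total
    absolute-flux cap.  All rows invalid is a hard error.
    """
    model = cm.model
    S = create_stoichiometric_matrix(model)
    order = [r.id for r in model.reactions]
    V = ss.fluxes[order].to_numpy()

    ok = np.abs(S @ V.T).max(axis=0) <= tol
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    ok &= (V >= lb - tol).all(axis=1) & (V <= ub + tol).all(axis=1)
    cap = cm.total_flux_cap
    if cap is not None:
        ok &= np.abs(V).sum(axis=1) <= cap + tol

    if not ok.any():
        raise RuntimeError(
            f"all {len(ok)} samples violate the {cm.scenario!r} constraints; "
            "sampler or scenario construction is broken"
        )
    return SampleSet(
        scenario=ss.scenario,
        fluxes=ss.fluxes,
        seed=ss.seed,
        thinning=ss.thinning,
        processes=ss.processes,
        valid=ok,
        geweke_z=ss.geweke_z,
        converged=ss.converged,
        n_discarded=int((~ok).sum()),
    )


def geweke_z(
    chain: np.ndarray,
    first_frac: float = GEWEKE_FIRST_FRAC,
    last_frac: float = GEWEKE_LAST_FRAC,
) -> float:
    """Geweke stationarity z-score for one ordered chain.

    Compares the mean of the first ``first_frac`` of the chain against the
    mean of the last ``last_frac``: z = (m1 - m2) / sqrt(se1^2 + se2^2) with
    each segment's squared standard error taken as its sample variance over
    its length (chains are pre-thinned, so no spectral correction is
    applied).  A constant chain returns 0 by convention.
    """
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n < 20:
        raise ValueError("chain too short for the Geweke diagnostic (need >= 20)")
    if not (0 < first_frac and 0 < last_frac and first_frac + last_frac <= 1):
        raise ValueError("segment fractions must be positive and sum to <= 1")
    n1 = max(int(np.floor(first_frac * n)), 2)
    n2 = max(int(np.floor(last_frac * n)), 2)
    a, b = chain[:n1], chain[n - n2 :]
    diff = a.mean() - b.mean()
    var = a.var(ddof=1) / n1 + b.var(ddof=1) / n2
    # constant chains (up to float noise relative to the chain's scale)
    scale = max(1.0, abs(a.mean()), abs(b.mean()))
    if np.sqrt(var) <= 1e-12 * scale:
        return 0.0
    return float(diff / np.sqrt(var))


def familywise_z_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Geweke cutoff controlling the family-wise false-exclusion rate.

    The per-chain default of 1.96 discards ~5% of perfectly stationary
    chains; on a model with only a handful of reactions that noise can
    swallow a whole pathway.  This returns the two-sided normal quantile at
    ``alpha / n_tests`` (Bonferroni over all reaction-chains screened, i.e.
    n_reactions x n_scenarios), appropriate for small models.
    """
    from scipy import stats as _stats

    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(_stats.norm.ppf(1.0 - alpha / (2.0 * n_tests)))


def convergence_filter(
    ss: SampleSet, z_threshold: float = GEWEKE_Z_THRESHOLD
) -> SampleSet:
    """Mark reactions whose chains fail the Geweke screen as non-converged.

    The z-score is computed per reaction on the retained (valid) rows in
    sampling order.  With multiple chains interleaved by the sampler each
    chain is scored separately and the worst |z| is kept.  Non-converged
    reactions stay in the matrix but are excluded from target analysis.
    """
    V = ss.valid_fluxes()
    z = {}
    for rid in ss.reaction_ids:
        col = V[rid].to_numpy()
        if ss.processes > 1:
            chains = [col[k :: ss.processes] for k in range(ss.processes)]
            chains = [c for c in chains if len(c) >= 20]
            z[rid] = max((abs(geweke_z(c)) for c in chains), default=0.0) * np.sign(
                geweke_z(chains[0]) if chains else 1.0
            )
        else:
            z[rid] = geweke_z(col)
    zser = pd.Series(z, name="geweke_z")
    converged = zser.abs() <= z_threshold
    converged.name = "converged"
    return SampleSet(
        scenario=ss.scenario,
        fluxes=ss.fluxes,
        seed=ss.seed,
        thinning=ss.thinning,
        processes=ss.processes,
        valid=ss.valid,
        geweke_z=zser,
        converged=converged,
        n_discarded=ss.n_discarded,
    )
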
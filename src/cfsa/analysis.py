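"""Statistical comparison of scenarios and target classification.

Per reaction, the growth-vs-production (KS1) and slow-growth-vs-production
(KS2) flux distributions are compared with the two-sample Kolmogorov-Smirnov
test, p-values Bonferroni-corrected.  A cascade of filters (convergence,
reaction category, p-value, KS1, flux change, production-scenario standard
deviation, biomass correlation) yields candidate targets, which are split on
the mean fold change of absolute fluxes: above 1 -> over-expression, below 1
-> down-regulation.  Down-regulations whose production and slow-growth
distributions overlap (KS2 below threshold) are false positives — their flux
drop merely tracks the slower growth.  Down-regulations with essentially
zero production flux and no essential gene are promoted to knock-outs.
Surviving targets are clustered on the correlation of absolute fluxes to
expose redundant (same-pathway) interventions, and each target's genes are
cross-indexed for off-target reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model_prep import EssentialityResult, MetabolicNetwork, ReactionCategories
from .sampling import SampleSet

__all__ = [
    "FilterParams",
    "CLASSES",
    "ks_two_sample",
    "bonferroni_adjust",
    "compare_scenarios",
    "classify_targets",
    "cluster_targets",
    "off_targets",
    "proteomics_filter",
    "FILTER_PRESETS",
]

#: terminal classification labels; every compared reaction gets exactly one
CLASSES = (
    "over_expression",
    "down_regulation",
    "knock_out",
    "false_positive",
    "rejected",
)

EPS_MEAN = 1e-9  # a mean below this counts as zero for ratios and signs


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the target-filtering cascade.

    ``ks1_min`` / ``ks2_min`` are minimum KS statistics (growth vs production
    and slow-growth vs production).  ``min_change`` is compared against the
    selected ``change_metric`` (mmol/gDW/h for ``absolute``).  The default
    preset follows the recommended values (KS 0.75, change 0.001, std 50);
    the ``case-study`` preset uses the stricter change >= 0.01.
    """

    ks1_min: float = 0.75
    ks2_min: float = 0.75
    p_adj_max: float = 0.05
    change_metric: str = "absolute"  # absolute | relative | fold
    min_change: float = 0.001
    max_std_production: float = 50.0
    biomass_corr_max: float = 0.9
    ko_zero_tol: float = 1e-6
    cluster_corr_min: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.ks1_min <= 1.0 and 0.0 <= self.ks2_min <= 1.0):
            raise ValueError("KS thresholds must lie in [0, 1]")
        if self.min_change < 0:
            raise ValueError("min_change must be >= 0")
        if self.change_metric not in ("absolute", "relative", "fold"):
            raise ValueError("change_metric must be absolute, relative or fold")


FILTER_PRESETS: dict[str, FilterParams] = {
    "default": FilterParams(),
    "case-study": FilterParams(min_change=0.01),
}


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic (sup ECDF difference) and asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p_values: np.ndarray) -> np.ndarray:
    """Bonferroni correction: p_adj = min(1, p * m), order preserved."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * len(p))


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) < 1e-300 or np.std(y) < 1e-300:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def compare_scenarios(
    growth: SampleSet,
    production: SampleSet,
    slow: SampleSet,
    biomass_reaction_id: str,
) -> pd.DataFrame:
    """Per-reaction statistics across the three scenarios.

    Returns a DataFrame indexed by reaction id with per-scenario means and
    standard deviations, KS1/KS2 statistics and raw + Bonferroni-adjusted
    p-values, the three change metrics, the Pearson correlation with biomass
    flux over the production samples, a convergence flag (converged in all
    three scenarios) and a direction-change flag (sign of the mean flips
    between growth and production).  Bonferroni's m is the number of
    converged reactions entering each comparison, corrected per family.
    """
    rids = growth.reaction_ids
    if production.reaction_ids != rids or slow.reaction_ids != rids:
        raise ValueError("sample sets do not share the same reaction index")

    G = growth.valid_fluxes()
    P = production.valid_fluxes()
    S = slow.valid_fluxes()

    conv = pd.Series(True, index=rids)
    for ss in (growth, production, slow):
        if ss.converged is not None:
            conv &= ss.converged.reindex(rids).fillna(False)

    biomass_prod = P[biomass_reaction_id].to_numpy()

    rows = {}
    for rid in rids:
        g, p, s = G[rid].to_numpy(), P[rid].to_numpy(), S[rid].to_numpy()
        ks1, p1 = ks_two_sample(g, p)
        ks2, p2 = ks_two_sample(s, p)
        mg, mp = g.mean(), p.mean()
        abs_change = abs(mp - mg)
        if abs(mg) < EPS_MEAN:
            rel_change = np.inf if abs_change >= EPS_MEAN else 0.0
            fold_change = np.inf if abs(mp) >= EPS_MEAN else np.nan
        else:
            rel_change = abs_change / abs(mg)
            fold_change = abs(mp) / abs(mg)
        rows[rid] = {
            "mean_growth": mg,
            "mean_production": mp,
            "mean_slow_growth": s.mean(),
            "std_growth": g.std(ddof=1),
            "std_production": p.std(ddof=1),
            "std_slow_growth": s.std(ddof=1),
            "ks1": ks1,
            "p1": p1,
            "ks2": ks2,
            "p2": p2,
            "abs_change": abs_change,
            "rel_change": rel_change,
            "fold_change": fold_change,
            "mean_abs_production": np.abs(p).mean(),
            "biomass_corr": _safe_corr(p, biomass_prod),
            "converged": bool(conv[rid]),
            "direction_change": bool(
                abs(mg) >= EPS_MEAN and abs(mp) >= EPS_MEAN and np.sign(mg) != np.sign(mp)
            ),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "reaction"

    # Bonferroni over the reactions actually tested (converged ones), each
    # KS family corrected separately
    tested = df.index[df["converged"]]
    for raw, adj in (("p1", "p1_adj"), ("p2", "p2_adj")):
        df[adj] = 1.0
        if len(tested):
            df.loc[tested, adj] = bonferroni_adjust(df.loc[tested, raw].to_numpy())
    return df


def _change_value(row: pd.Series, params: FilterParams) -> float:
    if params.change_metric == "absolute":
        return row["abs_change"]
    if params.change_metric == "relative":
        return row["rel_change"]
    fold = row["fold_change"]
    return np.inf if not np.isfinite(fold) else abs(fold - 1.0)


def classify_targets(
    comparisons: pd.DataFrame,
    params: FilterParams,
    cats: ReactionCategories,
    essentials: EssentialityResult,
) -> pd.DataFrame:
    """Apply the filter cascade and classify every compared reaction.

    Each reaction ends in exactly one class.  Rejection reasons are recorded
    in order: not_converged, category (required / not_biological / blocked /
    no_gene), p_adj, ks1, change, std_production, biomass_corr, no_direction
    (fold change exactly 1 or undefined).  Down-regulation candidates whose
    slow-growth and production distributions overlap (KS2 < ``ks2_min``) are
    false positives; the remainder with near-zero production flux and neither
    an essential reaction nor an essential gene become knock-outs.
    """
    out = comparisons.copy()
    classification = []
    reasons = []
    for rid, row in comparisons.iterrows():
        cls, reason = _classify_one(rid, row, params, cats, essentials)
        classification.append(cls)
        reasons.append(reason)
    out["classification"] = classification
    out["reason"] = reasons
    return out


def _classify_one(rid, row, params, cats, essentials):
    if not row["converged"]:
        return "rejected", "not_converged"
    category = cats.of(rid)
    for bad in ("required", "not_biological", "blocked", "no_gene"):
        if bad in category:
            return "rejected", f"category:{bad}"
    if row["p1_adj"] > params.p_adj_max:
        return "rejected", "p_adj"
    if row["ks1"] < params.ks1_min:
        return "rejected", "ks1"
    if _change_value(row, params) < params.min_change:
        return "rejected", "change"
    if row["std_production"] > params.max_std_production:
        return "rejected", "std_production"
    if abs(row["biomass_corr"]) > params.biomass_corr_max:
        return "rejected", "biomass_corr"

    fold = row["fold_change"]
    if not np.isfinite(fold):
        if np.isnan(fold):
            return "rejected", "no_direction"
        return "over_expression", ""  # +inf: production flux from a zero base
    if fold > 1.0:
        return "over_expression", ""
    if fold < 1.0:
        if row["ks2"] < params.ks2_min:
            return "false_positive", "slow_growth_overlap"
        essential = rid in essentials.essential_reactions or "has_essential_gene" in cats.of(rid)
        if row["mean_abs_production"] < params.ko_zero_tol and not essential:
            return "knock_out", ""
        return "down_regulation", ""
    return "rejected", "no_direction"


def cluster_targets(
    production: SampleSet, targets: pd.DataFrame, params: FilterParams
) -> pd.DataFrame:
    """Assign cluster ids to targets by absolute-flux correlation.

    Average-linkage hierarchical clustering on distance 1 - |r| over the
    production samples, cut at 1 - ``cluster_corr_min``; over-expression
    targets are clustered separately from down-regulation/knock-out targets.
    Cluster ids are per stratum, starting at 1.
    """
    out = targets.copy()
    out["cluster"] = pd.array([None] * len(out), dtype="Int64")
    P = production.valid_fluxes()
    strata = {
        "OV": out.index[out["classification"] == "over_expression"],
        "KD": out.index[out["classification"].isin(["down_regulation", "knock_out"])],
    }
    for ids in strata.values():
        ids = [i for i in ids if i in P.columns]
        if not ids:
            continue
        if len(ids) == 1:
            out.loc[ids, "cluster"] = 1
            continue
        A = np.abs(P[ids].to_numpy())
        R = np.corrcoef(A, rowvar=False)
        R = np.nan_to_num(R, nan=0.0)  # constant columns: no correlation
        np.fill_diagonal(R, 1.0)
        D = 1.0 - np.abs(R)
        D = np.clip((D + D.T) / 2.0, 0.0, None)
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method="average")
        labels = fcluster(Z, t=1.0 - params.cluster_corr_min, criterion="distance")
        for rid, lab in zip(ids, labels):
            out.loc[rid, "cluster"] = int(lab)
    return out


def off_targets(net: MetabolicNetwork, targets: pd.DataFrame) -> pd.DataFrame:
    """Annotate targets with genes, equations and off-target reactions.

    For each target reaction, every associated gene is looked up across the
    whole model; other reactions sharing the gene are potential off-targets
    of an intervention on that gene (multifunctional enzymes).
    """
    model = net.model
    out = targets.copy()
    genes_col, offs_col, eq_col = [], [], []
    for rid in out.index:
        if rid in {r.id for r in model.reactions}:
            rxn = model.reactions.get_by_id(rid)
            genes = sorted(g.id for g in rxn.genes)
            offs = {
                g: sorted(
                    r.id
                    for r in model.genes.get_by_id(g).reactions
                    if r.id != rid
                )
                for g in genes
            }
            offs = {g: rs for g, rs in offs.items() if rs}
            eq = rxn.build_reaction_string()
        else:
            genes, offs, eq = [], {}, ""
        genes_col.append(";".join(genes))
        offs_col.append(
            ";".join(f"{g}:{','.join(rs)}" for g, rs in sorted(offs.items()))
        )
        eq_col.append(eq)
    out["genes"] = genes_col
    out["off_targets"] = offs_col
    out["equation"] = eq_col
    return out


def proteomics_filter(targets: pd.DataFrame, detected_genes: set[str]) -> pd.DataFrame:
    """Flag down-regulation/knock-out targets without detected proteins.

    Targets none of whose genes appear in ``detected_genes`` are annotated
    ``protein_detected = False`` (demoted in ranking, never deleted);
    over-expression targets are untouched.
    """
    out = targets.copy()
    flags = []
    for rid, row in out.iterrows():
        if row.get("classification") in ("down_regulation", "knock_out"):
            genes = set(filter(None, str(row.get("genes", "")).split(";")))
            flags.append(bool(genes & set(detected_genes)))
        else:
            flags.append(None)
    out["protein_detected"] = pd.array(flags, dtype="boolean")
    return out
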
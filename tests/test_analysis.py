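"""KS comparison, filter cascade, classification, clustering, off-targets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfsa.analysis import (
    FILTER_PRESETS,
    FilterParams,
    bonferroni_adjust,
    classify_targets,
    cluster_targets,
    compare_scenarios,
    ks_two_sample,
    off_targets,
    proteomics_filter,
)
from cfsa.model_prep import EssentialityResult, ReactionCategories

from conftest import ecdf_sup_distance


# --- KS test -----------------------------------------------------------------

def test_ks_identical_samples_zero():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    stat, _ = ks_two_sample(a, a)
    assert stat == 0.0


def test_ks_disjoint_supports_one():
    stat, _ = ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert stat == 1.0


def test_ks_half_overlap_known_value():
    stat, _ = ks_two_sample([1, 2, 3, 4], [3, 4, 5, 6])
    assert stat == pytest.approx(0.5, abs=1e-12)
    assert ecdf_sup_distance([1, 2, 3, 4], [3, 4, 5, 6]) == pytest.approx(0.5)


def test_ks_matches_bruteforce_on_random_pairs():
    rng = np.random.default_rng(7)
    for _ in range(300):
        n, m = rng.integers(2, 40, size=2)
        a = rng.normal(0, 1, n)
        b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), m)
        stat, _ = ks_two_sample(a, b)
        assert stat == pytest.approx(ecdf_sup_distance(a, b), abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    a=st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=30),
    b=st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=30),
)
def test_ks_statistic_properties(a, b):
    stat, p = ks_two_sample(a, b)
    assert 0.0 <= stat <= 1.0
    assert 0.0 <= p <= 1.0
    assert stat == pytest.approx(ecdf_sup_distance(a, b), abs=1e-12)


def test_ks_rejects_tiny_samples():
    with pytest.raises(ValueError):
        ks_two_sample([1.0], [1.0, 2.0])


# --- Bonferroni --------------------------------------------------------------

def test_bonferroni_arithmetic_cap_and_order():
    p = np.array([0.01, 0.5, 0.002, 0.3, 0.04])
    adj = bonferroni_adjust(p)
    np.testing.assert_allclose(adj, np.minimum(1.0, p * 5), atol=0)
    assert adj[1] == 1.0  # capped
    # elementwise map: relative order of uncapped entries preserved
    assert adj[2] < adj[0] < adj[4]


# --- compare_scenarios -------------------------------------------------------

def test_compare_matches_naive_recomputation(sampled_triple, toy_comparisons):
    """Every statistic re-derived from the raw matrices with plain numpy."""
    G = sampled_triple["growth"].valid_fluxes()
    P = sampled_triple["production"].valid_fluxes()
    S = sampled_triple["slow_growth"].valid_fluxes()
    bm = P["BIOMASS"].to_numpy()
    for rid in ("DEG", "PP1", "GLYC", "BIOSYN"):
        row = toy_comparisons.loc[rid]
        g, p, s = G[rid].to_numpy(), P[rid].to_numpy(), S[rid].to_numpy()
        assert row["mean_growth"] == pytest.approx(g.mean(), rel=1e-12)
        assert row["std_production"] == pytest.approx(p.std(ddof=1), rel=1e-12)
        assert row["ks1"] == pytest.approx(ecdf_sup_distance(g, p), abs=1e-12)
        assert row["ks2"] == pytest.approx(ecdf_sup_distance(s, p), abs=1e-12)
        assert row["abs_change"] == pytest.approx(abs(p.mean() - g.mean()), rel=1e-12)
        assert row["fold_change"] == pytest.approx(
            abs(p.mean()) / abs(g.mean()), rel=1e-9
        )
        assert row["biomass_corr"] == pytest.approx(
            np.corrcoef(p, bm)[0, 1], abs=1e-12
        )


def test_compare_adjusted_p_not_below_raw(toy_comparisons):
    conv = toy_comparisons[toy_comparisons["converged"]]
    assert (conv["p1_adj"] >= conv["p1"] - 1e-300).all()
    assert (conv["p2_adj"] >= conv["p2"] - 1e-300).all()


def test_compare_index_mismatch_rejected(sampled_triple):
    from cfsa.sampling import SampleSet

    g = sampled_triple["growth"]
    shuffled = SampleSet(
        scenario="production",
        fluxes=g.fluxes[list(reversed(g.reaction_ids))],
        seed=0,
        thinning=1,
    )
    with pytest.raises(ValueError, match="reaction index"):
        compare_scenarios(g, shuffled, g, "BIOMASS")


# --- classification ----------------------------------------------------------

def _row(**kw):
    base = dict(
        mean_growth=1.0,
        mean_production=3.0,
        mean_slow_growth=1.0,
        std_growth=0.1,
        std_production=0.1,
        std_slow_growth=0.1,
        ks1=0.9,
        p1=1e-10,
        p1_adj=1e-8,
        ks2=0.9,
        p2=1e-10,
        p2_adj=1e-8,
        abs_change=2.0,
        rel_change=2.0,
        fold_change=3.0,
        mean_abs_production=3.0,
        biomass_corr=0.0,
        converged=True,
        direction_change=False,
    )
    base.update(kw)
    return base


def _frame(rows: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "reaction"
    return df


def _cats(rows, special=None):
    cats = {rid: set() for rid in rows}
    if special:
        for rid, s in special.items():
            cats[rid] = set(s)
    return ReactionCategories(categories=cats)


def _ess(genes=(), rxns=()):
    return EssentialityResult(set(genes), set(rxns), 1.0, 0.01)


def test_classification_rules():
    rows = {
        "ov": _row(),
        "kd": _row(fold_change=0.2, mean_abs_production=0.5),
        "fp": _row(fold_change=0.2, ks2=0.1, mean_abs_production=0.5),
        "ko": _row(fold_change=0.0, mean_abs_production=1e-9),
        "ko_essential": _row(fold_change=0.0, mean_abs_production=1e-9),
        "weak_ks1": _row(ks1=0.3),
        "tiny_change": _row(abs_change=1e-5),
        "broad": _row(std_production=100.0),
        "growth_coupled": _row(biomass_corr=0.97),
        "nonconv": _row(converged=False),
        "no_dir": _row(fold_change=1.0),
        "required_rxn": _row(),
        "exchange": _row(),
    }
    df = _frame(rows)
    cats = _cats(
        rows,
        {
            "required_rxn": {"required"},
            "exchange": {"not_biological", "no_gene"},
            "ko_essential": {"has_essential_gene"},
        },
    )
    out = classify_targets(df, FilterParams(), cats, _ess())
    cls = out["classification"]
    assert cls["ov"] == "over_expression"
    assert cls["kd"] == "down_regulation"
    assert cls["fp"] == "false_positive"
    assert out.loc["fp", "reason"] == "slow_growth_overlap"
    assert cls["ko"] == "knock_out"
    assert cls["ko_essential"] == "down_regulation"  # essential gene blocks KO
    for rid, reason in [
        ("weak_ks1", "ks1"),
        ("tiny_change", "change"),
        ("broad", "std_production"),
        ("growth_coupled", "biomass_corr"),
        ("nonconv", "not_converged"),
        ("no_dir", "no_direction"),
        ("required_rxn", "category:required"),
        ("exchange", "category:not_biological"),
    ]:
        assert cls[rid] == "rejected" and out.loc[rid, "reason"] == reason, rid


def test_fold_change_uses_absolute_fluxes():
    """Sign flips do not hide a magnitude increase: mean -2 -> 4 is fold 2."""
    rows = {"flip": _row(mean_growth=-2.0, mean_production=4.0, fold_change=2.0,
                         abs_change=6.0, direction_change=True)}
    out = classify_targets(_frame(rows), FilterParams(), _cats(rows), _ess())
    assert out.loc["flip", "classification"] == "over_expression"
    assert bool(out.loc["flip", "direction_change"])


def test_zero_growth_mean_gives_infinite_fold():
    rows = {"inf": _row(mean_growth=0.0, mean_production=1.0, fold_change=np.inf,
                        abs_change=1.0)}
    out = classify_targets(_frame(rows), FilterParams(), _cats(rows), _ess())
    assert out.loc["inf", "classification"] == "over_expression"


def test_classification_is_a_partition(toy_comparisons, toy_categories, toy_essentials):
    out = classify_targets(
        toy_comparisons, FilterParams(biomass_corr_max=1.0), toy_categories, toy_essentials
    )
    assert out["classification"].isin(
        ["over_expression", "down_regulation", "knock_out", "false_positive", "rejected"]
    ).all()
    targets = out[out["classification"] != "rejected"]
    for rid in targets.index:
        assert not toy_categories.never_target(rid), rid


def test_filter_monotonicity_on_fixed_samples(toy_comparisons, toy_categories, toy_essentials):
    """Stricter thresholds never yield more targets on the same samples."""

    def counts(**kw):
        params = FilterParams(biomass_corr_max=1.0, **kw)
        out = classify_targets(toy_comparisons, params, toy_categories, toy_essentials)
        c = out["classification"].value_counts()
        ov = c.get("over_expression", 0)
        kd = c.get("down_regulation", 0) + c.get("knock_out", 0)
        return ov, kd

    prev = None
    for ks1 in np.arange(0.1, 1.0, 0.1):
        ov, kd = counts(ks1_min=float(ks1))
        if prev is not None:
            assert ov + kd <= prev
        prev = ov + kd

    prev = None
    for ks2 in np.arange(0.1, 1.0, 0.1):
        _, kd = counts(ks2_min=float(ks2))
        if prev is not None:
            assert kd <= prev
        prev = kd

    prev = None
    for max_std in (50.0, 1.0, 0.1, 0.01):
        ov, kd = counts(max_std_production=max_std)
        if prev is not None:
            assert ov + kd <= prev
        prev = ov + kd


# --- clustering / off-targets / proteomics ----------------------------------

def test_series_reactions_cluster_together(sampled_triple, toy_comparisons,
                                           toy_categories, toy_essentials):
    out = classify_targets(
        toy_comparisons, FilterParams(biomass_corr_max=1.0), toy_categories, toy_essentials
    )
    out = cluster_targets(sampled_triple["production"], out, FilterParams())
    # PP1/PP2/NARt carry identical flux -> r = 1 -> one OV cluster
    ov = out[out["classification"] == "over_expression"]
    assert ov.loc[["PP1", "PP2", "NARt"], "cluster"].nunique() == 1
    # DEG/T_W likewise in the KD stratum, numbered independently of OV
    kd = out[out["classification"].isin(["down_regulation", "knock_out"])]
    assert kd.loc["DEG", "cluster"] == kd.loc["T_W", "cluster"]


def test_independent_branches_cluster_apart(sampled_triple):
    P = sampled_triple["production"]
    targets = pd.DataFrame(
        {
            "classification": ["over_expression", "over_expression"],
            "abs_change": [1.0, 1.0],
        },
        index=pd.Index(["PP1", "DEG"], name="reaction"),
    )
    out = cluster_targets(P, targets, FilterParams())
    # product flux and overflow flux are anti-correlated branches, |r| < 0.95
    assert out.loc["PP1", "cluster"] != out.loc["DEG", "cluster"] or (
        abs(
            np.corrcoef(
                np.abs(P.valid_fluxes()["PP1"]), np.abs(P.valid_fluxes()["DEG"])
            )[0, 1]
        )
        >= 0.95
    )


def test_single_target_gets_cluster_one(sampled_triple):
    targets = pd.DataFrame(
        {"classification": ["over_expression"], "abs_change": [1.0]},
        index=pd.Index(["PP1"], name="reaction"),
    )
    out = cluster_targets(sampled_triple["production"], targets, FilterParams())
    assert out.loc["PP1", "cluster"] == 1


def test_off_targets_shared_gene_symmetric(toy_net):
    net = toy_net.copy()
    # share a gene between two reactions (multifunctional enzyme)
    net.model.reactions.get_by_id("PP1").gene_reaction_rule = "g_shared"
    net.model.reactions.get_by_id("DEG").gene_reaction_rule = "g_shared"
    targets = pd.DataFrame(
        {"classification": ["over_expression", "down_regulation"]},
        index=pd.Index(["PP1", "DEG"], name="reaction"),
    )
    out = off_targets(net, targets)
    assert out.loc["PP1", "off_targets"] == "g_shared:DEG"
    assert out.loc["DEG", "off_targets"] == "g_shared:PP1"
    assert out.loc["PP1", "genes"] == "g_shared"


def test_off_targets_unique_gene_empty(toy_net, sampled_triple):
    targets = pd.DataFrame(
        {"classification": ["down_regulation"]},
        index=pd.Index(["DEG"], name="reaction"),
    )
    out = off_targets(toy_net, targets)
    assert out.loc["DEG", "off_targets"] == ""
    assert "P_c" in out.loc["DEG", "equation"]


@pytest.mark.parametrize(
    "detected,expect",
    [({"g_deg"}, True), ({"other"}, False), (set(), False)],
)
def test_proteomics_filter_flags_kd_targets(toy_net, detected, expect):
    targets = pd.DataFrame(
        {
            "classification": ["down_regulation", "over_expression"],
            "genes": ["g_deg", "g_pp1"],
        },
        index=pd.Index(["DEG", "PP1"], name="reaction"),
    )
    out = proteomics_filter(targets, detected)
    assert out.loc["DEG", "protein_detected"] == expect
    assert pd.isna(out.loc["PP1", "protein_detected"])  # OV untouched


def test_presets():
    assert FILTER_PRESETS["default"].min_change == 0.001
    assert FILTER_PRESETS["case-study"].min_change == 0.01
    assert FILTER_PRESETS["case-study"].ks1_min == 0.75
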
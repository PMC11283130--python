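"""Two-stage workflow: sampling stage and filter stage.

The sampling stage (model preparation, scenario construction, sampling,
validation, convergence screening) is the expensive half; its artifacts —
flux matrices, diagnostics, the curated model and a content hash binding
them together — are persisted so the cheap filter stage can be re-run with
different thresholds without re-sampling.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

import cobra

from .analysis import (
    FILTER_PRESETS,
    FilterParams,
    classify_targets,
    cluster_targets,
    compare_scenarios,
    off_targets,
    proteomics_filter,
)
from .model_prep import (
    ConfigurationError,
    EssentialityResult,
    MediaSpec,
    MetabolicNetwork,
    PathwayReaction,
    PathwaySpec,
    ReactionCategories,
    apply_media,
    add_pathway,
    assess_essentiality,
    categorize_reactions,
    load_model,
)
from .reporting import render_target_reports, write_workbooks
from .sampling import (
    SampleSet,
    convergence_filter,
    sample_scenario,
    validate_samples,
)
from .scenarios import SCENARIO_NAMES, build_all_scenarios

__all__ = [
    "RunConfig",
    "load_config",
    "model_hash",
    "run_sampling_stage",
    "run_filter_stage",
    "run_cfsa",
    "load_sampling_artifacts",
]

META_FILE = "sampling_meta.json"
MODEL_FILE = "model.json"


@dataclass
class RunConfig:
    """Run parameters for the two-stage workflow (mirrors the YAML config)."""

    model_path: str
    model_format: str | None = None
    biomass_reaction: str | None = None
    maintenance_reactions: list[str] | None = None
    product_reaction: str | None = None
    media: MediaSpec | None = None
    pathway: PathwaySpec | None = None
    optimality: float = 0.9
    flux_fraction: float = 1.25
    min_production_rate: float | None = None
    n_samples: int = 10_000
    thinning: int = 100
    seed: int = 0
    processes: int = 1
    z_threshold: float = 1.96
    growth_cutoff_fraction: float = 0.01
    filters: FilterParams = field(default_factory=FilterParams)
    output_dir: str = "cfsa_results"
    proteins_path: str | None = None


def load_config(path: str) -> RunConfig:
    """Parse a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "model" not in raw:
        raise ConfigurationError("config must name a 'model' file")

    media = None
    if "media" in raw:
        m = raw["media"]
        media = MediaSpec(
            bounds={k: (float(v[0]), float(v[1])) for k, v in (m.get("bounds") or {}).items()},
            aerobic=m.get("aerobic"),
            oxygen_exchange_id=m.get("oxygen_exchange_id", "EX_o2_e"),
            unlisted_uptake=m.get("unlisted_uptake", "close"),
        )
    pathway = None
    if "pathway" in raw:
        p = raw["pathway"]
        pathway = PathwaySpec(
            reactions=[
                PathwayReaction(
                    id=r["id"], equation=r["equation"], gpr=r.get("gpr", "")
                )
                for r in p.get("reactions", [])
            ],
            metabolites=p.get("metabolites", {}),
            product_exchange_id=p.get("product_exchange"),
        )
    fraw = dict(raw.get("filters") or {})
    preset = fraw.pop("preset", None)
    filters = FILTER_PRESETS[preset] if preset else FilterParams()
    if fraw:
        filters = replace(filters, **fraw)
    scen = raw.get("scenario") or {}
    samp = raw.get("sampler") or {}
    return RunConfig(
        model_path=raw["model"],
        model_format=raw.get("format"),
        biomass_reaction=raw.get("biomass_reaction"),
        maintenance_reactions=raw.get("maintenance_reactions"),
        product_reaction=raw.get("product_reaction"),
        media=media,
        pathway=pathway,
        optimality=float(scen.get("optimality", 0.9)),
        flux_fraction=float(scen.get("flux_fraction", 1.25)),
        min_production_rate=scen.get("min_production_rate"),
        n_samples=int(samp.get("n_samples", 10_000)),
        thinning=int(samp.get("thinning", 100)),
        seed=int(samp.get("seed", 0)),
        processes=int(samp.get("processes", 1)),
        z_threshold=float(samp.get("z_threshold", 1.96)),
        growth_cutoff_fraction=float(
            (raw.get("essentiality") or {}).get("growth_cutoff_fraction", 0.01)
        ),
        filters=filters,
        output_dir=raw.get("output_dir", "cfsa_results"),
        proteins_path=raw.get("proteins"),
    )


def model_hash(net: MetabolicNetwork) -> str:
    """Content hash of the canonicalized stoichiometry, bounds and GPRs.

    Binds sampling artifacts to the filter stage: a filter run on artifacts
    produced from a different (even slightly edited) model is refused.
    """
    payload = {
        "biomass": net.biomass_reaction_id,
        "product": net.product_reaction_id,
        "reactions": [
            [
                r.id,
                repr(r.lower_bound),
                repr(r.upper_bound),
                sorted((m.id, repr(c)) for m, c in r.metabolites.items()),
                r.gene_reaction_rule,
            ]
            for r in sorted(net.model.reactions, key=lambda r: r.id)
        ],
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()


def prepare_network(config: RunConfig) -> MetabolicNetwork:
    """Load the model and apply medium / pathway / product settings."""
    net = load_model(
        config.model_path,
        format=config.model_format,
        biomass_reaction_id=config.biomass_reaction,
        maintenance_reaction_ids=config.maintenance_reactions,
    )
    if config.media is not None:
        net = apply_media(net, config.media)
    if config.pathway is not None:
        net = add_pathway(net, config.pathway)
    if config.product_reaction is not None:
        net.product_reaction_id = config.product_reaction
    if net.product_reaction_id is None:
        raise ConfigurationError(
            "no product reaction: set 'product_reaction' or a pathway "
            "'product_exchange' in the config"
        )
    return net


def _sample_all(
    net: MetabolicNetwork, config: RunConfig
) -> tuple[dict[str, SampleSet], dict[str, dict[str, float]]]:
    cms = build_all_scenarios(
        net,
        optimality=config.optimality,
        flux_fraction=config.flux_fraction,
        min_production_rate=config.min_production_rate,
    )
    samplesets: dict[str, SampleSet] = {}
    records: dict[str, dict[str, float]] = {}
    for name in SCENARIO_NAMES:
        cm = cms[name]
        ss = sample_scenario(
            cm,
            n_samples=config.n_samples,
            thinning=config.thinning,
            seed=config.seed,
            processes=config.processes,
        )
        ss = validate_samples(ss, cm)
        ss = convergence_filter(ss, z_threshold=config.z_threshold)
        samplesets[name] = ss
        records[name] = cm.records
    return samplesets, records


def run_sampling_stage(config: RunConfig, out_dir: str | None = None) -> str:
    """Execute model prep, scenario construction and sampling; persist.

    Writes per-scenario flux matrices (CSV), a JSON sidecar with seeds,
    thinning, validity masks, Geweke report, scenario optima, categories,
    essentiality and the model hash, the curated model itself, and the
    sampling workbook.  Returns the artifact directory.
    """
    out_dir = out_dir or config.output_dir
    os.makedirs(out_dir, exist_ok=True)
    t0 = time.time()

    net = prepare_network(config)
    essentials = assess_essentiality(net, config.growth_cutoff_fraction)
    cats = categorize_reactions(net, essentials)
    samplesets, records = _sample_all(net, config)

    cobra.io.save_json_model(net.model, os.path.join(out_dir, MODEL_FILE))
    meta = {
        "model_hash": model_hash(net),
        "biomass_reaction": net.biomass_reaction_id,
        "maintenance_reactions": net.maintenance_reaction_ids,
        "product_reaction": net.product_reaction_id,
        "pathway_reactions": net.pathway_reaction_ids,
        "seed": config.seed,
        "thinning": config.thinning,
        "n_samples": config.n_samples,
        "processes": config.processes,
        "z_threshold": config.z_threshold,
        "optimality": config.optimality,
        "flux_fraction": config.flux_fraction,
        "scenario_records": records,
        "essential_genes": sorted(essentials.essential_genes),
        "essential_reactions": sorted(essentials.essential_reactions),
        "wild_type_growth": essentials.wild_type_growth,
        "growth_cutoff_fraction": essentials.growth_cutoff_fraction,
        "categories": {k: sorted(v) for k, v in cats.categories.items()},
        "scenarios": {},
        "elapsed_s": None,
    }
    for name, ss in samplesets.items():
        ss.fluxes.to_csv(os.path.join(out_dir, f"samples_{name}.csv"), index=False)
        meta["scenarios"][name] = {
            "invalid_rows": np.flatnonzero(~ss.valid).tolist()
            if ss.valid is not None
            else [],
            "n_discarded": ss.n_discarded,
            "geweke_z": {k: float(v) for k, v in ss.geweke_z.items()},
            "non_converged": sorted(ss.converged.index[~ss.converged]),
        }
    meta["elapsed_s"] = round(time.time() - t0, 3)
    with open(os.path.join(out_dir, META_FILE), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)

    write_workbooks(
        samplesets,
        _empty_targets(samplesets["growth"]),
        out_dir,
        run_info={"model_hash": meta["model_hash"], "seed": config.seed},
    )
    return out_dir


def _empty_targets(ss: SampleSet) -> pd.DataFrame:
    df = pd.DataFrame(index=pd.Index([], name="reaction"))
    df["classification"] = []
    df["abs_change"] = []
    return df


def load_sampling_artifacts(
    artifacts_dir: str,
) -> tuple[MetabolicNetwork, dict[str, SampleSet], dict]:
    """Reload persisted sampling artifacts."""
    with open(os.path.join(artifacts_dir, META_FILE)) as fh:
        meta = json.load(fh)
    model = cobra.io.load_json_model(os.path.join(artifacts_dir, MODEL_FILE))
    net = MetabolicNetwork(
        model=model,
        biomass_reaction_id=meta["biomass_reaction"],
        maintenance_reaction_ids=meta["maintenance_reactions"],
        product_reaction_id=meta["product_reaction"],
        pathway_reaction_ids=meta.get("pathway_reactions", []),
    )
    if model_hash(net) != meta["model_hash"]:
        raise ConfigurationError(
            "sampling artifacts do not match the stored model (hash mismatch)"
        )
    samplesets = {}
    for name in SCENARIO_NAMES:
        fluxes = pd.read_csv(os.path.join(artifacts_dir, f"samples_{name}.csv"))
        info = meta["scenarios"][name]
        valid = np.ones(len(fluxes), dtype=bool)
        valid[info["invalid_rows"]] = False
        geweke = pd.Series(info["geweke_z"], name="geweke_z").reindex(fluxes.columns)
        converged = ~geweke.index.isin(info["non_converged"])
        samplesets[name] = SampleSet(
            scenario=name,
            fluxes=fluxes,
            seed=meta["seed"],
            thinning=meta["thinning"],
            processes=meta["processes"],
            valid=valid,
            geweke_z=geweke,
            converged=pd.Series(converged, index=geweke.index, name="converged"),
            n_discarded=info["n_discarded"],
        )
    return net, samplesets, meta


def _analyse(
    net: MetabolicNetwork,
    samplesets: dict[str, SampleSet],
    meta: dict,
    params: FilterParams,
    detected_genes: set[str] | None = None,
) -> pd.DataFrame:
    cats = ReactionCategories(
        categories={k: set(v) for k, v in meta["categories"].items()}
    )
    essentials = EssentialityResult(
        essential_genes=set(meta["essential_genes"]),
        essential_reactions=set(meta["essential_reactions"]),
        wild_type_growth=meta["wild_type_growth"],
        growth_cutoff_fraction=meta["growth_cutoff_fraction"],
    )
    comp = compare_scenarios(
        samplesets["growth"],
        samplesets["production"],
        samplesets["slow_growth"],
        net.biomass_reaction_id,
    )
    targets = classify_targets(comp, params, cats, essentials)
    targets = cluster_targets(samplesets["production"], targets, params)
    targets = off_targets(net, targets)
    if detected_genes is not None:
        targets = proteomics_filter(targets, detected_genes)
    return targets


def run_filter_stage(
    artifacts_dir: str,
    params: FilterParams | None = None,
    out_dir: str | None = None,
    detected_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Classify targets from persisted sampling artifacts and write reports.

    A pure function of (artifacts, params): re-running with different
    thresholds never re-samples.  Writes the filtered workbook, CSV mirror,
    the OV/KD PDFs and a provenance record.
    """
    params = params or FilterParams()
    out_dir = out_dir or artifacts_dir
    net, samplesets, meta = load_sampling_artifacts(artifacts_dir)
    targets = _analyse(net, samplesets, meta, params, detected_genes)

    os.makedirs(out_dir, exist_ok=True)
    write_workbooks(
        samplesets,
        targets,
        out_dir,
        run_info={"model_hash": meta["model_hash"], "seed": meta["seed"]},
    )
    render_target_reports(targets, samplesets, out_dir)
    with open(os.path.join(out_dir, "filter_provenance.json"), "w") as fh:
        json.dump(
            {
                "model_hash": meta["model_hash"],
                "filter_params": asdict(params),
                "n_detected_genes": len(detected_genes) if detected_genes else None,
                "class_counts": targets["classification"].value_counts().to_dict(),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return targets


def run_cfsa(
    net: MetabolicNetwork,
    n_samples: int = 2000,
    thinning: int = 10,
    seed: int = 0,
    optimality: float = 0.9,
    flux_fraction: float = 1.25,
    z_threshold: float = 1.96,
    params: FilterParams | None = None,
    growth_cutoff_fraction: float = 0.01,
) -> dict:
    """In-memory end-to-end run on an already-prepared network.

    Returns a dict with the constrained models' records, the sample sets,
    the comparison table and the classified target table.  Convenience for
    scripts and notebooks; the CLI goes through the persisted two-stage path.
    """
    params = params or FilterParams()
    essentials = assess_essentiality(net, growth_cutoff_fraction)
    cats = categorize_reactions(net, essentials)
    cms = build_all_scenarios(
        net, optimality=optimality, flux_fraction=flux_fraction
    )
    samplesets = {}
    for name in SCENARIO_NAMES:
        ss = sample_scenario(cms[name], n_samples, thinning, seed)
        ss = validate_samples(ss, cms[name])
        ss = convergence_filter(ss, z_threshold=z_threshold)
        samplesets[name] = ss
    comp = compare_scenarios(
        samplesets["growth"],
        samplesets["production"],
        samplesets["slow_growth"],
        net.biomass_reaction_id,
    )
    targets = classify_targets(comp, params, cats, essentials)
    targets = cluster_targets(samplesets["production"], targets, params)
    targets = off_targets(net, targets)
    return {
        "network": net,
        "essentials": essentials,
        "categories": cats,
        "constrained_models": cms,
        "samplesets": samplesets,
        "comparisons": comp,
        "targets": targets,
    }
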
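"""Distribution figures and workbook outputs.

Produces the user-facing artifacts of a run: per-reaction flux-distribution
graphs (growth, production and slow-growth densities overlaid, each
normalised to unit area), one multi-page PDF per target direction, and two
workbooks — the raw sampling summary and the filtered target table — with
full-precision CSV mirrors for machine use.
"""

from __future__ import annotations

import datetime
import os
import re
import zipfile
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages

from .sampling import SampleSet

__all__ = [
    "plot_reaction_distributions",
    "render_target_reports",
    "write_workbooks",
]

SCENARIO_COLORS = {
    "growth": "tab:blue",
    "production": "tab:orange",
    "slow_growth": "tab:green",
}

DEGENERATE_STD = 1e-12

#: filtered-workbook sheets, one per classification
TARGET_SHEETS = ("over_expression", "down_regulation", "knock_out", "false_positive")


def _plot_density(ax, values: np.ndarray, label: str, color: str) -> None:
    values = np.asarray(values, dtype=float)
    if values.std() < DEGENERATE_STD:
        # degenerate distribution: all mass at one flux -> labelled spike
        ax.axvline(values[0], color=color, label=f"{label} (fixed)", linewidth=2)
        return
    # Freedman-Diaconis bins, falling back to sqrt rule on zero IQR
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr > 0:
        width = 2 * iqr / len(values) ** (1 / 3)
        bins = max(int(np.ceil((values.max() - values.min()) / width)), 1)
    else:
        bins = max(int(np.sqrt(len(values))), 1)
    ax.hist(
        values,
        bins=min(bins, 200),
        density=True,
        histtype="stepfilled",
        alpha=0.35,
        color=color,
        label=label,
    )


def plot_reaction_distributions(
    reaction_id: str,
    growth: SampleSet,
    production: SampleSet,
    slow: SampleSet,
    classification: str | None = None,
    ax=None,
):
    """Overlay the three scenario flux densities for one reaction.

    Histograms are normalised to unit area (``density=True``); a constant
    flux is rendered as a labelled spike.  Returns the matplotlib figure.
    """
    for ss in (growth, production, slow):
        if reaction_id not in ss.reaction_ids:
            raise KeyError(f"reaction {reaction_id!r} missing from {ss.scenario} samples")
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    for ss in (growth, production, slow):
        _plot_density(
            ax,
            ss.valid_fluxes()[reaction_id].to_numpy(),
            ss.scenario,
            SCENARIO_COLORS.get(ss.scenario, "gray"),
        )
    title = reaction_id if classification is None else f"{reaction_id} — {classification}"
    ax.set_title(title)
    ax.set_xlabel("flux (mmol/gDW/h)")
    ax.set_ylabel("normalized frequency")
    ax.legend(fontsize=8)
    return fig


def _ordered_target_ids(targets: pd.DataFrame, classes: tuple[str, ...]) -> list[str]:
    sub = targets[targets["classification"].isin(classes)].copy()
    if sub.empty:
        return []
    if "cluster" not in sub.columns:
        sub["cluster"] = 1
    # clusters ordered by their best |mean absolute change|, pages descending
    # within each cluster
    sub["_chg"] = sub["abs_change"].abs()
    cluster_rank = sub.groupby("cluster")["_chg"].max().sort_values(ascending=False)
    ordered: list[str] = []
    for cl in cluster_rank.index:
        block = sub[sub["cluster"] == cl].sort_values("_chg", ascending=False)
        ordered.extend(block.index.tolist())
    return ordered


def render_target_reports(
    targets: pd.DataFrame,
    samplesets: Mapping[str, SampleSet],
    out_dir: str,
) -> dict[str, str]:
    """Write targets_OV.pdf and targets_KD.pdf under ``out_dir``.

    One page per target, ordered by |mean absolute change| descending within
    cluster; knock-outs share the KD report.  Empty target sets still produce
    a PDF with a "no targets" page.
    """
    os.makedirs(out_dir, exist_ok=True)
    growth, production, slow = (
        samplesets["growth"],
        samplesets["production"],
        samplesets["slow_growth"],
    )
    paths = {}
    for fname, classes in (
        ("targets_OV.pdf", ("over_expression",)),
        ("targets_KD.pdf", ("down_regulation", "knock_out")),
    ):
        path = os.path.join(out_dir, fname)
        with PdfPages(path) as pdf:
            ids = _ordered_target_ids(targets, classes)
            if not ids:
                fig, ax = plt.subplots(figsize=(6, 4))
                ax.text(0.5, 0.5, "no targets", ha="center", va="center", fontsize=16)
                ax.set_axis_off()
                pdf.savefig(fig)
                plt.close(fig)
            for rid in ids:
                fig = plot_reaction_distributions(
                    rid,
                    growth,
                    production,
                    slow,
                    classification=targets.loc[rid, "classification"],
                )
                pdf.savefig(fig)
                plt.close(fig)
        paths[fname] = path
    return paths


# ---------------------------------------------------------------------------
# workbooks
# ---------------------------------------------------------------------------

_FIXED_STAMP = datetime.datetime(2000, 1, 1)


def _finalize_workbook(writer: pd.ExcelWriter) -> None:
    props = writer.book.properties
    props.created = _FIXED_STAMP
    props.modified = _FIXED_STAMP
    props.creator = "cfsa"
    props.lastModifiedBy = "cfsa"


def _canonicalize_zip(path: str) -> None:
    """Rewrite an xlsx zip with fixed entry order and timestamps.

    Makes identical content produce identical bytes, so re-runs with the same
    seed are bitwise reproducible.
    """
    with zipfile.ZipFile(path) as zin:
        entries = {name: zin.read(name) for name in zin.namelist()}
    core = "docProps/core.xml"
    if core in entries:
        # openpyxl stamps the save time regardless of workbook properties
        entries[core] = re.sub(
            rb"(<dcterms:modified[^>]*>)[^<]*(</dcterms:modified>)",
            rb"\g<1>2000-01-01T00:00:00Z\g<2>",
            entries[core],
        )
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED, compresslevel=6) as zout:
        for name in sorted(entries):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o600 << 16
            zout.writestr(info, entries[name])


def _sampling_summary(ss: SampleSet) -> pd.DataFrame:
    V = ss.valid_fluxes()
    df = pd.DataFrame(
        {
            "mean": V.mean(),
            "std": V.std(ddof=1),
        }
    )
    df["geweke_z"] = ss.geweke_z if ss.geweke_z is not None else np.nan
    df["converged"] = ss.converged if ss.converged is not None else True
    df.index.name = "reaction"
    return df


def write_workbooks(
    samplesets: Mapping[str, SampleSet],
    targets: pd.DataFrame,
    out_dir: str,
    run_info: Mapping[str, object] | None = None,
) -> dict[str, str]:
    """Write sampling_results.xlsx, filtered_results.xlsx and CSV mirrors.

    The sampling workbook has one summary sheet per scenario (mean, std,
    Geweke z, convergence) plus a run_info sheet with seeds, thinning,
    discard counts and the scenario optima.  The filtered workbook has one
    sheet per classification carrying the reaction equation, genes,
    off-targets, cluster id and all comparison statistics.  CSV mirrors keep
    full double precision; workbook values are written unrounded and
    displayed by Excel at its default precision.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    sampling_path = os.path.join(out_dir, "sampling_results.xlsx")
    with pd.ExcelWriter(sampling_path, engine="openpyxl") as writer:
        for name in ("growth", "production", "slow_growth"):
            ss = samplesets[name]
            summary = _sampling_summary(ss)
            summary.to_excel(writer, sheet_name=name)
            summary.to_csv(os.path.join(out_dir, f"sampling_{name}.csv"))
        info_rows = []
        for name, ss in samplesets.items():
            info_rows.append(
                {
                    "scenario": name,
                    "seed": ss.seed,
                    "thinning": ss.thinning,
                    "n_samples": len(ss.fluxes),
                    "n_discarded": ss.n_discarded,
                    "n_nonconverged": int((~ss.converged).sum())
                    if ss.converged is not None
                    else 0,
                }
            )
        info = pd.DataFrame(info_rows).set_index("scenario")
        if run_info:
            for key, value in run_info.items():
                if isinstance(value, (int, float, str)):
                    info[key] = value
        info.to_excel(writer, sheet_name="run_info")
        _finalize_workbook(writer)
    _canonicalize_zip(sampling_path)
    paths["sampling_results.xlsx"] = sampling_path

    filtered_path = os.path.join(out_dir, "filtered_results.xlsx")
    ordered_cols = [
        c
        for c in (
            "classification",
            "reason",
            "equation",
            "genes",
            "off_targets",
            "cluster",
            "protein_detected",
            "mean_growth",
            "mean_production",
            "mean_slow_growth",
            "std_growth",
            "std_production",
            "std_slow_growth",
            "ks1",
            "p1",
            "p1_adj",
            "ks2",
            "p2",
            "p2_adj",
            "abs_change",
            "rel_change",
            "fold_change",
            "biomass_corr",
            "direction_change",
            "converged",
        )
        if c in targets.columns
    ]
    table = targets[ordered_cols]
    with pd.ExcelWriter(filtered_path, engine="openpyxl") as writer:
        for sheet in TARGET_SHEETS:
            sub = table[table["classification"] == sheet]
            sub.to_excel(writer, sheet_name=sheet)
        table[table["classification"] == "rejected"].to_excel(
            writer, sheet_name="rejected"
        )
        _finalize_workbook(writer)
    _canonicalize_zip(filtered_path)
    table.to_csv(os.path.join(out_dir, "filtered_results.csv"))
    paths["filtered_results.xlsx"] = filtered_path
    paths["filtered_results.csv"] = os.path.join(out_dir, "filtered_results.csv")
    return paths
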
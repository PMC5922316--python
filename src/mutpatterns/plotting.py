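"""Figure preparation and rendering.

All aggregation that determines the marks of a figure (normalization,
group means, display filters, clustered leaf orders) happens in
`prepare_plot_data`, which returns a `PlotData` whose table alone
determines the figure. `render` only draws; it never changes the data.
This keeps figures testable as numbers, independent of any rendering
backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .signatures import cluster_samples

PLOT_KINDS = (
    "spectrum",
    "profile96",
    "profile192",
    "compare",
    "contribution_bar",
    "contribution_heatmap",
    "cosine_heatmap",
    "strand_bias",
    "enrichment_depletion",
    "rainfall",
)

#: signatures with at least this relative contribution in at least one
#: sample are kept in contribution displays
DISPLAY_CONTRIBUTION_THRESHOLD = 0.10


@dataclass
class PlotData:
    kind: str
    table: pd.DataFrame
    options: dict = field(default_factory=dict)


def prepare_plot_data(kind: str, inputs, options: dict | None = None) -> PlotData:
    """Build the data behind a figure.

    ``inputs`` is the output of the corresponding analysis operation
    (a matrix, a `GroupSpectrum`, a `ProfileComparison`, a result
    table...). See `PLOT_KINDS` for the supported figure kinds.
    """
    options = dict(options or {})
    if kind not in PLOT_KINDS:
        raise ValueError(f"unknown plot kind {kind!r}")

    if kind == "spectrum":
        gs = inputs  # GroupSpectrum
        rows = []
        for group in gs.mean.columns:
            for cat in gs.mean.index:
                rows.append(
                    {"group": group, "type": cat, "mean": gs.mean.loc[cat, group], "sd": gs.sd.loc[cat, group]}
                )
        options["totals"] = {g: int(t) for g, t in gs.totals.items()}
        return PlotData(kind, pd.DataFrame(rows), options)

    if kind in ("profile96", "profile192"):
        matrix = inputs
        rel = matrix / matrix.sum(axis=0).replace(0, np.nan)
        return PlotData(kind, rel, options)

    if kind == "compare":
        comp = inputs  # ProfileComparison plus channel labels in options
        channels = options.pop("channels", list(range(len(comp.difference))))
        table = pd.DataFrame({"difference": comp.difference}, index=channels)
        options.update({"rss": comp.rss, "cosine": comp.cosine})
        return PlotData(kind, table, options)

    if kind in ("contribution_bar", "contribution_heatmap"):
        contributions = inputs  # signatures x samples
        totals = contributions.sum(axis=0)
        rel = contributions / totals.replace(0, np.nan)
        threshold = options.get("display_threshold", DISPLAY_CONTRIBUTION_THRESHOLD)
        keep = (rel >= threshold).any(axis=1)
        table = contributions.loc[keep]
        if options.get("mode", "relative") == "relative":
            table = rel.loc[keep]
        if kind == "contribution_heatmap" and options.get("cluster", False):
            order = cluster_samples(table.T).leaf_order
            table = table[order]
            options["leaf_order"] = order
        return PlotData(kind, table, options)

    if kind == "cosine_heatmap":
        sim = inputs  # samples x signatures cosine matrix
        table = sim
        if options.get("cluster", True):
            order = cluster_samples(sim).leaf_order
            table = sim.loc[order]
            options["leaf_order"] = order
        return PlotData(kind, table, options)

    # result tables pass through unchanged
    return PlotData(kind, pd.DataFrame(inputs), options)


def render(plot_data: PlotData, path) -> None:
    """Render a PlotData to png/svg/pdf (chosen by file extension)."""
    table = plot_data.table
    if table.empty:
        raise ValueError("nothing to plot: empty table")
    kind = plot_data.kind
    fig, ax = plt.subplots(figsize=(10, 4))
    try:
        if kind == "spectrum":
            pivot = table.pivot(index="type", columns="group", values="mean")
            err = table.pivot(index="type", columns="group", values="sd")
            pivot.plot.bar(ax=ax, yerr=err, capsize=2)
            ax.set_ylabel("relative contribution")
        elif kind in ("profile96", "profile192", "contribution_bar"):
            table.T.plot.bar(ax=ax, stacked=(kind == "contribution_bar"), legend=kind == "contribution_bar", width=0.9)
            ax.set_ylabel("relative contribution")
            if kind != "contribution_bar":
                ax.set_xticks([])
        elif kind == "compare":
            ax.bar(range(len(table)), table["difference"].to_numpy())
            ax.set_ylabel("difference")
            ax.set_title(
                f"RSS = {plot_data.options.get('rss', float('nan')):.3e}, "
                f"cosine = {plot_data.options.get('cosine', float('nan')):.4f}"
            )
        elif kind in ("contribution_heatmap", "cosine_heatmap"):
            data = table.to_numpy(dtype=float)
            im = ax.imshow(data, aspect="auto", cmap="viridis")
            ax.set_yticks(range(len(table.index)), labels=[str(i) for i in table.index])
            ax.set_xticks(range(len(table.columns)), labels=[str(c) for c in table.columns], rotation=90)
            fig.colorbar(im, ax=ax)
        elif kind in ("strand_bias", "enrichment_depletion"):
            sub = table.dropna(subset=["log2_ratio"])
            labels = [f"{g}:{t}" for g, t in zip(sub["group"], sub.get("type", sub.get("region")))]
            ax.bar(labels, sub["log2_ratio"].to_numpy())
            for x, (_, row) in enumerate(sub.iterrows()):
                if row.get("significant", False):
                    ax.annotate("*", (x, row["log2_ratio"]), ha="center")
            ax.set_ylabel("log2 ratio")
            ax.tick_params(axis="x", rotation=90)
        elif kind == "rainfall":
            sub = table.dropna(subset=["distance"])
            if sub.empty:
                raise ValueError("nothing to plot: no intermutation distances")
            for mut_type, grp in sub.groupby("type"):
                ax.scatter(grp["pos"], grp["distance"], s=6, label=mut_type)
            ax.set_yscale("log")
            ax.set_xlabel("genomic position")
            ax.set_ylabel("intermutation distance (bp)")
            ax.legend(markerscale=2, fontsize=7)
        fig.tight_layout()
        fig.savefig(path)
    finally:
        plt.close(fig)
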
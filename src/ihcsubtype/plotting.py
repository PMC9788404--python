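"""Figure export: clustered heatmap, cutoff sweep, Kaplan-Meier curves.

Plotting never recomputes statistics — every figure is drawn from the same
tables the pipeline writes to CSV, so figures are regenerable from stage
outputs alone.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "ihcsubtype"  # deterministic SVG ids

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram

from .clustering import ClusterTree
from .datamodel import CohortMatrix
from .survival import KMCurve


def heatmap_with_dendrogram(
    matrix: CohortMatrix,
    tree: ClusterTree,
    path: str | Path,
    title: str = "IHC expression (%)",
) -> None:
    """Marker x patient heatmap with the patient dendrogram on top."""
    dend = dendrogram(tree.to_linkage(), no_plot=True, labels=matrix.patient_ids)
    order = dend["leaves"]
    data = matrix.values[order].T  # markers as rows, patients as columns

    fig, (ax_d, ax_h) = plt.subplots(
        2, 1, figsize=(max(6, 0.28 * matrix.n_patients), 6),
        gridspec_kw={"height_ratios": [1, 2.4], "hspace": 0.05},
    )
    for xs, ys in zip(dend["icoord"], dend["dcoord"]):
        ax_d.plot(xs, ys, color="black", lw=0.8)
    ax_d.set_xlim(0, 10 * matrix.n_patients)
    ax_d.set_xticks([])
    ax_d.set_yticks([])
    for spine in ax_d.spines.values():
        spine.set_visible(False)
    ax_d.set_title(title)

    im = ax_h.imshow(data, aspect="auto", cmap="viridis", vmin=0, vmax=100)
    ax_h.set_yticks(range(len(matrix.markers)), matrix.markers)
    ax_h.set_xticks(range(len(order)), [matrix.patient_ids[i] for i in order],
                    rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax_h, shrink=0.8, label="% positive cells")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def cutoff_sweep_plot(
    sensitivity: pd.DataFrame, path: str | Path, working_cutoff: float = 20.0
) -> None:
    """Subtype shares across cutoffs, with the working cutoff as a dotted line."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for subtype in sensitivity.columns:
        ax.plot(sensitivity.index, sensitivity[subtype], marker="o", label=subtype)
    ax.axvline(working_cutoff, linestyle=":", color="grey")
    ax.set_xlabel("expression cutoff (%)")
    ax.set_ylabel("share of patients (%)")
    ax.legend()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def km_plot(curves: list[KMCurve], path: str | Path, endpoint: str = "PFS") -> None:
    """Step plot of per-group Kaplan-Meier curves."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        times = np.concatenate([[0.0], curve.times])
        surv = np.concatenate([[1.0], curve.survival])
        ax.step(times, surv, where="post",
                label=f"{curve.group} (n={curve.n_subjects}, events={curve.n_events})")
    ax.set_xlabel("months from cystectomy")
    ax.set_ylabel(f"{endpoint} probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
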
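"""Basic figures: diversity contrast, top-clone trajectories, enrichment factors.

Convenience layer over matplotlib; every function returns the Figure so
callers control saving and backends.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import pandas as pd

from .io_model import TIMEPOINTS
from .tracking import ClonotypeTrajectory


def plot_diversity(pooled: pd.DataFrame, ax=None):
    """Donor vs recipient pooled inverse Simpson per pair.

    ``pooled`` needs columns pair, role, inverse_simpson (the
    ``diversity_pooled.tsv`` layout).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    data = [pooled.loc[pooled["role"] == role, "inverse_simpson"]
            for role in ("donor", "recipient")]
    ax.boxplot(data, tick_labels=["donor", "recipient"])
    for _, row in pooled.pivot(index="pair", columns="role",
                               values="inverse_simpson").iterrows():
        ax.plot([1, 2], [row["donor"], row["recipient"]], color="grey", alpha=0.6)
    ax.set_ylabel("inverse Simpson diversity")
    return ax.figure


def plot_trajectories(trajectories: list[ClonotypeTrajectory], ax=None, title=""):
    """Frequencies of top clonotypes across the four ordered timepoints."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for traj in trajectories:
        ax.plot(range(4), traj.frequencies, marker="o", alpha=0.7)
    ax.set_xticks(range(4), TIMEPOINTS)
    ax.set_ylabel("clonotype frequency")
    if title:
        ax.set_title(title)
    return ax.figure


def plot_enrichment(results: pd.DataFrame, ax=None):
    """Enrichment-factor boxes per feature set and classifier family.

    ``results`` is the long ``enrichment_results.tsv`` layout (columns
    feature_set, family, factor).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    groups = results.dropna(subset=["factor"]).groupby(["feature_set", "family"])
    labels, data = [], []
    for (fs, fam), sub in groups:
        labels.append(f"{fs}\n{fam.replace('_', ' ')}")
        data.append(sub["factor"])
    ax.boxplot(data, tick_labels=labels)
    ax.axhline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_ylabel("enrichment factor")
    ax.tick_params(axis="x", labelsize=7)
    return ax.figure
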
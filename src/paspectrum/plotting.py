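"""Figure machinery: standardized-mean spectrum profiles and selectivity-ratio plots.

Both plot families share conventions: the x-axis walks the intensity-spectrum
bins from sedentary to the open top bin, dotted vertical lines mark the
traditional cut-points, and an optional secondary axis maps bin intensity to
METs or locomotion speed from a user-supplied mapping table (the mapping is
taken from configuration, not computed here).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .spectrum import SpectrumDefinition, default_bin_edges, DEFAULT_CUTPOINTS_MG

__all__ = ["plot_group_profiles", "plot_selectivity_ratio"]


def _bin_centers(definition: SpectrumDefinition) -> np.ndarray:
    e = np.asarray(definition.edges_mg, dtype=float)
    centers = (e[:-1] + e[1:]) / 2.0
    if definition.open_top:
        top = e[-1] + (e[-1] - e[-2]) / 2.0
        centers = np.append(centers, top)
    return centers


def _cutpoint_lines(ax, definition, cuts_mg):
    for c in cuts_mg:
        ax.axvline(c, linestyle=":", color="0.4", linewidth=0.8)


def _secondary_axis(ax, mapping: pd.DataFrame | None):
    if mapping is None or mapping.empty:
        return
    # mapping columns: intensity_mg plus one or more label columns (met, speed)
    for col in [c for c in mapping.columns if c != "intensity_mg"]:
        sec = ax.secondary_xaxis("top")
        sec.set_xticks(mapping["intensity_mg"].to_numpy())
        sec.set_xticklabels([str(v) for v in mapping[col]])
        sec.set_xlabel(col)
        break  # one secondary axis; further columns would overlap


def plot_group_profiles(
    profiles: pd.DataFrame,
    definition: SpectrumDefinition | None = None,
    cuts_mg=DEFAULT_CUTPOINTS_MG,
    secondary_mapping: pd.DataFrame | None = None,
    ax=None,
    title: str | None = None,
):
    """Standardized mean spectrum per group with CI ribbons.

    ``profiles`` is the long table from :func:`paspectrum.spectrum.group_profile`
    (columns group, bin, mean, ci_low, ci_high).
    """
    definition = definition or default_bin_edges()
    x = _bin_centers(definition)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    for g, sub in profiles.groupby("group", sort=False):
        sub = sub.reset_index(drop=True)
        ax.plot(x[: len(sub)], sub["mean"], label=str(g))
        ax.fill_between(x[: len(sub)], sub["ci_low"], sub["ci_high"], alpha=0.2)
    _cutpoint_lines(ax, definition, cuts_mg)
    _secondary_axis(ax, secondary_mapping)
    ax.axhline(0.0, color="0.7", linewidth=0.8)
    ax.set_xlabel("intensity (mg)")
    ax.set_ylabel("standardized mean (z)")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    return ax


def plot_selectivity_ratio(
    sr_frame: pd.DataFrame,
    n_spectrum_bins: int,
    definition: SpectrumDefinition | None = None,
    cuts_mg=DEFAULT_CUTPOINTS_MG,
    secondary_mapping: pd.DataFrame | None = None,
    title: str | None = None,
    percent: bool = True,
):
    """Two-panel selectivity-ratio figure: spectrum bins left, confounders right.

    ``sr_frame`` has columns predictor, sr and optionally ci_low/ci_high; the
    first ``n_spectrum_bins`` rows are the intensity-spectrum predictors, the
    rest the confounder dummies (drawn as a whisker panel).
    """
    definition = definition or default_bin_edges()
    scale = 100.0 if percent else 1.0
    spec = sr_frame.iloc[:n_spectrum_bins]
    conf = sr_frame.iloc[n_spectrum_bins:]
    has_conf = len(conf) > 0
    fig, axes = plt.subplots(
        1, 2 if has_conf else 1, figsize=(10 if has_conf else 7, 4),
        gridspec_kw={"width_ratios": [3, 2]} if has_conf else None, squeeze=False,
    )
    ax = axes[0, 0]
    x = _bin_centers(definition)[: len(spec)]
    ax.plot(x, spec["sr"] * scale, color="tab:blue")
    if "ci_low" in spec:
        ax.fill_between(x, spec["ci_low"] * scale, spec["ci_high"] * scale,
                        alpha=0.25, color="tab:blue")
    _cutpoint_lines(ax, definition, cuts_mg)
    _secondary_axis(ax, secondary_mapping)
    ax.axhline(0.0, color="0.6", linewidth=0.8)
    ax.set_xlabel("intensity (mg)")
    ax.set_ylabel("explained variance of response (%)" if percent else "selectivity ratio")
    if has_conf:
        axc = axes[0, 1]
        pos = np.arange(len(conf))
        axc.axhline(0.0, color="0.6", linewidth=0.8)
        if "ci_low" in conf:
            yerr = np.vstack([
                (conf["sr"] - conf["ci_low"]) * scale,
                (conf["ci_high"] - conf["sr"]) * scale,
            ])
            axc.errorbar(pos, conf["sr"] * scale, yerr=yerr, fmt="o", markersize=3,
                         capsize=2, color="tab:orange")
        else:
            axc.plot(pos, conf["sr"] * scale, "o", markersize=3, color="tab:orange")
        axc.set_xticks(pos)
        axc.set_xticklabels(conf["predictor"], rotation=90, fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig
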
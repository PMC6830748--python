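"""Report figures (requires matplotlib).

Four figure styles: the phenotypic trend with its regression line, the
breeding-value trend with per-sample splines, posterior densities of the
predicted and estimated evolutionary change, and the components-of-change
summary.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["fig_phenotypic_trend", "fig_bv_trend", "fig_posteriors",
           "fig_components", "report_figures"]


def fig_phenotypic_trend(records, ax=None):
    """Individual parturition dates and yearly means with the OLS line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.plot(records["year"], records["pdate"], ".", ms=2, alpha=0.2, color="grey")
    ym = records.groupby("year")["pdate"].mean()
    ax.plot(ym.index, ym.values, "o", color="black", ms=4)
    b, a = np.polyfit(records["year"], records["pdate"], 1)
    xs = np.array([records["year"].min(), records["year"].max()])
    ax.plot(xs, a + b * xs, "-", color="crimson")
    ax.set_xlabel("year")
    ax.set_ylabel("parturition date (days after May 1)")
    return ax


def fig_bv_trend(spline_curves, blup, ax=None):
    """Per-sample spline curves of yearly mean breeding values plus the
    posterior-mode linear trend."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for s, g in spline_curves.groupby("sample"):
        ax.plot(g["year"], g["value"], "-", color="black", alpha=0.08, lw=0.6)
    years = np.sort(spline_curves["year"].unique()).astype(float)
    mid = years.mean()
    ax.plot(years, blup.summary.mode * (years - mid), color="crimson", lw=2)
    for b in (blup.summary.hpd_low, blup.summary.hpd_high):
        ax.plot(years, b * (years - mid), ":", color="crimson", lw=1)
    ax.set_xlabel("year")
    ax.set_ylabel("mean breeding value (working scale)")
    return ax


def fig_posteriors(named_samples: dict, ax=None, xlabel="days over study period"):
    """Overlaid kernel densities for a set of posterior sample arrays."""
    from scipy.stats import gaussian_kde

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for name, samples in named_samples.items():
        x = np.asarray(samples, float)
        if np.ptp(x) == 0:
            continue
        grid = np.linspace(x.min(), x.max(), 300)
        ax.plot(grid, gaussian_kde(x)(grid), label=name)
    ax.legend(fontsize=7)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("posterior density")
    return ax


def fig_components(components_table, ax=None):
    """Modes and HPD bars for every component of change."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    tab = components_table
    y = np.arange(len(tab))[::-1]
    ax.errorbar(
        tab["mode"], y,
        xerr=[tab["mode"] - tab["hpd_low"], tab["hpd_high"] - tab["mode"]],
        fmt="o", ms=4, capsize=2,
    )
    ax.axvline(0.0, color="grey", lw=0.5)
    ax.set_yticks(y)
    ax.set_yticklabels(tab["component"], fontsize=7)
    ax.set_xlabel("days over study period")
    return ax


def report_figures(outdir, records, objects, tables):
    """Write the standard figure set as PNGs under ``outdir``."""
    ax = fig_phenotypic_trend(records)
    ax.figure.savefig(f"{outdir}/fig_phenotypic_trend.png", dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
    if "spline_curves" in tables and "blup_trend" in objects:
        ax = fig_bv_trend(tables["spline_curves"], objects["blup_trend"])
        ax.figure.savefig(f"{outdir}/fig_bv_trend.png", dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    dens = {}
    for key in ("prediction_univariate", "prediction_multivariate", "sts"):
        if key in objects:
            dens[key] = objects[key].units["days_span"]
    for key in ("blup_trend", "blup_trend_noyear"):
        if key in objects and objects[key].days_span is not None:
            dens[key] = objects[key].days_span.units["days_span"]
    if "drift_null" in objects:
        pass  # drift slopes are on the working-scale slope axis; skip overlay
    if dens:
        ax = fig_posteriors(dens)
        ax.figure.savefig(f"{outdir}/fig_evolution_posteriors.png", dpi=150,
                          bbox_inches="tight")
        plt.close(ax.figure)
    if "components" in tables:
        tab = tables["components"]
        ax = fig_components(tab[tab["kind"] != "observed"])
        ax.figure.savefig(f"{outdir}/fig_components.png", dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
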
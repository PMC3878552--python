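"""Forest plot for a fitted risk-ratio meta-analysis."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .meta import Z_95  # noqa: E402


def forest_plot(results, ax=None):
    """Per-study and pooled risk ratios with 95% CIs on a log axis.

    Excluded studies are shown without a marker and labelled with the
    exclusion reason.  Returns the matplotlib axes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(results.estimates) + 1.5))
    rows = list(zip(results.model.tables, results.estimates))
    n = len(rows)
    for i, (table, est) in enumerate(rows):
        y = n - i
        name = table.label or f"{table.a}/{table.n1} vs {table.c}/{table.n2}"
        if est.excluded:
            ax.text(1.0, y, f"{name} (excluded: {est.exclusion_reason})",
                    va="center", ha="center", fontsize=8, color="grey")
            continue
        se = math.sqrt(est.var_log_rr)
        lo, hi = math.exp(est.log_rr - Z_95 * se), math.exp(est.log_rr + Z_95 * se)
        ax.plot([lo, hi], [y, y], color="black", lw=1)
        ax.plot([est.rr], [y], marker="s", color="black", ms=5)
        ax.text(ax.get_xlim()[0], y, name, va="center", ha="left", fontsize=8)
    p = results.pooled
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.plot([p.ci_low, p.ci_high], [0, 0], color="darkred", lw=2)
    ax.plot([p.rr], [0], marker="D", color="darkred", ms=7)
    ax.set_xscale("log")
    ax.set_yticks([])
    ax.set_xlabel("risk ratio (log scale)")
    title = "Pooled RR %.2f (%.2f, %.2f)" % (p.rr, p.ci_low, p.ci_high)
    if results.model.description:
        title = f"{results.model.description}: {title}"
    ax.set_title(title, fontsize=9)
    return ax
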
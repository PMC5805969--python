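"""Growth-curve plotting helpers (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt

from .experiment import COMPARTMENTS, GrowthCurve

__all__ = ["plot_growth_curve"]


def plot_growth_curve(curve: GrowthCurve, ax=None, compartments=None,
                      logy: bool = True):
    """Plot compartment counts over time; SD band on the total if available."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    comps = compartments or [c for c in COMPARTMENTS if c != "total"]
    t = curve.times
    for comp in comps:
        y = curve.data[comp]
        if y.max() > 0:
            ax.plot(t, y, label=comp, lw=1.0)
    ax.plot(t, curve.total, "k-", lw=1.8, label="total")
    if curve.sd is not None:
        sd = curve.sd["total"]
        ax.fill_between(t, curve.total - sd, curve.total + sd,
                        color="k", alpha=0.15, lw=0)
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("cell count")
    ax.legend(fontsize=8, ncol=2)
    return ax
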
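"""Diagnostic plots for the pipeline results."""

from __future__ import annotations

import numpy as np

from .stats import AgreementResult, bland_altman

__all__ = ["plot_bland_altman", "plot_depth_profile"]


def plot_bland_altman(counts_a, counts_b, ax=None, result: AgreementResult | None = None):
    """Bland-Altman plot: per-pair mean vs difference with bias and 95%
    limits of agreement drawn as horizontal lines."""
    import matplotlib.pyplot as plt

    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if result is None:
        result = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2.0, a - b, s=12, alpha=0.6)
    ax.axhline(result.bias, color="k", label=f"bias = {result.bias:.2f}")
    for y, lbl in ((result.loa_low, "-1.96 SD"), (result.loa_high, "+1.96 SD")):
        ax.axhline(y, color="r", ls="--", label=lbl)
    ax.set_xlabel("mean of counters")
    ax.set_ylabel("difference (A - B)")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_depth_profile(profile, ax=None):
    """Morphology fractions against tissue depth."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for col in [c for c in profile.columns if c.endswith("_fraction")]:
        ax.plot(profile["depth_um"], profile[col], marker="o", ms=3, label=col)
    ax.set_xlabel("depth (um)")
    ax.set_ylabel("area fraction")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax
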
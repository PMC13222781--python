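"""Forest-style plots of a panel's effects 1-7."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def forest_plot(panel, ax=None):
    """Forest plot of the six difference-score effects and the pooled
    effect (diamond marker) of one exposure -> outcome panel."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels, estimates, lows, highs = [], [], [], []
    for num, eff in enumerate(panel.effects, start=1):
        lo, hi = eff.ci()
        labels.append(f"{num}: {eff.variant} {eff.timeframe[0]}->{eff.timeframe[1]}")
        estimates.append(eff.coefficient)
        lows.append(lo)
        highs.append(hi)
    pooled = panel.pooled
    labels.append(f"7: pooled ({pooled.method})")
    estimates.append(pooled.estimate)
    lows.append(pooled.ci_low)
    highs.append(pooled.ci_high)

    y = range(len(labels), 0, -1)
    for yi, est, lo, hi in zip(y, estimates, lows, highs):
        marker = "D" if yi == 1 else "s"
        ax.plot([lo, hi], [yi, yi], color="black", lw=1)
        ax.plot(est, yi, marker, color="black", ms=5)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(y))
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("standardized effect (95% CI)")
    ax.set_title(
        f"Panel {panel.spec.panel_id}: {panel.spec.exposure} → {panel.spec.outcome}"
    )
    return ax.figure
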
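"""Longitudinal group-mean profiles with 95% confidence intervals."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

RESPONSE_LABELS = {
    "volume_mm3": "volumetric change (mm$^3$)",
    "rms_mm": "RMS (mm)",
    "area_mm2": "area change (mm$^2$)",
}


def plot_group_time_means(ls_means, time_levels, group_levels,
                          response_type="volume_mm3", ax=None):
    """Plot per-period group LS means with 95% CI error bars.

    ``ls_means`` is the cell-level table from
    :meth:`RepeatedMeasuresCSResults.ls_means` (columns ``effect``,
    ``estimate``, ``CI_low``, ``CI_high``, with effect labels "<group> <time>").
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    x = range(len(time_levels))
    for gi, g in enumerate(group_levels):
        est, lo, hi = [], [], []
        for t in time_levels:
            row = ls_means[ls_means["effect"] == f"{g} {t}"]
            est.append(float(row["estimate"].iloc[0]))
            lo.append(float(row["CI_low"].iloc[0]))
            hi.append(float(row["CI_high"].iloc[0]))
        off = (gi - (len(group_levels) - 1) / 2) * 0.06
        xs = [xi + off for xi in x]
        ax.errorbar(xs, est,
                    yerr=[[e - l for e, l in zip(est, lo)],
                          [h - e for e, h in zip(est, hi)]],
                    marker="o", capsize=3, label=g)
    ax.axhline(0.0, color="gray", lw=0.8, ls=":")
    ax.set_xticks(list(x))
    ax.set_xticklabels(time_levels)
    ax.set_xlabel("immersion period")
    ax.set_ylabel(RESPONSE_LABELS.get(response_type, response_type))
    ax.legend(title="group", fontsize=8)
    return ax
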
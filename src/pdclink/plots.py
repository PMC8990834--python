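"""Basic summary plots for cohort PDC results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_REGIME_LABELS = {
    "pdc_pharmacy": "Pharmacy dispensing data",
    "pdc_claims": "Claims records",
    "pdc_combined": "Combined",
}


def plot_pdc_distributions(adherence: pd.DataFrame, threshold: float = 80.0):
    """Histograms of the per-patient PDC under each data-source regime,
    one panel per pharmacy-use subgroup plus the total cohort."""
    groups = [("total", adherence)] + [
        (str(c), g) for c, g in adherence.groupby("pharmacy_use_class")
    ]
    fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3.2),
                             sharey=True)
    if len(groups) == 1:
        axes = [axes]
    for ax, (name, sub) in zip(axes, groups):
        for col, label in _REGIME_LABELS.items():
            ax.hist(sub[col], bins=20, range=(0, 100), histtype="step", label=label)
        ax.axvline(threshold, linestyle="--", linewidth=1, color="grey")
        ax.set_title(f"{name} (n={len(sub)})")
        ax.set_xlabel("PDC (%)")
    axes[0].set_ylabel("patients")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    return fig
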
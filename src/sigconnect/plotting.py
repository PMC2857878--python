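"""Enrichment running-sum plots (one panel per scored gene set)."""

from __future__ import annotations

import numpy as np

from .enrichment import EnrichmentResult

__all__ = ["plot_enrichment"]


def plot_enrichment(results, ax=None, labels=None):
    """Plot one or more running-sum profiles.

    Parameters
    ----------
    results
        An :class:`EnrichmentResult` or a sequence of them (e.g. the up and
        down halves of a signature).
    ax
        Existing matplotlib axes; created if omitted.
    """
    import matplotlib.pyplot as plt

    if isinstance(results, EnrichmentResult):
        results = [results]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    for i, res in enumerate(results):
        label = labels[i] if labels else res.set_name
        x = np.arange(res.running_sum.size)
        ax.plot(x, res.running_sum, lw=1.2,
                label=f"{label} (ES={res.es:.2f})")
        ax.axvline(res.peak_index, ls=":", lw=0.8, color="grey")
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("rank in ordered list")
    ax.set_ylabel("running enrichment")
    ax.legend(frameon=False, fontsize=8)
    return ax
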
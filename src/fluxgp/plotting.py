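"""Minimal optional band-plot helper (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .predict import PosteriorPrediction

__all__ = ["plot_bands"]


def plot_bands(pred: PosteriorPrediction, output: str, quantity: str = "function",
               ax=None, truth=None, observations=None, width: float = 2.0):
    """Plot posterior mean with a +/- ``width`` sd band for one output.

    ``truth`` is an optional ``(times, values)`` pair; ``observations`` a
    :class:`~fluxgp.io.TimeSeriesSet` (only shown for ``quantity='function'``).
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = pred.test_times[output]
    mean = getattr(pred, f"mean_{quantity}")[output]
    lo, hi = pred.band(output, quantity, width)
    ax.fill_between(t, lo, hi, alpha=0.25, label=f"+/-{width:g} sd")
    ax.plot(t, mean, label="posterior mean")
    if truth is not None:
        tt, tv = truth
        ax.plot(np.asarray(tt), np.asarray(tv), "--", label="truth")
    if observations is not None and quantity == "function":
        ax.plot(observations.times(output), observations.values(output), ".",
                label="data")
    ax.set_xlabel("time")
    ax.set_ylabel(f"{output} ({quantity})")
    ax.legend()
    return ax
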
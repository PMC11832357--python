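"""Observed-vs-expected time-series figures.

One figure per subgroup: observed monthly counts as black dots, the model's
expected (counterfactual) counts as a red line extended through the
intervention window, and a dashed vertical rule at the first intervention
month.  Figures are written as SVG without embedded timestamps so identical
runs produce identical files.
"""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

logger = logging.getLogger(__name__)

__all__ = ["plot_observed_vs_expected"]


def plot_observed_vs_expected(observed: pd.DataFrame, expected: pd.DataFrame,
                              intervention_index: int | None, subgroup: str,
                              path) -> dict:
    """Render the observed/expected series to ``path`` (SVG/PDF by extension).

    ``observed`` needs columns ``month_index``, ``count``; ``expected`` needs
    ``month_index``, ``expected``.  ``intervention_index`` is the month index
    of the first intervention month (``None`` plots the fit window only, with
    a warning).  Returns the plotted arrays for data-level assertions.
    """
    if len(expected) and len(observed):
        common = np.intersect1d(observed["month_index"], expected["month_index"])
        if len(common) == 0:
            raise ValueError("observed and expected series share no months")
    if intervention_index is None:
        logger.warning("no intervention month for %r: plotting fit window only", subgroup)

    plt.rcParams["svg.hashsalt"] = "itscount"  # reproducible SVG element ids
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(observed["month_index"], observed["count"], "o", color="black",
            markersize=3, label="observed")
    ax.plot(expected["month_index"], expected["expected"], "-", color="red",
            label="expected")
    if intervention_index is not None:
        ax.axvline(intervention_index, color="black", linestyle="--", linewidth=1)
    ax.set_xlabel("months from start of study window")
    ax.set_ylabel("monthly visits")
    ax.set_title(subgroup)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
    return {
        "observed_x": np.asarray(observed["month_index"]),
        "observed_y": np.asarray(observed["count"]),
        "expected_x": np.asarray(expected["month_index"]),
        "expected_y": np.asarray(expected["expected"]),
        "vline": intervention_index,
    }
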
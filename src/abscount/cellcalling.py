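"""Knee-point cell calling on the cumulative read-count curve.

Cell labels are sorted by descending read count and the running sum is
plotted on log10 axes (log10 rank vs log10 cumulative reads).  Labels up
to and including the curvature minimum — the knee where per-label
contributions collapse from cell-scale to ambient-scale — are called as
cells; the rest are treated as noise.

Curvature is estimated as the *change in secant slope* across each rank:
the slope of the log-log curve over the ``smooth_window // 2`` ranks to
the right minus the slope over the same span to the left.  The wide
baseline averages out rank-to-rank noise exactly like a pre-smoothing
pass would while keeping the estimator's minimum pinned to the kink of a
piecewise curve (a centered moving average followed by narrow central
differences smears the minimum several ranks off the plateau boundary).
The slope change is deliberately not re-divided by the rank spacing:
that normalization blows up as log-rank spacing shrinks and makes small
read-count quantization steps deep in the noise tail (e.g. constant
per-molecule read depth) outscore the true knee.  A first-derivative
variant (argmin of the secant slope itself) is available via
``mode="first"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

MIN_LABELS = 10


@dataclass
class KneeCurve:
    """Sorted label curve plus (after calling) the inflection point."""

    labels: list          # sorted by descending reads, ties lexicographic
    counts: np.ndarray    # reads per label, same order
    log10_cum_reads: np.ndarray
    curvature: Optional[np.ndarray] = None
    inflection_rank: Optional[int] = None
    called: list = field(default_factory=list)
    degenerate: bool = False

    @property
    def n_labels(self) -> int:
        return len(self.labels)


def build_knee_curve(reads_per_label: Mapping) -> KneeCurve:
    """Sort labels by read count (descending; ties lexicographic) and
    accumulate."""
    items = [(label, int(c)) for label, c in reads_per_label.items() if c > 0]
    if len(items) < MIN_LABELS:
        raise ValueError(
            f"need at least {MIN_LABELS} labels with positive counts, "
            f"got {len(items)}"
        )
    items.sort(key=lambda lc: (-lc[1], str(lc[0])))
    labels = [l for l, _ in items]
    counts = np.array([c for _, c in items], dtype=np.int64)
    cum = np.cumsum(counts)
    return KneeCurve(
        labels=labels, counts=counts, log10_cum_reads=np.log10(cum)
    )


def _slope_change(y: np.ndarray, x: np.ndarray, h: int) -> np.ndarray:
    """Right minus left secant slope over a +-h baseline."""
    n = len(y)
    d2 = np.full(n, np.nan)
    i = np.arange(h, n - h)
    if len(i) == 0:
        return d2
    right = (y[i + h] - y[i]) / (x[i + h] - x[i])
    left = (y[i] - y[i - h]) / (x[i] - x[i - h])
    d2[i] = right - left
    return d2


def call_cells(
    curve: KneeCurve,
    smooth_window: int = 15,
    mode: str = "second",
    curvature_tol: float = 1e-9,
) -> KneeCurve:
    """Locate the inflection and call all labels at or left of it.

    The argmin is taken over interior ranks, excluding the first and
    last ``smooth_window`` ranks (boundary guard).  When the curvature
    range is below ``curvature_tol`` (e.g. all counts equal) the curve
    is flagged degenerate and nothing is called.
    """
    if mode not in ("second", "first"):
        raise ValueError(f"mode must be 'second' or 'first', got {mode!r}")
    n = curve.n_labels
    h = max(1, smooth_window // 2)
    x = np.log10(np.arange(1, n + 1, dtype=float))
    y = curve.log10_cum_reads

    if mode == "second":
        stat = _slope_change(y, x, h)
    else:
        stat = np.full(n, np.nan)
        i = np.arange(h, n - h)
        if len(i):
            stat[i] = (y[i + h] - y[i - h]) / (x[i + h] - x[i - h])
    curve.curvature = stat

    lo = max(1, smooth_window)          # rank >= 2 and boundary guard
    hi = n - 1 - smooth_window
    window = stat[lo:hi]
    finite = window[np.isfinite(window)]
    if len(finite) == 0 or (finite.max() - finite.min()) < curvature_tol:
        curve.degenerate = True
        curve.inflection_rank = None
        curve.called = []
        return curve

    idx = lo + int(np.nanargmin(window))
    vmin = stat[idx]
    near = np.isfinite(stat) & (np.abs(stat - vmin) < curvature_tol)
    if near.sum() > 1:
        curve.degenerate = True  # minimum not unique; keep leftmost call
    curve.inflection_rank = idx + 1  # ranks are 1-based
    curve.called = curve.labels[: curve.inflection_rank]
    return curve


def knee_table(curve: KneeCurve):
    """Diagnostics table (rank, reads, cumulative, curvature) as a DataFrame."""
    import pandas as pd

    cum = np.cumsum(curve.counts)
    return pd.DataFrame(
        {
            "rank": np.arange(1, curve.n_labels + 1),
            "label": [str(l) for l in curve.labels],
            "reads": curve.counts,
            "cum_reads": cum,
            "log10_cum_reads": curve.log10_cum_reads,
            "curvature": curve.curvature
            if curve.curvature is not None
            else np.full(curve.n_labels, np.nan),
        }
    )


def plot_knee(curve: KneeCurve, path) -> None:
    """Rank plot with the called/noise boundary (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ranks = np.arange(1, curve.n_labels + 1)
    ax.plot(ranks, 10 ** curve.log10_cum_reads, lw=1.2)
    if curve.inflection_rank:
        ax.axvline(curve.inflection_rank, color="red", lw=1, ls="--")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("cell label rank")
    ax.set_ylabel("cumulative reads")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
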
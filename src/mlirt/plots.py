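"""Plotting helpers for diagnostics output."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .diagnostics import DiagnosticsReport  # noqa: E402

__all__ = ["plot_rest_score_curves"]


def plot_rest_score_curves(report: DiagnosticsReport, path,
                           ncols: int = 5) -> None:
    """One panel per item: binned mean item score against mean rest-score.

    A monotone (non-decreasing) curve supports the monotonicity assumption.
    """
    verdicts = [v for v in report.monotonicity.values() if v.passed is not None]
    if not verdicts:
        return
    nrows = (len(verdicts) + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.4 * nrows),
                             squeeze=False)
    for ax in axes.ravel():
        ax.set_visible(False)
    for ax, v in zip(axes.ravel(), verdicts):
        ax.set_visible(True)
        ax.plot(v.rest_score_bins, v.item_means, "o-", ms=3,
                color="tab:green" if v.passed else "tab:red")
        ax.set_title(f"{v.item_id} ({v.verdict})", fontsize=8)
        ax.tick_params(labelsize=7)
    fig.supxlabel("mean rest-score")
    fig.supylabel("mean item score")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
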
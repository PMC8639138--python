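"""Plot helpers for the interaction-count comparison."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_kpdi_curves(
    frames: Mapping[str, pd.DataFrame],
    path: str | Path,
    title: str = "Observed vs random drug-interaction burden",
) -> None:
    """Mean interaction count against medication count, one line per group.

    ``frames`` maps a group label (e.g. ``random``, ``hiv_negative``) to a
    summary frame with ``set_size`` and ``mean`` columns, as produced by
    the null simulation and the observed-by-count summaries.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, frame in sorted(frames.items()):
        frame = frame.sort_values("set_size")
        ax.plot(frame["set_size"], frame["mean"], marker="o", ls=":", label=label)
    ax.set_xlabel("medication count")
    ax.set_ylabel("mean KPDI count")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
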
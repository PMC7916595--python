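"""Optional heatmap rendering — a thin layer over the profile matrices.

The TSV/CSV profile outputs are the contract; these helpers only draw them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_profile_heatmap(matrix: pd.DataFrame, path, cmap: str = "viridis") -> None:
    """Render a (protein, condition) x slice matrix as a heatmap PNG/PDF.

    Rows keep the matrix's order (complex then display order); values are
    the linear [0, 1] relative intensities.
    """
    fig, ax = plt.subplots(
        figsize=(8, max(2.0, 0.12 * len(matrix)))
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap=cmap, vmin=0, vmax=1)
    ax.set_xlabel("gel slice (top → bottom)")
    labels = [
        f"{pid} [{cond}]" if isinstance(idx, tuple) else str(idx)
        for idx in matrix.index
        for pid, cond in [idx if isinstance(idx, tuple) else (idx, "")]
    ]
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=4)
    fig.colorbar(im, ax=ax, label="relative intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=200)
    plt.close(fig)
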
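"""Minimal GAM heatmap: values only, no clustering or dendrograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def gam_heatmap(matrix: pd.DataFrame, pdf_path: str | Path) -> Path:
    """Render a samples x genes GAM matrix (percent) to a PDF heatmap.

    Cell annotations show the value at 6 significant digits; NA cells are
    hatched grey. Returns the output path.
    """
    pdf_path = Path(pdf_path)
    values = matrix.to_numpy(dtype=float)
    n_samples, n_genes = values.shape

    fig, ax = plt.subplots(
        figsize=(max(3.0, 1.2 * n_genes + 2), max(2.5, 0.5 * n_samples + 1.5))
    )
    masked = np.ma.masked_invalid(values)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(masked, aspect="auto", cmap=cmap)
    ax.set_xticks(range(n_genes), labels=[str(c) for c in matrix.columns], rotation=45,
                  ha="right")
    ax.set_yticks(range(n_samples), labels=[str(i) for i in matrix.index])
    for i in range(n_samples):
        for j in range(n_genes):
            v = values[i, j]
            text = "NA" if np.isnan(v) else f"{v:.6g}"
            ax.text(j, i, text, ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="GAM (%)")
    ax.set_xlabel("gene")
    ax.set_ylabel("sample")
    fig.tight_layout()
    fig.savefig(pdf_path, format="pdf")
    plt.close(fig)
    return pdf_path
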
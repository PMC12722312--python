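"""Minimal diagnostic read plot: coverage rows over the switch regions."""

from __future__ import annotations

import numpy as np

from .annotation import SwitchAnnotation
from .cluster import ClusterSet
from .msa import MSAMatrix


def read_plot(msa: MSAMatrix, cs: ClusterSet, annot: SwitchAnnotation,
              path: str | None = None, max_reads: int = 2000):
    """Render reads (rows, ordered by cluster) x reduced positions.

    Colors encode the signed coverage: normal, duplicated, inverted.
    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(cs.labels, kind="stable")[:max_reads]
    cov = msa.coverage()[order].toarray()
    img = np.zeros_like(cov, dtype=float)
    img[cov == 1] = 1.0
    img[cov > 1] = 2.0
    img[cov < 0] = -1.0
    fig, ax = plt.subplots(figsize=(10, 6))
    ax.imshow(img, aspect="auto", interpolation="nearest", cmap="coolwarm",
              vmin=-2, vmax=2)
    for r in annot:
        ax.axvline(r.offset, color="grey", lw=0.5)
        ax.text(r.offset + len(r) / 2, -0.02 * len(order), r.name,
                ha="center", fontsize=7)
    ax.set_xlabel("reduced position (nt)")
    ax.set_ylabel("reads (by cluster)")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
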
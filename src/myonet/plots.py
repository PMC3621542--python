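"""PCA scatter export: control green, MD red, NA blue, centroid star."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from myonet.severity import CONTROL_LABEL, SeverityModel

_COLORS = {CONTROL_LABEL: "tab:green", "MD": "tab:red", "NA": "tab:blue"}


def plot_pca(model: SeverityModel, X: np.ndarray, labels, path: str | Path) -> None:
    """Save a 2-D or 3-D scatter of projections with the control centroid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    proj = model.transform(X)
    labels = np.asarray(labels)
    dim = min(proj.shape[1], 3)
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(111, projection="3d" if dim == 3 else None)
    for lab in np.unique(labels):
        pts = proj[labels == lab]
        ax.scatter(*pts[:, :dim].T, s=18, color=_COLORS.get(str(lab), "gray"),
                   label=str(lab))
    ax.scatter(*model.centroid[:dim], marker="*", s=160, color="black",
               label="control centroid")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
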
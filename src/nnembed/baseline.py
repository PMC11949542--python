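"""PCA reconstruction baseline at matched component count.

Principal components are fitted on the pooled, mean-centred node rows of
all networks (mirroring the autoencoder's pooled training); each row is
projected onto the leading components and back-projected, clipped to
[0, 1] and thresholded at 0.5 (the boundary counts as 1, matching the
autoencoder's rule).  ``n_components = 0`` degenerates to thresholding
the column means — the majority-class baseline per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .exceptions import AlignmentError, ConfigurationError
from .netio import DirectedBinaryNetwork
from .nne import accuracy, error_rate, tp_accuracy

logger = logging.getLogger(__name__)

__all__ = ["BaselineReport", "pca_reconstruct", "compare_nne_pca"]


@dataclass
class BaselineReport:
    """Per-network reconstruction quality of one method."""

    method: str  # "nne" | "pca"
    component_count: int
    table: pd.DataFrame  # columns: network, accuracy, error_rate, tp_accuracy


def pca_reconstruct(
    nets: Sequence[DirectedBinaryNetwork],
    n_components: int = 13,
    threshold: float = 0.5,
) -> tuple[list[DirectedBinaryNetwork], BaselineReport]:
    """Low-rank reconstruction of every network through pooled PCA."""
    n_nodes = nets[0].n_nodes
    if any(net.n_nodes != n_nodes for net in nets):
        raise ConfigurationError("all networks must share the same node count")
    if n_components > n_nodes:
        raise ConfigurationError(
            f"n_components={n_components} exceeds node count {n_nodes}"
        )
    x = np.vstack([net.adjacency for net in nets]).astype(float)
    if n_components == 0:
        recon_rows = np.tile(x.mean(axis=0), (x.shape[0], 1))
    else:
        rank = np.linalg.matrix_rank(x - x.mean(axis=0))
        if n_components > rank:
            logger.warning(
                "n_components=%d exceeds centred rank %d; excess components are inert",
                n_components, rank,
            )
        pca = PCA(n_components=min(n_components, *x.shape))
        recon_rows = pca.inverse_transform(pca.fit_transform(x))
    recon_rows = np.clip(recon_rows, 0.0, 1.0)
    binary = (recon_rows >= threshold).astype(np.int8)

    recons, rows = [], []
    for i, net in enumerate(nets):
        b = binary[i * n_nodes : (i + 1) * n_nodes].copy()
        np.fill_diagonal(b, 0)
        recons.append(
            DirectedBinaryNetwork(b, list(net.node_ids), None, f"{net.name}_pca")
        )
        rows.append(
            {
                "network": net.name or str(i),
                "accuracy": accuracy(b, net.adjacency),
                "error_rate": error_rate(b, net.adjacency),
                "tp_accuracy": tp_accuracy(b, net.adjacency),
            }
        )
    return recons, BaselineReport("pca", n_components, pd.DataFrame(rows))


def compare_nne_pca(
    nne_report: BaselineReport, pca_report: BaselineReport
) -> pd.DataFrame:
    """Paired per-network accuracy differences (positive = NNE better).

    Both reports must cover the same networks at the same component
    count.  The returned frame carries per-network deltas plus a summary
    row with their mean and standard deviation.
    """
    if nne_report.component_count != pca_report.component_count:
        raise AlignmentError("reports use different component counts")
    a = nne_report.table.set_index("network")
    b = pca_report.table.set_index("network")
    if set(a.index) != set(b.index):
        raise AlignmentError("reports cover different network sets")
    b = b.loc[a.index]
    delta = pd.DataFrame(
        {
            "accuracy_delta": a["accuracy"] - b["accuracy"],
            "tp_accuracy_delta": a["tp_accuracy"] - b["tp_accuracy"],
        }
    )
    summary = pd.DataFrame(
        {
            "accuracy_delta": [delta["accuracy_delta"].mean(), delta["accuracy_delta"].std()],
            "tp_accuracy_delta": [
                delta["tp_accuracy_delta"].mean(),
                delta["tp_accuracy_delta"].std(),
            ],
        },
        index=["mean", "sd"],
    )
    return pd.concat([delta, summary])
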
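"""Single-linkage clustering of percent-identity matrices.

The homolog families are summarised by a symmetric percent-identity matrix;
converting identity to dissimilarity (100 − identity) and agglomerating
with nearest-point (single) linkage yields the family dendrogram. The
linkage itself is scipy's; this module wraps it in a small
:class:`Dendrogram` with labels, cophenetic distances and merge bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .types import GagesdError


def identity_to_distance(identity: np.ndarray) -> np.ndarray:
    """d_ij = 100 − P_ij; symmetric with zero diagonal."""
    identity = np.asarray(identity, dtype=float)
    d = 100.0 - identity
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class Dendrogram:
    """Merge list in scipy linkage convention plus leaf labels.

    ``merges`` rows are (node u, node v, height, member count); leaves are
    nodes 0..n-1 and merge step k creates node n+k.
    """

    merges: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.labels)
        if n >= 2 and self.merges.shape != (n - 1, 4):
            raise ValueError("merge list must have n-1 rows of 4")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges,
                            columns=["node_u", "node_v", "height", "count"])


def single_linkage(distance: np.ndarray, labels: list[str]) -> Dendrogram:
    """Agglomerate with the nearest-point (single linkage) algorithm."""
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 2:
        raise GagesdError("distance matrix must be square with n >= 2")
    if np.isnan(d).any():
        raise GagesdError("distance matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-9):
        raise GagesdError("distance matrix is not symmetric")
    if len(labels) != d.shape[0]:
        raise GagesdError("label count does not match matrix size")
    Z = linkage(squareform(d, checks=False), method="single")
    return Dendrogram(merges=Z, labels=list(labels))


def cophenetic(dendrogram: Dendrogram) -> np.ndarray:
    """Cophenetic distances: height of the lowest common merge per pair."""
    condensed = cophenet(dendrogram.merges)
    return squareform(condensed)
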
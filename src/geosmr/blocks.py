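"""Spatial cross-validation blocks via hierarchical clustering.

Regions are agglomerated on their inter-centroid distance matrix and the
dendrogram is cut at the semivariogram range, so that held-out blocks are
separated from the training regions by roughly the decorrelation distance.
Complete linkage is the default because it alone bounds every block's
internal diameter by the cut distance, which is what makes cutting at the
range meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import InvalidInputError
from .types import BlockAssignment

_LINKAGES = ("complete", "average", "single")


def cluster_regions(
    distmat: np.ndarray,
    cut_distance: float,
    linkage_name: str = "complete",
    region_ids: np.ndarray | None = None,
) -> BlockAssignment:
    """Agglomerate and cut at ``cut_distance``; labels are 0..n_blocks-1.

    Labels are renumbered by first occurrence in region order, so the
    partition is invariant (up to renaming) under region permutation.
    Raises if the cut yields a single block — leave-one-block-out CV needs
    at least two.
    """
    distmat = np.asarray(distmat, dtype=float)
    if cut_distance <= 0:
        raise InvalidInputError("cut_distance must be positive")
    if linkage_name not in _LINKAGES:
        raise InvalidInputError(f"linkage must be one of {_LINKAGES}")
    if distmat.ndim != 2 or distmat.shape[0] != distmat.shape[1]:
        raise InvalidInputError("distance matrix must be square")
    if not np.allclose(distmat, distmat.T) or np.any(np.diag(distmat) != 0):
        raise InvalidInputError("distance matrix must be symmetric with zero diagonal")

    n = distmat.shape[0]
    z = linkage(squareform(distmat, checks=False), method=linkage_name)
    raw = fcluster(z, t=cut_distance, criterion="distance")

    # canonical renumbering by first occurrence
    labels = np.empty(n, dtype=int)
    mapping: dict[int, int] = {}
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        labels[i] = mapping[r]
    n_blocks = len(mapping)
    if n_blocks < 2:
        raise InvalidInputError(
            f"cut at {cut_distance:g} yields a single block; "
            "choose a smaller cut distance to enable cross-validation"
        )
    if region_ids is None:
        region_ids = np.arange(n)
    return BlockAssignment(
        region_ids=np.asarray(region_ids),
        labels=labels,
        cut_distance=float(cut_distance),
        linkage_name=linkage_name,
        n_blocks=n_blocks,
    )


def block_summary(assignment: BlockAssignment, distmat: np.ndarray) -> pd.DataFrame:
    """Per-block diagnostics: size, diameter, mean intra-block distance."""
    distmat = np.asarray(distmat, dtype=float)
    rows = []
    for b in range(assignment.n_blocks):
        idx = np.nonzero(assignment.labels == b)[0]
        sub = distmat[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        rows.append(
            {
                "block": b,
                "size": len(idx),
                "diameter": float(sub[iu].max()) if len(idx) > 1 else 0.0,
                "mean_intra_distance": float(sub[iu].mean()) if len(idx) > 1 else 0.0,
                "singleton": len(idx) == 1,
            }
        )
    return pd.DataFrame(rows)
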
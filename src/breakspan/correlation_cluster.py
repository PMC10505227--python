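"""Factor comparison at cut sites: correlation and rank clustering.

Builds a sites x factors enrichment matrix, compares factors pairwise with
the Pearson product-moment correlation on raw enrichment, and clusters
factors by average-linkage (UPGMA) agglomeration on Euclidean distances
between per-factor rank vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .coverage_signal import DEFAULT_FLANK, site_enrichment
from .formats_io import SignalTrack
from .genome_sites import CutSite


def build_matrix(
    tracks: Dict[str, SignalTrack],
    sites: Sequence[CutSite],
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Sites x factors enrichment matrix (rows = site_ids, columns = factors)."""
    if len(tracks) < 1:
        raise ValueError("need at least one track")
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    columns = {}
    site_ids = [s.site_id for s in sites]
    for name, track in tracks.items():
        enr = site_enrichment(track, sites, flank)
        columns[name] = [enr[sid] for sid in site_ids]
    return pd.DataFrame(columns, index=pd.Index(site_ids, name="site_id"))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; constant vectors are an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson rho over factor columns, one row per unordered pair."""
    rows = []
    for fa, fb in combinations(matrix.columns, 2):
        rows.append(
            {
                "factor_a": fa,
                "factor_b": fb,
                "rho": pearson(matrix[fa].to_numpy(), matrix[fb].to_numpy()),
                "n": len(matrix),
            }
        )
    return pd.DataFrame(rows, columns=["factor_a", "factor_b", "rho", "n"])


def rank_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Within each factor column, ascending ranks with average ties."""
    return matrix.rank(axis=0, method="average", ascending=True)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over factors.

    ``linkage`` is a scipy-style (n-1, 4) merge matrix over ``labels``;
    cluster ids >= n refer to earlier merges.
    """

    labels: List[str]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have shape (n_factors - 1, 4)")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> List[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance matrix (pairing order of pdist)."""
        return hierarchy.cophenet(self.linkage)

    def to_newick(self) -> str:
        n = len(self.labels)
        names: Dict[int, str] = {i: self.labels[i] for i in range(n)}
        height: Dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            names[n + k] = f"({names[a]}:{la:g},{names[b]}:{lb:g})"
            height[n + k] = h
        return names[2 * n - 2] + ";"


def cluster_factors(rank_matrix: pd.DataFrame) -> Dendrogram:
    """UPGMA over Euclidean distances between per-factor rank vectors.

    Factors are taken in column order, which breaks distance ties
    deterministically; pass columns sorted by name for name-order ties.
    """
    if rank_matrix.shape[1] < 2:
        raise ValueError("need at least 2 factors to cluster")
    vectors = rank_matrix.to_numpy(dtype=float).T  # factors x sites
    dist = pdist(vectors, metric="euclidean")
    linkage = hierarchy.linkage(dist, method="average")
    return Dendrogram(list(rank_matrix.columns), linkage)


def attach_groups(
    matrix: pd.DataFrame, groups: Dict[str, str], column: str = "group"
) -> pd.DataFrame:
    """Attach optional per-site group labels (e.g. HR-prone / NHEJ-prone)."""
    out = matrix.copy()
    out[column] = [groups.get(sid, "") for sid in matrix.index]
    return out
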
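"""CAST (Cluster Affinity Search Technique) over enrichment-profile affinities.

CAST grows one cluster at a time from a high-connectivity seed, alternately
adding outside elements whose mean affinity to the open cluster reaches the
threshold t and removing members whose mean affinity falls below t, until the
cluster is stable; it then closes the cluster and repeats on the remainder.
Affinity between two genes is their Pearson correlation across challenge
steps mapped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class AffinityMatrix:
    """Symmetric gene x gene similarity matrix with entries in [0, 1]."""

    data: pd.DataFrame
    constant_profiles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = self.data.to_numpy(float)
        if m.size == 0:
            return
        if not np.allclose(m, m.T):
            raise ValueError("affinity matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("affinity diagonal must be 1")
        if m.min() < -1e-9 or m.max() > 1 + 1e-9:
            raise ValueError("affinities must lie in [0, 1]")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class ClusterAssignment:
    """gene_id -> cluster index (0-based, in order of formation)."""

    assignment: pd.Series
    threshold: float
    cluster_order: list[list[str]] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return 0 if self.assignment.empty else int(self.assignment.max()) + 1

    def members(self, k: int) -> list[str]:
        return list(self.assignment.index[self.assignment == k])


def profile_similarity(profiles: pd.DataFrame, metric: str = "pearson") -> AffinityMatrix:
    """Pairwise profile affinity, s = (r + 1)/2 for Pearson r.

    Constant profiles have undefined correlation; their r is defined as 0
    (affinity 0.5) and the gene ids are flagged. ``metric='euclidean'`` maps
    plain Euclidean distance d through 1/(1 + d) as an alternative affinity.
    """
    if len(profiles) < 2 or profiles.shape[1] < 2:
        raise ValueError("need >= 2 profiles of length >= 2")
    x = profiles.to_numpy(float)
    ids = list(profiles.index)
    if metric == "pearson":
        sd = x.std(axis=1)
        const = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x)
        r = np.nan_to_num(r, nan=0.0)
        s = (r + 1.0) / 2.0
        flagged = [ids[i] for i in np.flatnonzero(const)]
        if flagged:
            logger.warning("profile_similarity: %d constant profiles, r set to 0", len(flagged))
    elif metric == "euclidean":
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
        s = 1.0 / (1.0 + d)
        flagged = []
    else:
        raise ValueError("metric must be 'pearson' or 'euclidean'")
    np.fill_diagonal(s, 1.0)
    s = np.clip((s + s.T) / 2.0, 0.0, 1.0)
    return AffinityMatrix(pd.DataFrame(s, index=ids, columns=ids), flagged)


def cast_cluster(affinity: AffinityMatrix, t: float = 0.8, max_sweeps: int = 1000) -> ClusterAssignment:
    """Run the CAST add/remove loop until every element is assigned.

    The open cluster is seeded with the unassigned element of maximal total
    affinity to the remaining pool; ADD takes the unassigned element with the
    highest mean affinity to the cluster provided it is >= t, REMOVE evicts
    the member with the lowest mean affinity to the other members when it is
    < t. Ties break lexicographically on gene_id so runs are reproducible.
    """
    if not (0.0 <= t <= 1.0):
        raise ValueError("threshold t must be in [0, 1]")
    ids = sorted(affinity.ids)
    if not ids:
        return ClusterAssignment(pd.Series(dtype=int), t, [])
    s = affinity.data.loc[ids, ids].to_numpy(float)
    index = {g: i for i, g in enumerate(ids)}

    unassigned = set(ids)
    clusters: list[list[str]] = []
    while unassigned:
        pool = sorted(unassigned)
        pool_idx = [index[g] for g in pool]
        # seed: maximal total affinity to the rest of the pool
        totals = s[np.ix_(pool_idx, pool_idx)].sum(axis=1)
        seed = pool[int(np.argmax(totals))]  # argmax takes first => lexicographic tie-break
        cluster = {seed}
        outside = unassigned - cluster

        for _ in range(max_sweeps):
            changed = False
            # ADD phase
            while outside:
                cl_idx = [index[g] for g in cluster]
                best_g, best_a = None, -1.0
                for g in sorted(outside):
                    a = s[index[g], cl_idx].mean()
                    if a > best_a + 1e-15:
                        best_g, best_a = g, a
                if best_a >= t:
                    cluster.add(best_g)
                    outside.discard(best_g)
                    changed = True
                else:
                    break
            # REMOVE phase
            while len(cluster) > 1:
                worst_g, worst_a = None, 2.0
                for g in sorted(cluster):
                    others = [index[h] for h in cluster if h != g]
                    a = s[index[g], others].mean()
                    if a < worst_a - 1e-15:
                        worst_g, worst_a = g, a
                if worst_a < t:
                    cluster.discard(worst_g)
                    outside.add(worst_g)
                    changed = True
                else:
                    break
            if not changed:
                break
        else:
            logger.warning("cast_cluster: add/remove loop hit max_sweeps; closing cluster as-is")

        clusters.append(sorted(cluster))
        unassigned -= cluster

    mapping = {g: k for k, members in enumerate(clusters) for g in members}
    assignment = pd.Series({g: mapping[g] for g in ids}, name="cluster").astype(int)
    assignment.index.name = "gene_id"
    return ClusterAssignment(assignment, t, clusters)


def cluster_mean_profiles(profiles: pd.DataFrame, assignment: ClusterAssignment) -> pd.DataFrame:
    """Mean profile per cluster (rows ordered by cluster index) for heat maps."""
    joined = profiles.join(assignment.assignment, how="inner")
    return joined.groupby("cluster").mean().sort_index()
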
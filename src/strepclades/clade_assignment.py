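"""Species clustering from pairwise ANI and clade label propagation.

Genomes are clustered into species by average-linkage agglomeration on the
distance 1 - ANI/100, cutting the tree at the conventional 95% ANI species
boundary.  Clade labels for named reference species are then propagated to
every genome in the same species cluster.  Clusters containing no named
species are classified by their position in the (uncut) dendrogram:
clusters falling inside the smallest subtree spanning every named genome
sit among the named clades and are labelled "Other", while clusters
attaching outside that spanning subtree are basal to all named clades and
are labelled "Unknown".  (For a single unplaced outgroup this reduces to
root-level attachment; the span form also classifies several independent
basal outgroups correctly when they chain onto the tree one after another.)

Merge order is made deterministic by breaking equal-height ties in favour of
the pair with the lexicographically smallest member ids, so genome input
order never changes an assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .table_io import CladeMap, TableFormatError

logger = logging.getLogger(__name__)


@dataclass
class ANIMatrix:
    """Symmetric pairwise average-nucleotide-identity percentages."""

    genome_ids: list[str]
    ani: np.ndarray

    def __post_init__(self) -> None:
        self.ani = np.asarray(self.ani, dtype=float)
        n = len(self.genome_ids)
        if self.ani.shape != (n, n):
            raise TableFormatError(
                f"ANI matrix shape {self.ani.shape} does not match "
                f"{n} genome ids"
            )
        if len(set(self.genome_ids)) != n:
            raise TableFormatError("duplicate genome ids")
        if np.isnan(self.ani).any():
            raise TableFormatError("NaN in ANI matrix")
        if not np.allclose(self.ani, self.ani.T, atol=1e-8):
            raise TableFormatError("ANI matrix is not symmetric")
        if not np.allclose(np.diag(self.ani), 100.0):
            raise TableFormatError("ANI diagonal must be 100")
        if self.ani.min() < 0 or self.ani.max() > 100:
            raise TableFormatError("ANI values outside [0, 100]")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def distances(self) -> np.ndarray:
        """1 - ANI/100 with an exact-zero diagonal."""
        d = 1.0 - self.ani / 100.0
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class SpeciesClusters:
    """A species partition plus the full dendrogram it was cut from."""

    genome_ids: list[str]
    partition: dict[str, int]
    linkage: np.ndarray  # scipy linkage over genomes, deterministic order
    threshold_ani: float
    named_members: dict[int, set[str]] = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.partition.values()))

    def members(self, cluster_id: int) -> list[str]:
        return sorted(g for g, c in self.partition.items() if c == cluster_id)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.partition)
        return pd.DataFrame(
            {"genome": rows, "cluster": [self.partition[g] for g in rows]}
        )


def _deterministic_order(ani: ANIMatrix) -> list[int]:
    """Process genomes in lexicographic id order so that equal-height merges
    resolve identically regardless of the input ordering."""
    return sorted(range(ani.n_genomes), key=lambda i: ani.genome_ids[i])


def cluster_species(ani: ANIMatrix, threshold_ani: float = 95.0) -> SpeciesClusters:
    """Average-linkage species clustering at a given ANI threshold.

    Returns the partition at distance 1 - threshold/100 together with the
    full (uncut) dendrogram for downstream clade-position queries.  A single
    genome yields one singleton cluster.
    """
    if not 0.0 < threshold_ani < 100.0:
        raise ValueError(f"threshold_ani must be in (0, 100), got {threshold_ani}")
    order = _deterministic_order(ani)
    ids = [ani.genome_ids[i] for i in order]
    if ani.n_genomes == 1:
        return SpeciesClusters(
            genome_ids=ids,
            partition={ids[0]: 1},
            linkage=np.empty((0, 4)),
            threshold_ani=threshold_ani,
        )
    dist = ani.distances()[np.ix_(order, order)]
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    cut = hierarchy.fcluster(link, t=1.0 - threshold_ani / 100.0, criterion="distance")
    # relabel clusters by smallest member id for stable numbering
    by_cluster: dict[int, list[str]] = {}
    for gid, c in zip(ids, cut):
        by_cluster.setdefault(int(c), []).append(gid)
    relabel = {
        c: rank + 1
        for rank, c in enumerate(sorted(by_cluster, key=lambda c: min(by_cluster[c])))
    }
    partition = {gid: relabel[int(c)] for gid, c in zip(ids, cut)}
    return SpeciesClusters(
        genome_ids=ids, partition=partition, linkage=link, threshold_ani=threshold_ani
    )


def _leaf_sets(linkage: np.ndarray, n_leaves: int) -> list[set[int]]:
    """Leaf index set under every node (leaves first, then merges)."""
    sets: list[set[int]] = [{i} for i in range(n_leaves)]
    for a, b, _, _ in linkage:
        sets.append(sets[int(a)] | sets[int(b)])
    return sets


def assign_clades(
    clusters: SpeciesClusters,
    named_labels: dict[str, str] | pd.DataFrame,
    *,
    on_conflict: str = "error",
) -> CladeMap:
    """Propagate clade labels from named reference species to all genomes.

    ``named_labels`` maps genome/species identifiers (which must match the
    genome ids that were clustered) to one of the eight named clades.  Every
    genome in a cluster containing a named reference inherits its clade.
    Clusters without any named member are labelled "Other" or "Unknown" by
    the dendrogram-position rule (see module docstring).

    A cluster containing named species of two different clades is an error
    by default; ``on_conflict="majority"`` downgrades it to a majority vote
    with a warning (ties resolved by label sort order).
    """
    if isinstance(named_labels, pd.DataFrame):
        named_labels = dict(zip(named_labels.iloc[:, 0], named_labels.iloc[:, 1]))
    if not named_labels:
        raise ValueError("named_labels is empty")
    if on_conflict not in ("error", "majority"):
        raise ValueError(f"on_conflict must be 'error' or 'majority': {on_conflict}")

    known = set(clusters.genome_ids)
    named_in_tree = {g: c for g, c in named_labels.items() if g in known}
    if not named_in_tree:
        raise ValueError("no named reference species matches a clustered genome")

    # clade per cluster from its named members
    cluster_clade: dict[int, str] = {}
    for cid in clusters.cluster_ids:
        members = clusters.members(cid)
        hits = sorted({named_in_tree[g] for g in members if g in named_in_tree})
        clusters.named_members[cid] = {g for g in members if g in named_in_tree}
        if len(hits) > 1:
            votes = pd.Series(
                [named_in_tree[g] for g in members if g in named_in_tree]
            ).value_counts()
            msg = (
                f"cluster {cid} contains named species of conflicting clades: "
                f"{dict(votes)}"
            )
            if on_conflict == "error":
                raise ValueError(msg)
            logger.warning("%s; taking majority vote", msg)
            top = votes[votes == votes.max()]
            cluster_clade[cid] = sorted(top.index)[0]
        elif hits:
            cluster_clade[cid] = hits[0]

    labels: dict[str, str] = {}
    provenance: dict[str, str] = {}

    n = len(clusters.genome_ids)
    idx = {g: i for i, g in enumerate(clusters.genome_ids)}
    leafsets = _leaf_sets(clusters.linkage, n) if n > 1 else [{0}]
    named_idx = {idx[g] for g in named_in_tree}
    # smallest subtree spanning every named genome
    named_span = min(
        (s for s in leafsets if named_idx <= s), key=len
    )

    for cid in clusters.cluster_ids:
        members = clusters.members(cid)
        if cid in cluster_clade:
            clade = cluster_clade[cid]
            for g in members:
                labels[g] = clade
                provenance[g] = (
                    "named_reference" if g in named_in_tree else "propagated"
                )
            continue
        # inside the named spanning subtree => Other; outside => basal =>
        # Unknown (tree leafsets nest, so the cluster is either contained
        # in the span or disjoint from it)
        want = {idx[g] for g in members}
        clade = "Unknown" if want.isdisjoint(named_span) else "Other"
        flag = "unknown_rule" if clade == "Unknown" else "other_rule"
        for g in members:
            labels[g] = clade
            provenance[g] = flag
    return CladeMap(labels, provenance)
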
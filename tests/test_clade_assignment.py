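"""ANI species clustering and clade label propagation.

Independent oracles: connected components of the >=threshold ANI graph for
well-separated planted blocks, and an explicit lowest-common-ancestor search
on the merge tree for the Other/Unknown dendrogram rule.
"""

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from strepclades import ANIMatrix, assign_clades, cluster_species, generate_ani
from strepclades.table_io import TableFormatError


def pair_ani(v: float) -> ANIMatrix:
    return ANIMatrix(["a", "b"], np.array([[100.0, v], [v, 100.0]]))


class TestClusterSpecies:
    @pytest.mark.parametrize("ani,expected", [(96.0, 1), (94.0, 2), (95.0, 1)])
    def test_95_percent_species_boundary(self, ani, expected):
        clusters = cluster_species(pair_ani(ani), threshold_ani=95.0)
        assert len(clusters.cluster_ids) == expected

    def test_single_genome_is_singleton_cluster(self):
        clusters = cluster_species(ANIMatrix(["only"], np.array([[100.0]])))
        assert clusters.partition == {"only": 1}

    def test_planted_blocks_match_component_oracle(self, rng):
        sizes = [4, 3, 5]
        n = sum(sizes)
        ani = rng.uniform(80, 85, size=(n, n))
        start = 0
        for s in sizes:
            block = rng.uniform(97, 99, size=(s, s))
            ani[start:start + s, start:start + s] = block
            start += s
        ani = (ani + ani.T) / 2
        np.fill_diagonal(ani, 100.0)
        mat = ANIMatrix([f"g{i:02d}" for i in range(n)], ani)
        clusters = cluster_species(mat, threshold_ani=95.0)
        # oracle: connected components of the thresholded ANI graph
        _, comp = connected_components(ani >= 95.0, directed=False)
        oracle = {}
        for gid, c in zip(mat.genome_ids, comp):
            oracle.setdefault(c, set()).add(gid)
        ours = {}
        for gid, c in clusters.partition.items():
            ours.setdefault(c, set()).add(gid)
        assert sorted(ours.values(), key=sorted) == sorted(
            oracle.values(), key=sorted
        )

    def test_threshold_monotone_never_merges(self, rng):
        n = 12
        ani = rng.uniform(70, 100, size=(n, n))
        ani = (ani + ani.T) / 2
        np.fill_diagonal(ani, 100.0)
        mat = ANIMatrix([f"g{i}" for i in range(n)], ani)
        lo = cluster_species(mat, threshold_ani=90.0).partition
        hi = cluster_species(mat, threshold_ani=96.0).partition
        # every high-threshold cluster is contained in one low-threshold cluster
        for cid in set(hi.values()):
            members = [g for g, c in hi.items() if c == cid]
            assert len({lo[g] for g in members}) == 1

    def test_genome_order_does_not_change_assignments(self, rng):
        planted = generate_ani(n_clades=3, species_per_clade=2,
                               genomes_per_species=2, n_unplaced=1, seed=5)
        perm = rng.permutation(planted.ani.n_genomes)
        shuffled = ANIMatrix(
            [planted.ani.genome_ids[i] for i in perm],
            planted.ani.ani[np.ix_(perm, perm)],
        )
        a = assign_clades(cluster_species(planted.ani), planted.references)
        b = assign_clades(cluster_species(shuffled), planted.references)
        assert a.labels == b.labels

    def test_nan_rejected(self):
        with pytest.raises(TableFormatError, match="NaN"):
            ANIMatrix(["a", "b"], np.array([[100.0, np.nan], [np.nan, 100.0]]))


def _lca_oracle_labels(clusters, references):
    """Independent Other/Unknown oracle: walk the scipy merge tree explicitly
    and find the smallest node spanning all named genomes; unnamed clusters
    inside that node are Other, clusters disjoint from it are basal and
    therefore Unknown."""
    idx = {g: i for i, g in enumerate(clusters.genome_ids)}
    tree = hierarchy.to_tree(clusters.linkage)
    nodes = []

    def collect(node):
        leaves = set(node.pre_order(lambda x: x.id))
        nodes.append(leaves)
        if not node.is_leaf():
            collect(node.left)
            collect(node.right)

    collect(tree)
    named = {idx[g] for g in references if g in idx}
    span = min((lv for lv in nodes if named <= lv), key=len)
    labels = {}
    for cid in clusters.cluster_ids:
        members = {idx[g] for g in clusters.members(cid)}
        named_in = {references[g] for g in clusters.members(cid) if g in references}
        if named_in:
            (clade,) = named_in
            for g in clusters.members(cid):
                labels[g] = clade
            continue
        verdict = "Other" if members & span else "Unknown"
        for g in clusters.members(cid):
            labels[g] = verdict
    return labels


class TestAssignClades:
    def test_named_cluster_inherits_clade(self):
        planted = generate_ani(n_clades=2, species_per_clade=2,
                               genomes_per_species=3, n_unplaced=0, seed=1)
        clusters = cluster_species(planted.ani)
        clades = assign_clades(clusters, planted.references)
        for genome, clade in planted.planted_labels.labels.items():
            assert clades[genome] == clade
        assert clades.provenance[list(planted.references)[0]] == "named_reference"

    def test_other_and_unknown_match_lca_oracle(self):
        planted = generate_ani(n_clades=3, species_per_clade=3,
                               genomes_per_species=2, n_unplaced=2, seed=11)
        clusters = cluster_species(planted.ani)
        # drop one in-clade species from the references: its cluster now has
        # no named member but still sits inside a named clade subtree
        refs = dict(planted.references)
        dropped = [g for g in refs if g.startswith("Mitis_sp2")]
        for g in dropped:
            del refs[g]
        clades = assign_clades(clusters, refs)
        oracle = _lca_oracle_labels(clusters, refs)
        assert clades.labels == oracle
        # the orphaned in-clade cluster is Other, basal genomes are Unknown
        assert clades["Mitis_sp2_g1"] == "Other"
        assert clades["basal_sp1_g1"] == "Unknown"
        assert clades.provenance["Mitis_sp2_g1"] == "other_rule"
        assert clades.provenance["basal_sp1_g1"] == "unknown_rule"

    def test_planted_labels_fully_recovered(self):
        planted = generate_ani(n_clades=4, species_per_clade=3,
                               genomes_per_species=3, n_unplaced=2, seed=3)
        clusters = cluster_species(planted.ani)
        clades = assign_clades(clusters, planted.references)
        assert clades.labels == planted.planted_labels.labels

    def test_conflicting_named_labels_error_and_majority(self):
        planted = generate_ani(n_clades=2, species_per_clade=1,
                               genomes_per_species=3, n_unplaced=0, seed=2)
        clusters = cluster_species(planted.ani)
        refs = dict(planted.references)
        # plant a conflicting label inside the Sanguinis species cluster
        refs["Sanguinis_sp1_g2"] = "Mitis"
        refs["Sanguinis_sp1_g3"] = "Sanguinis"
        with pytest.raises(ValueError, match="conflicting clades"):
            assign_clades(clusters, refs)
        majority = assign_clades(clusters, refs, on_conflict="majority")
        assert majority["Sanguinis_sp1_g1"] == "Sanguinis"

    def test_empty_named_labels_is_error(self):
        planted = generate_ani(seed=0)
        clusters = cluster_species(planted.ani)
        with pytest.raises(ValueError, match="empty"):
            assign_clades(clusters, {})
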
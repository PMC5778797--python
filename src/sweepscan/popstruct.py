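"""Population structure: Reynolds distances, rooted trees, drift kinship F.

The FLK/hapFLK model treats population allele frequencies as a Gaussian
diffusion along a rooted tree whose branch lengths are in drift units
(Reynolds scale).  The kinship matrix F collects, for each pair of
populations, the drift accumulated on the part of their root-to-leaf paths
they share; its diagonal is the total drift of each population.  The tree
is built by neighbour joining on Reynolds distances and rooted on an
outgroup, which is then pruned before computing F.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import nnls

from .genotype_io import FrequencyTable


@dataclass
class DistanceMatrix:
    """Symmetric population x population Reynolds distance matrix."""

    populations: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.populations)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite distances")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.populations.index(a), self.populations.index(b)])


@dataclass
class KinshipF:
    """Population kinship matrix F derived from a rooted drift tree."""

    populations: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def subset(self, pops: list[str]) -> "KinshipF":
        ix = [self.populations.index(p) for p in pops]
        return KinshipF(list(pops), self.values[np.ix_(ix, ix)])


# ---------------------------------------------------------------------------
# Reynolds distances
# ---------------------------------------------------------------------------


def reynolds_distance(
    freqs: FrequencyTable,
    pop_a: str,
    pop_b: str,
    snp_subset=None,
    corrected: bool = False,
) -> float:
    """Reynolds coancestry distance between two populations.

    The default frequency-only estimator is, over usable biallelic loci l,

        D = sum_l sum_alleles (p_al - p_bl)^2
            / (2 sum_l (1 - sum_alleles p_al p_bl))

    ``corrected=True`` applies the classical sample-size correction, which
    subtracts the expected within-population sampling contribution from the
    numerator (requires allele counts in the table).
    """
    ia, ib = freqs.populations.index(pop_a), freqs.populations.index(pop_b)
    idx = np.arange(freqs.n_snps) if snp_subset is None else np.asarray(snp_subset)
    pa, pb = freqs.freq[ia, idx], freqs.freq[ib, idx]
    na, nb = freqs.n_obs[ia, idx], freqs.n_obs[ib, idx]
    usable = np.isfinite(pa) & np.isfinite(pb)
    if corrected:
        usable &= (na >= 4) & (nb >= 4)
    if not usable.any():
        raise ValueError(f"no usable locus for populations {pop_a!r}, {pop_b!r}")
    pa, pb, na, nb = pa[usable], pb[usable], na[usable], nb[usable]
    # biallelic: sum over both alleles of the squared frequency difference
    num_l = 2 * (pa - pb) ** 2
    den_l = 2 * (1 - (pa * pb + (1 - pa) * (1 - pb)))
    if corrected:
        # Reynolds/Weir/Cockerham 1983 bias correction, per-locus sample sizes
        # expressed in diploid individuals
        n_a, n_b = na / 2.0, nb / 2.0
        het_a = 2 * pa * (1 - pa)
        het_b = 2 * pb * (1 - pb)
        al = num_l / 2 - (n_a + n_b) * (
            n_a * het_a + n_b * het_b
        ) / (4 * n_a * n_b * (n_a + n_b - 1))
        bl = (num_l / 2) * (
            1 - (4 * n_a * n_b) / ((n_a + n_b) * (4 * n_a * n_b - n_a - n_b))
        ) + (4 * n_a * n_b - n_a - n_b) / (
            (n_a + n_b) * (4 * n_a * n_b - n_a - n_b)
        ) * (n_a * het_a + n_b * het_b) / 2
        with np.errstate(invalid="ignore", divide="ignore"):
            d = float(al.sum() / (al.sum() + bl.sum()))
        return max(d, 0.0)
    den = float(den_l.sum())
    if den == 0:
        return 0.0
    return float(num_l.sum()) / den


def build_distance_matrix(
    freqs: FrequencyTable, snp_subset=None, corrected: bool = False
) -> DistanceMatrix:
    """Elementwise Reynolds distances over all population pairs."""
    pops = list(freqs.populations)
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = reynolds_distance(
                freqs, pops[i], pops[j], snp_subset=snp_subset, corrected=corrected
            )
    return DistanceMatrix(pops, d)


# ---------------------------------------------------------------------------
# neighbour joining with outgroup rooting
# ---------------------------------------------------------------------------


def nj_tree(D: DistanceMatrix, outgroup_label: str | None = None) -> dendropy.Tree:
    """Neighbour-joining tree, optionally rooted at the outgroup branch midpoint.

    Negative NJ branch lengths are clamped to zero and the deficit shifted to
    the sibling branch so pairwise path lengths are preserved where possible.
    """
    labels = list(D.populations)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 populations")
    if outgroup_label is not None and outgroup_label not in labels:
        raise ValueError(f"outgroup {outgroup_label!r} not among populations")
    if not np.isfinite(D.values).all():
        raise ValueError("non-finite distances")

    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
    dist = D.values.astype(float).copy()
    active = list(range(n))

    def _clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb, la = lb + la, 0.0
        if lb < 0:
            la, lb = max(la + lb, 0.0), 0.0
        return max(la, 0.0), lb

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        la = 0.5 * sub[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lb = sub[i, j] - la
        la, lb = _clamp(la, lb)
        parent = dendropy.Node()
        na, nb = nodes[a], nodes[b]
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length, nb.edge.length = la, lb
        new_d = 0.5 * (dist[a, :] + dist[b, :] - dist[a, b])
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_d
        dist[:-1, -1] = new_d
        dist[-1, -1] = 0.0
        nodes.append(parent)
        active = [k for k in active if k not in (a, b)] + [len(nodes) - 1]

    # final three-point join
    a, b, c = active
    dab, dac, dbc = dist[a, b], dist[a, c], dist[b, c]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    root = dendropy.Node()
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        root.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True

    if outgroup_label is not None:
        og = tree.find_node_with_taxon_label(outgroup_label)
        half = (og.edge.length or 0.0) / 2
        tree.reroot_at_edge(og.edge, length1=max(half, 0.0), length2=max(half, 0.0),
                            update_bipartitions=False)
        # ensure the outgroup hangs directly off the new root
    for e in tree.preorder_edge_iter():
        if e.length is None:
            e.length = 0.0
    tree.suppress_unifurcations()
    return tree


def prune_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Drop the outgroup leaf (rooting retained) before computing F."""
    pruned = tree.clone(depth=1)
    taxon = pruned.taxon_namespace.get_taxon(outgroup_label)
    if taxon is None:
        raise ValueError(f"outgroup {outgroup_label!r} not in tree")
    pruned.prune_taxa([taxon], suppress_unifurcations=False)
    # remove the root unifurcation left behind but keep the rooting point:
    # the child edge of a unifurcating root carries shared drift of everyone,
    # which is unobservable in F only if the root has a single child; drop it.
    root = pruned.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        child.parent_node = None
        child.edge.length = 0.0
        pruned.seed_node = child
        root = child
    pruned.update_bipartitions(suppress_unifurcations=False)
    return pruned


def kinship_from_tree(tree: dendropy.Tree, outgroup_label: str | None = None) -> KinshipF:
    """Shared root-path drift for every population pair.

    ``F_ij`` is the summed length of branches common to the root-to-i and
    root-to-j paths; ``F_ii`` is the root-to-i path length.  If
    ``outgroup_label`` is given that leaf is pruned first.
    """
    if not tree.is_rooted:
        raise ValueError("kinship requires a rooted tree")
    work = prune_outgroup(tree, outgroup_label) if outgroup_label else tree
    leaves = [l for l in work.leaf_node_iter()]
    labels = [l.taxon.label for l in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate population leaves")
    paths = []
    for leaf in leaves:
        edges = []
        node = leaf
        while node.parent_node is not None:
            length = node.edge.length or 0.0
            if length < 0:
                raise ValueError("negative branch length")
            edges.append((id(node.edge), length))
            node = node.parent_node
        paths.append(dict(edges))
    n = len(labels)
    f = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            shared = paths[i].keys() & paths[j].keys()
            f[i, j] = f[j, i] = sum(paths[i][e] for e in shared)
    return KinshipF(labels, f)


REYNOLDS_TO_DRIFT = 2.0
"""Pairwise Reynolds distance estimates the coancestry of the pair, which
under pure drift is half the drift accumulated along the path separating the
two populations (each population contributes its own branch).  Distances are
therefore doubled before tree fitting so branch lengths — and hence F —
come out in the per-population drift units of the FLK covariance model."""


def build_kinship(
    freqs: FrequencyTable,
    outgroup: str,
    snp_subset=None,
    corrected: bool = False,
    drift_scale: float = REYNOLDS_TO_DRIFT,
) -> tuple[KinshipF, dendropy.Tree]:
    """Convenience: Reynolds distances -> NJ -> outgroup root -> F.

    Returns the ingroup kinship matrix and the rooted tree (outgroup still
    attached, for inspection / local-tree refits).  Branch lengths are in
    drift units (Reynolds distances scaled by ``drift_scale``).
    """
    D = build_distance_matrix(freqs, snp_subset=snp_subset, corrected=corrected)
    D = DistanceMatrix(D.populations, D.values * drift_scale)
    tree = nj_tree(D, outgroup_label=outgroup)
    F = kinship_from_tree(tree, outgroup_label=outgroup)
    return F, tree


def local_tree_from_freqs(
    global_tree: dendropy.Tree,
    freqs: FrequencyTable,
    snp_subset,
    corrected: bool = False,
    drift_scale: float = REYNOLDS_TO_DRIFT,
) -> dendropy.Tree:
    """Branch lengths of the genome-wide topology re-fit from the Reynolds
    distances of a genomic region (drift-unit scaling as in build_kinship).
    Elongated terminal branches relative to the genome tree flag the
    populations a local sweep acted on."""
    leaf_labels = [l.taxon.label for l in global_tree.leaf_node_iter()]
    sub = freqs.subset_pops([p for p in freqs.populations if p in leaf_labels])
    D = build_distance_matrix(sub, snp_subset=snp_subset, corrected=corrected)
    D = DistanceMatrix(D.populations, D.values * drift_scale)
    return fit_local_tree(global_tree, D)


# ---------------------------------------------------------------------------
# local trees
# ---------------------------------------------------------------------------


def tree_path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            t1 = tree.taxon_namespace.get_taxon(labels[i])
            t2 = tree.taxon_namespace.get_taxon(labels[j])
            d[i, j] = d[j, i] = pdm.patristic_distance(t1, t2)
    return DistanceMatrix(labels, d)


def fit_local_tree(global_tree: dendropy.Tree, local_D: DistanceMatrix) -> dendropy.Tree:
    """Re-fit branch lengths of the genome-wide topology to local distances.

    The topology is kept fixed; branch lengths are re-estimated by
    non-negative least squares of leaf-to-leaf path lengths against the
    local Reynolds distances.  The two edges meeting at the root are not
    separately identifiable from leaf-to-leaf distances, so they are fitted
    as one parameter and split in the proportion the global tree uses.
    Terminal branches that lengthen locally relative to the global fit are
    the classical signature of a population-specific sweep.
    """
    tree = global_tree.clone(depth=1)
    leaves = [l for l in tree.leaf_node_iter()]
    labels = [l.taxon.label for l in leaves]
    if set(labels) != set(local_D.populations):
        raise ValueError("local distance matrix and tree leaves disagree")

    # collect edges; merge the root's child edges into one parameter
    root_children = tree.seed_node.child_nodes()
    edge_ids: list[tuple] = []
    edge_lookup: dict[int, int] = {}
    if len(root_children) == 2:
        eid = ("root_pair",)
        edge_ids.append(eid)
        for ch in root_children:
            edge_lookup[id(ch.edge)] = 0
        merged_global = sum((ch.edge.length or 0.0) for ch in root_children)
        root_split = [
            (ch, (ch.edge.length or 0.0) / merged_global if merged_global > 0 else 0.5)
            for ch in root_children
        ]
    else:
        root_split = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None or id(node.edge) in edge_lookup:
            continue
        edge_lookup[id(node.edge)] = len(edge_ids)
        edge_ids.append((id(node.edge),))

    # root-to-leaf edge sets (raw edge ids; merged root pair resolved below)
    root_edge_ids = (
        {id(ch.edge) for ch in root_children} if root_split is not None else set()
    )
    paths = {}
    for leaf in leaves:
        eids = set()
        node = leaf
        while node.parent_node is not None:
            eids.add(id(node.edge))
            node = node.parent_node
        paths[leaf.taxon.label] = eids

    n = len(labels)
    rows, targets = [], []
    for i in range(n):
        for j in range(i + 1, n):
            row = np.zeros(len(edge_ids))
            # symmetric difference of root paths = edges on the i<->j path;
            # a path crossing the root uses both root edges, i.e. the full
            # merged root parameter once
            for eid in paths[labels[i]] ^ paths[labels[j]]:
                if eid in root_edge_ids:
                    row[0] += 0.5
                else:
                    row[edge_lookup[eid]] += 1.0
            rows.append(row)
            targets.append(local_D.get(labels[i], labels[j]))
    A = np.vstack(rows)
    y = np.asarray(targets)
    lengths, _ = nnls(A, y)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        # rank-deficient design: NNLS still returns a feasible solution
        pass

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        col = edge_lookup[id(node.edge)]
        if root_split is not None and col == 0:
            continue
        node.edge.length = float(lengths[col])
    if root_split is not None:
        for ch, frac in root_split:
            ch.edge.length = float(lengths[0]) * frac
    return tree
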
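"""Reynolds distances, NJ trees, kinship F and local-tree refits."""

import dendropy
import numpy as np
import pytest

from sweepscan import popstruct as ps
from sweepscan import simulate as sim
from sweepscan.genotype_io import FrequencyTable, allele_frequencies


def _freq_table(freq: np.ndarray, pops=None) -> FrequencyTable:
    n_pops, n_snps = freq.shape
    pops = pops or [f"P{i+1}" for i in range(n_pops)]
    return FrequencyTable(
        populations=list(pops),
        snp_ids=[f"m{j}" for j in range(n_snps)],
        chromosomes=["1"] * n_snps,
        positions=np.arange(1, n_snps + 1) * 100,
        freq=freq,
        n_obs=np.full((n_pops, n_snps), 100),
    )


def _tree(newick: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


# ---------------------------------------------------------------------------
# Reynolds distance
# ---------------------------------------------------------------------------


def test_reynolds_identical_populations_zero():
    f = _freq_table(np.array([[0.3, 0.6, 0.1], [0.3, 0.6, 0.1]]))
    assert ps.reynolds_distance(f, "P1", "P2") == pytest.approx(0.0)


def test_reynolds_opposite_fixation_is_one():
    f = _freq_table(np.array([[1.0, 1.0], [0.0, 0.0]]))
    assert ps.reynolds_distance(f, "P1", "P2") == pytest.approx(1.0)


def test_reynolds_matches_per_locus_oracle():
    rng = np.random.default_rng(0)
    for _ in range(200):
        pa = rng.uniform(0, 1, 50)
        pb = rng.uniform(0, 1, 50)
        f = _freq_table(np.vstack([pa, pb]))
        num = sum((pa[l] - pb[l]) ** 2 + ((1 - pa[l]) - (1 - pb[l])) ** 2
                  for l in range(50))
        den = 2 * sum(1 - (pa[l] * pb[l] + (1 - pa[l]) * (1 - pb[l]))
                      for l in range(50))
        assert ps.reynolds_distance(f, "P1", "P2") == pytest.approx(num / den)


def test_reynolds_no_usable_locus_raises():
    f = _freq_table(np.array([[np.nan, np.nan], [0.5, 0.5]]))
    f.n_obs[0] = 0
    with pytest.raises(ValueError):
        ps.reynolds_distance(f, "P1", "P2")


def test_distance_matrix_zero_and_permutation():
    freq = np.array([[0.2, 0.7], [0.2, 0.7]])
    D = ps.build_distance_matrix(_freq_table(freq))
    assert np.allclose(D.values, 0.0)

    rng = np.random.default_rng(5)
    freq = rng.uniform(0.1, 0.9, (4, 30))
    D1 = ps.build_distance_matrix(_freq_table(freq))
    perm = [2, 0, 3, 1]
    D2 = ps.build_distance_matrix(
        _freq_table(freq[perm], pops=[f"P{i+1}" for i in perm])
    )
    for a in range(4):
        for b in range(4):
            assert D2.values[a, b] == pytest.approx(D1.values[perm[a], perm[b]])


def test_distance_matrix_snp_subset_equals_restriction():
    rng = np.random.default_rng(9)
    freq = rng.uniform(0.1, 0.9, (3, 40))
    subset = np.arange(10, 25)
    D_sub = ps.build_distance_matrix(_freq_table(freq), snp_subset=subset)
    D_dir = ps.build_distance_matrix(_freq_table(freq[:, subset]))
    assert np.allclose(D_sub.values, D_dir.values)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------


def test_nj_three_point_formulas():
    D = ps.DistanceMatrix(
        ["A", "B", "C"],
        np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]]),
    )
    tree = ps.nj_tree(D)
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
    assert lengths["B"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
    assert lengths["C"] == pytest.approx((0.5 + 0.4 - 0.3) / 2)


def test_nj_recovers_known_four_leaf_tree():
    t = _tree("((A:0.1,B:0.12):0.05,(C:0.2,D:0.07):0.03);")
    D = ps.tree_path_distances(t)
    rebuilt = ps.nj_tree(D)
    D2 = ps.tree_path_distances(rebuilt)
    idx = [D2.populations.index(p) for p in D.populations]
    assert np.abs(D.values - D2.values[np.ix_(idx, idx)]).max() < 1e-9


def test_nj_all_zero_distances_star():
    D = ps.DistanceMatrix(["A", "B", "C", "D"], np.zeros((4, 4)))
    tree = ps.nj_tree(D)
    for leaf in tree.leaf_node_iter():
        assert leaf.edge.length == pytest.approx(0.0)


def test_nj_additive_recovery_random_trees():
    """NJ on exactly additive distances recovers the generating tree
    (checked by path-distance identity, which pins the topology) for
    100 random binary trees with 5-8 leaves."""
    for seed in range(100):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        tree = sim.random_tree(n, total_drift=1.0, seed=seed)
        # strictly positive branch lengths so the topology is identifiable
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = float(e.length) + 0.02
        D = ps.tree_path_distances(tree)
        rebuilt = ps.nj_tree(D)
        D2 = ps.tree_path_distances(rebuilt)
        idx = [D2.populations.index(p) for p in D.populations]
        assert np.abs(D.values - D2.values[np.ix_(idx, idx)]).max() < 1e-9, seed


def test_nj_rejects_nonfinite_and_too_few():
    with pytest.raises(ValueError):
        ps.nj_tree(ps.DistanceMatrix(["A", "B"], np.zeros((2, 2))))
    bad = np.zeros((3, 3))
    bad[0, 1] = bad[1, 0] = np.nan
    with pytest.raises(ValueError):
        ps.DistanceMatrix(["A", "B", "C"], bad)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def test_kinship_star_tree_is_diagonal():
    t = _tree("(A:0.1,B:0.2,C:0.05);")
    F = ps.kinship_from_tree(t)
    order = [F.populations.index(p) for p in ["A", "B", "C"]]
    vals = F.values[np.ix_(order, order)]
    assert np.allclose(vals, np.diag([0.1, 0.2, 0.05]))


def test_kinship_hand_example():
    t = _tree("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
    F = ps.kinship_from_tree(t)
    get = lambda a, b: F.values[F.populations.index(a), F.populations.index(b)]
    assert get("A", "B") == pytest.approx(0.05)
    assert get("A", "C") == pytest.approx(0.0)
    assert get("A", "A") == pytest.approx(0.15)


def test_kinship_reconstructs_path_lengths_and_is_psd():
    for seed in range(20):
        tree = sim.random_tree(6, total_drift=0.5, seed=seed)
        F = ps.kinship_from_tree(tree)
        D = ps.tree_path_distances(tree)
        for i, a in enumerate(F.populations):
            for j, b in enumerate(F.populations):
                path = F.values[i, i] + F.values[j, j] - 2 * F.values[i, j]
                assert path == pytest.approx(D.get(a, b), abs=1e-10)
        assert np.linalg.eigvalsh(F.values).min() >= -1e-10


def test_kinship_outgroup_rooting_and_pruning():
    t = _tree("(((A:0.1,B:0.12):0.05,C:0.2):0.07,OUT:0.4);")
    D = ps.tree_path_distances(t)
    rooted = ps.nj_tree(D, outgroup_label="OUT")
    F = ps.kinship_from_tree(rooted, outgroup_label="OUT")
    assert "OUT" not in F.populations
    get = lambda a, b: F.values[F.populations.index(a), F.populations.index(b)]
    # drift is measured from the ingroup ancestor
    assert get("A", "A") == pytest.approx(0.15)
    assert get("A", "B") == pytest.approx(0.05)
    assert get("A", "C") == pytest.approx(0.0)


def test_kinship_requires_rooted_tree():
    t = dendropy.Tree.get(data="(A:0.1,B:0.1,C:0.1);", schema="newick")
    t.is_rooted = False
    with pytest.raises(ValueError):
        ps.kinship_from_tree(t)


# ---------------------------------------------------------------------------
# local trees
# ---------------------------------------------------------------------------


def test_local_fit_identity_on_global_distances():
    tree = sim.random_tree(6, total_drift=0.4, seed=3, outgroup="OUT")
    D = ps.tree_path_distances(tree)
    fitted = ps.fit_local_tree(tree, D)
    D2 = ps.tree_path_distances(fitted)
    idx = [D2.populations.index(p) for p in D.populations]
    assert np.abs(D.values - D2.values[np.ix_(idx, idx)]).max() < 1e-8


def test_local_fit_scales_linearly():
    tree = sim.random_tree(5, total_drift=0.4, seed=8)
    D = ps.tree_path_distances(tree)
    doubled = ps.DistanceMatrix(D.populations, D.values * 2)
    fitted = ps.fit_local_tree(tree, doubled)
    D2 = ps.tree_path_distances(fitted)
    idx = [D2.populations.index(p) for p in D.populations]
    assert np.abs(2 * D.values - D2.values[np.ix_(idx, idx)]).max() < 1e-8


def test_local_tree_lengthens_swept_terminal_branch():
    """Inside a swept window the selected population's terminal branch must
    come out longer than in the genome-wide tree (20/20 strong sweeps)."""
    hits = 0
    for rep in range(20):
        ds = sim.sweep_dataset(seed=500 + rep, n_snps=2000, n_loci=20,
                               outgroup="OUT", n_per_pop=25)
        freqs = allele_frequencies(ds.genotypes)
        _, gtree = ps.build_kinship(freqs, outgroup="OUT")
        window = np.array(sorted({e.locus for e in ds.selected}))
        local = ps.local_tree_from_freqs(gtree, freqs, snp_subset=window)
        g_len = gtree.find_node_with_taxon_label("P1").edge.length
        l_len = local.find_node_with_taxon_label("P1").edge.length
        hits += l_len > g_len
    assert hits == 20
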
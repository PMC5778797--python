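"""Synthetic drift/sweep datasets with known truth.

The generator mirrors the statistical model the scans assume: SNPs are
polymorphic in an ancestral population with frequency p0, and population
frequencies diffuse independently down a rooted tree whose branch lengths
are in drift units.  Two drift engines are provided: a truncated-normal
Gaussian diffusion (the FLK model itself) and a Wright–Fisher binomial
engine for cross-validation.  On top of the neutral frequencies one can
plant selection events (instantaneous displacement of a target population's
frequency, the final state a sweep leaves behind), mosaic haplotypes from K
founder haplotypes (the structure the cluster model fits), and spiked-in
related sample pairs (what the relatedness filter must catch).

Defaults are chosen to emulate SNP-array data from livestock breeds: p0
drawn uniformly on [0.25, 0.75] (array ascertainment favours common
variants and the scans assume ancestrally polymorphic SNPs), 5 kb marker
spacing, 20–25 diploid samples per population, and a few percent of total
drift per branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats

from .genotype_io import GenotypeTable
from .popstruct import KinshipF, kinship_from_tree

DEFAULT_P0_RANGE = (0.25, 0.75)
DEFAULT_SPACING_BP = 5_000


@dataclass
class SelectionEvent:
    """Instantaneous frequency displacement at one locus."""

    locus: int
    populations: list[str]
    target_freq: float

    def __post_init__(self) -> None:
        if not 0 <= self.target_freq <= 1:
            raise ValueError("target frequency must be in [0, 1]")


@dataclass
class SimulatedDataset:
    """Genotypes (and optionally haplotypes) plus the generating truth."""

    genotypes: GenotypeTable | None
    haplotypes: np.ndarray | None
    haplotype_populations: list[str] | None
    frequencies: np.ndarray  # (n_pops, n_snps) post-selection truth
    populations: list[str]
    tree: dendropy.Tree
    kinship: KinshipF
    p0: np.ndarray
    selected: list[SelectionEvent] = field(default_factory=list)
    related_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    founder_truth: dict | None = None


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def random_tree(
    n_pops: int,
    total_drift: float = 0.2,
    seed: int = 0,
    outgroup: str | None = None,
    outgroup_drift: float | None = None,
) -> dendropy.Tree:
    """Random rooted bifurcating tree over populations P1..Pn.

    Branch lengths are a Dirichlet(1) partition of ``total_drift``.  If an
    outgroup label is given it is attached directly at the root with its own
    branch length (default: ``total_drift``), so rooting by the outgroup
    recovers the true root.
    """
    rng = np.random.default_rng(seed)
    labels = [f"P{i + 1}" for i in range(n_pops)]
    taxa = dendropy.TaxonNamespace(labels + ([outgroup] if outgroup else []))
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for n in nodes:
        root.add_child(n)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    edges = [e for e in tree.preorder_edge_iter() if e.head_node is not root]
    parts = rng.dirichlet(np.ones(len(edges))) * total_drift
    for e, l in zip(edges, parts):
        e.length = float(l)
    if outgroup is not None:
        og = dendropy.Node(taxon=taxa.get_taxon(outgroup))
        root.add_child(og)
        og.edge.length = float(
            total_drift if outgroup_drift is None else outgroup_drift
        )
    return tree


# ---------------------------------------------------------------------------
# neutral drift
# ---------------------------------------------------------------------------


def simulate_frequencies(
    tree: dendropy.Tree,
    n_snps: int,
    seed: int = 0,
    p0_range: tuple[float, float] = DEFAULT_P0_RANGE,
    p0_beta: tuple[float, float] | None = None,
    engine: str = "truncated_normal",
    ne: int = 500,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Propagate ancestral frequencies down the tree.

    Returns ``(populations, freq (n_pops, n_snps), p0)``.  The
    truncated-normal engine draws child ~ N(parent, p0 (1-p0) df) truncated
    to [0, 1] for a branch of drift length df; the Wright–Fisher engine
    iterates binomial sampling over ``round(2 ne df)`` generations in a
    population of ``ne`` diploids.
    """
    rng = np.random.default_rng(seed)
    if p0_beta is not None:
        a, b = p0_beta
        p0 = rng.beta(a, b, size=n_snps)
    else:
        lo, hi = p0_range
        p0 = rng.uniform(lo, hi, size=n_snps)
    var_unit = p0 * (1 - p0)

    node_freq: dict[int, np.ndarray] = {id(tree.seed_node): p0.copy()}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        df = node.edge.length or 0.0
        if df < 0:
            raise ValueError("negative branch drift length")
        parent = node_freq[id(node.parent_node)]
        if df == 0:
            node_freq[id(node)] = parent.copy()
            continue
        if engine == "truncated_normal":
            sd = np.sqrt(var_unit * df)
            a = (0.0 - parent) / sd
            b = (1.0 - parent) / sd
            child = stats.truncnorm.rvs(a, b, loc=parent, scale=sd,
                                        random_state=rng)
        elif engine == "wright_fisher":
            gens = max(1, int(round(2 * ne * df)))
            child = parent.copy()
            for _ in range(gens):
                child = rng.binomial(2 * ne, child) / (2 * ne)
        else:
            raise ValueError(f"unknown drift engine {engine!r}")
        node_freq[id(node)] = child
    leaves = [l for l in tree.leaf_node_iter()]
    pops = [l.taxon.label for l in leaves]
    freq = np.vstack([node_freq[id(l)] for l in leaves])
    return pops, freq, p0


def inject_selection(
    freq: np.ndarray,
    populations: list[str],
    events: list[SelectionEvent],
) -> np.ndarray:
    """Apply selection events (returns a modified copy).

    Overlapping events that set the same (population, locus) cell to two
    different targets are contradictory and raise.
    """
    out = freq.copy()
    seen: dict[tuple[int, int], float] = {}
    for ev in events:
        if not 0 <= ev.locus < freq.shape[1]:
            raise ValueError(f"event locus {ev.locus} out of range")
        for pop in ev.populations:
            i = populations.index(pop)
            key = (i, ev.locus)
            if key in seen and seen[key] != ev.target_freq:
                raise ValueError(
                    f"contradictory selection events at locus {ev.locus}, "
                    f"population {pop}"
                )
            seen[key] = ev.target_freq
            out[i, ev.locus] = ev.target_freq
    return out


def copy_window(
    freq: np.ndarray,
    populations: list[str],
    donor: str,
    recipient: str,
    loci: slice,
) -> np.ndarray:
    """Adaptive-introgression scenario: copy the donor's local frequency
    profile into the recipient over a window of loci."""
    out = freq.copy()
    out[populations.index(recipient), loci] = freq[populations.index(donor), loci]
    return out


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    freq: np.ndarray,
    populations: list[str],
    n_per_pop: int,
    seed: int = 0,
    chromosome: str = "1",
    spacing_bp: int = DEFAULT_SPACING_BP,
    positions: np.ndarray | None = None,
) -> GenotypeTable:
    """Binomial(2, p) genotype calls per individual; deterministic in seed."""
    rng = np.random.default_rng(seed)
    n_pops, n_snps = freq.shape
    calls = np.empty((n_pops * n_per_pop, n_snps), dtype=np.int8)
    sample_ids, labels = [], []
    for i, pop in enumerate(populations):
        block = rng.binomial(2, np.clip(freq[i], 0, 1),
                             size=(n_per_pop, n_snps)).astype(np.int8)
        calls[i * n_per_pop:(i + 1) * n_per_pop] = block
        sample_ids += [f"{pop}_{j + 1}" for j in range(n_per_pop)]
        labels += [pop] * n_per_pop
    if positions is None:
        positions = np.arange(1, n_snps + 1, dtype=np.int64) * spacing_bp
    return GenotypeTable(
        sample_ids=sample_ids,
        populations=labels,
        snp_ids=[f"snp{j + 1}" for j in range(n_snps)],
        chromosomes=[chromosome] * n_snps,
        positions=positions,
        allele_a=["A"] * n_snps,
        allele_b=["B"] * n_snps,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# mosaic haplotypes
# ---------------------------------------------------------------------------


def simulate_haplotypes(
    tree: dendropy.Tree,
    n_snps: int,
    n_haps_per_pop: int,
    K: int = 5,
    switch_rate: float = 0.02,
    founder_theta: float = 0.5,
    weight_drift_scale: float = 4.0,
    noise: float = 0.01,
    seed: int = 0,
    fix_founder: dict | None = None,
):
    """Mosaic haplotypes from K founders with tree-drifted founder weights.

    Founder haplotypes are Bernoulli(``founder_theta``) per SNP.  Each
    population's founder weights start uniform at the root and drift along
    the tree on the logit scale (softmax of logits perturbed by
    N(0, weight_drift_scale^2 * branch_length)), which keeps the simplex
    valid without rejection.  Each sampled haplotype is a founder mosaic:
    the founder is re-drawn from the population weights with probability
    ``switch_rate`` per SNP interval; alleles are copied from the founder
    with a small flip ``noise`` (genotyping error / recent mutation).

    ``fix_founder`` optionally maps a population label to
    ``(founder_index, locus_slice)``: inside the window every haplotype of
    that population copies the given founder (a haplotype sweep).

    Returns ``(haplotypes, populations_per_hap, truth)`` where truth records
    founders, weights and founder paths.
    """
    if K < 2:
        raise ValueError("need at least 2 founders")
    if not 0 < switch_rate < 1:
        raise ValueError("switch rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    founders = rng.binomial(1, founder_theta, size=(K, n_snps)).astype(np.int8)
    logits: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(K)}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        df = node.edge.length or 0.0
        parent = logits[id(node.parent_node)]
        logits[id(node)] = parent + rng.normal(
            0.0, weight_drift_scale * np.sqrt(max(df, 0.0)), size=K
        )
    leaves = [l for l in tree.leaf_node_iter()]
    pops = [l.taxon.label for l in leaves]
    weights = {}
    for leaf, pop in zip(leaves, pops):
        e = np.exp(logits[id(leaf)] - logits[id(leaf)].max())
        weights[pop] = e / e.sum()

    haps = np.empty((len(pops) * n_haps_per_pop, n_snps), dtype=np.int8)
    hap_pops: list[str] = []
    paths = np.empty_like(haps)
    row = 0
    for pop in pops:
        w = weights[pop]
        for _ in range(n_haps_per_pop):
            path = np.empty(n_snps, dtype=np.int64)
            path[0] = rng.choice(K, p=w)
            switches = rng.random(n_snps - 1) < switch_rate
            redraws = rng.choice(K, p=w, size=n_snps - 1)
            for s in range(1, n_snps):
                path[s] = redraws[s - 1] if switches[s - 1] else path[s - 1]
            if fix_founder and pop in fix_founder:
                founder_idx, window = fix_founder[pop]
                path[window] = founder_idx
            hap = founders[path, np.arange(n_snps)]
            if noise > 0:
                flips = rng.random(n_snps) < noise
                hap = np.where(flips, 1 - hap, hap)
            haps[row] = hap
            paths[row] = path
            hap_pops.append(pop)
            row += 1
    truth = {
        "founders": founders,
        "weights": weights,
        "paths": paths,
        "theta_effective": founders * (1 - noise) + (1 - founders) * noise,
    }
    return haps, hap_pops, truth


# ---------------------------------------------------------------------------
# related pairs
# ---------------------------------------------------------------------------


def spike_related_pairs(
    G: GenotypeTable,
    n_duplicates: int = 0,
    n_half_kin: int = 0,
    seed: int = 0,
) -> tuple[GenotypeTable, list[tuple[str, str, float]]]:
    """Append related copies of existing samples.

    Duplicates share the full genome (kinship 1/2, GRM off-diagonal near the
    diagonal).  Half-kin pairs share one gamete: the new sample inherits one
    allele from a random gamete of the template and one drawn from the
    population frequency (kinship 1/4).
    """
    rng = np.random.default_rng(seed)
    total = n_duplicates + n_half_kin
    if total == 0:
        return G, []
    if total > G.n_samples:
        raise ValueError("not enough samples to clone")
    templates = rng.choice(G.n_samples, size=total, replace=False)
    new_calls = [G.calls]
    new_ids, new_pops, pairs = [], [], []
    pop_index = G.population_index()
    for k, t in enumerate(templates):
        t = int(t)
        if k < n_duplicates:
            clone = G.calls[t].copy()
            kin = 0.5
            tag = "dup"
        else:
            pop = G.populations[t]
            ix = pop_index[pop]
            obs = G.calls[ix] >= 0
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(obs, G.calls[ix], 0).sum(axis=0) / (2 * obs.sum(axis=0))
            p = np.nan_to_num(p, nan=0.5)
            gamete_t = (rng.random(G.n_snps) < np.clip(G.calls[t], 0, 2) / 2.0)
            gamete_rand = rng.random(G.n_snps) < p
            clone = (gamete_t.astype(np.int8) + gamete_rand.astype(np.int8))
            kin = 0.25
            tag = "half"
        new_id = f"{G.sample_ids[t]}_{tag}{k + 1}"
        new_calls.append(clone[None, :])
        new_ids.append(new_id)
        new_pops.append(G.populations[t])
        pairs.append((G.sample_ids[t], new_id, kin))
    out = GenotypeTable(
        sample_ids=G.sample_ids + new_ids,
        populations=G.populations + new_pops,
        snp_ids=list(G.snp_ids),
        chromosomes=list(G.chromosomes),
        positions=G.positions.copy(),
        allele_a=list(G.allele_a),
        allele_b=list(G.allele_b),
        calls=np.vstack(new_calls),
    )
    return out, pairs


# ---------------------------------------------------------------------------
# scenario builders (the study conditions used throughout the tests)
# ---------------------------------------------------------------------------


def neutral_dataset(
    seed: int,
    n_pops: int = 8,
    n_snps: int = 20_000,
    total_drift: float = 0.2,
    n_per_pop: int | None = None,
    outgroup: str | None = None,
    engine: str = "truncated_normal",
) -> SimulatedDataset:
    """Neutral drift on a random tree; genotypes only if ``n_per_pop`` set."""
    tree = random_tree(n_pops, total_drift=total_drift, seed=seed,
                       outgroup=outgroup)
    pops, freq, p0 = simulate_frequencies(tree, n_snps, seed=seed + 1,
                                          engine=engine)
    ingroup = [p for p in pops if p != outgroup]
    F = kinship_from_tree(tree, outgroup_label=outgroup)
    G = None
    if n_per_pop is not None:
        G = simulate_genotypes(freq, pops, n_per_pop, seed=seed + 2)
    return SimulatedDataset(
        genotypes=G, haplotypes=None, haplotype_populations=None,
        frequencies=freq, populations=pops, tree=tree, kinship=F, p0=p0,
    )


def sweep_dataset(
    seed: int,
    n_pops: int = 8,
    n_snps: int = 2_000,
    n_loci: int = 20,
    total_drift: float = 0.2,
    n_per_pop: int | None = 25,
    outgroup: str | None = None,
    swept_pop: str = "P1",
    sweep_p0_max: float = 0.30,
    p0_range: tuple[float, float] = (0.1, 0.9),
) -> SimulatedDataset:
    """Hard sweeps: one population fixes the rarer ancestral allele at
    ``n_loci`` loci.  The frequency spectrum is broader than in the pure
    calibration scenario and selected loci are drawn among SNPs with low
    ancestral frequency — the rare-variant-rises-to-fixation picture of a
    hard sweep."""
    tree = random_tree(n_pops, total_drift=total_drift, seed=seed,
                       outgroup=outgroup)
    pops, freq, p0 = simulate_frequencies(tree, n_snps, seed=seed + 1,
                                          p0_range=p0_range)
    rng = np.random.default_rng(seed + 2)
    eligible = np.flatnonzero(p0 <= sweep_p0_max)
    if eligible.size < n_loci:
        eligible = np.argsort(p0)[:max(n_loci, 1)]
    loci = np.sort(rng.choice(eligible, size=n_loci, replace=False))
    events = [SelectionEvent(int(l), [swept_pop], 1.0) for l in loci]
    freq = inject_selection(freq, pops, events)
    G = None
    if n_per_pop is not None:
        G = simulate_genotypes(freq, pops, n_per_pop, seed=seed + 3)
    return SimulatedDataset(
        genotypes=G, haplotypes=None, haplotype_populations=None,
        frequencies=freq, populations=pops, tree=tree,
        kinship=kinship_from_tree(tree, outgroup_label=outgroup),
        p0=p0, selected=events,
    )


def heterogeneity_dataset(
    seed: int,
    mode: str,
    n_pops: int = 8,
    n_snps: int = 500,
    total_drift: float = 0.2,
    window: tuple[int, int] = (230, 270),
) -> SimulatedDataset:
    """One region, one vs two independent selected variants.

    ``mode='single'``: one locus fixed in one population.  ``mode='double'``:
    two loci inside the same window fixed in two different populations —
    the allelic-heterogeneity scenario (different variants selected in
    different populations at the same genomic location).
    """
    tree = random_tree(n_pops, total_drift=total_drift, seed=seed)
    pops, freq, p0 = simulate_frequencies(tree, n_snps, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    lo, hi = window
    eligible = lo + np.flatnonzero(p0[lo:hi] <= 0.35)
    if eligible.size < 2:
        eligible = lo + np.argsort(p0[lo:hi])[:2]
    if mode == "single":
        loci = rng.choice(eligible, size=1, replace=False)
        events = [SelectionEvent(int(loci[0]), [pops[0]], 1.0)]
    elif mode == "double":
        loci = rng.choice(eligible, size=2, replace=False)
        events = [
            SelectionEvent(int(loci[0]), [pops[0]], 1.0),
            SelectionEvent(int(loci[1]), [pops[-1]], 1.0),
        ]
    else:
        raise ValueError("mode must be 'single' or 'double'")
    freq = inject_selection(freq, pops, events)
    return SimulatedDataset(
        genotypes=None, haplotypes=None, haplotype_populations=None,
        frequencies=freq, populations=pops, tree=tree,
        kinship=kinship_from_tree(tree), p0=p0, selected=events,
    )


def mosaic_dataset(
    seed: int,
    n_pops: int = 8,
    n_snps: int = 5_000,
    n_haps_per_pop: int = 40,
    K: int = 5,
    total_drift: float = 0.2,
    switch_rate: float = 0.02,
    fix_founder: dict | None = None,
    weight_drift_scale: float = 4.0,
) -> SimulatedDataset:
    """Mosaic haplotypes on a random tree (the hapFLK study condition).

    ``weight_drift_scale`` controls how far founder weights drift between
    populations; parameter-recovery conditions use a mild value so every
    founder stays represented in the sample (an unsampled founder's
    frequencies are unrecoverable by construction).
    """
    tree = random_tree(n_pops, total_drift=total_drift, seed=seed)
    haps, hap_pops, truth = simulate_haplotypes(
        tree, n_snps, n_haps_per_pop, K=K, switch_rate=switch_rate,
        seed=seed + 1, fix_founder=fix_founder,
        weight_drift_scale=weight_drift_scale,
    )
    pops = list(dict.fromkeys(hap_pops))
    return SimulatedDataset(
        genotypes=None, haplotypes=haps, haplotype_populations=hap_pops,
        frequencies=np.empty((len(pops), 0)), populations=pops, tree=tree,
        kinship=kinship_from_tree(tree), p0=np.empty(0),
        founder_truth=truth,
    )
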
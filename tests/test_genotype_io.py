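"""Genotype I/O, QC chain, GRM, relatedness and LD-decay unit tests."""

import warnings
from math import lgamma, log

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan import genotype_io as gio
from sweepscan import simulate as sim
from sweepscan.genotype_io import MISSING

from conftest import random_table

# ---------------------------------------------------------------------------
# round trips and format errors
# ---------------------------------------------------------------------------


def test_plink_round_trip_identity(small_table, tmp_path):
    prefix = str(tmp_path / "fixture")
    gio.write_plink(small_table, prefix)
    back = gio.read_plink(f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam")
    assert back == small_table


def test_text_round_trip_identity(small_table, tmp_path):
    path = str(tmp_path / "fixture.tsv")
    gio.write_text(small_table, path)
    assert gio.read_text(path) == small_table


def test_plink_missing_cell_preserved(small_table, tmp_path):
    prefix = str(tmp_path / "fx")
    gio.write_plink(small_table, prefix)
    back = gio.read_plink(f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam")
    assert back.calls[1, 2] == MISSING
    mask = np.ones_like(back.calls, dtype=bool)
    mask[1, 2] = False
    assert np.array_equal(back.calls[mask], small_table.calls[mask])


def test_plink_individual_major_mode_rejected(small_table, tmp_path):
    prefix = str(tmp_path / "fx")
    gio.write_plink(small_table, prefix)
    raw = bytearray((tmp_path / "fx.bed").read_bytes())
    raw[2] = 0x00  # individual-major mode byte
    (tmp_path / "fx.bed").write_bytes(bytes(raw))
    with pytest.raises(gio.PlinkFormatError):
        gio.read_plink(f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam")


def test_plink_truncated_payload_rejected(small_table, tmp_path):
    prefix = str(tmp_path / "fx")
    gio.write_plink(small_table, prefix)
    raw = (tmp_path / "fx.bed").read_bytes()
    (tmp_path / "fx.bed").write_bytes(raw[:-1])
    with pytest.raises(gio.PlinkIntegrityError):
        gio.read_plink(f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam")


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def test_allele_frequency_simple_cases():
    G = gio.GenotypeTable(
        ["a", "b", "c"], ["P", "P", "P"], ["m1", "m2"], ["1", "1"],
        np.array([10, 20]), ["A", "A"], ["B", "B"],
        np.array([[0, MISSING], [1, MISSING], [2, MISSING]], dtype=np.int8),
    )
    f = gio.allele_frequencies(G)
    assert f.freq[0, 0] == pytest.approx(0.5)
    assert f.n_obs[0, 0] == 6
    assert np.isnan(f.freq[0, 1]) and f.n_obs[0, 1] == 0  # undefined flag


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_allele_frequency_matches_counting_oracle(seed):
    G = random_table(seed)
    f = gio.allele_frequencies(G)
    for k, pop in enumerate(f.populations):
        idx = [i for i, p in enumerate(G.populations) if p == pop]
        for j in range(G.n_snps):
            alleles = 0
            count = 0
            for i in idx:
                c = G.calls[i, j]
                if c != MISSING:
                    alleles += 2
                    count += int(c)
            assert f.n_obs[k, j] == alleles
            if alleles:
                assert f.freq[k, j] == pytest.approx(count / alleles)
            else:
                assert np.isnan(f.freq[k, j])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def _hwe_enumeration_oracle(naa: int, nab: int, nbb: int) -> float:
    """Direct enumeration of the conditional heterozygote distribution."""
    n = naa + nab + nbb
    nb = 2 * nbb + nab
    rare = min(nb, 2 * n - nb)
    logps = {}
    for nh in range(rare % 2, rare + 1, 2):
        nrr = (rare - nh) // 2
        ncc = n - nh - nrr
        if ncc < 0:
            continue
        logps[nh] = (lgamma(n + 1) - lgamma(ncc + 1) - lgamma(nh + 1)
                     - lgamma(nrr + 1) + nh * log(2))
    mx = max(logps.values())
    z = sum(np.exp(v - mx) for v in logps.values())
    probs = {k: float(np.exp(v - mx) / z) for k, v in logps.items()}
    p_obs = probs[nab]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def test_hwe_perfect_proportions_give_p_one():
    assert gio.hwe_test(25, 50, 25) == pytest.approx(1.0)


def test_hwe_complete_het_deficit_is_extreme():
    assert gio.hwe_test(50, 0, 50) < 1e-20


@pytest.mark.parametrize("counts", [(3, 4, 3), (1, 8, 1), (0, 5, 7), (10, 2, 0)])
def test_hwe_matches_enumeration(counts):
    assert gio.hwe_test(*counts) == pytest.approx(_hwe_enumeration_oracle(*counts))


def test_hwe_exhaustive_small_counts():
    for total in range(1, 21):
        for naa in range(total + 1):
            for nab in range(total - naa + 1):
                nbb = total - naa - nab
                assert gio.hwe_test(naa, nab, nbb) == pytest.approx(
                    _hwe_enumeration_oracle(naa, nab, nbb)
                ), (naa, nab, nbb)


def test_hwe_pvalues_conservative_under_null():
    """Exact-test p-values are valid (P(p <= a) <= a) under HWE sampling.

    The discrete support makes them conservative rather than exactly
    uniform, so the check is a one-sided bound with sampling slack.
    """
    rng = np.random.default_rng(7)
    n = 100
    reps = 10_000
    p = rng.uniform(0.1, 0.9, reps)
    probs = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)
    pvals = np.empty(reps)
    for r in range(reps):
        naa, nab, nbb = rng.multinomial(n, probs[r])
        pvals[r] = gio.hwe_test(int(naa), int(nab), int(nbb))
    for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
        emp = (pvals <= alpha).mean()
        slack = 3 * np.sqrt(alpha * (1 - alpha) / reps)
        assert emp <= alpha + slack


def test_hwe_zero_total_is_undefined():
    assert np.isnan(gio.hwe_test(0, 0, 0))


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------


def test_bh_qvalues_match_step_up_oracle():
    q = gio.fdr_qvalues([0.01, 0.02, 0.03, 0.04, 1.0], method="bh")
    assert np.allclose(q, [0.05, 0.05, 0.05, 0.05, 1.0])


def test_qvalue_edge_cases():
    assert gio.fdr_qvalues([], method="bh").size == 0
    assert gio.fdr_qvalues([0.05], method="bh")[0] == pytest.approx(0.05)
    assert gio.fdr_qvalues([0.05], method="storey")[0] == pytest.approx(0.05)
    assert np.allclose(gio.fdr_qvalues([0.2] * 10, method="bh"), 0.2)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_qvalue_properties(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, 1, 200)
    bh = gio.fdr_qvalues(p, method="bh")
    storey = gio.fdr_qvalues(p, method="storey")
    order = np.argsort(p)
    # monotone non-decreasing in sorted-p order
    assert np.all(np.diff(bh[order]) >= -1e-12)
    # step-up oracle
    m = p.size
    expected = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    assert np.allclose(bh[order], np.minimum(expected, 1.0))
    # Storey never exceeds BH (pi0 <= 1)
    assert np.all(storey <= bh + 1e-12)


# ---------------------------------------------------------------------------
# QC chain
# ---------------------------------------------------------------------------


def _qc_fixture():
    rng = np.random.default_rng(0)
    n, m = 100, 40
    p = rng.uniform(0.2, 0.8, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    calls[:, 3] = 0              # monomorphic
    calls[0:2, 7] = MISSING      # SNP missing rate 0.02
    calls[5, : m // 2] = MISSING  # sample missing rate 0.5
    return gio.GenotypeTable(
        [f"s{i:03d}" for i in range(n)], ["A"] * 50 + ["B"] * 50,
        [f"m{j}" for j in range(m)], ["1"] * m, np.arange(1, m + 1) * 10,
        ["A"] * m, ["C"] * m, calls,
    )


def test_qc_filter_reasons_and_order():
    out, report = gio.qc_filter(_qc_fixture())
    reasons = dict(report.removed_snps)
    assert reasons["m3"] == "MAF"
    assert reasons["m7"] == "SNP_MISSING"
    assert ("s005", "IND_MISSING") in report.removed_samples
    ids = [i for i, _ in report.removed_snps]
    assert len(ids) == len(set(ids))  # one reason per item


def test_qc_filter_idempotent():
    out, _ = gio.qc_filter(_qc_fixture())
    again, report = gio.qc_filter(out)
    assert again == out
    assert not report.removed_snps and not report.removed_samples


def test_qc_filter_clean_table_untouched():
    rng = np.random.default_rng(4)
    calls = rng.integers(0, 2, size=(30, 10)).astype(np.int8)
    calls[0] = 2 - calls[1]  # guarantee polymorphism crudely
    G = gio.GenotypeTable(
        [f"s{i}" for i in range(30)], ["A"] * 30,
        [f"m{j}" for j in range(10)], ["1"] * 10, np.arange(1, 11) * 5,
        ["A"] * 10, ["B"] * 10, calls,
    )
    out, report = gio.qc_filter(G, hwe_fdr=0.0)  # disable HWE for this check
    assert out == G
    assert not report.removed_snps and not report.removed_samples


def test_qc_filter_hwe_removes_gross_violation():
    rng = np.random.default_rng(2)
    n, m = 200, 60
    p = rng.uniform(0.3, 0.7, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    # SNP 11: all heterozygous in population A -> extreme HWE violation
    calls[:100, 11] = 1
    G = gio.GenotypeTable(
        [f"s{i:03d}" for i in range(n)], ["A"] * 100 + ["B"] * 100,
        [f"m{j}" for j in range(m)], ["1"] * m, np.arange(1, m + 1) * 10,
        ["A"] * m, ["C"] * m, calls,
    )
    _, report = gio.qc_filter(G)
    assert ("m11", "HWE") in report.removed_snps


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


def test_grm_identical_samples_share_diagonal():
    rng = np.random.default_rng(5)
    calls = rng.integers(0, 3, size=(1, 50)).astype(np.int8)
    calls = np.vstack([calls, calls, rng.integers(0, 3, size=(1, 50)).astype(np.int8)])
    G = gio.GenotypeTable(
        ["a", "b", "c"], ["P"] * 3, [f"m{j}" for j in range(50)], ["1"] * 50,
        np.arange(1, 51) * 10, ["A"] * 50, ["B"] * 50, calls,
    )
    grm = gio.compute_grm(G)
    assert grm[0, 1] == pytest.approx(grm[0, 0])
    assert grm[0, 1] == pytest.approx(grm[1, 1])


def test_grm_matches_direct_formula():
    calls = np.array(
        [[0, 1, 2, 1], [2, 1, 0, 0], [1, 2, 1, 0]], dtype=np.int8
    )
    G = gio.GenotypeTable(
        ["a", "b", "c"], ["P"] * 3, [f"m{j}" for j in range(4)], ["1"] * 4,
        np.arange(1, 5) * 10, ["A"] * 4, ["B"] * 4, calls,
    )
    p = calls.mean(axis=0) / 2
    z = calls - 2 * p
    expected = z @ z.T / np.sum(2 * p * (1 - p))
    assert np.allclose(gio.compute_grm(G), expected)


def test_grm_diagonal_near_one_under_hwe():
    rng = np.random.default_rng(11)
    p = rng.uniform(0.05, 0.95, 5000)
    calls = rng.binomial(2, p, size=(200, 5000)).astype(np.int8)
    G = gio.GenotypeTable(
        [f"s{i}" for i in range(200)], ["P"] * 200,
        [f"m{j}" for j in range(5000)], ["1"] * 5000,
        np.arange(1, 5001) * 10, ["A"] * 5000, ["B"] * 5000, calls,
    )
    grm = gio.compute_grm(G)
    assert abs(grm.diagonal().mean() - 1.0) < 0.05
    iu = np.triu_indices(200, k=1)
    off = grm[iu]
    # centering on sample-estimated frequencies forces row sums toward zero,
    # so the off-diagonal mean sits at -diag_mean/(n-1) rather than exactly 0
    expected = -grm.diagonal().mean() / (200 - 1)
    assert abs(off.mean() - expected) < 3 * off.std() / np.sqrt(off.size)


# ---------------------------------------------------------------------------
# relatedness filter
# ---------------------------------------------------------------------------


def test_relatedness_filter_needs_three_samples():
    with pytest.raises(ValueError):
        gio.relatedness_filter(np.eye(2), ["a", "b"])


def test_relatedness_filter_removes_one_per_duplicate_pair():
    rng = np.random.default_rng(3)
    p = rng.uniform(0.1, 0.9, 1500)
    calls = rng.binomial(2, p, size=(45, 1500)).astype(np.int8)
    G = gio.GenotypeTable(
        [f"s{i:03d}" for i in range(45)], ["P"] * 45,
        [f"m{j}" for j in range(1500)], ["1"] * 1500,
        np.arange(1, 1501) * 10, ["A"] * 1500, ["B"] * 1500, calls,
    )
    G2, pairs = sim.spike_related_pairs(G, n_duplicates=5, seed=3)
    grm = gio.compute_grm(G2)
    _, removed, fit = gio.relatedness_filter(grm, G2.sample_ids, fdr=0.05, seed=0)
    assert len(removed) == 5
    for a, b, _ in pairs:
        assert len({a, b} & set(removed)) == 1


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


def test_ld_identical_snps_have_r2_one():
    rng = np.random.default_rng(9)
    col = rng.integers(0, 3, size=20).astype(np.int8)
    calls = np.stack([col, col], axis=1)
    G = gio.GenotypeTable(
        [f"s{i}" for i in range(20)], ["P"] * 20, ["m1", "m2"], ["1", "1"],
        np.array([1000, 61_000]), ["A"] * 2, ["B"] * 2, calls,
    )
    t = gio.ld_decay(G, max_dist_bp=200_000, bin_bp=50_000)
    row = t[t["n_pairs"] > 0].iloc[0]
    assert row["bin_start_bp"] == 50_000  # distance 60 kb -> second bin
    assert row["mean_r2"] == pytest.approx(1.0)


def test_ld_independent_snps_hit_sampling_floor():
    rng = np.random.default_rng(3)
    n = 100
    calls = rng.binomial(2, rng.uniform(0.2, 0.8, 600), size=(n, 600)).astype(np.int8)
    G = gio.GenotypeTable(
        [f"s{i}" for i in range(n)], ["P"] * n,
        [f"m{j}" for j in range(600)], ["1"] * 600,
        np.arange(1, 601) * 1000, ["A"] * 600, ["B"] * 600, calls,
    )
    t = gio.ld_decay(G, max_dist_bp=600_000, bin_bp=600_000)
    mean_r2 = float(t["mean_r2"].iloc[0])
    n_pairs = int(t["n_pairs"].iloc[0])
    floor = 1 / (n - 1)
    se = floor * np.sqrt(2)  # r2 ~ chi2(1)/(n-1): sd ~ sqrt(2)*mean
    assert abs(mean_r2 - floor) < 3 * se / np.sqrt(n_pairs / 50)


def test_ld_decays_with_distance_on_mosaic_haplotypes():
    ds = sim.mosaic_dataset(seed=13, n_pops=2, n_snps=800, n_haps_per_pop=60,
                            K=4, switch_rate=0.01)
    h = ds.haplotypes
    g = (h[0::2] + h[1::2]).astype(np.int8)
    G = gio.GenotypeTable(
        [f"s{i}" for i in range(g.shape[0])], ["P"] * g.shape[0],
        [f"m{j}" for j in range(800)], ["1"] * 800,
        np.arange(1, 801) * 5000, ["A"] * 800, ["B"] * 800, g,
    )
    t = gio.ld_decay(G, max_dist_bp=1_000_000, bin_bp=50_000)
    r2 = t["mean_r2"].to_numpy()[:5]
    assert np.all(np.diff(r2) <= 1e-12)
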
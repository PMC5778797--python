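"""Genotype containers, PLINK I/O and the quality-control chain.

The QC chain mirrors standard practice for SNP-array data from structured
populations: per-population exact Hardy–Weinberg tests with FDR control,
removal of monomorphic and badly-genotyped SNPs and samples, a VanRaden
genomic relationship matrix, and removal of cryptically related individuals
identified by a two-component normal mixture fitted to the off-diagonal
relationship coefficients.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MISSING = np.int8(-1)
"""Sentinel for a missing genotype call."""

_PLINK_MAGIC = b"\x6c\x1b"
_PLINK_SNP_MAJOR = b"\x01"


class PlinkFormatError(ValueError):
    """Raised when a .bed file does not look like SNP-major PLINK binary."""


class PlinkIntegrityError(ValueError):
    """Raised when .bed payload size disagrees with .bim/.fam dimensions."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Sample x SNP genotype matrix with map and population labels.

    ``calls[i, s]`` counts copies of ``allele_b[s]`` carried by sample ``i``
    (0, 1, 2) or :data:`MISSING`.  Positions are 1-based and must be strictly
    increasing within each chromosome.
    """

    sample_ids: list[str]
    populations: list[str]
    snp_ids: list[str]
    chromosomes: list[str]
    positions: np.ndarray
    allele_a: list[str]
    allele_b: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, s = self.calls.shape
        if n != len(self.sample_ids) or s != len(self.snp_ids):
            raise ValueError("calls shape does not match sample/SNP counts")
        if len(self.populations) != n:
            raise ValueError("every sample needs exactly one population label")
        if n and not self.populations:
            raise ValueError("population label set is empty")
        ok = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= 2))
        if not ok.all():
            raise ValueError("calls must be 0, 1, 2 or MISSING")
        for chrom in dict.fromkeys(self.chromosomes):
            idx = [i for i, c in enumerate(self.chromosomes) if c == chrom]
            pos = self.positions[idx]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def population_index(self) -> dict[str, np.ndarray]:
        """Map population label -> integer sample indices (insertion order)."""
        out: dict[str, list[int]] = {}
        for i, p in enumerate(self.populations):
            out.setdefault(p, []).append(i)
        return {p: np.asarray(ix, dtype=int) for p, ix in out.items()}

    def snp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chrom": self.chromosomes,
                "pos": self.positions,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
            }
        )

    def subset(self, samples=None, snps=None) -> "GenotypeTable":
        """Return a copy restricted to the given sample / SNP index arrays."""
        si = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        vi = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeTable(
            sample_ids=[self.sample_ids[i] for i in si],
            populations=[self.populations[i] for i in si],
            snp_ids=[self.snp_ids[j] for j in vi],
            chromosomes=[self.chromosomes[j] for j in vi],
            positions=self.positions[vi],
            allele_a=[self.allele_a[j] for j in vi],
            allele_b=[self.allele_b[j] for j in vi],
            calls=self.calls[np.ix_(si, vi)],
        )

    def __eq__(self, other) -> bool:  # round-trip identity checks
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.populations == other.populations
            and self.snp_ids == other.snp_ids
            and self.chromosomes == other.chromosomes
            and np.array_equal(self.positions, other.positions)
            and self.allele_a == other.allele_a
            and self.allele_b == other.allele_b
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class FrequencyTable:
    """Per-(population, SNP) frequency of allele B plus allele counts.

    ``n_obs`` counts non-missing *alleles* (2 x genotyped samples); where it
    is zero the frequency is undefined and ``freq`` holds NaN.
    """

    populations: list[str]
    snp_ids: list[str]
    chromosomes: list[str]
    positions: np.ndarray
    freq: np.ndarray  # (n_pops, n_snps), NaN where undefined
    n_obs: np.ndarray  # (n_pops, n_snps) int

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def defined(self) -> np.ndarray:
        return self.n_obs > 0

    def subset_snps(self, idx) -> "FrequencyTable":
        idx = np.asarray(idx)
        return FrequencyTable(
            populations=list(self.populations),
            snp_ids=[self.snp_ids[j] for j in idx],
            chromosomes=[self.chromosomes[j] for j in idx],
            positions=self.positions[idx],
            freq=self.freq[:, idx],
            n_obs=self.n_obs[:, idx],
        )

    def subset_pops(self, pops: list[str]) -> "FrequencyTable":
        ix = [self.populations.index(p) for p in pops]
        return FrequencyTable(
            populations=list(pops),
            snp_ids=list(self.snp_ids),
            chromosomes=list(self.chromosomes),
            positions=self.positions,
            freq=self.freq[ix],
            n_obs=self.n_obs[ix],
        )


@dataclass
class QcReport:
    """Record of what the QC chain removed and why."""

    removed_snps: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("snp", i, r) for i, r in self.removed_snps]
        rows += [("sample", i, r) for i, r in self.removed_samples]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


# ---------------------------------------------------------------------------
# PLINK binary and plain-text I/O
# ---------------------------------------------------------------------------

# 2-bit PLINK codes, SNP-major: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# A1 is stored as allele_a, A2 as allele_b, so codes map to B-allele counts
# 0 / MISSING / 1 / 2.
_CODE_TO_CALL = np.array([0, MISSING, 1, 2], dtype=np.int8)
_CALL_TO_CODE = {0: 0, 1: 2, 2: 3, int(MISSING): 1}


def read_plink(bed_path, bim_path, fam_path) -> GenotypeTable:
    """Read a SNP-major PLINK binary fileset.

    The FAM family-ID column (column 1) is used as the population label.
    """
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    n, m = len(fam), len(bim)
    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        payload = fh.read()
    if len(header) < 3 or header[:2] != _PLINK_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes, not a PLINK .bed file")
    if header[2:3] != _PLINK_SNP_MAJOR:
        raise PlinkFormatError(
            f"{bed_path}: mode byte {header[2]:#04x}; only SNP-major (0x01) is supported"
        )
    bytes_per_snp = (n + 3) // 4
    if len(payload) != bytes_per_snp * m:
        raise PlinkIntegrityError(
            f"{bed_path}: payload is {len(payload)} bytes, expected "
            f"{bytes_per_snp * m} for {n} samples x {m} SNPs"
        )
    raw = np.frombuffer(payload, dtype=np.uint8).reshape(m, bytes_per_snp)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (raw[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    calls = _CODE_TO_CALL[codes].T  # -> samples x SNPs

    order = np.lexsort((bim[3].astype(np.int64).to_numpy(), bim[0].to_numpy()))
    # keep file order if already sorted; otherwise sort by (chrom, pos)
    if not np.array_equal(order, np.arange(m)):
        bim = bim.iloc[order].reset_index(drop=True)
        calls = calls[:, order]
    return GenotypeTable(
        sample_ids=fam[1].tolist(),
        populations=fam[0].tolist(),
        snp_ids=bim[1].tolist(),
        chromosomes=bim[0].tolist(),
        positions=bim[3].astype(np.int64).to_numpy(),
        allele_a=bim[4].tolist(),
        allele_b=bim[5].tolist(),
        calls=calls,
    )


def write_plink(G: GenotypeTable, prefix: str) -> None:
    """Write ``prefix``.bed/.bim/.fam (SNP-major)."""
    n, m = G.n_samples, G.n_snps
    bytes_per_snp = (n + 3) // 4
    code = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    calls = G.calls.T  # SNP-major
    lut = np.zeros(256, dtype=np.uint8)
    for call, c in _CALL_TO_CODE.items():
        lut[call & 0xFF] = c
    code[:, :n] = lut[calls.view(np.uint8)]
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (
        (code.reshape(m, bytes_per_snp, 4) << shifts[None, None, :])
        .sum(axis=2)
        .astype(np.uint8)
    )
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_PLINK_MAGIC + _PLINK_SNP_MAJOR)
        fh.write(packed.tobytes())
    with open(f"{prefix}.bim", "w") as fh:
        for j in range(m):
            fh.write(
                f"{G.chromosomes[j]}\t{G.snp_ids[j]}\t0\t{G.positions[j]}\t"
                f"{G.allele_a[j]}\t{G.allele_b[j]}\n"
            )
    with open(f"{prefix}.fam", "w") as fh:
        for i in range(n):
            fh.write(f"{G.populations[i]}\t{G.sample_ids[i]}\t0\t0\t0\t-9\n")


def write_text(G: GenotypeTable, path: str) -> None:
    """Plain-text fixture dialect: two header lines, one SNP per line."""
    with open(path, "w") as fh:
        fh.write("#samples\t" + "\t".join(G.sample_ids) + "\n")
        fh.write("#populations\t" + "\t".join(G.populations) + "\n")
        for j in range(G.n_snps):
            calls = "\t".join(
                "NA" if c == MISSING else str(int(c)) for c in G.calls[:, j]
            )
            fh.write(
                f"{G.snp_ids[j]}\t{G.chromosomes[j]}\t{G.positions[j]}\t"
                f"{G.allele_a[j]}\t{G.allele_b[j]}\t{calls}\n"
            )


def read_text(path: str) -> GenotypeTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        pops = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#samples" or pops[0] != "#populations":
            raise ValueError(f"{path}: not a sweepscan genotype text file")
        sample_ids = header[1:]
        populations = pops[1:]
        snp_ids, chroms, positions, aa, ab, rows = [], [], [], [], [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            snp_ids.append(parts[0])
            chroms.append(parts[1])
            positions.append(int(parts[2]))
            aa.append(parts[3])
            ab.append(parts[4])
            rows.append([MISSING if x == "NA" else np.int8(x) for x in parts[5:]])
    calls = np.asarray(rows, dtype=np.int8).T if rows else np.zeros(
        (len(sample_ids), 0), dtype=np.int8
    )
    return GenotypeTable(
        sample_ids, populations, snp_ids, chroms,
        np.asarray(positions, dtype=np.int64), aa, ab, calls,
    )


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(G: GenotypeTable, grouping: dict[str, str] | None = None) -> FrequencyTable:
    """Per-population B-allele frequencies.

    ``grouping`` optionally remaps sample_id -> population; by default the
    table's own population labels are used.  A population with zero genotyped
    samples at a SNP gets an undefined (NaN) frequency, not an exception.
    """
    if grouping is not None:
        missing = [s for s in G.sample_ids if s not in grouping]
        if missing:
            raise ValueError(f"grouping does not cover samples: {missing[:5]}")
        labels = [grouping[s] for s in G.sample_ids]
    else:
        labels = G.populations
    pops = list(dict.fromkeys(labels))
    n_pops, n_snps = len(pops), G.n_snps
    freq = np.full((n_pops, n_snps), np.nan)
    n_obs = np.zeros((n_pops, n_snps), dtype=np.int64)
    calls = G.calls
    observed = calls != MISSING
    counts = np.where(observed, calls, 0).astype(np.int64)
    for k, p in enumerate(pops):
        ix = [i for i, l in enumerate(labels) if l == p]
        n_obs[k] = 2 * observed[ix].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[k] = counts[ix].sum(axis=0) / n_obs[k]
    return FrequencyTable(
        populations=pops,
        snp_ids=list(G.snp_ids),
        chromosomes=list(G.chromosomes),
        positions=G.positions.copy(),
        freq=freq,
        n_obs=n_obs,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_test(n_aa: int, n_ab: int, n_bb: int, method: str = "exact") -> float:
    """Hardy–Weinberg equilibrium test p-value for one genotype-count triple.

    ``method='exact'`` is the conditional exact test (probability-ordering,
    no mid-p correction): the p-value sums the probabilities of all
    heterozygote counts, given the allele counts, whose conditional
    probability does not exceed that of the observed count.
    ``method='chi2'`` is the 1-df asymptotic test.

    Returns NaN when the total count is zero.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        return float("nan")
    if method == "chi2":
        p = (2 * n_bb + n_ab) / (2 * n)
        exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        obs = np.array([n_aa, n_ab, n_bb], dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            x2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
        return float(stats.chi2.sf(x2, df=1))
    if method != "exact":
        raise ValueError(f"unknown HWE method {method!r}")
    probs = _hwe_het_probabilities(n, 2 * n_bb + n_ab)
    p_obs = probs.get(n_ab, 0.0)
    return float(min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))))


def _hwe_het_probabilities(n: int, n_b: int) -> dict[int, float]:
    """Conditional distribution of the heterozygote count given allele counts.

    ``n`` diploid individuals, ``n_b`` copies of the rarer-or-not B allele.
    Uses the standard recurrence outward from the modal heterozygote count to
    stay in floating range.
    """
    rare = min(n_b, 2 * n - n_b)
    het_max = rare
    # parity of het count matches parity of rare-allele count
    mid = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1 if mid < rare else -1
    probs = {mid: 1.0}

    def common(nh):  # homozygous-common count
        return n - nh - (rare - nh) // 2

    nh = mid
    while nh >= 2:
        # P(nh-2)/P(nh) = nh(nh-1) / (4 (n_rr+1)(n_cc+1))
        n_rr = (rare - nh) // 2
        probs[nh - 2] = probs[nh] * nh * (nh - 1) / (4.0 * (n_rr + 1) * (common(nh) + 1))
        nh -= 2
    nh = mid
    while nh + 2 <= het_max:
        n_rr = (rare - nh) // 2
        probs[nh + 2] = probs[nh] * 4.0 * n_rr * common(nh) / ((nh + 2) * (nh + 1))
        nh += 2
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


# ---------------------------------------------------------------------------
# FDR q-values
# ---------------------------------------------------------------------------


def fdr_qvalues(p_values, method: str = "storey") -> np.ndarray:
    """Monotone step-up q-values from p-values.

    ``method='bh'`` is Benjamini–Hochberg (pi0 = 1).  ``method='storey'``
    estimates pi0 with the cubic-smoother fit of pi0(lambda) over a lambda
    grid and rescales the BH q-values; with pi0 <= 1 the Storey q-values are
    elementwise <= the BH ones.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    if method == "bh":
        return q
    if method != "storey":
        raise ValueError(f"unknown FDR method {method!r}")
    pi0 = _storey_pi0(p)
    return np.minimum(q * pi0, 1.0)


def _storey_pi0(p: np.ndarray) -> float:
    """Cubic-smoother estimate of the null proportion pi0."""
    m = p.size
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1 - l)) for l in lam])
    if m < 100:
        return 1.0  # too few tests to estimate pi0; fall back to BH
    coef = np.polyfit(lam, pi0_lam, deg=3)
    pi0 = float(np.polyval(coef, lam[-1]))
    return float(np.clip(pi0, 1e-8, 1.0))


# ---------------------------------------------------------------------------
# QC filter chain
# ---------------------------------------------------------------------------


def qc_filter(
    G: GenotypeTable,
    maf_min: float = 0.0,
    snp_miss_max: float = 0.01,
    ind_miss_max: float = 0.05,
    hwe_fdr: float = 0.05,
    hwe_method: str = "exact",
    qvalue_method: str = "storey",
) -> tuple[GenotypeTable, QcReport]:
    """Apply the QC chain; order: sample missingness -> SNP MAF ->
    SNP missingness -> per-population HWE.

    A SNP fails MAF when its overall minor-allele frequency is <=
    ``maf_min`` (the default 0.0 removes exactly the monomorphic SNPs).  A
    SNP fails HWE when its q-value is below ``hwe_fdr`` in at least one
    population (q-values computed across SNPs within each population).
    Each removed item is reported once with the first failing reason in the
    fixed order MAF, SNP_MISSING, HWE.
    """
    for name, thr in [("maf_min", maf_min), ("snp_miss_max", snp_miss_max),
                      ("ind_miss_max", ind_miss_max), ("hwe_fdr", hwe_fdr)]:
        if not 0 <= thr <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    report = QcReport(thresholds={
        "maf_min": maf_min, "snp_miss_max": snp_miss_max,
        "ind_miss_max": ind_miss_max, "hwe_fdr": hwe_fdr,
    })

    # 1. sample missingness
    miss = (G.calls == MISSING).mean(axis=1) if G.n_snps else np.zeros(G.n_samples)
    keep_samples = np.flatnonzero(miss <= ind_miss_max)
    for i in np.flatnonzero(miss > ind_miss_max):
        report.removed_samples.append((G.sample_ids[i], "IND_MISSING"))
    G = G.subset(samples=keep_samples)

    # 2. SNP filters on the reduced sample set
    observed = G.calls != MISSING
    n_obs = 2 * observed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(observed, G.calls, 0).sum(axis=0) / n_obs
    maf = np.minimum(f, 1 - f)
    fails_maf = (n_obs == 0) | (maf <= maf_min)
    snp_miss = 1 - observed.mean(axis=0) if G.n_samples else np.ones(G.n_snps)
    fails_miss = snp_miss > snp_miss_max

    # 3. per-population HWE on SNPs that survived the marginal filters
    candidate = ~(fails_maf | fails_miss)
    fails_hwe = np.zeros(G.n_snps, dtype=bool)
    if hwe_fdr > 0 and candidate.any():
        cidx = np.flatnonzero(candidate)
        for pop, six in G.population_index().items():
            sub = G.calls[np.ix_(six, cidx)]
            n_aa = (sub == 0).sum(axis=0)
            n_ab = (sub == 1).sum(axis=0)
            n_bb = (sub == 2).sum(axis=0)
            pvals = np.array([
                hwe_test(int(a), int(h), int(b), method=hwe_method)
                for a, h, b in zip(n_aa, n_ab, n_bb)
            ])
            defined = ~np.isnan(pvals)
            if not defined.any():
                continue
            qv = np.ones_like(pvals)
            qv[defined] = fdr_qvalues(pvals[defined], method=qvalue_method)
            fails_hwe[cidx[qv < hwe_fdr]] = True

    keep_snps = []
    for j in range(G.n_snps):
        if fails_maf[j]:
            report.removed_snps.append((G.snp_ids[j], "MAF"))
        elif fails_miss[j]:
            report.removed_snps.append((G.snp_ids[j], "SNP_MISSING"))
        elif fails_hwe[j]:
            report.removed_snps.append((G.snp_ids[j], "HWE"))
        else:
            keep_snps.append(j)
    out = G.subset(snps=keep_snps)
    if out.n_snps == 0:
        report.warnings.append("all SNPs removed by QC")
        warnings.warn("qc_filter removed every SNP", stacklevel=2)
    return out, report


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------


def compute_grm(G: GenotypeTable) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    ``G_rel = Z Z' / sum_s 2 p_s (1 - p_s)`` with ``Z = calls - 2 p_s`` and
    missing calls mean-imputed to ``2 p_s``.
    """
    if G.n_samples < 2:
        raise ValueError("GRM needs at least two samples")
    calls = G.calls.astype(float)
    observed = calls != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(observed, calls, 0).sum(axis=0) / (2 * observed.sum(axis=0))
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNP: GRM undefined")
    p = p[poly]
    z = np.where(observed[:, poly], calls[:, poly], 2 * p) - 2 * p
    denom = float(np.sum(2 * p * (1 - p)))
    return z @ z.T / denom


# ---------------------------------------------------------------------------
# two-component normal mixture + relatedness filter
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """Parameters of a 1-d two-component normal mixture (EM fit)."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    converged: bool
    degenerate: bool = False

    @property
    def major(self) -> int:
        return int(np.argmax(self.weights))


def fit_normal_mixture(x: np.ndarray, seed: int = 0, n_restarts: int = 5,
                       max_iter: int = 200, tol: float = 1e-9) -> MixtureFit:
    """EM fit of a 2-component normal mixture with quantile initialization.

    Restarts perturb the initial split point; the best log-likelihood wins.
    A fit is flagged degenerate when a component collapses onto a point mass.
    """
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    scale = float(np.std(x))
    if scale == 0:
        return MixtureFit(np.array([1.0, 0.0]), np.array([x[0], x[0]]),
                          np.array([0.0, 0.0]), -np.inf, False, degenerate=True)
    best: MixtureFit | None = None
    var_floor = max((1e-4 * scale) ** 2, 1e-300)
    for r in range(max(1, min(n_restarts, 50))):
        q = 0.95 if r == 0 else float(rng.uniform(0.7, 0.99))
        cut = np.quantile(x, q)
        lower, upper = x[x <= cut], x[x > cut]
        if upper.size == 0:
            upper = np.array([x.max()])
        mu = np.array([lower.mean(), upper.mean()])
        sd = np.array([max(lower.std(), 1e-3 * scale),
                       max(upper.std(), 1e-3 * scale)])
        w = np.array([lower.size, max(upper.size, 1)], dtype=float)
        w /= w.sum()
        ll_prev, converged = -np.inf, False
        for _ in range(max_iter):
            logpdf = stats.norm.logpdf(x[:, None], mu[None, :], sd[None, :])
            logpdf += np.log(w)[None, :]
            norm = np.logaddexp(logpdf[:, 0], logpdf[:, 1])
            ll = float(norm.sum())
            resp = np.exp(logpdf - norm[:, None])
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-10):
                break
            w = nk / x.size
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            sd = np.sqrt(np.maximum(var, var_floor))
            if ll - ll_prev < tol * max(1.0, abs(ll)):
                converged = True
                break
            ll_prev = ll
        degenerate = bool(np.any(sd <= np.sqrt(var_floor) * (1 + 1e-9)))
        fit = MixtureFit(w, mu, sd, ll, converged, degenerate)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    return best


def relatedness_filter(
    grm: np.ndarray,
    sample_ids: list[str],
    fdr: float = 0.05,
    seed: int = 0,
    fallback_threshold: float = 0.35,
) -> tuple[list[str], list[str], MixtureFit]:
    """Remove one member of each cryptically related pair.

    The off-diagonal relationship coefficients are modelled as a
    two-component normal mixture whose major component represents unrelated
    pairs.  Each pair's local FDR is its posterior probability of belonging
    to the major component; pairs are flagged while the running mean of the
    sorted local FDRs stays below ``fdr``.  Samples are then removed
    greedily: the sample in the most flagged pairs first (ties broken by
    lexicographically smallest sample id) until no flagged pair survives.
    """
    grm = np.asarray(grm, dtype=float)
    n = grm.shape[0]
    if n < 3:
        raise ValueError("relatedness filter needs at least 3 samples")
    if grm.shape != (n, n) or len(sample_ids) != n:
        raise ValueError("GRM shape and sample_ids disagree")
    iu = np.triu_indices(n, k=1)
    coeffs = grm[iu]
    fit = fit_normal_mixture(coeffs, seed=seed)
    if fit.degenerate:
        warnings.warn(
            "mixture fit degenerate; falling back to fixed coefficient threshold",
            stacklevel=2,
        )
        flagged_mask = coeffs > fallback_threshold
    elif (fit.means[1 - fit.major] - fit.means[fit.major]
          < 3 * fit.sds[fit.major]):
        # the non-major component is not separated from the unrelated bulk:
        # the fit is splitting the null distribution, not finding a related
        # class, so nothing is flagged
        flagged_mask = np.zeros(coeffs.size, dtype=bool)
    else:
        major = fit.major
        logpdf = stats.norm.logpdf(coeffs[:, None], fit.means[None, :],
                                   np.maximum(fit.sds, 1e-12)[None, :])
        logpdf += np.log(np.maximum(fit.weights, 1e-300))[None, :]
        norm = np.logaddexp(logpdf[:, 0], logpdf[:, 1])
        lfdr = np.exp(logpdf[:, major] - norm)
        # only coefficients on the related (upper) side of the major mean
        side = coeffs > fit.means[major]
        order = np.argsort(lfdr, kind="mergesort")
        flagged_mask = np.zeros(coeffs.size, dtype=bool)
        running, count = 0.0, 0
        for idx in order:
            if not side[idx]:
                continue
            if (running + lfdr[idx]) / (count + 1) < fdr:
                flagged_mask[idx] = True
                running += lfdr[idx]
                count += 1
            else:
                break
    flagged_pairs = {(int(iu[0][k]), int(iu[1][k]))
                     for k in np.flatnonzero(flagged_mask)}
    removed: list[str] = []
    alive = set(range(n))
    while True:
        live_pairs = [p for p in flagged_pairs if p[0] in alive and p[1] in alive]
        if not live_pairs:
            break
        degree: dict[int, int] = {}
        for a, b in live_pairs:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        # tie-break: lexicographically smallest sample id among max-degree
        max_deg = max(degree.values())
        candidates = sorted(
            (i for i, d in degree.items() if d == max_deg),
            key=lambda i: sample_ids[i],
        )
        worst_i = candidates[0]
        alive.discard(worst_i)
        removed.append(sample_ids[worst_i])
    kept = [sample_ids[i] for i in sorted(alive)]
    return kept, removed, fit


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


def ld_decay(
    G: GenotypeTable,
    population: str | None = None,
    max_dist_bp: int = 5_000_000,
    bin_bp: int = 50_000,
) -> pd.DataFrame:
    """Mean composite r^2 between SNP pairs, binned by bp distance.

    r^2 is the squared Pearson correlation of genotype dosages (composite
    LD: no phasing required), averaged over chromosomes.  Monomorphic SNPs
    are skipped.
    """
    if population is not None:
        ix = [i for i, p in enumerate(G.populations) if p == population]
        if not ix:
            raise ValueError(f"population {population!r} not present")
        G = G.subset(samples=ix)
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    any_pair = False
    for chrom in dict.fromkeys(G.chromosomes):
        jdx = np.asarray([j for j, c in enumerate(G.chromosomes) if c == chrom])
        pos = G.positions[jdx]
        calls = np.where(G.calls[:, jdx] == MISSING, np.nan,
                         G.calls[:, jdx]).astype(float)
        sd = np.nanstd(calls, axis=0)
        poly = sd > 0
        jdx, pos, calls = jdx[poly], pos[poly], calls[:, poly]
        if pos.size < 2:
            continue
        # mean-impute, then correlation matrix
        col_mean = np.nanmean(calls, axis=0)
        filled = np.where(np.isnan(calls), col_mean, calls)
        c = np.corrcoef(filled.T)
        for a in range(pos.size - 1):
            dist = pos[a + 1:] - pos[a]
            within = dist <= max_dist_bp
            if not within.any():
                continue
            any_pair = True
            b = np.flatnonzero(within) + a + 1
            bins = np.minimum((dist[within] - 1) // bin_bp, n_bins - 1)
            r2 = c[a, b] ** 2
            np.add.at(sums, bins, r2)
            np.add.at(counts, bins, 1)
    if not any_pair:
        raise ValueError("no SNP pair within max_dist_bp on any chromosome")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / counts, np.nan)
    return pd.DataFrame({
        "bin_start_bp": np.arange(n_bins) * bin_bp,
        "bin_end_bp": np.arange(1, n_bins + 1) * bin_bp,
        "n_pairs": counts,
        "mean_r2": mean_r2,
    })
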
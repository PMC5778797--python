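"""FLK: single-SNP differentiation test against hierarchical drift.

FLK extends the Lewontin–Krakauer test: under neutral drift the vector of
population allele frequencies p at a SNP is approximately

    p ~ N(p0 * 1, p0 (1 - p0) F)

where p0 is the ancestral frequency and F the tree-derived population
kinship matrix.  The statistic is the Mahalanobis distance of p from the
estimated ancestral frequency and is chi-squared with n_pops - 1 degrees of
freedom under neutrality (one df is lost to estimating p0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import FrequencyTable, GenotypeTable, allele_frequencies, fdr_qvalues
from .popstruct import KinshipF

_RIDGE = 1e-8

SCAN_COLUMNS = ["snp_id", "chrom", "pos", "p0", "flk", "pvalue", "qvalue", "significant"]


def _inverse(F: np.ndarray) -> np.ndarray:
    """Inverse of F with a small ridge if near-singular."""
    try:
        cond = np.linalg.cond(F)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        F = F + _RIDGE * np.eye(F.shape[0])
    return np.linalg.inv(F)


def estimate_ancestral_freq(p: np.ndarray, F: KinshipF | np.ndarray) -> np.ndarray:
    """BLUE of the ancestral frequency: p0 = (1' F^-1 p) / (1' F^-1 1).

    ``p`` may be one SNP (length n_pops) or a matrix (n_pops, n_snps);
    the result is clamped to [0, 1].
    """
    Fm = F.values if isinstance(F, KinshipF) else np.asarray(F, dtype=float)
    Fi = _inverse(Fm)
    w = Fi.sum(axis=0) / Fi.sum()
    return np.clip(w @ np.asarray(p, dtype=float), 0.0, 1.0)


def ancestral_maf_filter(p0: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Boolean mask of SNPs whose ancestral *minor* allele frequency is
    at least ``threshold`` (the model assumes ancestrally polymorphic SNPs)."""
    p0 = np.asarray(p0, dtype=float)
    return np.minimum(p0, 1 - p0) >= threshold


def flk_statistic(p: np.ndarray, p0: np.ndarray, F: KinshipF | np.ndarray):
    """FLK statistic and chi-squared p-value.

    ``p`` is (n_pops,) or (n_pops, n_snps); p0 scalar or (n_snps,).
    SNPs with p0 in {0, 1} yield NaN (they should be removed by the
    ancestral-MAF filter first).
    """
    Fm = F.values if isinstance(F, KinshipF) else np.asarray(F, dtype=float)
    Fi = _inverse(Fm)
    p = np.atleast_2d(np.asarray(p, dtype=float).T).T  # -> (n_pops, n_snps)
    scalar = np.ndim(p0) == 0 and p.shape[1] == 1
    p0 = np.atleast_1d(np.asarray(p0, dtype=float))
    n = Fm.shape[0]
    d = p - p0[None, :]
    quad = np.einsum("is,ij,js->s", d, Fi, d)
    denom = p0 * (1 - p0)
    with np.errstate(invalid="ignore", divide="ignore"):
        flk = np.where(denom > 0, quad / denom, np.nan)
    pval = stats.chi2.sf(flk, df=n - 1)
    if scalar:
        return float(flk[0]), float(pval[0])
    return flk, pval


def run_flk_scan(
    data: FrequencyTable | GenotypeTable,
    F: KinshipF,
    fdr: float = 0.01,
    maf_threshold: float = 0.05,
    drop_pops: list[str] | None = None,
    qvalue_method: str = "storey",
) -> pd.DataFrame:
    """Genome scan: per-SNP FLK with ancestral-MAF filter and FDR q-values.

    The scan runs on the populations of ``F`` (minus ``drop_pops``, for
    leave-one-breed-out re-analyses).  SNPs with any scanned population
    undefined are dropped; SNPs failing the ancestral-MAF filter are
    excluded.  Returns a DataFrame with fixed column order
    ``snp_id, chrom, pos, p0, flk, pvalue, qvalue, significant``.
    """
    freqs = data if isinstance(data, FrequencyTable) else allele_frequencies(data)
    pops = [p for p in F.populations if not (drop_pops and p in drop_pops)]
    absent = [p for p in pops if p not in freqs.populations]
    if absent:
        raise ValueError(f"populations in F absent from data: {absent}")
    Fs = F.subset(pops)
    sub = freqs.subset_pops(pops)
    defined = np.isfinite(sub.freq).all(axis=0)
    keep = np.flatnonzero(defined)
    sub = sub.subset_snps(keep)
    p0 = estimate_ancestral_freq(sub.freq, Fs)
    maf_ok = ancestral_maf_filter(p0, threshold=maf_threshold)
    idx = np.flatnonzero(maf_ok)
    sub = sub.subset_snps(idx)
    p0 = p0[idx]
    flk, pval = flk_statistic(sub.freq, p0, Fs)
    finite = np.isfinite(pval)
    qval = np.full_like(pval, np.nan)
    if finite.any():
        qval[finite] = fdr_qvalues(pval[finite], method=qvalue_method)
    out = pd.DataFrame(
        {
            "snp_id": sub.snp_ids,
            "chrom": sub.chromosomes,
            "pos": sub.positions,
            "p0": p0,
            "flk": flk,
            "pvalue": pval,
            "qvalue": qval,
            "significant": (qval < fdr).astype(int),
        }
    )
    out.attrs["fdr"] = fdr
    out.attrs["populations"] = pops
    return out[SCAN_COLUMNS]
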
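"""Selection-signature regions: chaining, gene annotation, set comparison.

Significant scan SNPs within a gap (1 Mbp by convention) of each other on
the same chromosome are chained into one selection signature.  Signatures
are annotated with the protein-coding genes overlapping their span; genes
are ranked by the distance from their midpoint to the region's best SNP
(the member SNP with the smallest p-value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SelectionSignature:
    """One merged genomic interval of significant scan SNPs (1-based, closed)."""

    chromosome: str
    start_bp: int
    end_bp: int
    member_snps: list[str]
    n_significant: int
    best_snp: tuple[str, int, float]  # (id, position, p_value)
    meets_min_snps: bool = True
    genes: list[tuple[str, int, int]] = field(default_factory=list)
    # ranked (gene_id, midpoint_bp, distance_to_best)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def build_regions(
    significant: pd.DataFrame,
    gap_bp: int = 1_000_000,
    min_snps: int = 1,
) -> list[SelectionSignature]:
    """Chain-merge significant SNPs into selection signatures.

    ``significant`` needs columns ``snp_id, chrom, pos, pvalue`` and must be
    sorted by (chromosome, position).  Consecutive SNPs on the same
    chromosome at distance <= ``gap_bp`` join the same region.  Regions with
    fewer than ``min_snps`` members are still reported but flagged below the
    gene-annotation threshold.  Region boundaries are the span of the member
    SNPs (not extended by the gap).
    """
    if significant.empty:
        return []
    df = significant.reset_index(drop=True)
    for chrom in df["chrom"].unique():
        pos = df.loc[df["chrom"] == chrom, "pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"SNPs not sorted by position on chromosome {chrom}")
    out: list[SelectionSignature] = []
    cur: list[int] = []

    def flush(idx: list[int]) -> None:
        sub = df.iloc[idx]
        best = sub.sort_values(["pvalue", "pos"], kind="mergesort").iloc[0]
        out.append(
            SelectionSignature(
                chromosome=str(sub["chrom"].iloc[0]),
                start_bp=int(sub["pos"].min()),
                end_bp=int(sub["pos"].max()),
                member_snps=sub["snp_id"].tolist(),
                n_significant=len(idx),
                best_snp=(str(best["snp_id"]), int(best["pos"]), float(best["pvalue"])),
                meets_min_snps=len(idx) >= min_snps,
            )
        )

    for i in range(len(df)):
        if not cur:
            cur = [i]
            continue
        prev = df.iloc[cur[-1]]
        row = df.iloc[i]
        if row["chrom"] == prev["chrom"] and row["pos"] - prev["pos"] <= gap_bp:
            cur.append(i)
        else:
            flush(cur)
            cur = [i]
    if cur:
        flush(cur)
    return out


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def read_gff3_genes(path: str, feature_type: str = "gene",
                    id_keys: tuple[str, ...] = ("ID", "Name")) -> pd.DataFrame:
    """Load gene records from a GFF3 file into a GeneSet frame.

    Coordinates are 1-based inclusive as in GFF3.  The gene identifier is
    taken from the first attribute key in ``id_keys`` that is present.
    """
    import gffutils

    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type(feature_type):
        gid = None
        for key in id_keys:
            if key in feat.attributes:
                gid = feat.attributes[key][0]
                break
        if gid is None:
            gid = feat.id
        rows.append((gid, feat.seqid, feat.start, feat.end, feat.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def annotate_genes(region: SelectionSignature, genes: pd.DataFrame) -> list[tuple[str, int, float]]:
    """Rank genes overlapping the region by midpoint distance to the best SNP.

    Any overlap of [gene_start, gene_end] with [region_start, region_end]
    includes the gene; the midpoint is used only for ranking.  Ties break on
    the smaller gene id.  Strand is ignored for distances.
    """
    sub = genes[
        (genes["chrom"].astype(str) == str(region.chromosome))
        & (genes["end"] >= region.start_bp)
        & (genes["start"] <= region.end_bp)
    ]
    best_pos = region.best_snp[1]
    ranked = []
    for _, g in sub.iterrows():
        mid = (int(g["start"]) + int(g["end"])) / 2.0
        ranked.append((str(g["gene_id"]), mid, abs(mid - best_pos)))
    ranked.sort(key=lambda t: (t[2], t[0]))
    region.genes = ranked
    return ranked


# ---------------------------------------------------------------------------
# comparing region sets
# ---------------------------------------------------------------------------


def _overlaps(a: SelectionSignature, b: SelectionSignature) -> bool:
    return (
        a.chromosome == b.chromosome
        and a.start_bp <= b.end_bp
        and b.start_bp <= a.end_bp
    )


def compare_region_sets(set_a: list[SelectionSignature],
                        set_b: list[SelectionSignature]) -> dict:
    """Classify regions as shared / a_only / b_only and summarize spans.

    A region is shared when it overlaps (> 0 bp) any region of the other
    set.  The summary includes per-set counts and mean merged-span lengths
    plus their ratio, supporting comparisons like "regions detected at
    lower marker density were 1.7 times the size".
    """
    shared_a = [a for a in set_a if any(_overlaps(a, b) for b in set_b)]
    shared_b = [b for b in set_b if any(_overlaps(b, a) for a in set_a)]
    a_only = [a for a in set_a if a not in shared_a]
    b_only = [b for b in set_b if b not in shared_b]

    def mean_len(rs):
        return float(np.mean([r.length_bp for r in rs])) if rs else float("nan")

    la, lb = mean_len(set_a), mean_len(set_b)
    return {
        "shared_a": shared_a,
        "shared_b": shared_b,
        "a_only": a_only,
        "b_only": b_only,
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_shared_a": len(shared_a),
        "mean_length_a": la,
        "mean_length_b": lb,
        "length_ratio_a_over_b": la / lb if lb and np.isfinite(lb) and lb > 0 else float("nan"),
    }


def regions_to_frame(regions: list[SelectionSignature]) -> pd.DataFrame:
    """BED-like frame (start is 0-based half-open for BED compliance)."""
    rows = []
    for r in regions:
        rows.append((
            r.chromosome, r.start_bp - 1, r.end_bp, r.n_significant,
            r.best_snp[0], r.best_snp[2], int(r.meets_min_snps),
            ";".join(g[0] for g in r.genes),
        ))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "n_snps", "best_snp", "best_p",
        "meets_min_snps", "genes",
    ])
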
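"""Consensus selective-sweep calling and candidate-gene enrichment.

Candidate regions come from three signals: the tails of the windowed
theta-pi ratio (both 5% tails), the right 5% tail of windowed FST, and the
top 1% of |XP-EHH| SNPs.  Each signal is mapped to the genes it overlaps;
only genes supported by all three are reported.  Candidates are then
summarised by functional category (COG-style single assignment per gene)
and tested for pathway over-representation with an upper-tail
hypergeometric test and Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import SCHEME_100KB_20KB, WindowScheme
from .variant_io import GenomeAnnotation


@dataclass
class OutlierSpec:
    """Quantile thresholds and geometry of the consensus scan.

    The theta-pi ratio is oriented reference/focal so a sweep in the focal
    population inflates the ratio (right tail); both tails are still
    scanned because selection in either population is of interest.
    """

    pi_ratio_tails: tuple[float, float] = (0.05, 0.05)
    fst_right_q: float = 0.05
    xpehh_top_q: float = 0.01
    scheme: WindowScheme = field(default_factory=lambda: SCHEME_100KB_20KB)
    gene_flank_bp: int = 0

    def __post_init__(self) -> None:
        for q in (*self.pi_ratio_tails, self.fst_right_q, self.xpehh_top_q):
            if not 0.0 < q < 1.0:
                raise ValueError(f"quantile {q} outside (0, 1)")


def tail_windows(
    track: pd.DataFrame, left_q: float = 0.05, right_q: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(low, high) outlier windows of a track by empirical quantiles.

    NA windows are excluded both from quantile estimation and from the
    outlier sets; thresholds use type-7 (linear-interpolation) quantiles
    and boundary ties are included.
    """
    vals = track["value"].to_numpy(float)
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("track has no finite windows")
    if finite.sum() < 20:
        raise ValueError(f"only {int(finite.sum())} finite windows; need >= 20")
    fv = vals[finite]
    lo_thr = np.quantile(fv, left_q)
    hi_thr = np.quantile(fv, 1.0 - right_q)
    if lo_thr == hi_thr:
        warnings.warn("degenerate track: identical tail thresholds; "
                      "both tails cover the same windows")
    low = track[finite & (vals <= lo_thr)].copy()
    high = track[finite & (vals >= hi_thr)].copy()
    return low, high


def genes_from_windows(
    windows: pd.DataFrame, annotation: GenomeAnnotation, flank_bp: int = 0
) -> set[str]:
    """Genes whose span overlaps any outlier window (within ``flank_bp``)."""
    out: set[str] = set()
    for row in windows.itertuples(index=False):
        out |= annotation.genes_overlapping(row.chrom, int(row.start), int(row.end),
                                            flank=flank_bp)
    return out


def genes_from_snps(
    snps: pd.DataFrame, annotation: GenomeAnnotation, flank_bp: int = 0
) -> set[str]:
    """Genes containing any outlier SNP (gene body extended by ``flank_bp``)."""
    out: set[str] = set()
    for row in snps.itertuples(index=False):
        pos = int(row.pos)
        out |= annotation.genes_overlapping(row.chrom, pos, pos, flank=flank_bp)
    return out


def consensus_candidates(
    pi_genes: set[str],
    fst_genes: set[str],
    xpehh_genes: set[str],
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """Genes supported by all three signals, ordered by chrom then start.

    Columns: gene_id, chrom, start, end, pi_ratio, fst, xpehh (the last
    three all True by the consensus rule, kept as an explicit evidence
    record).
    """
    genes = pi_genes & fst_genes & xpehh_genes
    g = annotation.genes
    sub = g[g["gene_id"].isin(genes)].copy()
    sub["pi_ratio"] = True
    sub["fst"] = True
    sub["xpehh"] = True
    return sub.sort_values(["chrom", "start"]).reset_index(drop=True)


def hypergeom_enrichment(
    candidates: set[str] | list[str],
    gene_pathways: pd.DataFrame,
) -> pd.DataFrame:
    """Pathway over-representation among candidate genes.

    ``gene_pathways`` has columns (gene, pathway); the background is every
    distinct gene in the table and candidates must be a subset of it.
    Per pathway with K background members and k candidate members, the
    p-value is the upper hypergeometric tail P(X >= k) with N background
    genes and n candidates; q is the Benjamini-Hochberg adjusted p.
    """
    cand = set(candidates)
    background = set(gene_pathways["gene"])
    unknown = cand - background
    if unknown:
        raise ValueError(f"candidate genes absent from the background: {sorted(unknown)[:5]}")
    N = len(background)
    n = len(cand)
    rows = []
    for pathway, grp in gene_pathways.groupby("pathway"):
        members = set(grp["gene"])
        K = len(members)
        if K == 0:
            continue
        k = len(members & cand)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((pathway, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["pathway", "k", "K", "n", "N", "p"])
    if len(df):
        df["q_bh"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values("p").reset_index(drop=True)
    return df


def cog_summary(
    candidates: set[str] | list[str], gene_categories: dict[str, str] | pd.DataFrame
) -> pd.DataFrame:
    """Counts of candidate genes per functional category.

    ``gene_categories`` maps gene -> single category (top-hit rule already
    applied upstream); unassigned genes count under "unannotated".  Counts
    sum to the number of candidates.
    """
    if isinstance(gene_categories, pd.DataFrame):
        gene_categories = dict(zip(gene_categories["gene"], gene_categories["category"]))
    counts: dict[str, int] = {}
    for g in candidates:
        cat = gene_categories.get(g, "unannotated")
        counts[cat] = counts.get(cat, 0) + 1
    return (pd.DataFrame(sorted(counts.items()), columns=["category", "count"])
            .reset_index(drop=True))


def consensus_scan(
    pi_ratio_track: pd.DataFrame,
    fst_track: pd.DataFrame,
    xpehh_table: pd.DataFrame,
    annotation: GenomeAnnotation,
    spec: OutlierSpec | None = None,
) -> dict:
    """Run the full three-signal consensus scan.

    Returns a dict with the per-signal outlier sets, the per-signal gene
    sets and the consensus candidate table.
    """
    from .haplotypes import top_fraction

    spec = spec or OutlierSpec()
    lq, rq = spec.pi_ratio_tails
    pi_low, pi_high = tail_windows(pi_ratio_track, lq, rq)
    _, fst_high = tail_windows(fst_track, spec.fst_right_q, spec.fst_right_q)
    xp_top = top_fraction(xpehh_table, spec.xpehh_top_q)
    pi_genes = (genes_from_windows(pi_low, annotation, spec.gene_flank_bp)
                | genes_from_windows(pi_high, annotation, spec.gene_flank_bp))
    fst_genes = genes_from_windows(fst_high, annotation, spec.gene_flank_bp)
    xp_genes = genes_from_snps(xp_top, annotation, spec.gene_flank_bp)
    candidates = consensus_candidates(pi_genes, fst_genes, xp_genes, annotation)
    return {
        "pi_low_windows": pi_low,
        "pi_high_windows": pi_high,
        "fst_high_windows": fst_high,
        "xpehh_top_snps": xp_top,
        "pi_genes": pi_genes,
        "fst_genes": fst_genes,
        "xpehh_genes": xp_genes,
        "candidates": candidates,
    }
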
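"""Extended haplotype homozygosity (EHH), its integral (iHH) and XP-EHH.

EHH at extent x is the probability that two haplotypes drawn without
replacement are identical over every site from the core to x inclusive.
iHH integrates the EHH curve over genetic distance (cM) by the trapezoid
rule on both flanks, under a constant-rate genetic map.  The
cross-population statistic XP-EHH is ln(iHH_A / iHH_B) per core SNP,
z-normalised genome-wide; extreme positive values indicate extended
haplotypes (a sweep) in population A, extreme negative values in B.

EHH here is computed over all haplotypes of a population (not partitioned
by core allele), the standard definition for the cross-population
statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Default genetic-map rate for the honeybee genome, cM per Mb.
DEFAULT_RATE_CM_PER_MB = 17.4
#: EHH level below which integration stops.
DEFAULT_EHH_CUTOFF = 0.05
#: Physical gap between adjacent SNPs beyond which integration aborts.
DEFAULT_MAX_GAP_BP = 200_000


@dataclass(frozen=True)
class GeneticMap:
    """Constant-rate genetic map: cM(pos) = pos_bp * rate / 1e6."""

    rate_cM_per_Mb: float = DEFAULT_RATE_CM_PER_MB

    def __post_init__(self) -> None:
        if self.rate_cM_per_Mb <= 0:
            raise ValueError("recombination rate must be positive")

    def cm(self, pos_bp) -> np.ndarray:
        return np.asarray(pos_bp, dtype=float) * self.rate_cM_per_Mb / 1e6


@dataclass
class Haplotypes:
    """Phased haplotypes for one population on one chromosome.

    ``alleles`` is (n_haplotypes x n_sites) int8 with 0/1 alleles and -1
    for missing; ``positions`` are sorted 1-based bp coordinates.
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("positions length must equal the number of sites")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


def haplotypes_from_records(records, sample_indices: Sequence[int], chrom: str) -> Haplotypes:
    """Build a haplotype matrix from phased SiteRecords of one chromosome.

    Raises on unphased input: haplotype statistics are undefined on
    genotypes, phase the VCF first.
    """
    recs = [r for r in records if r.chrom == chrom]
    if not recs:
        raise ValueError(f"no records on chromosome {chrom}")
    cols = np.asarray(sample_indices)
    hap_rows = []
    for r in recs:
        if not r.phased or r.haplotypes is None:
            raise ValueError(
                f"unphased genotypes at {r.chrom}:{r.pos}; haplotype statistics "
                "require phased input — phase the VCF first"
            )
        hap_rows.append(r.haplotypes[cols].reshape(-1))
    alleles = np.stack(hap_rows, axis=1)
    pos = np.array([r.pos for r in recs], dtype=np.int64)
    return Haplotypes(alleles, pos, chrom)


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

def _allele_codes(haps: Haplotypes, site: int) -> np.ndarray:
    """Alleles at a site with missing values made unique per haplotype.

    A missing allele can match nothing (conservative mismatch), so each
    missing entry gets its own code.
    """
    col = haps.alleles[:, site].astype(np.int64)
    miss = col < 0
    if miss.any():
        col = col.copy()
        col[miss] = 2 + np.flatnonzero(miss)
    return col


def _ehh_from_groups(group_ids: np.ndarray) -> float:
    n = group_ids.size
    counts = np.bincount(group_ids)
    return float((counts * (counts - 1)).sum()) / (n * (n - 1))


def ehh_at(core: int, haps: Haplotypes, extent: int) -> float:
    """EHH for the span from ``core`` to ``extent`` (site indices, inclusive).

    Haplotypes are partitioned by identity of their allele sequence over the
    span; EHH = sum_g C(k_g, 2) / C(n, 2).
    """
    n = haps.n_haplotypes
    if n < 2:
        raise ValueError("EHH requires at least two haplotypes")
    lo, hi = min(core, extent), max(core, extent)
    ids = np.zeros(n, dtype=np.int64)
    for site in range(lo, hi + 1):
        codes = _allele_codes(haps, site)
        _, ids = np.unique(ids * (n + 2) + codes, return_inverse=True)
    return _ehh_from_groups(ids)


@dataclass
class EhhCurve:
    """One flank of an EHH decay curve around a core SNP.

    ``distances_cm`` are unsigned genetic distances from the core (the core
    itself is the first point, distance 0, where the zero-length-haplotype
    anchor value is 1 by convention; ``values[0]`` is the homozygosity of
    the core site).  ``truncated`` is set when the flank hit the chromosome
    edge or a physical gap before EHH dropped below the cutoff.
    """

    distances_cm: np.ndarray
    values: np.ndarray
    truncated: bool
    reason: str = ""


def _flank_curve(
    core: int,
    haps: Haplotypes,
    gmap: GeneticMap,
    direction: int,
    cutoff: float,
    max_gap_bp: int,
) -> EhhCurve:
    """Walk one flank, refining the haplotype partition site by site."""
    n = haps.n_haplotypes
    pos = haps.positions
    cm = gmap.cm(pos)
    dists = [0.0]
    _, ids = np.unique(_allele_codes(haps, core), return_inverse=True)
    values = [_ehh_from_groups(ids)]
    site = core
    if values[0] < cutoff:
        return EhhCurve(np.array(dists), np.array(values), False)
    while True:
        nxt = site + direction
        if nxt < 0 or nxt >= haps.n_sites:
            return EhhCurve(np.array(dists), np.array(values), True, "chromosome edge")
        if abs(int(pos[nxt]) - int(pos[site])) > max_gap_bp:
            return EhhCurve(np.array(dists), np.array(values), True, "gap")
        codes = _allele_codes(haps, nxt)
        _, ids = np.unique(ids * (n + 2) + codes, return_inverse=True)
        e = _ehh_from_groups(ids)
        dists.append(abs(cm[nxt] - cm[core]))
        values.append(e)
        site = nxt
        if e < cutoff:
            return EhhCurve(np.array(dists), np.array(values), False)


def ehh_curve(
    core: int,
    haps: Haplotypes,
    gmap: GeneticMap | None = None,
    cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> tuple[EhhCurve, EhhCurve]:
    """(left, right) EHH decay curves around a core SNP."""
    gmap = gmap or GeneticMap()
    left = _flank_curve(core, haps, gmap, -1, cutoff, max_gap_bp)
    right = _flank_curve(core, haps, gmap, +1, cutoff, max_gap_bp)
    return left, right


def ihh(
    core: int,
    haps: Haplotypes,
    gmap: GeneticMap | None = None,
    cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> tuple[float, bool]:
    """Integrated EHH at a core SNP: trapezoid integral over both flanks.

    Integration on each flank starts at the core position and stops at the
    first site where EHH < cutoff (that final trapezoid is included), at
    the chromosome edge, or at a physical gap larger than ``max_gap_bp``.
    Returns (iHH, truncated) where ``truncated`` reports that either flank
    ended for a reason other than EHH decay.
    """
    left, right = ehh_curve(core, haps, gmap, cutoff, max_gap_bp)
    total = float(np.trapezoid(left.values, left.distances_cm)
                  + np.trapezoid(right.values, right.distances_cm))
    return total, left.truncated or right.truncated


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

@dataclass
class XpehhResult:
    """Per-core XP-EHH table plus a log of dropped cores.

    ``table`` columns: chrom, pos, ihh_a, ihh_b, raw, normalized, pvalue,
    rank_fraction.  ``dropped`` columns: chrom, pos, reason.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)


def xpehh(
    haps_a: Haplotypes,
    haps_b: Haplotypes,
    gmap: GeneticMap | None = None,
    cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> XpehhResult:
    """Cross-population XP-EHH over the shared site set of two populations.

    Per core SNP, raw = ln(iHH_A / iHH_B); cores where either population's
    iHH is zero or where either flank failed to decay below the cutoff
    (edge or gap) are dropped with a recorded reason.  Retained raw scores
    are z-normalised; the two-sided normal tail gives the p-value and the
    rank fraction orders |normalized| descending.
    """
    if not np.array_equal(haps_a.positions, haps_b.positions):
        raise ValueError("populations must share an identical site set")
    gmap = gmap or GeneticMap()
    n_sites = haps_a.n_sites
    rows, dropped = [], []
    for core in range(n_sites):
        ihh_a, trunc_a = ihh(core, haps_a, gmap, cutoff, max_gap_bp)
        ihh_b, trunc_b = ihh(core, haps_b, gmap, cutoff, max_gap_bp)
        pos = int(haps_a.positions[core])
        if trunc_a or trunc_b:
            dropped.append((haps_a.chrom, pos, "flank failed to drop below cutoff"))
            continue
        if ihh_a <= 0 or ihh_b <= 0:
            dropped.append((haps_a.chrom, pos, "zero iHH"))
            continue
        rows.append((haps_a.chrom, pos, ihh_a, ihh_b, float(np.log(ihh_a / ihh_b))))
    if not rows:
        raise ValueError("no cores retained for XP-EHH normalisation")
    if dropped:
        logger.info("xpehh: dropped %d of %d cores", len(dropped), n_sites)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ihh_a", "ihh_b", "raw"])
    raw = df["raw"].to_numpy()
    sd = raw.std(ddof=0)
    if sd == 0:
        df["normalized"] = 0.0
    else:
        df["normalized"] = (raw - raw.mean()) / sd
    df["pvalue"] = 2.0 * stats.norm.sf(np.abs(df["normalized"]))
    order = np.argsort(-np.abs(df["normalized"].to_numpy()), kind="stable")
    ranks = np.empty(len(df), dtype=float)
    ranks[order] = (np.arange(len(df)) + 1) / len(df)
    df["rank_fraction"] = ranks
    drop_df = pd.DataFrame(dropped, columns=["chrom", "pos", "reason"])
    return XpehhResult(table=df, dropped=drop_df)


def top_fraction(result: XpehhResult | pd.DataFrame, q: float = 0.01) -> pd.DataFrame:
    """Rows whose |normalized| score ranks in the top ``q`` fraction.

    Boundary ties are all included, so the output can exceed ceil(q*m) rows.
    """
    df = result.table if isinstance(result, XpehhResult) else result
    if len(df) == 0:
        raise ValueError("empty XP-EHH result")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    scores = np.abs(df["normalized"].to_numpy())
    k = max(1, int(np.ceil(q * len(df))))
    threshold = np.sort(scores)[::-1][k - 1]
    return df[scores >= threshold].copy()
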
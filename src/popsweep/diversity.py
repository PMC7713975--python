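"""Nucleotide diversity (theta-pi), Weir-Cockerham FST and windowed tracks.

Per-site diversity is the mean pairwise difference among sampled alleles;
windowed diversity divides the per-window sum by the window length in bp
(monomorphic positions contribute zero implicitly).  FST uses the
Weir & Cockerham (1984) variance components a (among populations),
b (among individuals within populations) and c (within individuals),
aggregated across sites as a ratio of sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_io import PopulationMap, SiteRecord, VariantSet


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window geometry: ``size_bp`` windows advancing by ``step_bp``."""

    size_bp: int
    step_bp: int

    def __post_init__(self) -> None:
        if self.size_bp <= 0 or self.step_bp <= 0:
            raise ValueError("window size and step must be positive")
        if self.step_bp > self.size_bp:
            raise ValueError("step must not exceed window size")

    def windows(self, contig_length: int) -> np.ndarray:
        """(n, 2) array of 1-based inclusive [start, end] windows.

        Number of windows is floor((L - size)/step) + 1 (zero if L < size).
        """
        if contig_length < self.size_bp:
            return np.zeros((0, 2), dtype=np.int64)
        n = (contig_length - self.size_bp) // self.step_bp + 1
        starts = 1 + self.step_bp * np.arange(n, dtype=np.int64)
        return np.column_stack([starts, starts + self.size_bp - 1])


#: The genome-wide presentation scheme (10-kb windows, 1-kb steps).
SCHEME_10KB_1KB = WindowScheme(10_000, 1_000)
#: The selection-scan scheme (100-kb windows, 20-kb steps).
SCHEME_100KB_20KB = WindowScheme(100_000, 20_000)


def site_pi(n_ref: int, n_alt: int) -> float:
    """Mean pairwise difference at one site: 2*n_ref*n_alt / (n*(n-1)).

    Returns NaN when fewer than two alleles were sampled.
    """
    n = n_ref + n_alt
    if n < 2:
        return float("nan")
    return 2.0 * n_ref * n_alt / (n * (n - 1.0))


def _site_pi_vector(n_ref: np.ndarray, n_alt: np.ndarray) -> np.ndarray:
    n = n_ref + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * n_ref * n_alt / (n * (n - 1.0))
    pi[n < 2] = np.nan
    return pi


def _window_sum(pos: np.ndarray, values: np.ndarray, windows: np.ndarray):
    """Sum `values` (and count sites) per [start, end] window via cumsum."""
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    values = np.nan_to_num(values[order], nan=0.0)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.searchsorted(pos, windows[:, 0], side="left")
    hi = np.searchsorted(pos, windows[:, 1], side="right")
    return csum[hi] - csum[lo], (hi - lo).astype(np.int64)


def _track_frame(chrom: str, windows: np.ndarray, n_snps: np.ndarray,
                 values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": chrom,
        "start": windows[:, 0],
        "end": windows[:, 1],
        "n_snps": n_snps,
        "value": values,
    })


# ---------------------------------------------------------------------------
# Windowed theta-pi
# ---------------------------------------------------------------------------

def windowed_pi_from_arrays(
    pos: np.ndarray,
    n_ref: np.ndarray,
    n_alt: np.ndarray,
    scheme: WindowScheme,
    contig_length: int,
    chrom: str = "1",
    per_snp_mean: bool = False,
) -> pd.DataFrame:
    """Windowed diversity from per-site allele counts on one contig.

    Default denominator is the window length in bp; ``per_snp_mean`` divides
    by the number of SNPs in the window instead (NaN for empty windows).
    """
    pos = np.asarray(pos, dtype=np.int64)
    pi = _site_pi_vector(np.asarray(n_ref, float), np.asarray(n_alt, float))
    windows = scheme.windows(contig_length)
    sums, counts = _window_sum(pos, pi, windows)
    if per_snp_mean:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = sums / counts
        values[counts == 0] = np.nan
    else:
        values = sums / scheme.size_bp
    return _track_frame(chrom, windows, counts, values)


def windowed_pi(
    records: Iterable[SiteRecord] | VariantSet,
    sample_indices: Sequence[int] | None,
    scheme: WindowScheme,
    contig_lengths: dict[str, int],
    per_snp_mean: bool = False,
) -> pd.DataFrame:
    """Windowed diversity track over every contig in ``contig_lengths``.

    ``sample_indices`` restricts the computation to one population's columns
    (None uses all samples).
    """
    recs = records.records if isinstance(records, VariantSet) else list(records)
    frames = []
    for chrom, length in contig_lengths.items():
        chrom_recs = [r for r in recs if r.chrom == chrom]
        pos = np.array([r.pos for r in chrom_recs], dtype=np.int64)
        nr, na = _allele_count_arrays(chrom_recs, sample_indices)
        frames.append(windowed_pi_from_arrays(
            pos, nr, na, scheme, length, chrom, per_snp_mean=per_snp_mean))
    return pd.concat(frames, ignore_index=True) if frames else _empty_track()


def _allele_count_arrays(recs, sample_indices):
    nr = np.zeros(len(recs))
    na = np.zeros(len(recs))
    for i, r in enumerate(recs):
        g = r.genotypes if sample_indices is None else r.genotypes[np.asarray(sample_indices)]
        called = g[g >= 0]
        na[i] = called.sum()
        nr[i] = 2 * called.size - na[i]
    return nr, na


def _empty_track() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "start", "end", "n_snps", "value"])


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

def wc_fst_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-site variance components (a, b, c).

    Parameters are per-population arrays, last axis of length r >= 2:
    ``n`` diploid sample sizes, ``p`` alternate-allele frequencies and
    ``h`` observed heterozygote fractions.  Accepts a single site
    (1-D input) or a stack of sites (2-D, sites x populations).
    Populations with n == 0 at a site are excluded from that site's sums.
    """
    one_site = np.ndim(n) == 1
    n = np.atleast_2d(np.asarray(n, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=float))
    present = n > 0
    r = present.sum(axis=1).astype(float)
    nz = np.where(present, n, 0.0)
    pz = np.where(present, p, 0.0)
    hz = np.where(present, h, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = nz.sum(axis=1) / r
        sum_n = r * nbar
        nc = (sum_n - (nz ** 2).sum(axis=1) / sum_n) / (r - 1.0)
        pbar = (nz * pz).sum(axis=1) / sum_n
        s2 = (nz * (pz - pbar[:, None]) ** 2 * present).sum(axis=1) / ((r - 1.0) * nbar)
        hbar = (nz * hz).sum(axis=1) / sum_n

        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (
                pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0
            )
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    bad = (r < 2) | ~np.isfinite(nbar) | (nbar <= 1.0)
    for comp in (a, b, c):
        comp[bad] = np.nan
    if one_site and a.shape[0] == 1:
        return a[0], b[0], c[0]
    return a, b, c


def wc_fst_site(n, p, h) -> tuple[float, float, float]:
    """Scalar convenience wrapper for one site; see :func:`wc_fst_components`."""
    a, b, c = wc_fst_components(np.asarray(n), np.asarray(p), np.asarray(h))
    return float(np.atleast_1d(a)[0]), float(np.atleast_1d(b)[0]), float(np.atleast_1d(c)[0])


def per_pop_site_stats(
    dosage: np.ndarray, pop_indices: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, p, h) per site per population from a samples x sites dosage matrix.

    ``n`` counts diploids with called genotypes; ``p`` is the alternate
    allele frequency and ``h`` the observed heterozygote fraction among them.
    """
    S = dosage.shape[1]
    r = len(pop_indices)
    n = np.zeros((S, r))
    p = np.zeros((S, r))
    h = np.zeros((S, r))
    for k, cols in enumerate(pop_indices):
        sub = dosage[np.asarray(cols), :]
        called = sub >= 0
        nk = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            alt = np.where(called, sub, 0).sum(axis=0)
            p[:, k] = np.where(nk > 0, alt / (2.0 * nk), 0.0)
            h[:, k] = np.where(nk > 0, np.where(called, sub == 1, False).sum(axis=0) / nk, 0.0)
        n[:, k] = nk
    return n, p, h


def fst_ratio_of_sums(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Genome-wide FST: sum(a) / sum(a+b+c) over sites with finite components."""
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if denom <= 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def windowed_fst_from_arrays(
    pos: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    scheme: WindowScheme,
    contig_length: int,
    chrom: str = "1",
) -> pd.DataFrame:
    """Windowed ratio-of-sums FST from per-site components on one contig."""
    windows = scheme.windows(contig_length)
    abc = a + b + c
    finite = np.isfinite(abc)
    a_f = np.where(finite, a, 0.0)
    abc_f = np.where(finite, abc, 0.0)
    num, counts = _window_sum(np.asarray(pos, np.int64), a_f, windows)
    den, _ = _window_sum(np.asarray(pos, np.int64), abc_f, windows)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / den, np.nan)
    return _track_frame(chrom, windows, counts, values)


def windowed_fst(
    records: Iterable[SiteRecord] | VariantSet,
    popmap: PopulationMap,
    pops: tuple[str, str],
    scheme: WindowScheme,
    contig_lengths: dict[str, int],
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Windowed Weir-Cockerham FST between two populations."""
    if len(pops) != 2:
        raise ValueError("windowed_fst compares exactly two populations")
    if isinstance(records, VariantSet):
        samples = records.samples
        recs = records.records
    else:
        recs = list(records)
        if samples is None:
            raise ValueError("samples required when passing raw records")
    idx = [popmap.indices_of(p, samples) for p in pops]
    frames = []
    for chrom, length in contig_lengths.items():
        chrom_recs = [r for r in recs if r.chrom == chrom]
        if not chrom_recs:
            frames.append(windowed_fst_from_arrays(
                np.array([], np.int64), np.array([]), np.array([]), np.array([]),
                scheme, length, chrom))
            continue
        dosage = np.stack([r.genotypes for r in chrom_recs], axis=1)
        n, p, h = per_pop_site_stats(dosage, idx)
        a, b, c = wc_fst_components(n, p, h)
        pos = np.array([r.pos for r in chrom_recs], np.int64)
        frames.append(windowed_fst_from_arrays(pos, a, b, c, scheme, length, chrom))
    return pd.concat(frames, ignore_index=True) if frames else _empty_track()


def fst_matrix(
    records: Iterable[SiteRecord] | VariantSet,
    popmap: PopulationMap,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Symmetric genome-wide pairwise FST matrix over all populations."""
    if isinstance(records, VariantSet):
        samples = records.samples
        dosage = records.dosage_matrix()
    else:
        recs = list(records)
        if samples is None:
            raise ValueError("samples required when passing raw records")
        dosage = np.stack([r.genotypes for r in recs], axis=1)
    return fst_matrix_from_dosage(dosage, popmap, samples)


def fst_matrix_from_dosage(
    dosage: np.ndarray, popmap: PopulationMap, samples: Sequence[str]
) -> pd.DataFrame:
    import warnings

    pops = popmap.populations
    idx = [popmap.indices_of(p, samples) for p in pops]
    for p, cols in zip(pops, idx):
        if len(cols) < 2:
            warnings.warn(f"population {p} has fewer than 2 diploids; its FST row is NA")
    n, p_, h = per_pop_site_stats(dosage, idx)
    out = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            if len(idx[i]) < 2 or len(idx[j]) < 2:
                out[i, j] = out[j, i] = np.nan
                continue
            cols = [i, j]
            a, b, c = wc_fst_components(n[:, cols], p_[:, cols], h[:, cols])
            out[i, j] = out[j, i] = fst_ratio_of_sums(a, b, c)
    return pd.DataFrame(out, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# theta-pi ratio track
# ---------------------------------------------------------------------------

def pi_ratio(track_a: pd.DataFrame, track_b: pd.DataFrame) -> pd.DataFrame:
    """Per-window ratio track_a.value / track_b.value.

    NaN when the denominator is zero or either input is NaN (never inf);
    window schemes must match exactly.
    """
    same = (
        len(track_a) == len(track_b)
        and (track_a["chrom"].values == track_b["chrom"].values).all()
        and (track_a["start"].values == track_b["start"].values).all()
        and (track_a["end"].values == track_b["end"].values).all()
    )
    if not same:
        raise ValueError("window schemes of the two tracks differ")
    a = track_a["value"].to_numpy(float)
    b = track_b["value"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where((b != 0) & np.isfinite(a) & np.isfinite(b), a / b, np.nan)
    out = track_a.copy()
    out["n_snps"] = track_a["n_snps"].to_numpy() + track_b["n_snps"].to_numpy()
    out["value"] = v
    return out


def write_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
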
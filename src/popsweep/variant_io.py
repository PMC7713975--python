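"""VCF / GFF3 input-output, hard filtering, site filters, and SNP-context summaries.

VCF and GFF3 coordinates are 1-based inclusive throughout the public API;
window arithmetic elsewhere in the package converts to 0-based half-open
intervals internally and converts back on output.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: INFO keys written by the simulator and consumed by the hard filter.
INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR")

#: GATK-style hard-filter expression used for SNP quality control.
DEFAULT_HARD_FILTER = (
    "QD < 2.0 || FS > 60.0 || MQ < 40.0 || MQRankSum < -12.5 "
    "|| ReadPosRankSum < -8.0 || SOR > 3.0"
)


@dataclass
class SiteRecord:
    """One VCF site: alleles, INFO annotations and per-sample genotypes.

    ``genotypes`` holds alternate-allele dosage per sample (0/1/2, -1 for
    missing).  When ``phased`` is true, ``haplotypes`` holds the ordered
    allele pair per sample (shape ``(n_samples, 2)``, -1 for missing).
    """

    chrom: str
    pos: int
    ref: str
    alt: tuple[str, ...]
    info: dict[str, float]
    genotypes: np.ndarray
    phased: bool = False
    haplotypes: np.ndarray | None = None
    site_id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"POS must be >= 1, got {self.pos}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alt) == 1
            and len(self.ref) == 1
            and len(self.alt[0]) == 1
            and self.ref in "ACGT"
            and self.alt[0] in "ACGT"
        )

    def allele_counts(self) -> tuple[int, int]:
        """(n_ref, n_alt) over non-missing diploid genotypes."""
        called = self.genotypes[self.genotypes >= 0]
        n_alt = int(called.sum())
        return 2 * called.size - n_alt, n_alt

    @property
    def missing_fraction(self) -> float:
        if self.genotypes.size == 0:
            return 1.0
        return float((self.genotypes < 0).sum()) / self.genotypes.size


class PopulationMap:
    """Assignment of every sample to exactly one population."""

    def __init__(self, sample_to_pop: Mapping[str, str]):
        self.sample_to_pop = dict(sample_to_pop)
        if not self.sample_to_pop:
            raise ValueError("empty population map")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.sample_to_pop.values():
            seen.setdefault(p)
        return list(seen)

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_pop)

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def indices_of(self, pop: str, samples: Sequence[str]) -> np.ndarray:
        """Column indices of a population within an ordered sample list."""
        return np.array(
            [i for i, s in enumerate(samples) if self.sample_to_pop.get(s) == pop],
            dtype=int,
        )

    def validate_samples(self, samples: Iterable[str]) -> None:
        missing = [s for s in samples if s not in self.sample_to_pop]
        if missing:
            raise ValueError(f"samples absent from population map: {missing[:5]}")


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a two-column ``sample<TAB>population`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    dup = df["sample"].duplicated()
    if dup.any():
        raise ValueError(f"sample assigned more than once: {df['sample'][dup].tolist()}")
    return PopulationMap(dict(zip(df["sample"], df["population"])))


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.sample_to_pop.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

@dataclass
class VariantSet:
    """An in-memory VCF: ordered records plus sample and contig metadata."""

    samples: list[str]
    records: list[SiteRecord]
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def dosage_matrix(self) -> np.ndarray:
        """samples x sites dosage matrix (int8; -1 missing)."""
        if not self.records:
            return np.zeros((len(self.samples), 0), dtype=np.int8)
        return np.stack([r.genotypes for r in self.records], axis=1)


def read_vcf(path: str | Path) -> VariantSet:
    """Read a VCF 4.2 file into a :class:`VariantSet` via cyvcf2.

    Dosage is the count of non-reference alleles; any genotype containing a
    missing allele is recorded as missing (-1).  Phased haplotype pairs are
    preserved in order.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # htslib errors are opaque; re-raise with path
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    contig_lengths: dict[str, int] = {}
    try:
        seqlens = vcf.seqlens
    except AttributeError:  # header without ##contig length entries
        seqlens = []
    for name, ln in zip(vcf.seqnames, seqlens or []):
        if ln:
            contig_lengths[name] = int(ln)

    records: list[SiteRecord] = []
    for lineno, v in enumerate(vcf, start=1):
        try:
            info = {}
            for key, value in v.INFO:
                try:
                    info[key] = float(value)
                except (TypeError, ValueError):
                    continue
            gts = v.genotypes  # [[a0, a1, phased], ...]
            n = len(gts)
            dosage = np.empty(n, dtype=np.int8)
            haps = np.empty((n, 2), dtype=np.int8)
            phased = n > 0
            for i, g in enumerate(gts):
                a0, a1 = g[0], g[1]
                phased = phased and bool(g[2])
                haps[i, 0] = a0 if a0 >= 0 else -1
                haps[i, 1] = a1 if a1 >= 0 else -1
                if a0 < 0 or a1 < 0:
                    dosage[i] = -1
                else:
                    dosage[i] = (a0 > 0) + (a1 > 0)
            records.append(
                SiteRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=tuple(v.ALT),
                    info=info,
                    genotypes=dosage,
                    phased=phased,
                    haplotypes=haps if phased else None,
                    site_id=v.ID or ".",
                )
            )
        except Exception as exc:
            raise ValueError(f"malformed VCF record #{lineno} in {path}: {exc}") from exc
    return VariantSet(samples=samples, records=records, contig_lengths=contig_lengths)


def write_vcf(variants: VariantSet, path: str | Path) -> None:
    """Write a VariantSet as plain-text VCF 4.2 (deterministic byte output)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=popsweep\n')
        for name, ln in variants.contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={ln}>\n")
        for key in INFO_KEYS:
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(variants.samples) + "\n")
        for r in variants.records:
            if r.info:
                info_str = ";".join(f"{k}={_fmt(v)}" for k, v in r.info.items())
            else:
                info_str = "."
            sep = "|" if r.phased else "/"
            if r.phased and r.haplotypes is not None:
                gt_strs = [
                    f"{_allele(a)}{sep}{_allele(b)}" for a, b in r.haplotypes
                ]
            else:
                gt_strs = [_unphased_gt(d) for d in r.genotypes]
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.site_id}\t{r.ref}\t{','.join(r.alt)}\t.\t.\t"
                f"{info_str}\tGT\t" + "\t".join(gt_strs) + "\n"
            )


def _fmt(x: float) -> str:
    return f"{x:.4f}".rstrip("0").rstrip(".")


def _allele(a: int) -> str:
    return "." if a < 0 else str(int(a))


def _unphased_gt(d: int) -> str:
    return {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(d), "./.")


# ---------------------------------------------------------------------------
# Hard filter (GATK VariantFiltration-style expression)
# ---------------------------------------------------------------------------

_CLAUSE_RE = re.compile(
    r"\s*([A-Za-z_][A-Za-z0-9_]*)\s*(<=|>=|==|!=|<|>)\s*([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*"
)

_COMPARATORS = {
    "<": np.less,
    ">": np.greater,
    "<=": np.less_equal,
    ">=": np.greater_equal,
    "==": np.equal,
    "!=": np.not_equal,
}


@dataclass(frozen=True)
class _Clause:
    key: str
    op: str
    value: float

    def triggers(self, info: Mapping[str, float]) -> bool:
        # Missing-annotation convention: an absent key never triggers.
        if self.key not in info:
            return False
        return bool(_COMPARATORS[self.op](info[self.key], self.value))


class HardFilter:
    """OR of AND-groups of ``KEY comparator literal`` clauses.

    A record FAILS when the expression evaluates true.  A clause whose INFO
    key is absent from the record evaluates false (the annotation-missing
    convention of the variant-calling tool this mirrors).
    """

    def __init__(self, expression: str):
        self.expression = expression
        expr = expression.replace("−", "-")  # tolerate unicode minus
        self.groups: list[list[_Clause]] = []
        for or_part in expr.split("||"):
            group = []
            for clause_text in or_part.split("&&"):
                if not clause_text.strip():
                    raise ValueError(f"empty clause in filter expression: {expression!r}")
                m = _CLAUSE_RE.fullmatch(clause_text)
                if m is None:
                    raise ValueError(f"cannot parse filter clause: {clause_text.strip()!r}")
                key, op, literal = m.groups()
                if op not in _COMPARATORS:
                    raise ValueError(f"unknown comparator {op!r}")
                group.append(_Clause(key, op, float(literal)))
            self.groups.append(group)

    def fails(self, info: Mapping[str, float]) -> bool:
        return any(all(c.triggers(info) for c in group) for group in self.groups)


def evaluate_hard_filter(record: SiteRecord, expression: str | HardFilter) -> bool:
    """True when the record PASSES the hard filter."""
    hf = expression if isinstance(expression, HardFilter) else HardFilter(expression)
    return not hf.fails(record.info)


# ---------------------------------------------------------------------------
# Site filters (biallelic / missingness / MAF)
# ---------------------------------------------------------------------------

@dataclass
class FilterPolicy:
    """Site-retention policy: hard-filter expression plus MAF/missingness bounds.

    The MAF bound is inclusive (``>= maf_min`` retained); the hard-filter
    comparators are exactly as written in the expression.
    """

    expression: str | None = DEFAULT_HARD_FILTER
    maf_min: float = 0.05
    max_missing_fraction: float = 0.5
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")


def site_maf(record: SiteRecord) -> float:
    """Minor-allele frequency over non-missing alleles; NaN if none called."""
    n_ref, n_alt = record.allele_counts()
    n = n_ref + n_alt
    if n == 0:
        return float("nan")
    p = n_alt / n
    return min(p, 1.0 - p)


def apply_site_filters(
    records: Iterable[SiteRecord],
    policy: FilterPolicy,
) -> tuple[list[SiteRecord], dict[str, int]]:
    """Apply hard-filter + biallelic + missingness + MAF filters.

    Returns surviving records and counts of sites removed per criterion
    (each removed site is attributed to the first criterion it fails, in
    the order hard_filter, not_biallelic, missingness, maf).  A site with
    zero called alleles is removed under missingness.
    """
    hf = HardFilter(policy.expression) if policy.expression else None
    counts = {"input": 0, "hard_filter": 0, "not_biallelic": 0,
              "missingness": 0, "maf": 0, "retained": 0}
    kept: list[SiteRecord] = []
    for rec in records:
        counts["input"] += 1
        if hf is not None and hf.fails(rec.info):
            counts["hard_filter"] += 1
            continue
        if policy.biallelic_only and not rec.is_biallelic_snp:
            counts["not_biallelic"] += 1
            continue
        if rec.missing_fraction > policy.max_missing_fraction:
            counts["missingness"] += 1
            continue
        maf = site_maf(rec)
        if not (maf >= policy.maf_min):  # NaN (no called alleles) also removed
            if np.isnan(maf):
                counts["missingness"] += 1
            else:
                counts["maf"] += 1
            continue
        counts["retained"] += 1
        kept.append(rec)
    return kept, counts


# ---------------------------------------------------------------------------
# Genomic-context classification
# ---------------------------------------------------------------------------

class GenomeAnnotation:
    """Gene and CDS intervals extracted from a GFF3 file (1-based inclusive)."""

    def __init__(self, genes: pd.DataFrame, cds: pd.DataFrame):
        # genes: gene_id, chrom, start, end ; cds: chrom, start, end
        self.genes = genes.reset_index(drop=True)
        self.cds = cds.reset_index(drop=True)
        self._gene_by_chrom = {c: df.sort_values("start") for c, df in genes.groupby("chrom")}
        self._cds_by_chrom = {c: df.sort_values("start") for c, df in cds.groupby("chrom")}

    @property
    def contigs(self) -> set[str]:
        return set(self._gene_by_chrom)

    def _in_intervals(self, chrom: str, pos: np.ndarray, table: dict) -> np.ndarray:
        out = np.zeros(len(pos), dtype=bool)
        df = table.get(chrom)
        if df is None:
            return out
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        for s, e in zip(starts, ends):
            out |= (pos >= s) & (pos <= e)
        return out

    def in_cds(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        return self._in_intervals(chrom, np.asarray(pos), self._cds_by_chrom)

    def in_gene(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        return self._in_intervals(chrom, np.asarray(pos), self._gene_by_chrom)

    def genes_overlapping(self, chrom: str, start: int, end: int, flank: int = 0) -> set[str]:
        df = self._gene_by_chrom.get(chrom)
        if df is None:
            return set()
        hit = (df["start"] - flank <= end) & (df["end"] + flank >= start)
        return set(df.loc[hit, "gene_id"])


def read_gff(path: str | Path) -> GenomeAnnotation:
    """Load gene and CDS features from GFF3 via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        genes.append((g.id, g.seqid, g.start, g.end))
    cds = []
    for c in db.features_of_type("CDS"):
        cds.append((c.seqid, c.start, c.end))
    gene_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end"])
    cds_df = pd.DataFrame(cds, columns=["chrom", "start", "end"])
    return GenomeAnnotation(gene_df, cds_df)


def classify_sites(
    records: Iterable[SiteRecord], annotation: GenomeAnnotation
) -> dict[str, int]:
    """Count sites by genomic context: coding (in CDS), intronic (in a gene
    span but not CDS; exonic-non-CDS counts here too), else intergenic."""
    labels = site_context_labels(records, annotation)
    counts = {"intergenic": 0, "intronic": 0, "coding": 0}
    for lab in labels:
        counts[lab] += 1
    return counts


def site_context_labels(
    records: Iterable[SiteRecord], annotation: GenomeAnnotation
) -> list[str]:
    recs = list(records)
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(recs):
        by_chrom.setdefault(r.chrom, []).append(i)
    labels = [""] * len(recs)
    for chrom, idx in by_chrom.items():
        pos = np.array([recs[i].pos for i in idx])
        if chrom not in annotation.contigs:
            logger.warning("contig %s absent from annotation; sites treated as intergenic", chrom)
        coding = annotation.in_cds(chrom, pos)
        genic = annotation.in_gene(chrom, pos)
        for j, i in enumerate(idx):
            if coding[j]:
                labels[i] = "coding"
            elif genic[j]:
                labels[i] = "intronic"
            else:
                labels[i] = "intergenic"
    return labels


# ---------------------------------------------------------------------------
# Shared / unique SNP counts (UpSet-style exclusive intersections)
# ---------------------------------------------------------------------------

def snp_sharing_counts(
    records: Iterable[SiteRecord],
    popmap: PopulationMap,
    samples: Sequence[str],
) -> dict[tuple[str, ...], int]:
    """Exclusive-intersection SNP counts over all population subsets.

    A SNP belongs to a population when at least one non-missing alternate
    allele is observed there.  Keys are sorted population tuples; counts sum
    to the number of SNPs segregating in at least one population.
    """
    pops = popmap.populations
    k = len(pops)
    if k < 2:
        raise ValueError("need at least two populations")
    if k > 20:
        raise ValueError(f"refusing {k} populations (> 20): 2^k subsets is intractable")
    popmap.validate_samples(samples)
    idx = [popmap.indices_of(p, samples) for p in pops]
    masks = np.zeros(2 ** k, dtype=np.int64)
    for rec in records:
        g = rec.genotypes
        bits = 0
        for b, cols in enumerate(idx):
            sub = g[cols]
            if np.any(sub > 0):
                bits |= 1 << b
        masks[bits] += 1
    out: dict[tuple[str, ...], int] = {}
    for bits in range(1, 2 ** k):
        if masks[bits]:
            subset = tuple(sorted(pops[b] for b in range(k) if bits >> b & 1))
            out[subset] = int(masks[bits])
    return out
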
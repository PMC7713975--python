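"""Synthetic cohorts with known ground truth for every pipeline stage.

The generators emulate only the statistical signatures the downstream
methods consume, not any real demographic history:

* structured populations under the Balding-Nichols model (per-population
  allele frequencies Beta-distributed around an ancestral frequency, with
  the Beta parameterised by a target differentiation F);
* a planted hard selective sweep (one long high-frequency core haplotype
  replacing a fraction of one population's haplotypes, locally erasing
  diversity and extending haplotype homozygosity);
* tree-structured populations whose allele frequencies drift along a
  rooted tree (truncated Brownian motion, variance proportional to branch
  length) for phylogeny-recovery tests;
* single-exon gene annotations (GFF3) overlapping a chosen sweep region;
* qPCR Ct tables with condition-dependent log2 expression shifts.

All generators are deterministic given their seed, and VCF output is
byte-identical across reruns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_io import (INFO_KEYS, PopulationMap, SiteRecord, VariantSet,
                         write_popmap, write_vcf)


# ---------------------------------------------------------------------------
# Balding-Nichols structured populations
# ---------------------------------------------------------------------------

@dataclass
class BaldingNicholsSpec:
    """Structured-population simulation parameters.

    ``F_per_pop`` sets the Balding-Nichols differentiation of each
    population from the shared ancestral pool (0 < F < 1; F -> 0 is the
    no-differentiation limit and is handled exactly).  Ancestral
    frequencies are uniform on ``ancestral_freq_range`` — (0.05, 0.95) by
    default so most simulated sites survive a MAF >= 0.05 filter.
    """

    n_pops: int
    F_per_pop: tuple[float, ...]
    n_diploids_per_pop: int
    n_sites: int
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0
    chrom: str = "1"
    spacing_bp: int = 200
    failing_info_fraction: float = 0.0
    pop_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.F_per_pop) != self.n_pops:
            raise ValueError("F_per_pop length must equal n_pops")
        for F in self.F_per_pop:
            if not 0.0 <= F < 1.0:
                raise ValueError(f"F must be in [0, 1), got {F}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must satisfy 0 < low < high < 1")
        if self.pop_labels is None:
            self.pop_labels = tuple(f"pop{k+1}" for k in range(self.n_pops))

    @property
    def contig_length(self) -> int:
        return self.spacing_bp * (self.n_sites + 1)


@dataclass
class SimulatedCohort:
    """In-memory simulated cohort: phased haplotypes plus metadata.

    ``haplotypes`` is (2 * n_samples) x n_sites int8; haplotype rows 2i and
    2i+1 belong to diploid sample i.  ``info`` holds the simulated VCF INFO
    annotations per site.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    chrom: str
    samples: list[str]
    sample_pops: list[str]
    contig_length: int
    pop_freqs: np.ndarray | None = None
    ancestral_freqs: np.ndarray | None = None
    info: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)

    @property
    def dosage(self) -> np.ndarray:
        return (self.haplotypes[0::2].astype(np.int8)
                + self.haplotypes[1::2].astype(np.int8))

    @property
    def popmap(self) -> PopulationMap:
        return PopulationMap(dict(zip(self.samples, self.sample_pops)))

    def hap_pop_labels(self) -> np.ndarray:
        return np.repeat(np.asarray(self.sample_pops, dtype=object), 2)

    def to_variant_set(self) -> VariantSet:
        records = []
        n = len(self.samples)
        for j in range(self.positions.size):
            haps = self.haplotypes[:, j].reshape(n, 2)
            info = ({k: float(self.info[k].iloc[j]) for k in self.info.columns}
                    if self.info is not None else {})
            records.append(SiteRecord(
                chrom=self.chrom,
                pos=int(self.positions[j]),
                ref="A",
                alt=("T",),
                info=info,
                genotypes=haps.sum(axis=1).astype(np.int8),
                phased=True,
                haplotypes=haps.astype(np.int8),
            ))
        return VariantSet(samples=list(self.samples), records=records,
                          contig_lengths={self.chrom: self.contig_length})

    def write(self, vcf_path: str | Path, popmap_path: str | Path | None = None) -> None:
        write_vcf(self.to_variant_set(), vcf_path)
        if popmap_path is not None:
            write_popmap(self.popmap, popmap_path)


def _simulate_info(rng: np.random.Generator, n_sites: int,
                   failing_fraction: float) -> pd.DataFrame:
    """INFO annotations from 'passing' distributions, with a chosen fraction
    of records violating exactly one hard-filter clause."""
    info = pd.DataFrame({
        "QD": np.round(rng.uniform(5.0, 35.0, n_sites), 2),
        "FS": np.round(rng.uniform(0.0, 20.0, n_sites), 3),
        "MQ": np.round(rng.uniform(50.0, 60.0, n_sites), 2),
        "MQRankSum": np.round(rng.normal(0.0, 1.0, n_sites), 3),
        "ReadPosRankSum": np.round(rng.normal(0.0, 1.0, n_sites), 3),
        "SOR": np.round(rng.uniform(0.3, 2.5, n_sites), 3),
    })
    n_fail = int(round(failing_fraction * n_sites))
    if n_fail:
        fail_idx = rng.choice(n_sites, size=n_fail, replace=False)
        which = rng.integers(0, len(INFO_KEYS), size=n_fail)
        bad = {
            "QD": lambda r: np.round(r.uniform(0.0, 1.9), 2),
            "FS": lambda r: np.round(r.uniform(60.5, 200.0), 3),
            "MQ": lambda r: np.round(r.uniform(10.0, 39.0), 2),
            "MQRankSum": lambda r: np.round(r.uniform(-20.0, -13.0), 3),
            "ReadPosRankSum": lambda r: np.round(r.uniform(-15.0, -8.5), 3),
            "SOR": lambda r: np.round(r.uniform(3.5, 9.0), 3),
        }
        for i, w in zip(fail_idx, which):
            key = INFO_KEYS[w]
            info.loc[i, key] = bad[key](rng)
    return info


def balding_nichols_freqs(rng: np.random.Generator, p_anc: np.ndarray,
                          F: float) -> np.ndarray:
    """Population allele frequencies Beta(p(1-F)/F, (1-p)(1-F)/F).

    The F -> 0 limit is exact: frequencies equal the ancestral frequency.
    """
    if F <= 0.0:
        return p_anc.copy()
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    return rng.beta(a, b)


def simulate_balding_nichols(spec: BaldingNicholsSpec) -> SimulatedCohort:
    """Generate a phased multi-population cohort under the model in
    :class:`BaldingNicholsSpec`; every haplotype allele is an independent
    Bernoulli draw from its population's site frequency."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, spec.n_sites)
    n_dip = spec.n_diploids_per_pop
    pop_freqs = np.empty((spec.n_pops, spec.n_sites))
    hap_blocks = []
    samples, sample_pops = [], []
    for k in range(spec.n_pops):
        pop_freqs[k] = balding_nichols_freqs(rng, p_anc, spec.F_per_pop[k])
        haps = (rng.random((2 * n_dip, spec.n_sites)) < pop_freqs[k][None, :])
        hap_blocks.append(haps.astype(np.int8))
        label = spec.pop_labels[k]
        samples += [f"{label}_s{i+1}" for i in range(n_dip)]
        sample_pops += [label] * n_dip
    info = _simulate_info(rng, spec.n_sites, spec.failing_info_fraction)
    positions = spec.spacing_bp * np.arange(1, spec.n_sites + 1, dtype=np.int64)
    return SimulatedCohort(
        haplotypes=np.vstack(hap_blocks),
        positions=positions,
        chrom=spec.chrom,
        samples=samples,
        sample_pops=sample_pops,
        contig_length=spec.contig_length,
        pop_freqs=pop_freqs,
        ancestral_freqs=p_anc,
        info=info,
        truth={"F_per_pop": dict(zip(spec.pop_labels, spec.F_per_pop))},
    )


def gen_balding_nichols(spec: BaldingNicholsSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write VCF + popmap for a Balding-Nichols cohort; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_balding_nichols(spec)
    vcf, popmap = out / "cohort.vcf", out / "cohort.popmap.tsv"
    cohort.write(vcf, popmap)
    return vcf, popmap


# ---------------------------------------------------------------------------
# Planted selective sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepSpec:
    """A hard sweep planted by haplotype copying.

    In ``sweep_pop``, a fraction ``sweep_frequency`` of haplotypes have
    their alleles inside ``region`` replaced by one core haplotype (chosen
    from the population), after which each copied allele is flipped with
    probability ``mutation_noise``.  Other populations are untouched.
    """

    sweep_pop: str
    region: tuple[str, int, int]  # (chrom, start_bp, end_bp), 1-based inclusive
    sweep_frequency: float = 0.9
    mutation_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _, start, end = self.region
        if start >= end:
            raise ValueError("region start must be < end")
        if not 0.0 < self.sweep_frequency <= 1.0:
            raise ValueError("sweep_frequency must be in (0, 1]")
        if not 0.0 <= self.mutation_noise < 0.5:
            raise ValueError("mutation_noise must be in [0, 0.5)")


def plant_sweep(cohort: SimulatedCohort, spec: SweepSpec) -> SimulatedCohort:
    """Return a copy of the cohort with the sweep planted.

    Raises ``ValueError('empty sweep region')`` when no SNP falls inside
    the region.  Ground truth (region, core haplotype carriers) is recorded
    in ``cohort.truth['sweep']``.
    """
    chrom, start, end = spec.region
    if chrom != cohort.chrom:
        raise ValueError(f"region chromosome {chrom!r} not in cohort ({cohort.chrom!r})")
    in_region = (cohort.positions >= start) & (cohort.positions <= end)
    if not in_region.any():
        raise ValueError("empty sweep region")
    hap_pops = cohort.hap_pop_labels()
    pop_rows = np.flatnonzero(hap_pops == spec.sweep_pop)
    if pop_rows.size == 0:
        raise ValueError(f"population {spec.sweep_pop!r} not in cohort")
    rng = np.random.default_rng(spec.seed)
    n_swept = int(round(spec.sweep_frequency * pop_rows.size))
    carriers = rng.choice(pop_rows, size=n_swept, replace=False)
    core_row = rng.choice(pop_rows)
    core = cohort.haplotypes[core_row, in_region].copy()
    haps = cohort.haplotypes.copy()
    block = np.tile(core, (n_swept, 1))
    if spec.mutation_noise > 0:
        flips = rng.random(block.shape) < spec.mutation_noise
        block = np.where(flips, 1 - block, block).astype(np.int8)
    haps[np.ix_(carriers, np.flatnonzero(in_region))] = block
    out = SimulatedCohort(
        haplotypes=haps,
        positions=cohort.positions,
        chrom=cohort.chrom,
        samples=list(cohort.samples),
        sample_pops=list(cohort.sample_pops),
        contig_length=cohort.contig_length,
        pop_freqs=cohort.pop_freqs,
        ancestral_freqs=cohort.ancestral_freqs,
        info=cohort.info,
        truth=dict(cohort.truth),
    )
    out.truth["sweep"] = {
        "pop": spec.sweep_pop, "chrom": chrom, "start": start, "end": end,
        "frequency": spec.sweep_frequency, "carrier_rows": sorted(int(i) for i in carriers),
    }
    return out


def write_sweep_truth(cohort: SimulatedCohort, path: str | Path) -> None:
    """Sidecar TSV recording the planted-sweep ground truth."""
    t = cohort.truth.get("sweep")
    if t is None:
        raise ValueError("cohort has no planted sweep")
    pd.DataFrame([{k: v for k, v in t.items() if k != "carrier_rows"}]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tree-structured populations
# ---------------------------------------------------------------------------

def gen_tree_structured(
    newick: str,
    n_per_tip: int,
    n_sites: int,
    seed: int = 0,
    drift_scale: float = 0.2,
    ancestral_freq_range: tuple[float, float] = (0.2, 0.8),
    spacing_bp: int = 200,
    chrom: str = "1",
) -> SimulatedCohort:
    """Populations whose allele frequencies drift along a rooted tree.

    Along each branch of length t the frequency moves by Normal(0,
    drift_scale^2 * t), truncated to (0.01, 0.99); tip populations then
    sample diploid genotypes at their final frequencies.  Expected
    p-distance between tips grows with path length on the tree, so
    distance-based tree building can be tested against the generating
    topology.
    """
    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick), format="newick")
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("tree must have at least two tips")
    rng = np.random.default_rng(seed)
    lo, hi = ancestral_freq_range
    freqs: dict[int, np.ndarray] = {id(tree): rng.uniform(lo, hi, n_sites)}
    for node in tree.preorder(include_self=False):
        bl = node.length or 0.0
        parent_f = freqs[id(node.parent)]
        step = rng.normal(0.0, drift_scale * np.sqrt(bl), n_sites) if bl > 0 else 0.0
        freqs[id(node)] = np.clip(parent_f + step, 0.01, 0.99)
    hap_blocks, samples, sample_pops = [], [], []
    for tip in tips:
        f = freqs[id(tip)]
        haps = (rng.random((2 * n_per_tip, n_sites)) < f[None, :]).astype(np.int8)
        hap_blocks.append(haps)
        samples += [f"{tip.name}_s{i+1}" for i in range(n_per_tip)]
        sample_pops += [tip.name] * n_per_tip
    positions = spacing_bp * np.arange(1, n_sites + 1, dtype=np.int64)
    return SimulatedCohort(
        haplotypes=np.vstack(hap_blocks),
        positions=positions,
        chrom=chrom,
        samples=samples,
        sample_pops=sample_pops,
        contig_length=spacing_bp * (n_sites + 1),
        truth={"tree": newick},
    )


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

def gen_annotations(
    contigs: dict[str, int],
    genes: list[tuple[str, str, int, int]],
    path: str | Path,
) -> Path:
    """Write a GFF3 with gene/mRNA/exon/CDS features (1-based inclusive).

    ``genes`` rows are (gene_id, chrom, start, end); single-exon genes with
    CDS spanning the whole gene body.  Malformed (start > end, outside the
    contig) or overlapping genes on one contig are rejected.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gene_id, chrom, start, end in genes:
        if chrom not in contigs:
            raise ValueError(f"gene {gene_id}: unknown contig {chrom}")
        if not (1 <= start <= end <= contigs[chrom]):
            raise ValueError(f"gene {gene_id}: [{start}, {end}] outside contig bounds")
        by_chrom.setdefault(chrom, []).append((start, end, gene_id))
    for chrom, rows in by_chrom.items():
        rows.sort()
        for (s1, e1, g1), (s2, e2, g2) in zip(rows, rows[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping genes {g1} and {g2} on {chrom}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in contigs.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gene_id, chrom, start, end in genes:
            attrs = f"ID={gene_id}"
            fh.write(f"{chrom}\tpopsweep\tgene\t{start}\t{end}\t.\t+\t.\t{attrs}\n")
            fh.write(f"{chrom}\tpopsweep\tmRNA\t{start}\t{end}\t.\t+\t.\t"
                     f"ID={gene_id}.t1;Parent={gene_id}\n")
            fh.write(f"{chrom}\tpopsweep\texon\t{start}\t{end}\t.\t+\t.\t"
                     f"ID={gene_id}.e1;Parent={gene_id}.t1\n")
            fh.write(f"{chrom}\tpopsweep\tCDS\t{start}\t{end}\t.\t+\t0\t"
                     f"ID={gene_id}.c1;Parent={gene_id}.t1\n")
    return path


def evenly_spaced_genes(
    chrom: str,
    contig_length: int,
    n_genes: int,
    gene_length: int = 10_000,
    prefix: str = "gene",
) -> list[tuple[str, str, int, int]]:
    """n single-exon genes evenly tiled along a contig (fixture helper)."""
    gap = contig_length // n_genes
    if gene_length >= gap:
        raise ValueError("genes would overlap; shorten gene_length")
    out = []
    for i in range(n_genes):
        start = i * gap + (gap - gene_length) // 2 + 1
        out.append((f"{prefix}{i+1:03d}", chrom, start, start + gene_length - 1))
    return out


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

@dataclass
class QpcrSpec:
    """Replicated qPCR Ct measurements with known expression shifts.

    ``true_log2_shift_per_condition`` maps each condition label to the true
    log2 expression change relative to the calibrator (whose shift should
    be 0); a shift of +1 halves the target Ct threshold cycle count by one
    cycle.  Temperatures emulated by default follow a cold-exposure design
    (0C/4C/10C vs a 25C calibrator) with three biological replicates.
    """

    conditions: tuple[str, ...] = ("0C", "4C", "10C", "25C")
    replicates_per_condition: int = 3
    true_log2_shift_per_condition: dict[str, float] = field(
        default_factory=lambda: {"0C": 2.0, "4C": 1.0, "10C": 0.5, "25C": 0.0})
    ct_noise_sd: float = 0.1
    reference_gene_ct: float = 18.0
    target_baseline_ct: float = 24.0
    calibrator: str = "25C"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.calibrator not in self.conditions:
            raise ValueError("calibrator condition must be present")
        missing = [c for c in self.conditions
                   if c not in self.true_log2_shift_per_condition]
        if missing:
            raise ValueError(f"no true shift given for conditions: {missing}")


def gen_qpcr(spec: QpcrSpec) -> pd.DataFrame:
    """Ct table with columns condition, replicate, gene, Ct.

    Target Ct = baseline - true_log2_shift + Normal(0, sd); reference-gene
    Ct = constant + Normal(0, sd).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cond in spec.conditions:
        shift = spec.true_log2_shift_per_condition[cond]
        for rep in range(1, spec.replicates_per_condition + 1):
            ct_t = spec.target_baseline_ct - shift + rng.normal(0, spec.ct_noise_sd)
            ct_r = spec.reference_gene_ct + rng.normal(0, spec.ct_noise_sd)
            rows.append((cond, rep, "target", ct_t))
            rows.append((cond, rep, "reference", ct_r))
    return pd.DataFrame(rows, columns=["condition", "replicate", "gene", "Ct"])


def write_qpcr(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# One-call sweep study
# ---------------------------------------------------------------------------

@dataclass
class SweepStudy:
    """A complete simulated selection study with ground truth.

    ``cohort`` carries the planted sweep; ``genes`` are the GFF3 gene rows
    (one of them, ``sweep_gene``, lies fully inside the sweep region);
    ``true_genes`` are all genes overlapping the region (recovering any of
    them is a true positive, the rest are false positives).
    """

    cohort: SimulatedCohort
    genes: list[tuple[str, str, int, int]]
    contigs: dict[str, int]
    sweep_spec: SweepSpec
    sweep_gene: str
    true_genes: set[str]
    focal_pop: str = "focal"
    ref_pop: str = "ref"

    def write_gff(self, path: str | Path) -> Path:
        return gen_annotations(self.contigs, self.genes, path)


def simulate_sweep_study(
    seed: int,
    n_sites: int = 4_000,
    n_diploids_per_pop: int = 30,
    background_F: float = 0.05,
    spacing_bp: int = 500,
    n_genes: int = 40,
    gene_length: int = 10_000,
    sweep_length: int = 50_000,
    sweep_frequency: float = 0.9,
    mutation_noise: float = 1e-3,
) -> SweepStudy:
    """Two populations on a ~2-Mb contig with a hard sweep in one of them.

    Defaults give a 2-Mb genome (4,000 SNPs every 500 bp), 40 genes of
    10 kb in 50-kb slots, and a 50-kb sweep at 90% frequency centred
    mid-contig; the gene in the central slot is re-centred on the sweep
    midpoint so the annotation contains one gene fully inside the region.
    """
    spec = BaldingNicholsSpec(
        n_pops=2, F_per_pop=(background_F, background_F),
        n_diploids_per_pop=n_diploids_per_pop, n_sites=n_sites, seed=seed,
        spacing_bp=spacing_bp, pop_labels=("focal", "ref"))
    L = spec.contig_length
    center = (L // 2 // spacing_bp) * spacing_bp
    region = (spec.chrom, center - sweep_length // 2 + 1, center + sweep_length // 2)
    gap = L // n_genes
    if gene_length >= gap:
        raise ValueError("genes would overlap; shorten gene_length")
    genes: list[tuple[str, str, int, int]] = []
    sweep_slot = center // gap
    sweep_gene = ""
    for i in range(n_genes):
        gene_id = f"gene{i+1:03d}"
        if i == sweep_slot:
            start = center - gene_length // 2 + 1
            sweep_gene = gene_id
        else:
            start = i * gap + (gap - gene_length) // 2 + 1
        genes.append((gene_id, spec.chrom, start, start + gene_length - 1))
    cohort = plant_sweep(simulate_balding_nichols(spec),
                         SweepSpec("focal", region, sweep_frequency,
                                   mutation_noise, seed=seed))
    true_genes = {g for g, _, s, e in genes if s <= region[2] and e >= region[1]}
    return SweepStudy(
        cohort=cohort, genes=genes, contigs={spec.chrom: L},
        sweep_spec=SweepSpec("focal", region, sweep_frequency, mutation_noise, seed=seed),
        sweep_gene=sweep_gene, true_genes=true_genes)
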
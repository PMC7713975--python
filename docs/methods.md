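# Methods

## Scope and data flow

The library analyses multi-sample SNP data for signatures of positive
selection and population structure. Inputs are a (phased or unphased)
VCF 4.2, a GFF3 gene annotation, a sample→population map, optional
gene→pathway and gene→category tables, and a qPCR Ct table. Upstream
steps — read mapping, genotype calling, statistical phasing, transcript
quantification and the count-model DE fit — are consumed, not
implemented: the VCF is assumed called and (for haplotype statistics)
phased, and the DE table is assumed to carry corrected p-values.

Coordinates are 1-based inclusive in all inputs and outputs (VCF/GFF
convention); window arithmetic is done internally on half-open intervals
and converted back on emission.

## SNP quality control

Hard filtering evaluates a GATK-style boolean expression over INFO
annotations (default `QD < 2.0 || FS > 60.0 || MQ < 40.0 ||
MQRankSum < -12.5 || ReadPosRankSum < -8.0 || SOR > 3.0`); a record fails
when the expression is true. A clause whose key is absent evaluates
false, mirroring the annotation-missing convention of the caller this
emulates. Comparators are exactly as written: `FS = 60.0` passes,
`QD = 2.0` passes.

Site filters keep biallelic SNPs with missing fraction ≤ 0.5 and minor
allele frequency ≥ 0.05 (inclusive bound) over non-missing alleles.
Multi-allelic sites are dropped, not split. Sites with zero called
alleles fall under missingness; no division by zero can occur. The
filters commute: hard-then-site equals site-then-hard on any input.

Context classification is three-way: a site inside any CDS is `coding`,
else inside any gene span `intronic`, else `intergenic`. Exonic-but-
non-CDS (UTR) positions therefore count as intronic; this is a documented
convention of the three-category summary, not a claim about any
particular dataset's definitions.

## Diversity and differentiation

Per-site diversity is the mean pairwise difference among sampled alleles,
θπ = 2·n_ref·n_alt/(n(n−1)); windowed θπ sums sites in the window and
divides by the window length in bp, so monomorphic positions implicitly
contribute zero (a `per_snp_mean` flag divides by the SNP count instead).
Two window schemes are built in: 10 kb sliding by 1 kb for genome-wide
presentation and 100 kb by 20 kb for the selection scan (the scan
default). Windows tile each contig as floor((L−size)/step)+1.

F_ST uses the Weir–Cockerham (1984) components a (among populations), b
(among individuals within populations) and c (within individuals),
computed per site from per-population sample sizes, allele frequencies
and observed heterozygosity, then aggregated as a ratio of sums
Σa/Σ(a+b+c) — the standard multi-site estimator; mean-of-ratios is noisier
and not offered. Negative per-window values are reported as computed.
Note the estimator's small-sample correction makes single sites (and
degenerate inputs with literally identical per-population statistics)
slightly negative in expectation components; only the aggregated
estimator is unbiased around the true differentiation.

The θπ-ratio track divides two same-scheme tracks window-wise; windows
with a zero or missing denominator are NA (never infinite) and NA windows
are excluded from all quantile computations.

## Haplotype statistics

EHH at extent x is the probability that two haplotypes drawn without
replacement are identical at every site from the core to x inclusive,
computed by partition refinement: Σ_g C(k_g,2)/C(n,2). It is exactly
non-increasing in |x − core|. For the cross-population statistic the
partition is over all haplotypes of a population (not conditioned on the
core allele), the standard XP-EHH definition. A missing allele matches
nothing — it breaks haplotype identity conservatively.

iHH integrates the EHH curve over genetic distance by the trapezoid rule
on each flank under a constant-rate map (default 17.4 cM/Mb, a honeybee
estimate; the rate is a parameter). Integration starts at the core
position (anchor value = core-site homozygosity) and stops at the first
site where EHH < 0.05 (that final trapezoid is included — the integral is
then continuous in the cutoff), at the chromosome edge, or at a physical
gap > 200 kb. Cutoff and gap are flags; the defaults are stated
assumptions, not reproductions of any particular scan's settings.

XP-EHH per core SNP is ln(iHH_A/iHH_B). Cores where either flank of
either population failed to decay below the cutoff (edge or gap) or where
either iHH is zero are dropped with a recorded reason; retained raw
scores are z-normalised genome-wide, giving two-sided normal p-values and
a rank fraction over |z|. The top-q rule (default q = 0.01) selects by
|z| with boundary ties included; selection in either population is
scanned by default, one-sidedness is a caller choice.

## Consensus sweep calling

Outlier windows: both 5% tails of the θπ-ratio and the right 5% tail of
F_ST, using type-7 (linear interpolation) empirical quantiles over finite
windows only, ties at the threshold included. The θπ ratio is oriented
reference/focal so a sweep in the focal population inflates the ratio;
the orientation is explicit in the pipeline API. Windows and SNPs map to
genes by interval overlap (gene body, flank 0 bp by default; the flank is
configurable because annotation completeness varies). The consensus is a
gene-level set intersection — windows and SNPs have incommensurable
coordinates, genes are the common currency — and only genes supported by
all three statistics are reported, ordered by position.

Enrichment: for each pathway with K background genes of which k are
candidates, p = P(X ≥ k) under the hypergeometric distribution with N
background genes and n candidates, BH-adjusted across pathways. The COG
summary counts one category per gene (top-hit assignment is upstream);
unassigned genes are reported as `unannotated`.

## Structure and phylogeny

PCA standardises dosages per site by (g − 2p̂)/√(p̂(1−p̂)) with p̂ the
sample frequency; missing entries are mean-imputed (zero after centring);
monomorphic sites are dropped; coordinates are eigenvectors of the
sample covariance scaled by √eigenvalue. Tracy–Widom scores for leading
eigenvalues use the moment-matching effective marker count; only the
tabulated TW1 95th/99th critical values ship, so the report flags
significance at those two levels rather than giving full p-values.

The admixture model treats individual i's genotype at site j as
Binomial(2, Σ_k q_ik f_kj). EM updates both Q and F from expected
allele-origin counts; missing genotypes are excluded from all sums; Q and
F are clipped to [1e−9, 1−1e−9] for numerical safety (the log-likelihood
is monotone to well within the 1e−8 assertion used in tests). Five
restarts from random initialisation by default, best likelihood kept;
convergence when the improvement falls below 1e−6. Q is identifiable only
up to column permutation; tests align columns greedily by correlation.
The accelerated quasi-Newton scheme of the reference tool is out of
scope — plain EM is slower but sufficient at these sizes.

Distances are p-distances on dosage: mean |g_i − g_j|/2 over sites called
in both samples (pairwise deletion); a pair sharing no called sites is an
error. Trees come from Saitou–Nei neighbor joining (scikit-bio's
implementation, negative branch lengths clamped to zero); on additive
matrices the tree reproduces the input path lengths to 1e−9. Bootstrap
resamples site columns with replacement, rebuilds the tree, and scores
each original bipartition by the percentage of replicates containing it.
Newick serialisation stores supports as internal labels; rooting on a
declared outgroup places it sister to the remaining taxa.

Three missing-data conventions coexist deliberately: mean imputation for
PCA (keeps the matrix dense), pairwise deletion for distances (unbiased
per pair), exclusion for EM (exact likelihood).

## qPCR quantification

Per replicate ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the mean
calibrator ΔCt (Livak convention); RQ = 2^−ΔΔCt, summarised as the mean
of per-replicate RQs. Significance per condition is a Welch
unequal-variance t test of replicate ΔCt values against the calibrator's:
ΔCt is the approximately normal scale, RQ is not. No correction across
the (few) condition comparisons. The whole computation is invariant to
any additive shift applied to all Ct values. DE thresholding is strict on
both bounds (|log2FC| > 2 and FDR < .05), so values exactly at a bound
are not flagged.

## Synthetic data

The generators produce the statistical signatures the pipeline consumes
and nothing more — no demographic history, recombination, linkage or
mutation-model realism is attempted.

* **Balding–Nichols cohorts**: per site an ancestral frequency uniform on
  (0.05, 0.95) (so most sites pass the MAF filter), per population a
  Beta(p(1−F)/F, (1−p)(1−F)/F) frequency (F → 0 handled exactly as the
  limit), haplotype alleles independent Bernoulli draws. Sites are
  independent and evenly spaced (default 200 bp), so genome-wide
  Weir–Cockerham F_ST converges to the generating F — the calibration is
  checked at 50k sites to within 0.01. INFO annotations are drawn from
  "passing" distributions independent of the genotypes, with a
  configurable fraction violating exactly one hard-filter clause.
* **Planted sweeps**: a chosen fraction of one population's haplotypes is
  replaced inside the region by one core haplotype, then per-allele noise
  is applied. Copying (rather than forward simulation) gives exact
  control of frequency and haplotype length and runs in milliseconds. All
  modification is confined to the swept population × region.
* **Tree-structured cohorts**: frequencies drift along a rooted Newick
  tree by Normal(0, s²·branch-length) steps truncated to (0.01, 0.99), so
  expected p-distance grows with path length; used for tree-recovery and
  bootstrap tests (exact NJ consistency is tested separately on additive
  matrices).
* **Annotations**: single-exon gene/mRNA/exon/CDS features, validated
  against contig bounds and mutual overlap.
* **qPCR tables**: target Ct = baseline − true log2 shift + noise,
  reference Ct = constant + noise; defaults emulate a cold-exposure
  design (0/4/10 °C vs a 25 °C calibrator, three replicates, shifts
  2/1/0.5/0, Ct noise SD 0.1).

All generators are deterministic given their seed; VCF output is
byte-identical across reruns.

Because sites are unlinked, the neutral EHH decay is much faster than in
real genomes and the planted sweep is correspondingly easier to separate;
passing the recovery tests demonstrates that the statistics respond to
the signatures they target, not that power on real data matches.

## Study sizes used in validation

The end-to-end sweep study is a 2-Mb contig with 4,000 SNPs every 500 bp,
two populations of 30 diploids at background F = 0.05, a 50-kb sweep at
frequency 0.9 with 1e−3 copy noise, and 40 genes of 10 kb (one centred on
the sweep, per the generator's contract that the annotation contain a
gene inside the region). Recovery is scored over 20 replicate seeds.
Calibration uses 100 diploids per population at 50k sites; ancestry
recovery uses K = 2, F = 0.2, 20 diploids per population at 1k sites;
PCA separation uses three populations at F = 0.15, 30 diploids each, 5k
sites; bootstrap support uses 200 replicates on a two-population F = 0.3
cohort. These sizes were chosen as the smallest at which the asymptotic
properties under test are comfortably expressed.

## Known limitations

* Haplotype statistics require phased input and refuse genotypes; no
  internal phasing.
* The constant-rate genetic map is per-run global; no map files,
  chromosome-specific rates or variable recombination.
* No Tajima's D, dXY, iHS/nSL, or allele-frequency-binned XP-EHH
  normalisation.
* The enrichment background is exactly the gene→pathway table supplied;
  no species-specific background construction.
* The Tracy–Widom report flags significance only at the 5% and 1%
  levels.
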
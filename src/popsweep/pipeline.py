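"""End-to-end orchestration of the selection scan on a two-population cohort.

Glues the stages together the way a study would run them: windowed
diversity per population, the reference/focal theta-pi ratio, windowed
FST, XP-EHH from the phased haplotypes, and the three-signal consensus
gene call.  Works directly on an in-memory :class:`SimulatedCohort` or on
anything providing the same arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diversity import (SCHEME_100KB_20KB, WindowScheme, pi_ratio,
                        wc_fst_components, windowed_fst_from_arrays,
                        windowed_pi_from_arrays, per_pop_site_stats)
from .haplotypes import GeneticMap, Haplotypes, XpehhResult, xpehh
from .simulate import SimulatedCohort, SweepStudy
from .sweep import OutlierSpec, consensus_scan
from .variant_io import GenomeAnnotation


def cohort_pi_track(cohort: SimulatedCohort, pop: str,
                    scheme: WindowScheme) -> pd.DataFrame:
    """Windowed theta-pi for one population of a cohort."""
    cols = cohort.popmap.indices_of(pop, cohort.samples)
    sub = cohort.dosage[cols].astype(float)
    called = sub >= 0
    n_alt = np.where(called, sub, 0.0).sum(axis=0)
    n_ref = 2.0 * called.sum(axis=0) - n_alt
    return windowed_pi_from_arrays(cohort.positions, n_ref, n_alt, scheme,
                                   cohort.contig_length, cohort.chrom)


def cohort_fst_track(cohort: SimulatedCohort, pops: tuple[str, str],
                     scheme: WindowScheme) -> pd.DataFrame:
    """Windowed Weir-Cockerham FST between two populations of a cohort."""
    pm = cohort.popmap
    idx = [pm.indices_of(p, cohort.samples) for p in pops]
    n, p, h = per_pop_site_stats(cohort.dosage.astype(np.int8), idx)
    a, b, c = wc_fst_components(n, p, h)
    return windowed_fst_from_arrays(cohort.positions, a, b, c, scheme,
                                    cohort.contig_length, cohort.chrom)


def cohort_haplotypes(cohort: SimulatedCohort, pop: str) -> Haplotypes:
    rows = cohort.hap_pop_labels() == pop
    return Haplotypes(cohort.haplotypes[rows], cohort.positions, cohort.chrom)


def cohort_xpehh(cohort: SimulatedCohort, focal: str, ref: str,
                 gmap: GeneticMap | None = None) -> XpehhResult:
    """XP-EHH with the focal population as A (sweeps there score positive)."""
    return xpehh(cohort_haplotypes(cohort, focal),
                 cohort_haplotypes(cohort, ref), gmap)


def run_selection_scan(
    cohort: SimulatedCohort,
    annotation: GenomeAnnotation,
    focal: str,
    ref: str,
    outlier_spec: OutlierSpec | None = None,
    gmap: GeneticMap | None = None,
) -> dict:
    """Full scan: tracks, XP-EHH and the consensus candidate genes.

    The theta-pi ratio is oriented ref/focal so a sweep in the focal
    population lands in the right tail.  Returns the consensus_scan dict
    augmented with the raw tracks under 'pi_focal', 'pi_ref', 'pi_ratio',
    'fst' and 'xpehh'.
    """
    spec = outlier_spec or OutlierSpec()
    pi_f = cohort_pi_track(cohort, focal, spec.scheme)
    pi_r = cohort_pi_track(cohort, ref, spec.scheme)
    ratio = pi_ratio(pi_r, pi_f)
    fst = cohort_fst_track(cohort, (focal, ref), spec.scheme)
    xp = cohort_xpehh(cohort, focal, ref, gmap)
    out = consensus_scan(ratio, fst, xp.table, annotation, spec)
    out.update({"pi_focal": pi_f, "pi_ref": pi_r, "pi_ratio": ratio,
                "fst": fst, "xpehh": xp})
    return out


def run_sweep_study(study: SweepStudy, gff_path,
                    outlier_spec: OutlierSpec | None = None) -> dict:
    """Run the scan on a simulated study and score it against ground truth.

    Adds 'recovered' (sweep gene called), 'false_genes' (candidates not
    overlapping the true region) to the scan result.
    """
    study.write_gff(gff_path)
    from .variant_io import read_gff

    ann = read_gff(gff_path)
    res = run_selection_scan(study.cohort, ann, study.focal_pop, study.ref_pop,
                             outlier_spec)
    called = set(res["candidates"]["gene_id"])
    res["recovered"] = study.sweep_gene in called
    res["false_genes"] = called - study.true_genes
    return res
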
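import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import popsweep as ps


@pytest.fixture(scope="session")
def small_cohort() -> ps.SimulatedCohort:
    """Two small populations, mild differentiation, some failing INFO rows."""
    spec = ps.BaldingNicholsSpec(
        n_pops=2, F_per_pop=(0.1, 0.1), n_diploids_per_pop=10, n_sites=200,
        seed=11, failing_info_fraction=0.1)
    return ps.simulate_balding_nichols(spec)


@pytest.fixture(scope="session")
def oracle_haps() -> tuple[np.ndarray, np.ndarray]:
    """20 haplotypes x 500 sites of 0/1 alleles with sorted positions."""
    rng = np.random.default_rng(42)
    haps = (rng.random((20, 500)) < rng.uniform(0.1, 0.9, 500)[None, :]).astype(np.int8)
    positions = np.sort(rng.choice(np.arange(1, 100_001), size=500, replace=False))
    return haps, positions


@pytest.fixture(scope="session")
def toy_annotation(tmp_path_factory) -> ps.GenomeAnnotation:
    """One 1-Mb contig: a gene with an internal CDS and a CDS-less gene."""
    path = tmp_path_factory.mktemp("gff") / "toy.gff3"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("##sequence-region chr1 1 1000000\n")
        fh.write("chr1\ttest\tgene\t10001\t12000\t.\t+\t.\tID=geneA\n")
        fh.write("chr1\ttest\tmRNA\t10001\t12000\t.\t+\t.\tID=geneA.t1;Parent=geneA\n")
        fh.write("chr1\ttest\tCDS\t10401\t10600\t.\t+\t0\tID=geneA.c1;Parent=geneA.t1\n")
        fh.write("chr1\ttest\tgene\t50001\t52000\t.\t+\t.\tID=geneB\n")
    return ps.read_gff(path)
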
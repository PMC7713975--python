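"""Generator contracts: determinism, calibration, locality, ground truth."""

import numpy as np
import pytest

import popsweep as ps

import oracles


class TestBaldingNichols:
    def test_f_zero_limit_equals_ancestral_frequency(self):
        rng = np.random.default_rng(0)
        p_anc = rng.uniform(0.1, 0.9, 100)
        np.testing.assert_array_equal(
            ps.balding_nichols_freqs(rng, p_anc, 0.0), p_anc)

    def test_seed_fixed_vcf_byte_identical(self, tmp_path):
        spec = ps.BaldingNicholsSpec(n_pops=2, F_per_pop=(0.1, 0.2),
                                     n_diploids_per_pop=5, n_sites=50, seed=7,
                                     failing_info_fraction=0.1)
        for name in ("a.vcf", "b.vcf"):
            ps.simulate_balding_nichols(spec).write(tmp_path / name)
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_genomewide_fst_calibrates_to_generator_f(self):
        """WC FST on Balding-Nichols data estimates the generating F.

        Checked at a reduced size here (2 pops, F=0.10, 50 diploids,
        10k sites, one seed); the full-scale calibration runs in the
        acceptance suite.
        """
        spec = ps.BaldingNicholsSpec(n_pops=2, F_per_pop=(0.10, 0.10),
                                     n_diploids_per_pop=50, n_sites=10_000, seed=3)
        cohort = ps.simulate_balding_nichols(spec)
        pm = cohort.popmap
        idx = [pm.indices_of(p, cohort.samples) for p in pm.populations]
        n, p, h = ps.per_pop_site_stats(cohort.dosage.astype(np.int8), idx)
        a, b, c = ps.wc_fst_components(n, p, h)
        assert ps.fst_ratio_of_sums(a, b, c) == pytest.approx(0.10, abs=0.015)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ps.BaldingNicholsSpec(n_pops=2, F_per_pop=(0.1,), n_diploids_per_pop=5,
                                  n_sites=10)
        with pytest.raises(ValueError):
            ps.BaldingNicholsSpec(n_pops=1, F_per_pop=(1.5,), n_diploids_per_pop=5,
                                  n_sites=10)
        with pytest.raises(ValueError):
            ps.BaldingNicholsSpec(n_pops=1, F_per_pop=(0.1,), n_diploids_per_pop=5,
                                  n_sites=10, ancestral_freq_range=(0.9, 0.1))


class TestPlantSweep:
    @pytest.fixture()
    def cohort(self):
        return ps.simulate_balding_nichols(ps.BaldingNicholsSpec(
            n_pops=2, F_per_pop=(0.05, 0.05), n_diploids_per_pop=10,
            n_sites=200, seed=13, pop_labels=("focal", "ref")))

    def test_full_frequency_no_noise_erases_diversity(self, cohort):
        region = ("1", 5_000, 15_000)
        swept = ps.plant_sweep(cohort, ps.SweepSpec("focal", region, 1.0, 0.0, seed=1))
        in_region = (cohort.positions >= 5_000) & (cohort.positions <= 15_000)
        rows = swept.hap_pop_labels() == "focal"
        block = swept.haplotypes[np.ix_(rows, in_region)]
        assert (block == block[0]).all()

    def test_other_populations_untouched(self, cohort):
        swept = ps.plant_sweep(cohort, ps.SweepSpec(
            "focal", ("1", 5_000, 15_000), 0.8, 0.01, seed=2))
        rows = cohort.hap_pop_labels() == "ref"
        np.testing.assert_array_equal(swept.haplotypes[rows],
                                      cohort.haplotypes[rows])

    def test_modifications_confined_to_region(self, cohort):
        swept = ps.plant_sweep(cohort, ps.SweepSpec(
            "focal", ("1", 5_000, 15_000), 0.8, 0.01, seed=2))
        outside = (cohort.positions < 5_000) | (cohort.positions > 15_000)
        np.testing.assert_array_equal(swept.haplotypes[:, outside],
                                      cohort.haplotypes[:, outside])

    def test_empty_region_rejected(self, cohort):
        # positions are multiples of 200; [5, 30] contains none
        with pytest.raises(ValueError, match="empty sweep region"):
            ps.plant_sweep(cohort, ps.SweepSpec("focal", ("1", 5, 30), 1.0, 0.0))

    def test_ground_truth_recorded(self, cohort, tmp_path):
        swept = ps.plant_sweep(cohort, ps.SweepSpec(
            "focal", ("1", 5_000, 15_000), 0.9, 0.001, seed=4))
        t = swept.truth["sweep"]
        assert t["pop"] == "focal" and t["start"] == 5_000
        n_focal_haps = (cohort.hap_pop_labels() == "focal").sum()
        assert len(t["carrier_rows"]) == round(0.9 * n_focal_haps)
        ps.write_sweep_truth(swept, tmp_path / "truth.tsv")
        assert (tmp_path / "truth.tsv").read_text().count("\n") == 2


class TestTreeStructured:
    def test_star_tree_zero_lengths_gives_exchangeable_tips(self):
        cohort = ps.gen_tree_structured("(a:0,b:0,c:0,d:0);", n_per_tip=5,
                                        n_sites=100, seed=1)
        # all tip populations share the identical frequency vector, so
        # expected between-tip p-distances are all equal; verify frequencies
        assert set(cohort.sample_pops) == {"a", "b", "c", "d"}

    def test_nj_recovers_topology_from_exact_expected_distances(self):
        """NJ is consistent on additive distances: the balanced 8-tip tree
        is recovered exactly from its own path-length matrix."""
        newick = ("(((a:1,b:1):1,(c:1,d:1):1):1,"
                  "((e:1,f:1):1,(g:1,h:1):1):1);")
        from popsweep.structure import tree_from_newick_string, tree_bipartitions
        true_tree = tree_from_newick_string(newick)
        tips = [t.name for t in true_tree.tips()]
        D = np.zeros((8, 8))
        for i, a in enumerate(tips):
            for j, b in enumerate(tips):
                if i < j:
                    D[i, j] = D[j, i] = true_tree.find(a).distance(true_tree.find(b))
        from skbio import DistanceMatrix
        nj = ps.nj_tree(DistanceMatrix(D, tips))
        assert tree_bipartitions(nj) == tree_bipartitions(true_tree)

    def test_fixed_seed_reproducible(self):
        a = ps.gen_tree_structured("((a:1,b:1):1,(c:1,d:1):1);", 4, 50, seed=9)
        b = ps.gen_tree_structured("((a:1,b:1):1,(c:1,d:1):1);", 4, 50, seed=9)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_p_distance_grows_with_path_length(self):
        cohort = ps.gen_tree_structured(
            "((a:2,b:2):2,(c:2,d:2):2);", n_per_tip=10, n_sites=2_000,
            seed=5, drift_scale=0.25)
        D = ps.p_distance_matrix(cohort.dosage, cohort.samples)
        pm = cohort.popmap
        def mean_between(x, y):
            ix = pm.indices_of(x, cohort.samples)
            iy = pm.indices_of(y, cohort.samples)
            return np.mean([D[cohort.samples[i], cohort.samples[j]]
                            for i in ix for j in iy])
        assert mean_between("a", "c") > mean_between("a", "b")


class TestAnnotations:
    def test_round_trip_coordinates(self, tmp_path):
        path = ps.gen_annotations({"chr1": 1_000_000},
                                  [("g1", "chr1", 10_001, 12_000)],
                                  tmp_path / "a.gff3")
        ann = ps.read_gff(path)
        row = ann.genes.iloc[0]
        assert (row["gene_id"], row["start"], row["end"]) == ("g1", 10_001, 12_000)

    def test_malformed_and_overlapping_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            ps.gen_annotations({"chr1": 100}, [("g1", "chr1", 50, 200)],
                               tmp_path / "b.gff3")
        with pytest.raises(ValueError, match="overlap"):
            ps.gen_annotations({"chr1": 10_000},
                               [("g1", "chr1", 100, 500), ("g2", "chr1", 400, 900)],
                               tmp_path / "c.gff3")


class TestQpcr:
    def test_noise_free_shift_one_gives_rq_two(self):
        spec = ps.QpcrSpec(ct_noise_sd=0.0,
                           true_log2_shift_per_condition={"0C": 1.0, "4C": 0.0,
                                                          "10C": 0.0, "25C": 0.0})
        summary, _ = ps.ddct(ps.gen_qpcr(spec), "25C")
        s = summary.set_index("condition")
        assert s.loc["0C", "rq"] == pytest.approx(2.0)
        assert s.loc["4C", "rq"] == pytest.approx(1.0)

    def test_rq_recovery_under_noise(self):
        """shift=2, sd=0.1, n=3: RQ lands in [3, 5] with p<.05 in >=95% of seeds."""
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            spec = ps.QpcrSpec(ct_noise_sd=0.1, seed=seed,
                               true_log2_shift_per_condition={
                                   "0C": 2.0, "4C": 0.0, "10C": 0.0, "25C": 0.0})
            summary, _ = ps.ddct(ps.gen_qpcr(spec), "25C")
            s = summary.set_index("condition")
            if 3.0 <= s.loc["0C", "rq"] <= 5.0 and s.loc["0C", "pvalue"] < 0.05:
                ok += 1
        assert ok >= 0.95 * n_seeds

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="calibrator"):
            ps.QpcrSpec(calibrator="37C")
        with pytest.raises(ValueError):
            ps.QpcrSpec(replicates_per_condition=1)


class TestSweepStudy:
    def test_annotation_contains_gene_inside_region(self, tmp_path):
        study = ps.simulate_sweep_study(seed=1)
        _, start, end = study.sweep_spec.region
        gene = next(g for g in study.genes if g[0] == study.sweep_gene)
        assert start <= gene[2] and gene[3] <= end
        assert study.sweep_gene in study.true_genes

    def test_top_xpehh_concentrates_in_sweep_region(self):
        study = ps.simulate_sweep_study(seed=2)
        res = ps.cohort_xpehh(study.cohort, "focal", "ref")
        top = ps.top_fraction(res, q=0.01)
        _, start, end = study.sweep_spec.region
        frac_inside = top["pos"].between(start, end).mean()
        assert frac_inside >= 0.9
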
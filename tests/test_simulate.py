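import numpy as np
import pytest
from scipy import stats

from introhmm import markers as mk, simulate as sim
from introhmm.tracts import Tract
from introhmm import hmm


def small_config(**kw):
    defaults = dict(chromosomes={"chr2L": 1_000_000},
                    fixed_diff_density=1 / 130,
                    polymorphism_density=1 / 1300)
    defaults.update(kw)
    return sim.SimConfig(**defaults)


class TestSpeciesPair:
    def test_fixed_difference_density(self):
        cfg = small_config()
        table = sim.simulate_species_pair(cfg, seed=0)
        fixed = ((table.gt[:, table.indices_of("donor")] == 2).all(axis=1)
                 & (table.gt[:, table.indices_of("recipient")] == 0)
                 .all(axis=1))
        expected = 1_000_000 / 130
        sd = np.sqrt(1_000_000 * (1 / 130) * (1 - 1 / 130))
        assert abs(fixed.sum() - expected) < 3 * sd + \
            table.n_sites * 0.01  # few poly sites can mimic fixed diffs

    def test_zero_density_no_sites(self):
        cfg = small_config(fixed_diff_density=0.0,
                           polymorphism_density=0.0)
        table = sim.simulate_species_pair(cfg, seed=0)
        assert table.n_sites == 0

    def test_deterministic_under_seed(self):
        cfg = small_config(chromosomes={"chr2L": 100_000})
        t1 = sim.simulate_species_pair(cfg, seed=7)
        t2 = sim.simulate_species_pair(cfg, seed=7)
        assert np.array_equal(t1.pos, t2.pos)
        assert np.array_equal(t1.gt, t2.gt)
        assert np.array_equal(t1.ad_alt, t2.ad_alt)

    def test_too_few_individuals_raise(self):
        with pytest.raises(ValueError):
            sim.simulate_species_pair(small_config(), n_donor=1)


class TestAdmixedIndividual:
    def test_homozygous_fixed_difference_sites_saturate(self):
        cfg = small_config(chromosomes={"chr2L": 500_000}, p_ab=0.0,
                           het_probability=0.0, polymorphism_density=0.0)
        table = sim.simulate_species_pair(cfg, seed=1)
        k, n, truth = sim.simulate_admixed_individual(table, cfg, seed=2)
        inside = np.zeros(table.n_sites, dtype=bool)
        for chrom, s, e, zyg in truth.intervals:
            assert zyg == "homo"
            inside |= (table.chrom == chrom) & (table.pos >= s) & \
                (table.pos <= e)
        assert np.array_equal(k[inside], n[inside])
        assert (k[~inside] == 0).all()

    def test_heterozygous_sites_binomial_half(self):
        cfg = small_config(chromosomes={"chr2L": 2_000_000}, p_ab=0.0,
                           het_probability=1.0, polymorphism_density=0.0,
                           introgression_sizes=(50_000,),
                           spacing=(25_000, 75_000))
        table = sim.simulate_species_pair(cfg, seed=3)
        k, n, truth = sim.simulate_admixed_individual(table, cfg, seed=4)
        inside = np.zeros(table.n_sites, dtype=bool)
        for chrom, s, e, _ in truth.intervals:
            inside |= (table.chrom == chrom) & (table.pos >= s) & \
                (table.pos <= e)
        ratios = k[inside] / n[inside]
        m = inside.sum()
        assert m > 1_000
        se = np.sqrt(0.25 / n[inside]).mean() / np.sqrt(m)
        assert abs(ratios.mean() - 0.5) < 3 * se

    def test_coverage_uniform_10_25(self):
        cfg = small_config(chromosomes={"chr2L": 10_000_000},
                           fixed_diff_density=1 / 100,
                           polymorphism_density=0.0)
        table = sim.simulate_species_pair(cfg, seed=5)
        k, n, _ = sim.simulate_admixed_individual(table, cfg, seed=6)
        assert n.min() >= 10 and n.max() <= 25
        counts = np.bincount(n)[10:26]
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.001

    def test_oversized_introgression_raises(self):
        cfg = small_config(chromosomes={"chr2L": 50_000},
                           introgression_sizes=(100_000,))
        table = sim.simulate_species_pair(cfg, seed=1)
        with pytest.raises(ValueError, match="exceeds"):
            sim.simulate_admixed_individual(table, cfg, seed=1)

    def test_truth_intervals_ordered_nonoverlapping(self):
        cfg = small_config(chromosomes={"chrA": 800_000,
                                        "chrB": 800_000})
        table = sim.simulate_species_pair(cfg, seed=8)
        _, _, truth = sim.simulate_admixed_individual(table, cfg, seed=9)
        by_chrom = {}
        for chrom, s, e, _ in truth.intervals:
            assert s > by_chrom.get(chrom, 0)
            by_chrom[chrom] = e


class TestEvaluateCalls:
    def truth(self):
        return sim.TruthSet([("c", 1000, 5000, "homo")])

    def test_perfect_calls(self):
        called = [Tract("c", 1000, 5000, hmm.HOMO_D, 30, 30)]
        ev = sim.evaluate_calls(called, self.truth(), 100_000)
        assert ev.false_negative_rate == 0.0
        assert ev.false_positive_count == 0
        assert ev.false_positive_length == 0

    def test_no_calls(self):
        ev = sim.evaluate_calls([], self.truth(), 100_000)
        assert ev.false_negative_rate == 1.0
        for v in ev.per_size_class.values():
            assert v["fn"] == 1.0

    def test_partial_overlap_conventions(self):
        called = [Tract("c", 4000, 6000, hmm.HOMO_D, 20, 20)]
        ev = sim.evaluate_calls(called, self.truth(), 100_000)
        assert ev.per_size_class[4001]["detected"] == 1
        assert ev.false_positive_count == 0          # any-overlap rule
        assert ev.false_positive_length == 0
        assert ev.false_positive_outside_truth == 1000  # bp outside truth

    def test_min_reciprocal_overlap(self):
        called = [Tract("c", 4990, 6000, hmm.HOMO_D, 20, 20)]
        ev = sim.evaluate_calls(called, self.truth(), 100_000,
                                min_reciprocal_overlap=0.5)
        assert ev.per_size_class[4001]["detected"] == 0

    def test_false_positive_accounting(self):
        called = [Tract("c", 50_000, 51_000, hmm.HET, 15, 15)]
        ev = sim.evaluate_calls(called, self.truth(), 100_000)
        assert ev.false_positive_count == 1
        assert ev.false_positive_length == 1001
        assert ev.non_introgressed_length == 100_000 - 4001


class TestEndToEndDetection:
    """Scaled-down detection properties of the full caller."""

    @staticmethod
    def run(density, zygosity, sizes, seed, length=2_000_000):
        from introhmm import pipeline

        cfg = sim.SimConfig(
            chromosomes={"chr2L": length},
            fixed_diff_density=density,
            polymorphism_density=density / 10,
            introgression_sizes=sizes,
            het_probability={"het": 1.0, "homo": 0.0}[zygosity],
        )
        return pipeline.simulation_benchmark(cfg, n_individuals=1,
                                             seed=seed)

    def test_fn_nonincreasing_in_size_and_density(self):
        sizes = (500, 2_000, 20_000)
        for density in (1 / 130, 1 / 55):
            res = self.run(density, "het", sizes, seed=11)
            fns = [res.evaluation.per_size_class[s]["fn"] for s in sizes]
            assert fns[0] >= fns[-1]
            assert fns[1] >= fns[2] - 0.05
        lo = self.run(1 / 130, "het", (2_000,), seed=12)
        hi = self.run(1 / 55, "het", (2_000,), seed=12)
        assert hi.evaluation.false_negative_rate <= \
            lo.evaluation.false_negative_rate + 0.05

    def test_homozygous_at_least_as_detectable_as_het(self):
        sizes = (1_000, 2_000)
        hom = self.run(1 / 130, "homo", sizes, seed=13)
        het = self.run(1 / 130, "het", sizes, seed=13)
        assert hom.evaluation.false_negative_rate <= \
            het.evaluation.false_negative_rate + 0.05

    def test_noiseless_recovery_with_tight_boundaries(self):
        # every homozygous introgression >= 10 kb recovered with
        # boundaries within one inter-marker gap of the truth
        cfg = sim.SimConfig(
            chromosomes={"chr2L": 2_000_000},
            fixed_diff_density=1 / 100,
            polymorphism_density=0.0,
            introgression_sizes=(10_000, 20_000),
            het_probability=0.0,
            p_ab=0.0,
        )
        table = sim.simulate_species_pair(cfg, seed=21)
        m = mk.select_markers(table, "donor", "recipient")
        k_alt, n, truth = sim.simulate_admixed_individual(table, cfg,
                                                          seed=22)
        from introhmm.pipeline import marker_observations_for_simulated
        from introhmm import tracts as tr

        kd, nm = marker_observations_for_simulated(m, k_alt, n)
        post = hmm.decode_observations(
            "chr2L", m.pos, kd, nm, hmm.HMMParams(p_ab=0.0))
        called = tr.reporting_filter(
            tr.filter_tracts(tr.build_raw_tracts(post)), repeats={})
        gaps = np.diff(m.pos)
        max_gap = gaps.max()
        for chrom, s, e, _ in truth.intervals:
            hits = [t for t in called
                    if t.start <= e and t.end >= s]
            assert hits, f"missed truth interval {s}-{e}"
            t = hits[0]
            assert abs(t.start - s) <= max_gap + 1
            assert abs(t.end - e) <= max_gap + 1
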
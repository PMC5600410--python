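"""End-to-end wiring: markers -> HMM decoding -> tract filtering -> regions,
plus the simulation benchmark used to validate the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import hmm, markers as mk, simulate as sim, tracts as tr


@dataclass
class RunConfig:
    """Configuration of a full VCF-to-tracts run."""

    vcf: str
    population_map: str
    donor: str = "donor"
    recipient: str = "recipient"
    params: hmm.HMMParams = field(default_factory=hmm.HMMParams)
    min_cov: int = 5
    upper_quantile: float = 0.99
    min_freq_diff: float = 0.3
    max_het_fraction: float = 0.8
    excluded_donor_individuals: frozenset[str] = frozenset()
    repeats_bed: str | None = None
    min_len: int = 500
    min_snps: int = 10
    max_repeat_frac: float = 0.3
    output_dir: str = "."
    denominator: str = "chromosome"   # or "marker-span"


def call_individual(markers_table: mk.MarkerTable, individual: str,
                    params: hmm.HMMParams | None = None,
                    repeats=None, min_len: int = 500, min_snps: int = 10,
                    max_repeat_frac: float = 0.3) -> list[tr.Tract]:
    """Decode one recipient individual and return reported introgressions."""
    params = params or hmm.HMMParams()
    out: list[tr.Tract] = []
    for post in hmm.posterior_decode(markers_table, individual, params):
        raw = tr.build_raw_tracts(post, line=individual)
        filt = tr.filter_tracts(raw)
        out.extend(tr.reporting_filter(
            filt, repeats=repeats, min_len=min_len, min_snps=min_snps,
            max_repeat_frac=max_repeat_frac))
    return out


def run_pipeline(config: RunConfig):
    """VCF -> per-line reported tracts + per-line percent-genome summary.

    Returns (per_line_tracts, summary DataFrame, regions).  The summary
    denominator is the total length of the chromosomes analysed (or the
    marker-spanned length with ``denominator='marker-span'``).
    """
    import pandas as pd

    pops = mk.read_population_map(config.population_map)
    table = mk.read_genotype_table(config.vcf, pops)
    table = mk.coverage_filter(table, config.min_cov, config.upper_quantile)
    markers_table = mk.select_markers(
        table, config.donor, config.recipient,
        min_freq_diff=config.min_freq_diff,
        max_het_fraction=config.max_het_fraction,
        excluded_donor_individuals=config.excluded_donor_individuals,
    )
    repeats = (tr.read_repeats_bed(config.repeats_bed)
               if config.repeats_bed else None)

    if config.denominator == "marker-span":
        denom = sum(
            int(markers_table.pos[markers_table.chrom == c].max()
                - markers_table.pos[markers_table.chrom == c].min() + 1)
            for c in markers_table.chromosomes())
    else:
        denom = sum(int(table.pos[table.chrom == c].max())
                    for c in dict.fromkeys(table.chrom))

    per_line: dict[str, list[tr.Tract]] = {}
    rows = []
    for individual in markers_table.recipient_samples:
        called = call_individual(
            markers_table, individual, config.params, repeats,
            config.min_len, config.min_snps, config.max_repeat_frac)
        per_line[individual] = called
        introgressed = sum(t.length for t in called)
        rows.append({
            "line": individual,
            "n_tracts": len(called),
            "introgressed_bp": introgressed,
            "percent_genome": 100.0 * introgressed / denom,
        })
    regions = tr.merge_regions(per_line, n_lines=len(per_line))
    return per_line, pd.DataFrame(rows), regions


def marker_observations_for_simulated(
    markers_table: mk.MarkerTable, k_alt: np.ndarray, n: np.ndarray):
    """Orient simulated per-site alt-read counts to the donor allele at
    marker sites."""
    idx = markers_table.site_index
    k_alt_m = k_alt[idx]
    n_m = n[idx]
    k_donor = np.where(markers_table.donor_is_alt, k_alt_m, n_m - k_alt_m)
    return k_donor.astype(np.int32), n_m.astype(np.int32)


@dataclass
class BenchmarkResult:
    """Aggregated detection scores over simulated admixed individuals."""

    evaluation: sim.EvaluationResult
    n_individuals: int
    n_markers: int
    marker_spacing_bp: float

    @property
    def fn_percent(self) -> float:
        return 100.0 * self.evaluation.false_negative_rate

    def fn_percent_for(self, min_size: int) -> float:
        return 100.0 * self.evaluation.false_negative_rate_for(min_size)

    @property
    def fp_percent(self) -> float:
        return 100.0 * self.evaluation.false_positive_genome_fraction


def simulation_benchmark(
    config: sim.SimConfig,
    n_individuals: int = 3,
    n_donor: int = 10,
    n_recipient: int = 10,
    params: hmm.HMMParams | None = None,
    seed: int = 0,
    min_len: int = 500,
    min_snps: int = 10,
) -> BenchmarkResult:
    """Simulate, decode and score admixed individuals under one regime.

    One synthetic species pair is generated; each admixed individual gets
    its own introgression truth set.  Individuals share the marker grid, so
    decoding is batched per chromosome.  Scores are pooled across
    individuals (per-size-class detection counts, false-positive lengths).
    """
    params = params or hmm.HMMParams(p_ab=config.p_ab)
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_individuals + 1)
    table = sim.simulate_species_pair(
        config, n_donor, n_recipient,
        seed=np.random.default_rng(child[0]))
    markers_table = mk.select_markers(table, "donor", "recipient")

    genome_length = sum(config.chromosomes.values())
    obs = []
    truths = []
    for i in range(n_individuals):
        k_alt, n, truth = sim.simulate_admixed_individual(
            table, config, seed=np.random.default_rng(child[i + 1]))
        k_donor, n_m = marker_observations_for_simulated(
            markers_table, k_alt, n)
        obs.append((k_donor, n_m))
        truths.append(truth)

    called_per_ind: list[list[tr.Tract]] = [[] for _ in range(n_individuals)]
    for chrom in markers_table.chromosomes():
        sel = markers_table.chrom == chrom
        pos = markers_table.pos[sel]
        kb = np.vstack([k[sel] for k, _ in obs])
        nb = np.vstack([n[sel] for _, n in obs])
        posts = hmm.decode_batch(chrom, pos, kb, nb, params)
        for i, post in enumerate(posts):
            raw = tr.build_raw_tracts(post, line=f"sim_{i}")
            filt = tr.filter_tracts(raw)
            # simulated genomes carry no repeats: empty annotation
            called_per_ind[i].extend(tr.reporting_filter(
                filt, repeats={}, min_len=min_len, min_snps=min_snps))

    # pool per-individual evaluations
    per_class: dict[int, dict[str, float]] = {}
    fp_count = fp_len = fp_outside = 0
    non_intro = 0
    for called, truth in zip(called_per_ind, truths):
        ev = sim.evaluate_calls(called, truth, genome_length)
        for size, v in ev.per_size_class.items():
            agg = per_class.setdefault(size, {"n": 0, "detected": 0,
                                              "fn": 0.0})
            agg["n"] += v["n"]
            agg["detected"] += v["detected"]
        fp_count += ev.false_positive_count
        fp_len += ev.false_positive_length
        fp_outside += ev.false_positive_outside_truth
        non_intro += ev.non_introgressed_length
    for v in per_class.values():
        v["fn"] = 1.0 - v["detected"] / v["n"]

    pooled = sim.EvaluationResult(
        per_size_class=dict(sorted(per_class.items())),
        false_positive_count=fp_count,
        false_positive_length=fp_len,
        false_positive_outside_truth=fp_outside,
        genome_length=genome_length * n_individuals,
        non_introgressed_length=non_intro,
    )
    spacing = float(np.mean([
        np.diff(markers_table.pos[markers_table.chrom == c]).mean()
        for c in markers_table.chromosomes()
    ]))
    return BenchmarkResult(
        evaluation=pooled,
        n_individuals=n_individuals,
        n_markers=markers_table.n_sites,
        marker_spacing_bp=spacing,
    )


def benchmark_config(
    regime: str = "yak/san-like",
    zygosity: str = "mixed",
    sizes: tuple[int, ...] = (4_000, 10_000, 50_000, 100_000),
    n_chromosomes: int = 3,
    chrom_length: int = 10_000_000,
    p_ab: float = 0.005,
) -> sim.SimConfig:
    """Study-condition presets for the validation benchmark.

    ``regime`` selects the marker-density preset; ``zygosity`` is 'het',
    'homo' or 'mixed' (50/50).
    """
    het_p = {"het": 1.0, "homo": 0.0, "mixed": 0.5}[zygosity]
    return sim.SimConfig(
        chromosomes={f"chr{i + 1}": chrom_length
                     for i in range(n_chromosomes)},
        fixed_diff_density=sim.DENSITY_PRESETS[regime],
        polymorphism_density=sim.DENSITY_PRESETS[regime] / 10.0,
        introgression_sizes=tuple(sizes),
        het_probability=het_p,
        p_ab=p_ab,
    )
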
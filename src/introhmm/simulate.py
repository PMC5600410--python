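"""Synthetic two-species genotype data with known introgression truth sets.

The generator emulates the published validation protocol: a donor and a
recipient population separated by a tunable density of fixed differences
(plus polymorphic noise sites), admixed recipient individuals carrying
known heterozygous/homozygous introgression tracts with sizes drawn from a
configurable list and inter-tract spacing uniform on 25-75 kb, per-site
coverage uniform on {10..25}, binomial allele sampling at heterozygous
sites and independent per-read sequencing error.

Two marker-density presets mirror the real data: ``yak/san-like``
(~1 informative marker / 130 bp) and ``yak/tei-like`` (~1 / 55 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .markers import (GT_HET, GT_HOM_ALT, GT_HOM_REF, GenotypeTable)
from .tracts import Tract

_NUC = np.array(list("ACGT"), dtype=object)


@dataclass
class SimConfig:
    """Study conditions for the validation simulator.

    Defaults follow the published protocol where it states them
    (introgression sizes up to 100 kb, spacing U(25, 75) kb, 50% het/hom,
    coverage U{10..25}, binomial allele split) and field-realistic choices
    elsewhere (polymorphism density an order of magnitude below the
    fixed-difference density; polymorphic allele frequencies uniform on
    [0.1, 0.9]).
    """

    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr2L": 10_000_000})
    fixed_diff_density: float = 1.0 / 130.0     # yak/san-like preset
    polymorphism_density: float = 1.0 / 1300.0
    freq_range: tuple[float, float] = (0.1, 0.9)
    introgression_sizes: tuple[int, ...] = (
        100, 500, 1000, 2000, 3000, 4000, 5000, 10_000, 20_000, 50_000,
        100_000)
    spacing: tuple[int, int] = (25_000, 75_000)
    het_probability: float = 0.5
    coverage: tuple[int, int] = (10, 25)
    p_ab: float = 0.005

    def __post_init__(self) -> None:
        if not 0 <= self.fixed_diff_density < 1:
            raise ValueError("fixed_diff_density must be in [0, 1)")
        if not 0 <= self.polymorphism_density < 1:
            raise ValueError("polymorphism_density must be in [0, 1)")
        if any(s < 1 for s in self.introgression_sizes):
            raise ValueError("introgression sizes must be >= 1 bp")
        lo, hi = self.spacing
        if lo <= 0 or hi < lo:
            raise ValueError("spacing bounds must be positive and ordered")


#: density presets mirroring the real marker spacings
DENSITY_PRESETS = {
    "yak/san-like": 1.0 / 130.0,
    "yak/tei-like": 1.0 / 55.0,
}


@dataclass
class TruthSet:
    """Simulated introgression intervals with zygosity ('het'/'homo')."""

    intervals: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        by_chrom: dict[str, int] = {}
        for chrom, start, end, zyg in self.intervals:
            if start > end or zyg not in ("het", "homo"):
                raise ValueError("malformed truth interval")
            if start <= by_chrom.get(chrom, 0):
                raise ValueError("truth intervals overlap or are unsorted")
            by_chrom[chrom] = end

    def __len__(self) -> int:
        return len(self.intervals)

    def total_length(self) -> int:
        return sum(e - s + 1 for _, s, e, _ in self.intervals)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, zyg in self.intervals:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{zyg}\n")


def _sample_positions(rng, length: int, density: float) -> np.ndarray:
    n = rng.binomial(length, density)
    return np.sort(rng.choice(length, size=n, replace=False)) + 1


def simulate_species_pair(config: SimConfig, n_donor: int = 10,
                          n_recipient: int = 10,
                          seed: int | np.random.Generator = 0
                          ) -> GenotypeTable:
    """Genotype table for a diverged donor/recipient population pair.

    Fixed differences are donor-monomorphic for the alternate allele with
    recipient donor-allele frequency 0.  Polymorphic noise sites segregate
    in the recipient (shared) or in the donor (breaking monomorphism), half
    each.  Genotypes are drawn under Hardy-Weinberg; depths are filled at
    the configured coverage so the table round-trips through marker
    selection.
    """
    if n_donor < 2 or n_recipient < 2:
        raise ValueError("need at least 2 individuals per population")
    rng = np.random.default_rng(seed)
    n_ind = n_donor + n_recipient
    chroms, poss, kinds = [], [], []
    for chrom, length in config.chromosomes.items():
        p_fix = _sample_positions(rng, length, config.fixed_diff_density)
        p_poly = _sample_positions(rng, length, config.polymorphism_density)
        p_poly = p_poly[~np.isin(p_poly, p_fix)]
        pos = np.concatenate([p_fix, p_poly])
        kind = np.concatenate([
            np.zeros(p_fix.size, dtype=int),                 # fixed diff
            rng.integers(1, 3, size=p_poly.size),            # 1 recip, 2 donor
        ])
        order = np.argsort(pos)
        chroms.extend([chrom] * pos.size)
        poss.append(pos[order])
        kinds.append(kind[order])
    pos = np.concatenate(poss)
    kind = np.concatenate(kinds)
    n_sites = pos.size

    ref_i = rng.integers(0, 4, size=n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4

    # per-population alt-allele frequencies by site kind
    lo, hi = config.freq_range
    f = rng.uniform(lo, hi, size=n_sites)
    freq_d = np.select([kind == 0, kind == 1, kind == 2], [1.0, 0.0, f])
    freq_r = np.select([kind == 0, kind == 1, kind == 2], [0.0, f, 0.0])

    def _hwe(freq, n):
        hap = rng.random((n_sites, n, 2)) < freq[:, None, None]
        return hap.sum(axis=2).astype(np.int8)

    gt = np.concatenate([_hwe(freq_d, n_donor), _hwe(freq_r, n_recipient)],
                        axis=1)
    # make the donor truly monomorphic at fixed differences regardless of
    # sampling noise (they are fixed by construction)
    gt[kind == 0, :n_donor] = GT_HOM_ALT

    cov_lo, cov_hi = config.coverage
    n_reads = rng.integers(cov_lo, cov_hi + 1, size=(n_sites, n_ind))
    alt_reads = np.where(
        gt == GT_HOM_ALT, n_reads,
        np.where(gt == GT_HET, rng.binomial(n_reads, 0.5), 0),
    )
    samples = [f"donor_{i}" for i in range(n_donor)] + \
        [f"recip_{i}" for i in range(n_recipient)]
    populations = {s: ("donor" if s.startswith("donor") else "recipient")
                   for s in samples}
    return GenotypeTable(
        chrom=np.array(chroms, dtype=object),
        pos=pos.astype(np.int64),
        ref=_NUC[ref_i],
        alt=_NUC[alt_i],
        gt=gt,
        ad_ref=(n_reads - alt_reads).astype(np.int32),
        ad_alt=alt_reads.astype(np.int32),
        samples=samples,
        populations=populations,
        has_depths=True,
    )


def _place_introgressions(rng, length: int, sizes, spacing,
                          het_probability: float, chrom: str,
                          cycle_sizes: bool):
    """Tile one chromosome with truth intervals; returns interval list."""
    out = []
    sizes = list(sizes)
    if max(sizes) > length:
        raise ValueError("introgression size exceeds chromosome length")
    order = rng.permutation(len(sizes))
    idx = 0
    cursor = 1 + int(rng.integers(spacing[0], spacing[1] + 1))
    while True:
        if cycle_sizes:
            size = sizes[order[idx % len(sizes)]]
            idx += 1
        else:
            size = sizes[rng.integers(len(sizes))]
        if cursor + size - 1 > length:
            break
        zyg = "het" if rng.random() < het_probability else "homo"
        out.append((chrom, cursor, cursor + size - 1, zyg))
        cursor += size + int(rng.integers(spacing[0], spacing[1] + 1))
    return out


def simulate_admixed_individual(
    table: GenotypeTable, config: SimConfig,
    seed: int | np.random.Generator = 0,
    cycle_sizes: bool = True,
):
    """Observations (k, n) for one admixed recipient individual, plus truth.

    The genome is tiled with introgression intervals (sizes from the
    configured list, spacing U(25, 75) kb, each heterozygous or homozygous).
    At every site two haploid alleles are drawn from the population allele
    frequencies — both donor inside homozygous introgressions, one donor
    and one recipient inside heterozygous ones, both recipient elsewhere.
    Coverage is uniform on {10..25}; reads sample the two haplotypes
    binomially and are mis-called with probability ``p_ab``.

    Returns ``(k, n, truth)`` with k/n aligned to ``table`` sites; k counts
    reads carrying the site's donor-population-leaning allele (the alternate
    allele, the donor allele at every fixed difference).
    """
    rng = np.random.default_rng(seed)
    intervals = []
    for chrom, length in sorted(
            {c: int(table.pos[table.chrom == c].max(initial=0))
             for c in dict.fromkeys(table.chrom)}.items()):
        chrom_len = config.chromosomes.get(chrom, length)
        intervals.extend(_place_introgressions(
            rng, chrom_len, config.introgression_sizes, config.spacing,
            config.het_probability, chrom, cycle_sizes))
    truth = TruthSet(intervals)

    donor_idx = table.indices_of("donor")
    recip_idx = table.indices_of("recipient")
    n_sites = table.n_sites
    freq_d = _alt_frequency(table, donor_idx)
    freq_r = _alt_frequency(table, recip_idx)

    zygosity = np.zeros(n_sites, dtype=int)   # donor haplotype copies: 0/1/2
    for chrom, start, end, zyg in truth.intervals:
        inside = (table.chrom == chrom) & (table.pos >= start) & \
            (table.pos <= end)
        zygosity[inside] = 1 if zyg == "het" else 2

    hap1_src_donor = zygosity >= 1   # first haplotype from donor pool
    hap2_src_donor = zygosity == 2
    hap1 = rng.random(n_sites) < np.where(hap1_src_donor, freq_d, freq_r)
    hap2 = rng.random(n_sites) < np.where(hap2_src_donor, freq_d, freq_r)

    cov_lo, cov_hi = config.coverage
    n = rng.integers(cov_lo, cov_hi + 1, size=n_sites)
    # reads drawn from the two haplotypes with equal probability
    reads_h1 = rng.binomial(n, 0.5)
    true_alt = np.where(hap1, reads_h1, 0) + np.where(hap2, n - reads_h1, 0)
    # independent per-read miscalls flip alt<->ref
    k = true_alt - rng.binomial(true_alt, config.p_ab) \
        + rng.binomial(n - true_alt, config.p_ab)
    return k.astype(np.int32), n.astype(np.int32), truth


def _alt_frequency(table: GenotypeTable, idx: np.ndarray) -> np.ndarray:
    gt = table.gt[:, idx]
    called = gt >= 0
    copies = np.where(gt == GT_HET, 1, 0) + np.where(gt == GT_HOM_ALT, 2, 0)
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, copies.sum(axis=1) / (2 * n_called), 0.0)


@dataclass
class EvaluationResult:
    """Detection scores of called tracts against a simulated truth set."""

    per_size_class: dict[int, dict[str, float]]   # size -> {n, detected, fn}
    false_positive_count: int
    false_positive_length: int          # full length of no-overlap calls
    false_positive_outside_truth: int   # called bp outside any truth interval
    genome_length: int
    non_introgressed_length: int

    @property
    def false_negative_rate(self) -> float:
        n = sum(v["n"] for v in self.per_size_class.values())
        det = sum(v["detected"] for v in self.per_size_class.values())
        return 1.0 - det / n if n else float("nan")

    def false_negative_rate_for(self, min_size: int) -> float:
        n = det = 0
        for size, v in self.per_size_class.items():
            if size >= min_size:
                n += v["n"]
                det += v["detected"]
        return 1.0 - det / n if n else float("nan")

    @property
    def false_positive_genome_fraction(self) -> float:
        """No-overlap called bp / non-introgressed genome length."""
        if not self.non_introgressed_length:
            return float("nan")
        return self.false_positive_length / self.non_introgressed_length


def evaluate_calls(called: list[Tract], truth: TruthSet,
                   genome_length: int,
                   min_reciprocal_overlap: float = 0.0) -> EvaluationResult:
    """Score called introgression tracts against the simulated truth.

    A truth interval is detected when at least one called tract overlaps it
    (by any amount, or by ``min_reciprocal_overlap`` of both lengths when
    set).  False positives are called tracts overlapping no truth interval;
    both their full cumulative length and the called length falling outside
    all truth intervals are reported.
    """
    per_class: dict[int, dict[str, float]] = {}
    truth_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, s, e, zyg in truth.intervals:
        truth_by_chrom.setdefault(chrom, []).append((s, e, zyg))

    def _overlap(s1, e1, s2, e2):
        return max(0, min(e1, e2) - max(s1, s2) + 1)

    detected_flags = []
    for chrom, s, e, zyg in truth.intervals:
        size = e - s + 1
        cls = per_class.setdefault(size, {"n": 0, "detected": 0, "fn": 0.0})
        cls["n"] += 1
        hit = False
        for t in called:
            if t.chrom != chrom:
                continue
            ov = _overlap(s, e, t.start, t.end)
            if ov <= 0:
                continue
            if min_reciprocal_overlap > 0:
                if (ov / size >= min_reciprocal_overlap
                        and ov / t.length >= min_reciprocal_overlap):
                    hit = True
                    break
            else:
                hit = True
                break
        cls["detected"] += int(hit)
        detected_flags.append(hit)
    for cls in per_class.values():
        cls["fn"] = 1.0 - cls["detected"] / cls["n"]

    fp_count = 0
    fp_len = 0
    fp_outside = 0
    for t in called:
        ivs = truth_by_chrom.get(t.chrom, [])
        ov = sum(_overlap(t.start, t.end, s, e) for s, e, _ in ivs)
        if ov == 0:
            fp_count += 1
            fp_len += t.length
        fp_outside += t.length - ov

    return EvaluationResult(
        per_size_class=dict(sorted(per_class.items())),
        false_positive_count=fp_count,
        false_positive_length=fp_len,
        false_positive_outside_truth=fp_outside,
        genome_length=genome_length,
        non_introgressed_length=genome_length - truth.total_length(),
    )


def write_vcf(table: GenotypeTable, path) -> None:
    """Export a genotype table as a minimal VCF (GT + AD FORMAT fields)."""
    gt_str = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(table.chrom):
            ln = int(table.pos[table.chrom == chrom].max())
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            cells = [
                f"{gt_str[int(table.gt[i, j])]}:"
                f"{table.ad_ref[i, j]},{table.ad_alt[i, j]}"
                for j in range(table.n_individuals)
            ]
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t.\t.\t.\tGT:AD\t" + "\t".join(cells) + "\n")
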
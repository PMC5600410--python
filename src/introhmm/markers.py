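"""Site filtering and selection of species-informative markers.

Markers are biallelic SNPs at which the putative donor species is monomorphic
and the donor-allele frequency differs between donor and recipient by at least
a configurable threshold (default 30%).  Such sites are the observation points
of the introgression HMM: at each marker the data for one recipient individual
are ``k`` reads carrying the donor allele out of ``n`` total reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GT_MISSING = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2

#: population roles recognised in a population map
ROLES = ("donor", "recipient", "allopatric", "outgroup")


@dataclass
class GenotypeTable:
    """In-memory image of a multi-sample VCF restricted to biallelic SNPs.

    Coordinates are 1-based (VCF convention).  ``gt`` holds per-individual
    genotype codes (-1 missing, 0 hom-ref, 1 het, 2 hom-alt); ``ad_ref`` and
    ``ad_alt`` hold per-individual allele depths.  All site arrays are ordered
    by (chromosome, position) with positions strictly increasing within a
    chromosome.
    """

    chrom: np.ndarray          # (n_sites,) str
    pos: np.ndarray            # (n_sites,) int64, 1-based
    ref: np.ndarray            # (n_sites,) str
    alt: np.ndarray            # (n_sites,) str
    gt: np.ndarray             # (n_sites, n_ind) int8
    ad_ref: np.ndarray         # (n_sites, n_ind) int32
    ad_alt: np.ndarray         # (n_sites, n_ind) int32
    samples: list[str]
    populations: dict[str, str]    # individual -> population name
    has_depths: bool = True

    def __post_init__(self) -> None:
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if np.any(self.ad_ref < 0) or np.any(self.ad_alt < 0):
            raise ValueError("negative allele depths")

    @property
    def n_sites(self) -> int:
        return self.pos.size

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    def indices_of(self, population: str) -> np.ndarray:
        """Column indices of the individuals assigned to *population*."""
        return np.array(
            [i for i, s in enumerate(self.samples)
             if self.populations.get(s) == population],
            dtype=int,
        )

    def total_depth(self) -> np.ndarray:
        return self.ad_ref + self.ad_alt


@dataclass
class MarkerTable:
    """Ordered informative sites for one direction of introgression.

    ``donor_is_alt`` records which VCF allele is the donor species' fixed
    allele.  ``k`` / ``n`` are per-recipient-individual read counts of the
    donor allele and total coverage (columns follow ``recipient_samples``).
    """

    chrom: np.ndarray
    pos: np.ndarray
    donor_allele: np.ndarray
    recipient_allele: np.ndarray
    donor_is_alt: np.ndarray       # bool
    freq_donor: np.ndarray         # donor-allele frequency in donor (1.0)
    freq_recipient: np.ndarray     # donor-allele frequency in recipient
    k: np.ndarray                  # (n_sites, n_recipient) int32
    n: np.ndarray                  # (n_sites, n_recipient) int32
    recipient_samples: list[str] = field(default_factory=list)
    site_index: np.ndarray | None = None   # rows into the source table

    def __post_init__(self) -> None:
        if np.any(self.k > self.n):
            raise ValueError("donor-allele depth k exceeds total depth n")

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)

    def individual_observations(self, individual: str):
        """(chrom, pos, k, n) arrays for one recipient individual."""
        j = self.recipient_samples.index(individual)
        return self.chrom, self.pos, self.k[:, j], self.n[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "donor_allele": self.donor_allele,
                "recipient_allele": self.recipient_allele,
                "freq_donor": self.freq_donor,
                "freq_recipient": self.freq_recipient,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_population_map(path) -> dict[str, str]:
    """Two-column whitespace-delimited text: individual, population."""
    pops: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed population map line: {line!r}")
            pops[parts[0]] = parts[1]
    return pops


def read_genotype_table(
    vcf_path,
    population_map: dict[str, str],
    pass_only: bool = True,
) -> GenotypeTable:
    """Load a VCF (GT + AD) into a :class:`GenotypeTable`.

    Multi-allelic records, indels and non-SNPs are skipped (counts logged).
    If the AD FORMAT field is absent the table falls back to genotype-only
    mode with zero depths and ``has_depths=False``.

    Parameters
    ----------
    pass_only:
        Keep only records whose FILTER column is PASS or '.'.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    gts: list[np.ndarray] = []
    adr: list[np.ndarray] = []
    ada: list[np.ndarray] = []

    n_skipped_multi = 0
    n_skipped_nonsnp = 0
    n_skipped_filter = 0
    has_depths = True

    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped_multi += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped_nonsnp += 1
            continue
        if pass_only and rec.FILTER is not None:  # cyvcf2: None == PASS/'.'
            n_skipped_filter += 1
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = GT_MISSING
        gts.append(g)
        if has_depths:
            ad = rec.format("AD")
            if ad is None:
                has_depths = False
                log.warning(
                    "AD field missing at %s:%d; falling back to "
                    "genotype-only mode", rec.CHROM, rec.POS,
                )
            else:
                ad = np.asarray(ad)
                adr.append(np.maximum(ad[:, 0], 0).astype(np.int32))
                ada.append(np.maximum(ad[:, 1], 0).astype(np.int32))
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])

    if n_skipped_multi or n_skipped_nonsnp or n_skipped_filter:
        log.info(
            "skipped %d multi-allelic, %d non-SNP, %d filtered records",
            n_skipped_multi, n_skipped_nonsnp, n_skipped_filter,
        )

    n_sites = len(poss)
    n_ind = len(samples)
    gt = (np.vstack(gts) if n_sites else
          np.empty((0, n_ind), dtype=np.int8))
    if has_depths and adr:
        ad_ref = np.vstack(adr)
        ad_alt = np.vstack(ada)
    else:
        has_depths = False
        ad_ref = np.zeros((n_sites, n_ind), dtype=np.int32)
        ad_alt = np.zeros((n_sites, n_ind), dtype=np.int32)

    return GenotypeTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        gt=gt,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        samples=samples,
        populations=dict(population_map),
        has_depths=has_depths,
    )


def coverage_filter(
    table: GenotypeTable,
    min_cov: int = 5,
    upper_quantile: float = 0.99,
) -> GenotypeTable:
    """Mask genotype calls at extreme coverages.

    Per individual, calls are set to missing where total depth is below
    ``min_cov`` or above that individual's genome-wide ``upper_quantile``
    depth.  The quantile is computed over the individual's called sites with
    the linear-interpolation estimator (numpy default).
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if not 0 < upper_quantile < 1:
        raise ValueError("upper_quantile must be in (0, 1)")

    depth = table.total_depth()
    gt = table.gt.copy()
    for j, sample in enumerate(table.samples):
        called = gt[:, j] != GT_MISSING
        if not called.any():
            raise ValueError(f"individual {sample!r} has no called sites")
        hi = np.quantile(depth[called, j], upper_quantile)
        bad = (depth[:, j] < min_cov) | (depth[:, j] > hi)
        gt[bad, j] = GT_MISSING

    out = GenotypeTable(
        chrom=table.chrom, pos=table.pos, ref=table.ref, alt=table.alt,
        gt=gt, ad_ref=table.ad_ref, ad_alt=table.ad_alt,
        samples=table.samples, populations=table.populations,
        has_depths=table.has_depths,
    )
    return out


def select_markers(
    table: GenotypeTable,
    donor: str,
    recipient: str,
    min_freq_diff: float = 0.3,
    max_het_fraction: float = 0.8,
    excluded_donor_individuals: set[str] | frozenset[str] = frozenset(),
) -> MarkerTable:
    """Select HMM markers for one direction of introgression.

    A site is retained when, on called genotypes:

    1. every donor individual (after exclusions) and at least one recipient
       individual has a called genotype;
    2. the donor population is monomorphic;
    3. the donor-allele frequency difference between donor and recipient is
       at least ``min_freq_diff``;
    4. at most ``max_het_fraction`` of the genotyped individuals (donor and
       recipient combined) are heterozygous.
    """
    donor_idx = np.array(
        [i for i, s in enumerate(table.samples)
         if table.populations.get(s) == donor
         and s not in excluded_donor_individuals],
        dtype=int,
    )
    recip_idx = table.indices_of(recipient)
    if donor_idx.size == 0:
        raise ValueError("donor population empty after exclusions")
    if recip_idx.size == 0:
        raise ValueError("recipient population empty")

    gt_d = table.gt[:, donor_idx]
    gt_r = table.gt[:, recip_idx]
    called_d = gt_d != GT_MISSING
    called_r = gt_r != GT_MISSING

    complete = called_d.all(axis=1) & (called_r.sum(axis=1) >= 1)

    # donor monomorphic: all called donor genotypes identical homozygotes
    all_hom_ref = (gt_d == GT_HOM_REF).all(axis=1)
    all_hom_alt = (gt_d == GT_HOM_ALT).all(axis=1)
    monomorphic = all_hom_ref | all_hom_alt
    donor_is_alt = all_hom_alt

    # allele frequencies of the donor allele (sample frequencies on calls)
    def _freq_of_alt(gt_part, called_part):
        n_called = called_part.sum(axis=1)
        alt_copies = np.where(gt_part == GT_HET, 1, 0) + \
            np.where(gt_part == GT_HOM_ALT, 2, 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                n_called > 0, alt_copies.sum(axis=1) / (2 * n_called), np.nan
            )

    alt_freq_d = _freq_of_alt(gt_d, called_d)
    alt_freq_r = _freq_of_alt(gt_r, called_r)
    freq_donor = np.where(donor_is_alt, alt_freq_d, 1.0 - alt_freq_d)
    freq_recipient = np.where(donor_is_alt, alt_freq_r, 1.0 - alt_freq_r)
    with np.errstate(invalid="ignore"):
        freq_ok = np.abs(freq_donor - freq_recipient) >= min_freq_diff

    gt_both = np.concatenate([gt_d, gt_r], axis=1)
    n_called_both = (gt_both != GT_MISSING).sum(axis=1)
    n_het = (gt_both == GT_HET).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_called_both > 0, n_het / n_called_both, 0.0)
    het_ok = het_frac <= max_het_fraction

    keep = complete & monomorphic & freq_ok & het_ok
    if not keep.any():
        counts = {
            "completeness": int((~complete).sum()),
            "monomorphism": int((complete & ~monomorphic).sum()),
            "freq_diff": int((complete & monomorphic & ~freq_ok).sum()),
            "het_fraction": int(
                (complete & monomorphic & freq_ok & ~het_ok).sum()),
        }
        raise ValueError(f"no markers retained; eliminated by rule: {counts}")

    idx = np.flatnonzero(keep)
    d_is_alt = donor_is_alt[idx]
    donor_allele = np.where(d_is_alt, table.alt[idx], table.ref[idx])
    recipient_allele = np.where(d_is_alt, table.ref[idx], table.alt[idx])
    ad_ref = table.ad_ref[idx][:, recip_idx]
    ad_alt = table.ad_alt[idx][:, recip_idx]
    k = np.where(d_is_alt[:, None], ad_alt, ad_ref).astype(np.int32)
    n = (ad_ref + ad_alt).astype(np.int32)

    return MarkerTable(
        chrom=table.chrom[idx],
        pos=table.pos[idx],
        donor_allele=donor_allele,
        recipient_allele=recipient_allele,
        donor_is_alt=d_is_alt,
        freq_donor=freq_donor[idx],
        freq_recipient=freq_recipient[idx],
        k=k,
        n=n,
        recipient_samples=[table.samples[i] for i in recip_idx],
        site_index=idx,
    )
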
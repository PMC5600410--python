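"""Allele-frequency ABBA-BABA statistics with block-jackknife errors.

Patterson's D contrasts the two discordant site patterns of a four-taxon
comparison (P1 allopatric recipient, P2 putative recipient, P3 putative
donor, P4 outgroup).  With population allele frequencies p1..p4 of the
derived allele, each site contributes

    ABBA = (1 - p1) p2 p3 (1 - p4)
    BABA = p1 (1 - p2) p3 (1 - p4)

and D = sum(ABBA - BABA) / sum(ABBA + BABA).  A positive D indicates an
excess of ABBA sites, i.e. gene flow between P2 and P3.  The admixture
fraction estimator f_d divides the same numerator by its value when the
donor role at each site is played by whichever of P2/P3 carries the higher
derived frequency (the complete-introgression expectation).  Significance
comes from a weighted block jackknife over non-overlapping genomic windows
(default 100 kb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FreqQuartet:
    """Per-site derived-allele frequencies for the four populations."""

    chrom: np.ndarray
    pos: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4"):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"{name} outside [0, 1]")
            setattr(self, name, p)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def polarize(self) -> "FreqQuartet":
        """Repolarise sites where the outgroup is majority-derived.

        Where p4 > 0.5 the reference/derived roles are swapped (p -> 1-p for
        all four populations) so the outgroup always carries the putatively
        ancestral allele; remaining intermediate outgroup frequencies are
        handled by the frequency weighting itself.
        """
        flip = self.p4 > 0.5
        def f(p):
            return np.where(flip, 1.0 - p, p)
        return FreqQuartet(self.chrom, self.pos, f(self.p1), f(self.p2),
                           f(self.p3), f(self.p4))


def site_patterns(q: FreqQuartet):
    """Frequency-weighted (abba, baba) contributions of each site."""
    abba = (1 - q.p1) * q.p2 * q.p3 * (1 - q.p4)
    baba = q.p1 * (1 - q.p2) * q.p3 * (1 - q.p4)
    return abba, baba


def d_statistic(q: FreqQuartet) -> float:
    """Patterson's D = sum(ABBA - BABA) / sum(ABBA + BABA), in [-1, 1]."""
    abba, baba = site_patterns(q)
    denom = (abba + baba).sum()
    if denom == 0:
        raise ValueError("no informative sites (ABBA + BABA all zero)")
    return float((abba - baba).sum() / denom)


def f_d(q: FreqQuartet) -> float:
    """Admixture-fraction estimator: D numerator over its value at full
    introgression, with the per-site donor role given to whichever of P2/P3
    has the higher derived frequency."""
    abba, baba = site_patterns(q)
    pd = np.maximum(q.p2, q.p3)
    abba_d = (1 - q.p1) * pd * pd * (1 - q.p4)
    baba_d = q.p1 * (1 - pd) * pd * (1 - q.p4)
    denom = (abba_d - baba_d).sum()
    if denom == 0:
        raise ValueError("zero f_d denominator")
    return float((abba - baba).sum() / denom)


@dataclass
class JackknifeResult:
    estimate: float
    se: float
    z: float
    n_blocks: int
    degenerate: bool = False


def _block_ids(q: FreqQuartet, block_size: int) -> np.ndarray:
    ids = np.empty(q.n_sites, dtype=np.int64)
    code = 0
    for chrom in dict.fromkeys(q.chrom.tolist()):
        sel = q.chrom == chrom
        ids[sel] = code * 10**9 + q.pos[sel] // block_size
        code += 1
    return ids


def block_jackknife(q: FreqQuartet, statistic, block_size: int = 100_000
                    ) -> JackknifeResult:
    """Weighted delete-one-block jackknife (Busing-style weighting).

    Blocks are consecutive non-overlapping genomic windows; block weights
    are proportional to their informative-site counts.  Returns the full
    estimate, its jackknife SE and Z = estimate / SE.
    """
    ids = _block_ids(q, block_size)
    blocks = np.unique(ids)
    if blocks.size < 2:
        raise ValueError("need at least 2 non-empty blocks")
    theta = statistic(q)
    n = q.n_sites
    m = np.array([(ids == b).sum() for b in blocks], dtype=float)
    theta_del = np.array([
        statistic(FreqQuartet(q.chrom[ids != b], q.pos[ids != b],
                              q.p1[ids != b], q.p2[ids != b],
                              q.p3[ids != b], q.p4[ids != b]))
        for b in blocks
    ])
    g = blocks.size
    h = n / m
    theta_J = g * theta - ((1 - m / n) * theta_del).sum()
    var = np.sum((h * theta - (h - 1) * theta_del - theta_J) ** 2
                 / (h - 1)) / g
    se = float(np.sqrt(var))
    if se == 0:
        return JackknifeResult(theta, 0.0, float("nan"), g, degenerate=True)
    return JackknifeResult(theta, se, theta / se, g)


def quartet_from_genotypes(table, populations: dict[str, str]):
    """Build a :class:`FreqQuartet` from a genotype table and a role map.

    ``populations`` maps population names to roles 'allopatric' (P1),
    'recipient' (P2), 'donor' (P3), 'outgroup' (P4).  Sites with no called
    genotypes in any of the four populations are dropped; frequencies are
    polarised against the outgroup.
    """
    from .simulate import _alt_frequency

    role_to_pop = {role: pop for pop, role in populations.items()}
    idx = {}
    for role in ("allopatric", "recipient", "donor", "outgroup"):
        pop = role_to_pop.get(role)
        if pop is None:
            raise ValueError(f"population map missing role {role!r}")
        cols = np.array([i for i, s in enumerate(table.samples)
                         if table.populations.get(s) == pop], dtype=int)
        if cols.size == 0:
            raise ValueError(f"no individuals for role {role!r}")
        idx[role] = cols

    called_all = np.ones(table.n_sites, dtype=bool)
    freqs = {}
    for role, cols in idx.items():
        called = (table.gt[:, cols] >= 0).sum(axis=1) > 0
        called_all &= called
        freqs[role] = _alt_frequency(table, cols)
    sel = called_all
    q = FreqQuartet(
        table.chrom[sel], table.pos[sel],
        freqs["allopatric"][sel], freqs["recipient"][sel],
        freqs["donor"][sel], freqs["outgroup"][sel],
    )
    return q.polarize()
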
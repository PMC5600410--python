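import numpy as np
import pytest

from introhmm import markers as mk


TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr2L,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\td1\td2\tr1\tr2
chr2L\t100\t.\tA\tT\t.\t.\t.\tGT:AD\t1/1:0,12\t1/1:0,15\t0/0:10,0\t0/1:7,5
chr2L\t200\t.\tC\tG\t.\t.\t.\tGT:AD\t1/1:0,11\t1/1:0,9\t0/0:12,0\t0/0:14,0
chr2L\t300\t.\tG\tGA\t.\t.\t.\tGT:AD\t0/0:9,0\t0/0:8,0\t0/0:10,0\t0/0:11,0
chr2L\t400\t.\tT\tA,C\t.\t.\t.\tGT:AD\t1/1:0,9,0\t1/1:0,8,0\t0/0:9,0,0\t0/0:9,0,0
chr2L\t500\t.\tA\tC\t.\t.\t.\tGT:AD\t0/1:6,6\t1/1:0,13\t0/0:12,0\t0/0:9,0
chr2L\t600\t.\tG\tT\t.\t.\t.\tGT:AD\t1/1:0,10\t1/1:0,12\t./.:0,0\t0/0:16,0
chr2L\t700\t.\tC\tA\t.\t.\t.\tGT:AD\t1/1:0,14\t./.:0,0\t0/0:11,0\t0/0:13,0
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    """Seven records: 5 usable SNPs, one indel (300), one multi-allelic
    (400); two donor and two recipient samples."""
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return str(path)


@pytest.fixture
def tiny_popmap(tmp_path):
    path = tmp_path / "pops.txt"
    path.write_text("d1 donor\nd2 donor\nr1 recipient\nr2 recipient\n")
    return str(path)


def make_table(gt, pos=None, n_donor=None, ad_ref=None, ad_alt=None,
               chrom="chr2L"):
    """Build a GenotypeTable from a genotype matrix (sites x individuals).

    The first ``n_donor`` columns are donor individuals, the rest
    recipients.  Depths default to 10 reads consistent with the genotype.
    """
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_ind = gt.shape
    if n_donor is None:
        n_donor = n_ind // 2
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if ad_alt is None:
        ad_alt = np.where(gt == 2, 10, np.where(gt == 1, 5, 0))
    if ad_ref is None:
        ad_ref = np.where(gt == 0, 10, np.where(gt == 1, 5, 0))
    samples = [f"d{i}" for i in range(n_donor)] + \
        [f"r{i}" for i in range(n_ind - n_donor)]
    pops = {s: ("donor" if s.startswith("d") else "recipient")
            for s in samples}
    return mk.GenotypeTable(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        gt=gt,
        ad_ref=np.asarray(ad_ref, dtype=np.int32),
        ad_alt=np.asarray(ad_alt, dtype=np.int32),
        samples=samples,
        populations=pops,
    )


@pytest.fixture
def small_species_pair():
    from introhmm import simulate as sim

    cfg = sim.SimConfig(chromosomes={"chr2L": 200_000},
                        fixed_diff_density=1 / 130,
                        polymorphism_density=1 / 1300)
    return cfg, sim.simulate_species_pair(cfg, seed=42)
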
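import numpy as np
import pytest

from mitoconcord.simdata import SimConfig, simulate_dataset
from mitoconcord.variant_io import apply_variant_filters


def small_config(**kw) -> SimConfig:
    """Reduced-size generator config for fast unit tests."""
    from mitoconcord.simdata import DemeConfig
    defaults = dict(
        n_per_parental=40,
        n_background_loci=400,
        n_chr5_background=60,
        n_island_loci=30,
        admixed_demes=[
            DemeConfig("adm1", 30, 0.8, 47.0, -127.0),
            DemeConfig("adm2", 30, 0.5, 50.0, -124.0),
            DemeConfig("adm3", 30, 0.2, 53.0, -122.0),
        ],
        generations=10,
        seed=11,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def sim_default():
    """One full-size simulated dataset under the selected regime."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def sim_filtered(sim_default):
    gm, counts = apply_variant_filters(sim_default.genotypes)
    return gm, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:GQ\t0/0:99\t0/1:99\t1/1:99
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT:GQ\t0|1:99\t./.:99\t0/0:99
chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT:GQ\t1/1:99\t1/1:99\t0/1:99
chr1\t400\t.\tT\tC\t.\tPASS\t.\tGT:GQ\t0/0:15\t0/1:99\t0/0:99
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    """3-sample, 4-site VCF with hand-decodable genotypes.

    Expected dosages (GQ ignored):
        site 100: 0, 1, 2
        site 200: 1, NaN, 0   (phased het; missing)
        site 300: 2, 2, 1
        site 400: 0, 1, 0     (s1 GQ=15)
    """
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return str(path)


def _filter_vcf_text() -> str:
    """25-sample, 5-site VCF exercising each filter criterion once.

    site 10: indel; site 20: triallelic; site 30: MAF 0.02 (1/50 alleles);
    site 40: 40% missing (10/25); site 50: clean (MAF 0.3).  Exactly one
    site survives the default filters.
    """
    n = 25
    header = ("##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
              '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(f"s{i + 1}" for i in range(n)) + "\n")

    def row(pos, ref, alt, gts):
        return (f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:GQ\t"
                + "\t".join(f"{g}:99" for g in gts) + "\n")

    indel = row(10, "A", "AT", ["0/1" if i % 2 else "0/0" for i in range(n)])
    triallelic = row(20, "C", "T,G", ["0/1" if i % 3 == 0 else "0/0" for i in range(n)])
    low_maf = row(30, "G", "A", ["0/1" if i == 0 else "0/0" for i in range(n)])
    missing = row(40, "T", "C", ["./." if i < 10 else ("0/1" if i % 2 else "0/0")
                                 for i in range(n)])
    clean = row(50, "A", "C", ["0/1" if i < 11 else ("1/1" if i == 11 else "0/0")
                               for i in range(n)])
    return header + indel + triallelic + low_maf + missing + clean


@pytest.fixture()
def filter_vcf(tmp_path):
    path = tmp_path / "filters.vcf"
    path.write_text(_filter_vcf_text())
    return str(path)
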
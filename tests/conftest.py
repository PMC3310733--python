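import numpy as np
import pytest

from mirsel.io_formats import HaplotypePanel, SnpRecord


def build_panel(matrix, positions=None, populations=None, ancestral="ref", chrom="1"):
    """Small hand-rolled panel: ``matrix`` rows are haplotypes (two per
    sample), ``populations`` assigns one population per sample."""
    matrix = np.asarray(matrix, dtype=np.int8)
    n_haps, n_snps = matrix.shape
    assert n_haps % 2 == 0
    if positions is None:
        positions = [100 * (j + 1) for j in range(n_snps)]
    n_samples = n_haps // 2
    if populations is None:
        populations = ["pop1"] * n_samples
    samples = [f"s{i:03d}" for i in range(n_samples)]
    snps = []
    for j in range(n_snps):
        snps.append(
            SnpRecord(
                snp_id=f"snp{j}",
                chrom=chrom,
                pos=int(positions[j]),
                ref_allele="A",
                alt_allele="G",
                ancestral_allele="A" if ancestral == "ref" else None,
            )
        )
    return HaplotypePanel(
        haplotypes=matrix,
        snps=snps,
        haplotype_samples=[s for s in samples for _ in range(2)],
        sample_to_population=dict(zip(samples, populations)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_pop_panel(rng):
    """40 haplotypes x 30 SNPs, two populations, random but reproducible."""
    matrix = (rng.random((40, 30)) < 0.4).astype(np.int8)
    # keep every column polymorphic
    matrix[0] = 0
    matrix[1] = 1
    return build_panel(matrix, populations=["pop1"] * 10 + ["pop2"] * 10)
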
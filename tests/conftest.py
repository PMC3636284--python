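import numpy as np
import pandas as pd
import pytest

from stratfdr.annotation import GeneModel, LDNeighborhood, ReferencePanel
from stratfdr import simulate as sim


@pytest.fixture
def small_panel():
    """10 SNPs x 6 individuals, hand-built dosages, no missing data."""
    rng = np.random.default_rng(42)
    dosages = rng.integers(0, 3, size=(10, 6)).astype(float)
    # make SNP 1 a perfect copy of SNP 0 and SNP 9 monomorphic
    dosages[1] = dosages[0]
    dosages[9] = 1.0
    snps = pd.DataFrame({
        "snp": [f"s{i}" for i in range(10)],
        "chrom": "1",
        "pos": 10_000 * np.arange(1, 11),
    })
    return ReferencePanel(snps, dosages, [f"i{j}" for j in range(6)])


@pytest.fixture
def block_panel():
    """Larger block-LD panel from the simulator."""
    return sim.simulate_reference_panel(sim.PanelSpec(
        n_individuals=200, n_snps=300, block_min=5, block_max=5,
        target_r2=0.8, chrom_length=3_000_000, seed=7,
    ))


@pytest.fixture
def plus_gene():
    """A '+' strand gene: 5'UTR [1000,1200), exons/introns, 3'UTR."""
    return GeneModel(
        gene_id="gA", transcript_id="tA", chrom="1", strand="+",
        tx_start=1000, tx_end=5000,
        elements=(
            ("utr5", 1000, 1200),
            ("exon", 1200, 2000),
            ("intron", 2000, 4000),
            ("exon", 4000, 4500),
            ("utr3", 4500, 5000),
        ),
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        gene_id="gB", transcript_id="tB", chrom="1", strand="-",
        tx_start=20_000, tx_end=24_000,
        elements=(
            ("utr3", 20_000, 20_500),
            ("exon", 20_500, 21_500),
            ("intron", 21_500, 23_000),
            ("exon", 23_000, 23_600),
            ("utr5", 23_600, 24_000),
        ),
    )


def independent_neighborhoods(snp_ids):
    """Neighborhoods with no LD partners beyond self (r^2 = 1 with self)."""
    return [LDNeighborhood(s, {s: 1.0}) for s in snp_ids]


@pytest.fixture
def annotated_track():
    """Panel + gene track + annotation table, shared by pipeline tests."""
    from stratfdr.annotation import annotate_tag_snps

    panel = sim.simulate_reference_panel(sim.PanelSpec(
        n_individuals=150, n_snps=400, block_min=4, block_max=4,
        target_r2=0.7, chrom_length=10_000_000, seed=11,
    ))
    genes = sim.simulate_gene_track(
        10_000_000,
        {"intron": 0.30, "exon": 0.06, "utr5": 0.02, "utr3": 0.03},
        n_genes=12, seed=12,
    )
    frame = annotate_tag_snps(panel, genes, panel.snps["snp"].tolist())
    return panel, genes, frame
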
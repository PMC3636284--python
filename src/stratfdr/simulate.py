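"""Synthetic reference panels, gene tracks, and summary statistics.

Everything the analysis modules consume can be generated here with known
ground truth: block-structured genotype panels, non-overlapping gene
tracks with configurable category proportions, two-component Gaussian
mixture z-scores with category-specific non-null rates and variances,
multiplicative genomic inflation, null GWAS runs against real simulated
genotypes, and sub-study sets sharing true effects.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import GeneModel, ReferencePanel
from .inflation import z_to_p
from .replication import SubStudySet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a block-LD genotype panel.

    Haplotypes are generated block-wise: each block has an anchor allele
    per haplotype, and every SNP in the block copies the anchor with
    probability ``target_r2 ** 0.25`` (two copying SNPs then correlate at
    r = c^2, giving pairwise r^2 ~= target_r2).  SNPs within a block share
    the block's allele frequency; between-block r^2 is ~0.
    """

    n_individuals: int = 200
    n_snps: int = 1000
    chrom_length: int = 10_000_000
    block_min: int = 1
    block_max: int = 1
    target_r2: float = 0.8
    maf_min: float = 0.05
    maf_max: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_individuals, self.n_snps, self.chrom_length,
               self.block_min, self.block_max) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.target_r2 < 1.0:
            raise ValueError(
                f"target_r2={self.target_r2} infeasible: the anchor-copy "
                "construction requires target_r2 in [0, 1); r^2 = 1 would "
                "need every SNP to duplicate the anchor exactly"
            )
        if not 0.0 < self.maf_min <= self.maf_max <= 0.5:
            raise ValueError("need 0 < maf_min <= maf_max <= 0.5")


def simulate_reference_panel(spec: PanelSpec) -> ReferencePanel:
    """Generate a diploid dosage panel with block LD structure."""
    rng = np.random.default_rng(spec.seed)
    n_hap = 2 * spec.n_individuals
    copy_prob = spec.target_r2 ** 0.25

    block_sizes = []
    remaining = spec.n_snps
    while remaining > 0:
        size = int(rng.integers(spec.block_min, spec.block_max + 1))
        block_sizes.append(min(size, remaining))
        remaining -= block_sizes[-1]

    haplotypes = np.empty((spec.n_snps, n_hap), dtype=np.int8)
    row = 0
    for size in block_sizes:
        freq = rng.uniform(spec.maf_min, spec.maf_max)
        anchor = rng.random(n_hap) < freq
        for _ in range(size):
            copies = rng.random(n_hap) < copy_prob
            fresh = rng.random(n_hap) < freq
            haplotypes[row] = np.where(copies, anchor, fresh)
            row += 1
    dosages = (
        haplotypes[:, ::2].astype(float) + haplotypes[:, 1::2].astype(float)
    )

    spacing = spec.chrom_length // spec.n_snps
    positions = spacing * np.arange(1, spec.n_snps + 1)
    snps = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(spec.n_snps)],
        "chrom": "1",
        "pos": positions,
    })
    individuals = [f"ind{i + 1}" for i in range(spec.n_individuals)]
    return ReferencePanel(snps, dosages, individuals)


# ---------------------------------------------------------------------------
# gene track
# ---------------------------------------------------------------------------

def simulate_gene_track(chrom_length: int, proportions: dict,
                        n_genes: int = 20, n_exons: int = 8,
                        chrom: str = "1", seed: int = 0):
    """Non-overlapping gene models hitting target category proportions.

    ``proportions`` maps 'utr5'/'exon'/'intron'/'utr3' to the fraction of
    the chromosome each should occupy (sum <= 1; the remainder is flank /
    intergenic space).  Each gene receives an equal share of every
    category's base-pair budget, laid out as
    5'UTR | (exon intron)* exon | 3'UTR on a random strand, so realized
    proportions on a dense SNP grid match the targets up to rounding.

    Raises ``ValueError`` if the budgets cannot be packed.
    """
    rng = np.random.default_rng(seed)
    targets = {c: float(proportions.get(c, 0.0))
               for c in ("utr5", "exon", "intron", "utr3")}
    if any(v < 0 for v in targets.values()):
        raise ValueError("proportions must be non-negative")
    genic = sum(targets.values())
    if genic > 1.0:
        raise ValueError("category proportions sum above 1")
    per_gene = {c: int(round(v * chrom_length / n_genes))
                for c, v in targets.items()}
    exon_piece = max(per_gene["exon"] // n_exons, 1) \
        if per_gene["exon"] else 0
    intron_piece = max(per_gene["intron"] // max(n_exons - 1, 1), 1) \
        if per_gene["intron"] else 0
    gene_len = (per_gene["utr5"] + per_gene["utr3"]
                + n_exons * exon_piece + (n_exons - 1) * intron_piece)
    if gene_len == 0:
        return []
    gap = (chrom_length - n_genes * gene_len) // (n_genes + 1)
    if gap < 0:
        raise ValueError(
            f"cannot pack {n_genes} genes of {gene_len} bp into "
            f"{chrom_length} bp"
        )
    genes = []
    cursor = gap
    for g in range(n_genes):
        start = cursor
        strand = "+" if rng.random() < 0.5 else "-"
        # lay elements 5'->3' along the transcription direction so the
        # 5'UTR budget always sits at the TSS end
        first, last = ("utr5", "utr3") if strand == "+" else ("utr3", "utr5")
        elements = []
        pos = start
        if per_gene[first]:
            elements.append((first, pos, pos + per_gene[first]))
            pos += per_gene[first]
        for e in range(n_exons):
            if exon_piece:
                elements.append(("exon", pos, pos + exon_piece))
                pos += exon_piece
            if e < n_exons - 1 and intron_piece:
                elements.append(("intron", pos, pos + intron_piece))
                pos += intron_piece
        if per_gene[last]:
            elements.append((last, pos, pos + per_gene[last]))
            pos += per_gene[last]
        genes.append(GeneModel(
            gene_id=f"gene{g + 1}", transcript_id=f"tx{g + 1}",
            chrom=chrom, strand=strand, tx_start=start, tx_end=pos,
            elements=tuple(elements),
        ))
        cursor = pos + gap
    return genes


# ---------------------------------------------------------------------------
# mixture summary statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureSpec:
    """Two-component mixture of z-scores with category-specific parameters.

    Per category c: non-null probability pi1(c) and non-null variance
    inflation sigma1_sq(c), so z ~ N(0,1) with probability 1 - pi1(c) and
    z ~ N(0, 1 + sigma1_sq(c)) otherwise.  Every z is then multiplied by
    sqrt(lambda_) (multiplicative genomic inflation).  Categories absent
    from the dicts (including intergenic/None) are fully null.
    """

    pi1: dict = field(default_factory=dict)
    sigma1_sq: dict = field(default_factory=dict)
    lambda_: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for c, v in self.pi1.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"pi1[{c!r}] outside [0, 1]")
        for c, v in self.sigma1_sq.items():
            if v < 0:
                raise ValueError(f"sigma1_sq[{c!r}] negative")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated summary table."""

    table: pd.DataFrame  # snp, category, is_null, effect, effect_var
    spec: MixtureSpec


def simulate_summary_stats(categories: pd.Series, spec: MixtureSpec):
    """Draw mixture z-scores for SNPs with known primary categories.

    ``categories`` maps SNP id (index) -> category label or None.  Returns
    ``(sumstats, truth)``; the summary table has snp/z/p columns and the
    truth records null labels and the latent effect of each SNP (the
    shared mean reused by :func:`simulate_substudies`).
    """
    rng = np.random.default_rng(spec.seed)
    snp_ids = categories.index.to_numpy()
    cats = categories.to_numpy(dtype=object)
    n = len(snp_ids)
    pi1 = np.array([spec.pi1.get(c, 0.0) for c in cats])
    s1 = np.array([spec.sigma1_sq.get(c, 0.0) for c in cats])
    nonnull = rng.random(n) < pi1
    effect_var = np.where(nonnull, s1, 0.0)
    effect = rng.normal(0.0, np.sqrt(effect_var))
    z = (effect + rng.normal(size=n)) * np.sqrt(spec.lambda_)
    stats = pd.DataFrame({
        "snp": snp_ids, "z": z, "p": z_to_p(z),
    })
    truth = SyntheticTruth(
        table=pd.DataFrame({
            "snp": snp_ids,
            "category": cats,
            "is_null": ~nonnull,
            "effect": effect,
            "effect_var": effect_var,
        }),
        spec=spec,
    )
    return stats, truth


def simulate_summary_stats_ld(neighborhoods, positional: dict,
                              spec: MixtureSpec):
    """LD-propagated variant: effects live on panel SNPs, not tags.

    Each panel SNP j carries a latent effect b_j ~ N(0, sigma1_sq(cat_j))
    with probability pi1(cat_j); a tag SNP's z is drawn
    N(0, 1 + sum_j r^2(tag, j) * b_j^2), scaled by sqrt(lambda_).  This
    realizes enrichment through LD tagging, exercising the rationale for
    LD-weighted (rather than positional) annotation.
    """
    rng = np.random.default_rng(spec.seed)
    panel_ids = sorted({p for nb in neighborhoods for p in nb.partners})
    b2 = {}
    for pid in panel_ids:
        cat = positional.get(pid)
        if rng.random() < spec.pi1.get(cat, 0.0):
            b2[pid] = rng.normal(
                0.0, np.sqrt(spec.sigma1_sq.get(cat, 0.0))
            ) ** 2
        else:
            b2[pid] = 0.0
    rows = []
    for nb in neighborhoods:
        tagged = sum(r2 * b2[pid] for pid, r2 in nb.partners.items())
        z = rng.normal(0.0, np.sqrt((1.0 + tagged) * spec.lambda_))
        rows.append((nb.tag, z, tagged))
    stats = pd.DataFrame(rows, columns=["snp", "z", "tagged_var"])
    stats["p"] = z_to_p(stats["z"].to_numpy())
    truth = SyntheticTruth(
        table=pd.DataFrame({
            "snp": stats["snp"],
            "category": [positional.get(s) for s in stats["snp"]],
            "is_null": stats["tagged_var"].to_numpy() == 0.0,
            "effect": 0.0,
            "effect_var": stats["tagged_var"].to_numpy(),
        }),
        spec=spec,
    )
    return stats[["snp", "z", "p"]], truth


# ---------------------------------------------------------------------------
# null GWAS on simulated genotypes
# ---------------------------------------------------------------------------

def simulate_null_gwas(panel: ReferencePanel, seed: int = 0) -> pd.DataFrame:
    """Association scan of a phenotype independent of genotype.

    The phenotype is N(0,1) per individual; each SNP's z comes from the
    simple-regression t statistic (n-2 df) mapped through the t and normal
    CDFs with the slope's sign.  Real LD and MAF structure is preserved,
    effects are not.  Monomorphic SNPs are skipped with a warning.
    """
    if panel.n_individuals < 50:
        raise ValueError("need at least 50 individuals for a null GWAS")
    rng = np.random.default_rng(seed)
    pheno = rng.normal(size=panel.n_individuals)
    rows = []
    n_mono = 0
    has_nan = np.isnan(panel.dosages).any()
    for i, snp in enumerate(panel.snps["snp"]):
        x = panel.dosages[i]
        if has_nan:
            mask = np.isfinite(x)
            xs, ys = x[mask], pheno[mask]
        else:
            xs, ys = x, pheno
        n = xs.size
        if n < 3 or xs.std() == 0.0:
            n_mono += 1
            continue
        r = np.corrcoef(xs, ys)[0, 1]
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
        z = np.sign(t) * sps.norm.isf(p / 2.0)
        rows.append((snp, float(z), float(p)))
    if n_mono:
        logger.warning("skipped %d monomorphic SNP(s) in null GWAS", n_mono)
    return pd.DataFrame(rows, columns=["snp", "z", "p"])


# ---------------------------------------------------------------------------
# sub-studies
# ---------------------------------------------------------------------------

def simulate_substudies(truth: SyntheticTruth, n_studies: int,
                        noise_scale: float = 1.0,
                        seed: int = 0) -> SubStudySet:
    """Sub-studies sharing the truth's latent effects.

    Each study draws z = effect + noise_scale * N(0,1) per SNP, with the
    effect shared across studies, so the mean-times-sqrt(k) combination of
    all studies recovers the meta z-score in expectation.
    """
    if n_studies < 2:
        raise ValueError("need at least 2 sub-studies")
    rng = np.random.default_rng(seed)
    snp_ids = truth.table["snp"].to_numpy()
    effect = truth.table["effect"].to_numpy(dtype=float)
    studies, labels = [], []
    for s in range(n_studies):
        z = effect + noise_scale * rng.normal(size=len(snp_ids))
        studies.append(pd.DataFrame({
            "snp": snp_ids, "z": z, "p": z_to_p(z),
        }))
        labels.append(f"study{s + 1}")
    return SubStudySet(studies, labels)
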
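"""LD-weighted genic annotation of tag SNPs.

Pipeline: QC a reference panel, assign each panel SNP a single positional
category from gene models, compute windowed pairwise LD (r^2) around each
tag SNP, sum r^2 per category into continuous annotation scores, binarize
into (non-exclusive) memberships, and flag intergenic SNPs.

Coordinates are 0-based half-open internally; readers in :mod:`stratfdr.io`
convert from 1-based inclusive (GTF-style) input when asked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .constants import CATEGORIES, DEFAULT_PRECEDENCE, GENIC_ELEMENTS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One protein-coding transcript with element intervals.

    ``elements`` holds ``(category, start, end)`` tuples with category in
    ``GENIC_ELEMENTS`` and 0-based half-open genomic coordinates.
    ``tx_start``/``tx_end`` are the genomic transcript bounds
    (tx_start < tx_end regardless of strand; the transcription start site
    is ``tx_start`` on '+' and ``tx_end`` on '-').
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    elements: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "elements", tuple(self.elements))
        self.validate()

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(
                f"transcript {self.transcript_id}: tx_end <= tx_start"
            )
        exonic = []
        for cat, start, end in self.elements:
            if cat not in GENIC_ELEMENTS:
                raise ValueError(f"unknown element category {cat!r}")
            if end <= start:
                raise ValueError(
                    f"transcript {self.transcript_id}: element end <= start"
                )
            if start < self.tx_start or end > self.tx_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: element outside bounds"
                )
            if cat in ("exon", "intron"):
                exonic.append((start, end))
        exonic.sort()
        for (s0, e0), (s1, e1) in zip(exonic, exonic[1:]):
            if s1 < e0:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping "
                    "exon/intron intervals"
                )


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of LD-weighted annotation scoring.

    Defaults are the primary configuration (r^2 >= 0.2 within 1 Mb, score
    threshold 1.0); the robustness configuration uses ``r2_min=0.05,
    window=2_000_000``.
    """

    r2_min: float = 0.2
    window: int = 1_000_000
    score_threshold: float = 1.0
    precedence: tuple = DEFAULT_PRECEDENCE

    def __post_init__(self):
        if not 0.0 < self.r2_min < 1.0:
            raise ValueError("r2_min must lie in (0, 1)")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be positive")
        if set(self.precedence) != set(CATEGORIES):
            raise ValueError("precedence must order all eight categories")


@dataclass
class ReferencePanel:
    """Bi-allelic SNP dosages over individuals.

    ``snps`` has columns snp/chrom/pos (positions strictly increasing
    within chromosome); ``dosages`` is (n_snps, n_individuals) float with
    values {0, 1, 2} and NaN for missing.
    """

    snps: pd.DataFrame
    dosages: np.ndarray
    individuals: list

    def __post_init__(self):
        if len(self.snps) != self.dosages.shape[0]:
            raise ValueError("snps and dosages row counts differ")
        if len(self.individuals) != self.dosages.shape[1]:
            raise ValueError("individuals and dosages column counts differ")
        for _, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    "positions must be strictly increasing within chromosome"
                )
        valid = self.dosages[np.isfinite(self.dosages)]
        if valid.size and not np.isin(valid, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP, ignoring missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=1) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def snp_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def individual_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def hwe_pvalues(self) -> np.ndarray:
        """1-df chi-square goodness-of-fit p-value per SNP.

        Observed genotype counts (0/1/2) against Hardy-Weinberg expectation
        at the observed allele frequency; monomorphic SNPs get p = 1.
        """
        pvals = np.ones(self.n_snps)
        for i in range(self.n_snps):
            row = self.dosages[i]
            row = row[np.isfinite(row)]
            n = row.size
            if n == 0:
                continue
            counts = np.array([(row == g).sum() for g in (0.0, 1.0, 2.0)])
            f = counts @ np.array([0, 1, 2]) / (2.0 * n)
            if f in (0.0, 1.0):
                continue
            expect = n * np.array(
                [(1 - f) ** 2, 2 * f * (1 - f), f ** 2]
            )
            stat = ((counts - expect) ** 2 / expect).sum()
            pvals[i] = sps.chi2.sf(stat, df=1)
        return pvals


@dataclass(frozen=True)
class LDNeighborhood:
    """Thresholded r^2 partners of one tag SNP (always includes self=1.0)."""

    tag: str
    partners: dict  # partner snp id -> r^2 in [r2_min, 1.0]

    def total_ld(self) -> float:
        return float(sum(self.partners.values()))


@dataclass(frozen=True)
class AnnotationProfile:
    """LD-weighted annotation of one tag SNP."""

    snp: str
    chrom: str
    pos: int
    scores: dict  # category -> summed r^2
    memberships: dict  # category -> bool, score >= threshold
    intergenic: bool
    total_ld: float
    n_tagged: int


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Tabulate profiles: snp/chrom/pos, score_*, member_*, intergenic, ..."""
    rows = []
    for pr in profiles:
        row = {"snp": pr.snp, "chrom": pr.chrom, "pos": pr.pos}
        for c in CATEGORIES:
            row[f"score_{c}"] = pr.scores.get(c, 0.0)
        for c in CATEGORIES:
            row[f"member_{c}"] = int(pr.memberships.get(c, False))
        row["intergenic"] = int(pr.intergenic)
        row["total_ld"] = pr.total_ld
        row["n_tagged"] = pr.n_tagged
        rows.append(row)
    return pd.DataFrame(rows)


def as_profile_frame(profiles) -> pd.DataFrame:
    """Accept either a profile table or a list of AnnotationProfile."""
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return profiles_to_frame(profiles)


# ---------------------------------------------------------------------------
# reference-panel QC
# ---------------------------------------------------------------------------

def qc_reference_panel(panel: ReferencePanel, maf_min: float = 0.01,
                       snp_missing_max: float = 0.05,
                       hwe_p_min: float = 1e-6,
                       indiv_missing_max: float = 0.10) -> ReferencePanel:
    """Filter a reference panel.

    Individuals missing more than ``indiv_missing_max`` of genotypes are
    removed first; per-SNP MAF/missingness/HWE are then recomputed and SNPs
    failing any of MAF < ``maf_min``, missingness > ``snp_missing_max`` or
    HWE p < ``hwe_p_min`` are removed.

    Raises
    ------
    ValueError
        If the panel is empty, a threshold is outside [0, 1], or a filter
        removes every SNP/individual (the message names the filter).
    """
    if panel.n_snps == 0:
        raise ValueError("empty reference panel")
    for name, val in (("maf_min", maf_min),
                      ("snp_missing_max", snp_missing_max),
                      ("hwe_p_min", hwe_p_min),
                      ("indiv_missing_max", indiv_missing_max)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")

    keep_ind = panel.individual_missingness() <= indiv_missing_max
    if not keep_ind.any():
        raise ValueError(
            "individual missingness filter removed all individuals"
        )
    panel = ReferencePanel(
        panel.snps.reset_index(drop=True),
        panel.dosages[:, keep_ind],
        [ind for ind, k in zip(panel.individuals, keep_ind) if k],
    )

    maf = panel.maf()
    miss = panel.snp_missingness()
    keep = (maf >= maf_min) & (miss <= snp_missing_max)
    if not keep.any():
        which = "MAF" if not (maf >= maf_min).any() else "SNP missingness"
        raise ValueError(f"{which} filter removed all SNPs")
    # HWE is by far the slowest check; run it only on survivors.
    hwe_ok = np.zeros_like(keep)
    idx = np.flatnonzero(keep)
    sub = ReferencePanel(
        panel.snps.iloc[idx].reset_index(drop=True),
        panel.dosages[idx], panel.individuals,
    )
    hwe_ok[idx] = sub.hwe_pvalues() >= hwe_p_min
    keep &= hwe_ok
    if not keep.any():
        raise ValueError("HWE filter removed all SNPs")
    return ReferencePanel(
        panel.snps.loc[keep].reset_index(drop=True),
        panel.dosages[keep],
        panel.individuals,
    )


# ---------------------------------------------------------------------------
# positional categories
# ---------------------------------------------------------------------------

def _flank_category(pos: int, gene: GeneModel) -> str | None:
    """Strand-aware flank category of ``pos`` relative to ``gene``."""
    if gene.strand == "+":
        tss, tes = gene.tx_start, gene.tx_end
        up = tss - pos  # bp upstream of TSS (>0 means upstream)
        down = pos - tes + 1  # bp downstream of transcript end
    else:
        tss, tes = gene.tx_end, gene.tx_start
        up = pos - tss + 1
        down = tes - pos
    if 1 <= up <= 1000:
        return "1k_up"
    if 1000 < up <= 10_000:
        return "10k_up"
    if 1 <= down <= 1000:
        return "1k_down"
    if 1000 < down <= 10_000:
        return "10k_down"
    return None


def assign_positional_category(chrom: str, pos: int, genes,
                               precedence=DEFAULT_PRECEDENCE) -> str | None:
    """Single mutually exclusive category of a genomic position.

    Element intervals win over flanks within a gene; across genes the
    configured precedence resolves conflicts.  Returns None when no gene
    element or 10-kb flank covers the position.
    """
    candidates = set()
    for gene in genes:
        if gene.chrom != chrom:
            continue
        hit = None
        if gene.tx_start <= pos < gene.tx_end:
            for cat, start, end in gene.elements:
                if start <= pos < end:
                    hit = cat
                    break
        if hit is None:
            hit = _flank_category(pos, gene)
        if hit is not None:
            candidates.add(hit)
    if not candidates:
        return None
    for cat in precedence:
        if cat in candidates:
            return cat
    raise AssertionError("unreachable: candidate outside precedence")


def assign_positional_categories(panel: ReferencePanel, genes,
                                 precedence=DEFAULT_PRECEDENCE) -> pd.Series:
    """Vector of positional categories for every panel SNP (None allowed)."""
    cats = [
        assign_positional_category(chrom, pos, genes, precedence)
        for chrom, pos in zip(panel.snps["chrom"], panel.snps["pos"])
    ]
    return pd.Series(cats, index=panel.snps["snp"].to_numpy(), dtype=object)


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------

def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation over pairwise-complete observations.

    Returns None when fewer than 2 complete pairs remain or either vector
    is constant (monomorphic) on the complete subset.
    """
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 2:
        return None
    xs, ys = x[mask], y[mask]
    sx, sy = xs.std(), ys.std()
    if sx == 0.0 or sy == 0.0:
        return None
    r = ((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy)
    return float(r * r)


def compute_pairwise_ld(panel: ReferencePanel, tag_snps,
                        config: ScoringConfig = ScoringConfig()):
    """Thresholded LD neighborhoods of the given tag SNPs.

    r^2 is the squared dosage correlation over pairwise-complete
    individuals; pairs beyond ``config.window`` bp or below
    ``config.r2_min`` are dropped; each tag carries (self, 1.0).  Tag ids
    absent from the panel are dropped with a logged count.  Monomorphic
    partners are skipped with a logged warning.
    """
    ids = panel.snps["snp"].to_numpy()
    index = {s: i for i, s in enumerate(ids)}
    chroms = panel.snps["chrom"].to_numpy()
    positions = panel.snps["pos"].to_numpy()
    missing = [t for t in tag_snps if t not in index]
    if missing:
        logger.info(
            "%d tag SNP(s) absent from the reference panel were dropped",
            len(missing),
        )
    has_nan = np.isnan(panel.dosages).any()
    n_monomorphic = 0
    out = []
    for tag in tag_snps:
        if tag not in index:
            continue
        i = index[tag]
        chrom, pos = chroms[i], positions[i]
        in_window = np.flatnonzero(
            (chroms == chrom) & (np.abs(positions - pos) <= config.window)
        )
        partners = {tag: 1.0}
        y = panel.dosages[i]
        if has_nan:
            for j in in_window:
                if j == i:
                    continue
                r2 = _pairwise_r2(panel.dosages[j], y)
                if r2 is None:
                    n_monomorphic += 1
                elif r2 >= config.r2_min:
                    partners[ids[j]] = r2
        else:
            block = panel.dosages[in_window]
            sy = y.std()
            if sy == 0.0:
                n_monomorphic += len(in_window) - 1
            else:
                centered = block - block.mean(axis=1, keepdims=True)
                sx = block.std(axis=1)
                ok = sx > 0.0
                n_monomorphic += int((~ok).sum())
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = (centered @ (y - y.mean())) / y.size / (sx * sy)
                r2 = r * r
                for j, val, good in zip(in_window, r2, ok):
                    if j == i or not good:
                        continue
                    if val >= config.r2_min:
                        partners[ids[j]] = float(val)
        out.append(LDNeighborhood(tag, partners))
    if n_monomorphic:
        logger.warning(
            "skipped %d monomorphic pair(s) with undefined r^2", n_monomorphic
        )
    return out


# ---------------------------------------------------------------------------
# LD-weighted scores and intergenic flag
# ---------------------------------------------------------------------------

def ld_weighted_scores(neighborhoods, positional, snp_positions,
                       config: ScoringConfig = ScoringConfig()):
    """Sum partner r^2 into per-category annotation scores.

    ``positional`` maps panel SNP id -> category (or None); ``snp_positions``
    maps id -> (chrom, pos) for the output coordinates.  Membership in a
    category requires score >= ``config.score_threshold``; memberships are
    non-exclusive.  The intergenic flag is initialized False here (see
    :func:`flag_intergenic`).
    """
    profiles = []
    for nb in neighborhoods:
        if nb.tag not in nb.partners:
            raise ValueError(
                f"neighborhood of {nb.tag!r} is missing its self pair"
            )
        scores = {c: 0.0 for c in CATEGORIES}
        for partner, r2 in nb.partners.items():
            cat = positional.get(partner)
            if cat is not None:
                scores[cat] += r2
        members = {
            c: scores[c] >= config.score_threshold for c in CATEGORIES
        }
        chrom, pos = snp_positions[nb.tag]
        profiles.append(AnnotationProfile(
            snp=nb.tag, chrom=chrom, pos=int(pos), scores=scores,
            memberships=members, intergenic=False,
            total_ld=nb.total_ld(), n_tagged=len(nb.partners),
        ))
    return profiles


class _IntervalIndex:
    """Merged per-chromosome intervals with O(log n) point queries."""

    def __init__(self, intervals):
        # intervals: iterable of (chrom, start, end), half-open
        by_chrom = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._merged = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([s for s, _ in merged])
            ends = np.array([e for _, e in merged])
            self._merged[chrom] = (starts, ends)

    def contains(self, chrom, pos) -> bool:
        if chrom not in self._merged:
            return False
        starts, ends = self._merged[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]


def flag_intergenic(profiles, neighborhoods, genes, snp_positions,
                    masks=None, gene_buffer: int = 100_000):
    """Set the intergenic flag on annotation profiles.

    A tag SNP is intergenic iff all eight scores are zero AND no LD partner
    (including itself) lies within ``gene_buffer`` bp of a protein-coding
    gene or inside any provided mask interval set (noncoding RNA, TFBS,
    miRNA binding sites, as BED-like (chrom, start, end) triples).  With
    ``masks=None`` the mask criterion is skipped with a logged warning.
    """
    if masks is None:
        logger.warning(
            "no functional masks provided; intergenic flag uses only the "
            "gene-proximity criterion"
        )
        mask_idx = None
    else:
        flat = [iv for mask in masks for iv in mask]
        mask_idx = _IntervalIndex(flat)
    near_genes = _IntervalIndex(
        (g.chrom, g.tx_start - gene_buffer, g.tx_end + gene_buffer)
        for g in genes
    )
    nb_by_tag = {nb.tag: nb for nb in neighborhoods}
    out = []
    for pr in profiles:
        if pr.snp not in nb_by_tag:
            raise ValueError(f"no LD neighborhood for profile {pr.snp!r}")
        if any(v > 0.0 for v in pr.scores.values()):
            out.append(replace(pr, intergenic=False))
            continue
        clean = True
        for partner in nb_by_tag[pr.snp].partners:
            chrom, pos = snp_positions[partner]
            if near_genes.contains(chrom, pos):
                clean = False
                break
            if mask_idx is not None and mask_idx.contains(chrom, pos):
                clean = False
                break
        out.append(replace(pr, intergenic=clean))
    return out


def annotate_tag_snps(panel: ReferencePanel, genes, tag_snps,
                      config: ScoringConfig = ScoringConfig(),
                      masks=None) -> pd.DataFrame:
    """Convenience wrapper: positional categories -> LD -> scores -> flag.

    Returns the annotation table (see :func:`profiles_to_frame`) with an
    extra ``category`` column holding the tag SNP's own positional
    category.
    """
    positional = assign_positional_categories(panel, genes, config.precedence)
    neighborhoods = compute_pairwise_ld(panel, tag_snps, config)
    positions = {
        s: (c, p) for s, c, p in zip(
            panel.snps["snp"], panel.snps["chrom"], panel.snps["pos"]
        )
    }
    profiles = ld_weighted_scores(
        neighborhoods, positional.to_dict(), positions, config
    )
    profiles = flag_intergenic(
        profiles, neighborhoods, genes, positions, masks=masks
    )
    frame = profiles_to_frame(profiles)
    frame["category"] = [
        positional.get(s) for s in frame["snp"]
    ]
    return frame
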
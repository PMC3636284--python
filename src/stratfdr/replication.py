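"""Discovery/replication evaluation across sub-study splits.

Sub-studies contributing to a meta-analysis are split into all possible
half/half discovery and replication sets; z-scores are combined per half as
mean x sqrt(k); discovery significance uses two-tailed p-values and
replication uses one-tailed p-values preserving the discovery effect
direction.  Cumulative replication-rate curves and rank-based comparisons
of sFDR- vs FDR-ordered SNPs are built on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .inflation import apply_inflation_control, estimate_lambda_gc

logger = logging.getLogger(__name__)


@dataclass
class SubStudySet:
    """Per-study summary tables over a common SNP set.

    Construction intersects the studies' SNP ids (dropped ids are logged)
    and aligns every table to the shared id order.
    """

    studies: list  # list of summary DataFrames
    labels: list
    inflation: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.studies) != len(self.labels):
            raise ValueError("labels and studies differ in length")
        common = set(self.studies[0]["snp"])
        total = set()
        for st in self.studies:
            total |= set(st["snp"])
            common &= set(st["snp"])
        dropped = len(total) - len(common)
        if dropped:
            logger.info(
                "dropped %d SNP(s) missing from at least one sub-study",
                dropped,
            )
        if not common:
            raise ValueError("sub-studies share no SNPs")
        order = sorted(common)
        self.studies = [
            st[st["snp"].isin(common)]
            .set_index("snp").loc[order].reset_index()
            for st in self.studies
        ]

    @property
    def snp_ids(self):
        return self.studies[0]["snp"].to_numpy()

    def z_matrix(self) -> pd.DataFrame:
        """(n_snps, n_studies) z-score matrix indexed by SNP id."""
        return pd.DataFrame(
            {lab: st["z"].to_numpy() for lab, st in
             zip(self.labels, self.studies)},
            index=self.snp_ids,
        )

    def correct_inflation(self, intergenic_ids=None,
                          quantile: float = 0.5) -> "SubStudySet":
        """Independently inflation-correct each study (intergenic subset)."""
        corrected, estimates = [], []
        for st in self.studies:
            subset = None if intergenic_ids is None else \
                st["snp"].isin(intergenic_ids).to_numpy()
            est = estimate_lambda_gc(
                st, subset=subset, quantile=quantile,
                subset_label="all" if intergenic_ids is None else "intergenic",
            )
            corrected.append(apply_inflation_control(st, est))
            estimates.append(est)
        out = SubStudySet(corrected, list(self.labels))
        out.inflation = estimates
        return out


def enumerate_splits(labels, k: int):
    """All C(n, k) (discovery, replication) label splits, k = n/2.

    Every size-k subset serves as discovery once, with its complement as
    replication; 8 studies with k = 4 yield 70 splits.
    """
    labels = list(labels)
    n = len(labels)
    if n % 2 != 0:
        raise ValueError("sub-study count must be even")
    if k != n // 2:
        raise ValueError(f"k must be n/2 = {n // 2}, got {k}")
    splits = []
    for disc in combinations(labels, k):
        rep = tuple(l for l in labels if l not in disc)
        splits.append((disc, rep))
    return splits


def combine_z(per_study_z) -> np.ndarray:
    """Equal-weight combination: mean across studies times sqrt(k).

    ``per_study_z`` is (n_snps, k) (or a length-k vector for one SNP).
    The sqrt(k) factor preserves unit variance for independent N(0,1)
    inputs.  Rows with missing values return NaN (callers drop and log).
    """
    z = np.asarray(per_study_z, dtype=float)
    k = z.shape[-1]
    if k < 1:
        raise ValueError("need at least one study")
    return z.mean(axis=-1) * np.sqrt(k)


def discovery_replication_pvalues(z_disc, z_rep):
    """(two-tailed discovery p, one-tailed replication p) for z pairs.

    The replication tail preserves the discovery effect direction:
    p_rep = 1 - Phi(z_rep * sign(z_disc)).  A discovery z of exactly 0 is
    treated as '+' with a warning.
    """
    z_disc = np.asarray(z_disc, dtype=float)
    z_rep = np.asarray(z_rep, dtype=float)
    sign = np.where(z_disc < 0, -1.0, 1.0)
    if np.any(z_disc == 0):
        logger.warning(
            "discovery z == 0 for %d SNP(s); direction taken as '+'",
            int((z_disc == 0).sum()),
        )
    p_disc = 2.0 * sps.norm.sf(np.abs(z_disc))
    p_rep = sps.norm.sf(z_rep * sign)
    return p_disc, p_rep


@dataclass
class ReplicationCurve:
    """Cumulative replication rates over discovery-significance bins."""

    bin_edges: np.ndarray  # lower bounds on the -log10 discovery-p axis
    rates: pd.DataFrame  # (n_bins, categories); NaN where undefined
    overall: pd.Series  # per-category overall replication rate (intercept)
    rep_alpha: float
    n_splits: int


def _split_pvalues(zmat: pd.DataFrame, disc_labels, rep_labels):
    """Combined discovery/replication p-values for one split; NaN rows dropped."""
    zd = combine_z(zmat[list(disc_labels)].to_numpy())
    zr = combine_z(zmat[list(rep_labels)].to_numpy())
    ok = np.isfinite(zd) & np.isfinite(zr)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("dropped %d SNP(s) with missing study z in a split",
                    n_drop)
    p_disc, p_rep = discovery_replication_pvalues(zd[ok], zr[ok])
    return pd.DataFrame(
        {"p_disc": p_disc, "p_rep": p_rep}, index=zmat.index[ok]
    )


def cumulative_replication_curve(studies: SubStudySet, strata,
                                 n_bins: int = 1000,
                                 rep_alpha: float = 0.05) -> ReplicationCurve:
    """Average cumulative replication rate per stratum over all splits.

    For each split and each bin lower bound b, the rate is the proportion
    of stratum SNPs with -log10 discovery p > b whose one-tailed
    replication p < ``rep_alpha``.  Bins are ``n_bins`` equally spaced
    lower bounds spanning the -log10 discovery-p range pooled over splits
    (shared across strata).  Bins with no qualifying SNPs are undefined
    (NaN) and excluded from the split average.  The overall rate (curve
    intercept) is the rate with no discovery threshold.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    splits = enumerate_splits(studies.labels, len(studies.labels) // 2)
    zmat = studies.z_matrix()
    per_split = [
        _split_pvalues(zmat, disc, rep) for disc, rep in splits
    ]
    nlp_max = max(
        (-np.log10(ps["p_disc"])).max() for ps in per_split
    )
    edges = np.linspace(0.0, nlp_max, n_bins, endpoint=False)

    labels = [s.label for s in strata]
    sums = np.zeros((n_bins, len(strata)))
    counts = np.zeros((n_bins, len(strata)), dtype=int)
    overall_sum = np.zeros(len(strata))
    overall_n = np.zeros(len(strata), dtype=int)
    for ps in per_split:
        nlp = -np.log10(ps["p_disc"].to_numpy())
        hit = (ps["p_rep"].to_numpy() < rep_alpha)
        for j, stratum in enumerate(strata):
            member = ps.index.isin(stratum.ids)
            if not member.any():
                continue  # empty in this split: contributes nothing
            nlp_m, hit_m = nlp[member], hit[member]
            order = np.argsort(nlp_m)
            nlp_s = nlp_m[order]
            # suffix counts: SNPs strictly above each bin's lower bound
            above = len(nlp_s) - np.searchsorted(nlp_s, edges, side="right")
            hits_cum = np.concatenate(
                [np.cumsum(hit_m[order][::-1])[::-1], [0]]
            )
            hits_above = hits_cum[len(nlp_s) - above]
            defined = above > 0
            sums[defined, j] += hits_above[defined] / above[defined]
            counts[defined, j] += 1
            overall_sum[j] += hit_m.mean()
            overall_n[j] += 1
    with np.errstate(invalid="ignore"):
        rates = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        overall = np.where(overall_n > 0, overall_sum /
                           np.maximum(overall_n, 1), np.nan)
    return ReplicationCurve(
        bin_edges=edges,
        rates=pd.DataFrame(rates, columns=labels),
        overall=pd.Series(overall, index=labels),
        rep_alpha=rep_alpha,
        n_splits=len(splits),
    )


def _stratum_adjusted_order(p: pd.Series, stratum_of: pd.Series) -> list:
    """SNP ids ordered by within-stratum BH adjusted p (ties by p, then id)."""
    qvals = pd.Series(index=p.index, dtype=float)
    for _, ids in p.groupby(stratum_of).groups.items():
        ps = p.loc[ids].sort_values(kind="mergesort")
        m = len(ps)
        raw = ps.to_numpy() * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(raw[::-1])[::-1]
        qvals.loc[ps.index] = q
    frame = pd.DataFrame({"q": qvals, "p": p})
    frame = frame.sort_values(["q", "p"], kind="mergesort")
    return list(frame.index)


def rank_replication_comparison(studies: SubStudySet, sfdr_result,
                                ranks=(100, 500, 1000),
                                rep_alpha: float = 0.05) -> pd.DataFrame:
    """Replication of top-ranked SNPs: pooled-p vs stratum-adjusted ranking.

    For every split and rank cutoff R, computes the proportion of the top R
    SNPs that replicate (one-tailed p < ``rep_alpha``) when SNPs are
    ordered (a) by pooled discovery p-value and (b) by the within-stratum
    BH level at which they are first rejected (ties by p).  Strata come
    from ``sfdr_result.table``.  Returns mean proportions across splits.
    """
    stratum_of = sfdr_result.table.set_index("snp")["stratum"]
    splits = enumerate_splits(studies.labels, len(studies.labels) // 2)
    zmat = studies.z_matrix()
    ranks = list(ranks)
    acc = {(r, m): [] for r in ranks for m in ("unadjusted", "adjusted")}
    for disc, rep in splits:
        ps = _split_pvalues(zmat, disc, rep)
        common = ps.index.intersection(stratum_of.index)
        ps = ps.loc[common]
        hit = (ps["p_rep"] < rep_alpha)
        pooled = list(
            ps["p_disc"].sort_values(kind="mergesort").index
        )
        adjusted = _stratum_adjusted_order(
            ps["p_disc"], stratum_of.loc[common]
        )
        for r in ranks:
            if r > len(ps):
                logger.warning(
                    "rank cutoff %d exceeds SNP count %d; truncated",
                    r, len(ps),
                )
            r_eff = min(r, len(ps))
            acc[(r, "unadjusted")].append(hit.loc[pooled[:r_eff]].mean())
            acc[(r, "adjusted")].append(hit.loc[adjusted[:r_eff]].mean())
    return pd.DataFrame({
        "rank": ranks,
        "unadjusted": [np.mean(acc[(r, "unadjusted")]) for r in ranks],
        "adjusted": [np.mean(acc[(r, "adjusted")]) for r in ranks],
    })
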
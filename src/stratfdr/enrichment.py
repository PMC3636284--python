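"""Stratified Q-Q curves, conservative FDR/TDR, and enrichment statistics.

The central object is a per-stratum curve relating each SNP's nominal
p-value ``p`` to its within-stratum empirical quantile ``q``.  Because the
theoretical null cdf is uniform, ``p/q`` (with the null proportion set
conservatively to 1) estimates the FDR at threshold p, and ``1 - p/q`` the
TDR; on the -log10 scale the FDR is the horizontal shift of the curve off
the x = y line.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import as_profile_frame
from .constants import CATEGORIES, SCORE_COLUMNS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Stratum:
    """A labeled SNP subset used as one Q-Q / FDR stratum."""

    label: str
    ids: frozenset
    source: str = "user"

    def __post_init__(self):
        object.__setattr__(self, "ids", frozenset(self.ids))
        if not self.ids:
            raise ValueError(f"stratum {self.label!r} is empty")


def strata_from_annotations(profiles, include_all_ids=None,
                            min_members: int = 1):
    """Build category/intergenic strata from an annotation table.

    One stratum per annotation category with >= ``min_members`` member tag
    SNPs, plus 'intergenic' and (when ``include_all_ids`` is given) 'all'.
    """
    frame = as_profile_frame(profiles)
    strata = []
    if include_all_ids is not None:
        strata.append(Stratum("all", frozenset(include_all_ids), "all"))
    for cat in CATEGORIES:
        ids = frame.loc[frame[f"member_{cat}"] == 1, "snp"]
        if len(ids) >= min_members:
            strata.append(Stratum(cat, frozenset(ids), "annotation category"))
    inter = frame.loc[frame["intergenic"] == 1, "snp"]
    if len(inter) >= min_members:
        strata.append(Stratum("intergenic", frozenset(inter), "intergenic"))
    return strata


def empirical_cdf(p_values) -> np.ndarray:
    """Empirical quantile q(p) = #{p_i <= p} / N for each input p.

    Ties share the same q (<= counting); q at the largest p is exactly 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empirical_cdf of an empty vector")
    order = np.sort(p)
    return np.searchsorted(order, p, side="right") / p.size


def stratified_qq(stats: pd.DataFrame, strata,
                  include_all: bool = True) -> pd.DataFrame:
    """Per-stratum Q-Q curves on the -log10 / -log10 scale.

    Returns a long table with columns stratum/snp/p/q/nlog10_p/nlog10_q,
    one row per (stratum, member SNP); q is the empirical cdf within the
    stratum.  An 'all' stratum over every SNP is prepended unless one is
    supplied or ``include_all=False``.  Strata with fewer than 10 SNPs get
    a warning but still produce a curve.  No display capping is applied
    here: plotting may cap at -log10 p = 7.3, computation never does.
    """
    strata = list(strata)
    if include_all and not any(s.label == "all" for s in strata):
        strata.insert(
            0, Stratum("all", frozenset(stats["snp"]), "all")
        )
    pieces = []
    for stratum in strata:
        sub = stats[stats["snp"].isin(stratum.ids)]
        if sub.empty:
            raise ValueError(
                f"stratum {stratum.label!r} has no SNPs in the table"
            )
        if len(sub) < 10:
            warnings.warn(
                f"stratum {stratum.label!r} has only {len(sub)} SNPs",
                stacklevel=2,
            )
        p = sub["p"].to_numpy(dtype=float)
        q = empirical_cdf(p)
        pieces.append(pd.DataFrame({
            "stratum": stratum.label,
            "snp": sub["snp"].to_numpy(),
            "p": p,
            "q": q,
            "nlog10_p": -np.log10(p),
            "nlog10_q": -np.log10(q),
        }))
    return pd.concat(pieces, ignore_index=True)


def estimate_fdr_tdr(curves: pd.DataFrame) -> pd.DataFrame:
    """Fill conservative FDR/TDR columns on a stratified Q-Q table.

    FDR(p) = min(1, p/q) with the null proportion fixed at 1; TDR = 1-FDR.
    """
    out = curves.copy()
    out["fdr"] = np.minimum(1.0, out["p"] / out["q"])
    out["tdr"] = 1.0 - out["fdr"]
    return out


@dataclass(frozen=True)
class EnrichmentScore:
    stratum: str
    raw: float  # mean(z^2) - 1
    normalized: float  # raw / max raw across strata
    n_snps: int


def enrichment_scores(stats: pd.DataFrame, strata):
    """mean(z^2) - 1 per stratum, normalized by the per-run maximum.

    The raw score conservatively estimates the effect variance contributed
    by non-null SNPs (null z^2 has mean 1); the stratum attaining the
    maximum gets normalized score exactly 1.
    """
    raw = {}
    counts = {}
    for stratum in strata:
        z = stats.loc[stats["snp"].isin(stratum.ids), "z"].to_numpy(float)
        if z.size == 0:
            raise ValueError(f"stratum {stratum.label!r} has no SNPs")
        raw[stratum.label] = float(np.mean(z ** 2) - 1.0)
        counts[stratum.label] = z.size
    top = max(raw.values())
    return [
        EnrichmentScore(lab, val, val / top if top != 0 else np.nan,
                        counts[lab])
        for lab, val in raw.items()
    ]


def ld_prune_random(snp_ids, neighborhoods, r2_max: float = 0.2,
                    seed: int = 0):
    """Greedy random LD pruning to approximate independence.

    SNPs are visited in a seeded random order; a SNP is kept iff no
    already-kept SNP is an LD partner at r^2 >= ``r2_max``.  Deterministic
    given the seed; no retained pair reaches ``r2_max``.
    """
    snp_ids = list(snp_ids)
    wanted = set(snp_ids)
    adjacency = {s: set() for s in snp_ids}
    for nb in neighborhoods:
        if nb.tag not in wanted:
            continue
        for partner, r2 in nb.partners.items():
            if partner == nb.tag or partner not in wanted:
                continue
            if r2 >= r2_max:
                adjacency[nb.tag].add(partner)
                adjacency[partner].add(nb.tag)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(snp_ids))
    kept = set()
    result = []
    for idx in order:
        snp = snp_ids[idx]
        if adjacency[snp] & kept:
            continue
        kept.add(snp)
        result.append(snp)
    return result


@dataclass(frozen=True)
class KSEnrichmentResult:
    stratum: str
    reference: str
    statistic: float  # lower-median KS statistic over repetitions
    p_value: float  # p-value of the repetition attaining it
    repetitions: int
    seed: int


def ks_enrichment_test(stats: pd.DataFrame, stratum, reference,
                       neighborhoods, repetitions: int = 10, seed: int = 0,
                       r2_max: float = 0.2,
                       values: str = "z") -> KSEnrichmentResult:
    """Two-sample KS test of a stratum against a reference stratum.

    Each repetition independently re-prunes both strata for LD (fresh
    derived seed) and compares the pruned test statistics; the reported
    p-value corresponds to the (lower-)median KS statistic across
    repetitions.  ``values`` selects signed z (default), 'abs_z' or 'p'.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    column = {"z": "z", "abs_z": "z", "p": "p"}[values]
    table = stats.set_index("snp")[column]
    seeds = np.random.SeedSequence(seed).generate_state(2 * repetitions)
    results = []
    for rep in range(repetitions):
        a_ids = ld_prune_random(
            sorted(stratum.ids), neighborhoods, r2_max, seeds[2 * rep]
        )
        b_ids = ld_prune_random(
            sorted(reference.ids), neighborhoods, r2_max, seeds[2 * rep + 1]
        )
        if not a_ids or not b_ids:
            raise ValueError("stratum empty after LD pruning")
        a = table.loc[a_ids].to_numpy(dtype=float)
        b = table.loc[b_ids].to_numpy(dtype=float)
        if values == "abs_z":
            a, b = np.abs(a), np.abs(b)
        ks = sps.ks_2samp(a, b)
        results.append((float(ks.statistic), float(ks.pvalue)))
    results.sort()
    stat, pval = results[(repetitions - 1) // 2]
    return KSEnrichmentResult(
        stratum.label, reference.label, stat, pval, repetitions, seed
    )


def covariate_regression(stats: pd.DataFrame, profiles,
                         response: str = "log_z2") -> pd.DataFrame:
    """OLS of z^2 (or log z^2) on annotation scores plus LD/MAF covariates.

    The design holds the eight continuous category scores, total LD,
    tagged-SNP count, MAF when present in ``stats``, and an intercept.
    Returns a coefficient table (coef/se/t/p indexed by term).

    Raises
    ------
    ValueError
        For a rank-deficient design; the message names the collinear
        columns found by pivoted QR.
    """
    import statsmodels.api as sm

    frame = as_profile_frame(profiles)
    merged = stats.merge(frame, on="snp", how="inner", suffixes=("", "_ann"))
    if merged.empty:
        raise ValueError("no overlap between stats and profiles")
    z2 = merged["z"].to_numpy(dtype=float) ** 2
    if response == "z2":
        y = z2
    elif response == "log_z2":
        y = np.log(np.maximum(z2, 1e-12))
    else:
        raise ValueError("response must be 'z2' or 'log_z2'")
    cols = list(SCORE_COLUMNS) + ["total_ld", "n_tagged"]
    if "maf" in merged.columns and merged["maf"].notna().all():
        cols.append("maf")
    X = merged[cols].to_numpy(dtype=float)
    _check_full_rank(X, cols)
    model = sm.OLS(y, sm.add_constant(pd.DataFrame(X, columns=cols)))
    fit = model.fit()
    return pd.DataFrame({
        "coef": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })


def _check_full_rank(X: np.ndarray, names) -> None:
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # pivoted QR: the trailing pivots with ~zero diagonal are the
        # columns expressible from the preceding ones
        from scipy.linalg import qr

        _, r, piv = qr(design, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = [piv[i] for i in range(len(diag)) if diag[i] < tol]
        labels = ["const"] + list(names)
        bad_names = [labels[i] for i in bad]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            f"collinear columns: {bad_names}"
        )
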
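"""Stratified false-discovery-rate control.

A linear model trained on one study's z^2 predicts each SNP's tagged
variance from its unthresholded LD-weighted annotation scores; SNPs are
ranked by the prediction and partitioned into near-equal strata; the
fixed-rejection-region FDR rule (equivalent to Benjamini-Hochberg) is then
applied within each stratum, and the rejection count is compared with
unstratified control at the same level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import as_profile_frame
from .constants import SCORE_COLUMNS
from .enrichment import Stratum, _check_full_rank, ld_prune_random

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaggedVarianceModel:
    """OLS weights predicting z^2 from the eight annotation scores."""

    intercept: float
    weights: pd.Series  # indexed by SCORE_COLUMNS
    training_label: str

    def __post_init__(self):
        if list(self.weights.index) != list(SCORE_COLUMNS):
            raise ValueError("weights must cover the eight score columns")

    def predict(self, profiles) -> pd.Series:
        frame = as_profile_frame(profiles)
        X = frame[list(SCORE_COLUMNS)].to_numpy(dtype=float)
        pred = self.intercept + X @ self.weights.to_numpy()
        return pd.Series(pred, index=frame["snp"].to_numpy())


def fit_tagged_variance_model(training_stats: pd.DataFrame, profiles,
                              label: str = "training") -> TaggedVarianceModel:
    """Train the z^2-on-scores regression on one (inflation-corrected) study.

    Score columns that are constant in the training data (categories with
    no scored SNPs) carry no information: they are dropped from the fit
    with a logged warning and get weight 0.  Genuine collinearity among
    the informative columns raises.
    """
    import statsmodels.api as sm

    frame = as_profile_frame(profiles)
    merged = training_stats.merge(frame, on="snp", how="inner")
    if merged.empty:
        raise ValueError("no overlap between training stats and profiles")
    y = merged["z"].to_numpy(dtype=float) ** 2
    cols = list(SCORE_COLUMNS)
    X_full = merged[cols]
    constant = [c for c in cols if X_full[c].nunique() <= 1]
    if constant:
        logger.warning(
            "score column(s) %s constant in training data; weight set to 0",
            constant,
        )
    used = [c for c in cols if c not in constant]
    if not used:
        raise ValueError("every score column is constant; cannot train")
    X = X_full[used].to_numpy(dtype=float)
    _check_full_rank(X, used)
    fit = sm.OLS(y, sm.add_constant(pd.DataFrame(X, columns=used))).fit()
    weights = pd.Series(0.0, index=cols)
    weights[used] = fit.params[used]
    return TaggedVarianceModel(
        intercept=float(fit.params["const"]),
        weights=weights,
        training_label=label,
    )


def predict_strata(model: TaggedVarianceModel, profiles,
                   n_strata: int = 5):
    """Partition SNPs into rank strata of predicted tagged variance.

    Near-equal-size strata ordered from lowest to highest prediction; ties
    broken deterministically by SNP id.  ``stratum_{n_strata}`` holds the
    SNPs predicted most enriched.
    """
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    pred = model.predict(profiles)
    if n_strata > len(pred):
        raise ValueError(
            f"n_strata={n_strata} exceeds SNP count {len(pred)}"
        )
    order = pred.reset_index().rename(columns={"index": "snp", 0: "pred"})
    order = order.sort_values(["pred", "snp"], kind="mergesort")
    chunks = np.array_split(order["snp"].to_numpy(), n_strata)
    return [
        Stratum(f"stratum_{i + 1}", frozenset(chunk), "predicted variance rank")
        for i, chunk in enumerate(chunks)
    ]


def fdr_fixed_rejection(p_values, alpha: float):
    """Benjamini-Hochberg rejections via the fixed-rejection-region rule.

    Rejects all p <= p* where p* = max{p_(i) : p_(i) <= alpha * i / N}
    (step-up).  Returns ``(flags, p_star)``; p_star is NaN when nothing is
    rejected.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    n = p.size
    if n == 0:
        return np.zeros(0, dtype=bool), float("nan")
    order = np.sort(p)
    ranks = np.arange(1, n + 1)
    passing = order <= alpha * ranks / n
    if not passing.any():
        return np.zeros(n, dtype=bool), float("nan")
    p_star = order[np.flatnonzero(passing)[-1]]
    return p <= p_star, float(p_star)


@dataclass
class SFDRResult:
    """Per-SNP decisions of stratified vs unstratified FDR control."""

    table: pd.DataFrame  # snp, stratum, p, reject_stratified, reject_unstratified
    thresholds: dict  # stratum label -> p*
    alpha: float
    n_reject_stratified: int
    n_reject_unstratified: int

    @property
    def power_ratio(self):
        return power_ratio(self)


def stratified_fdr(stats: pd.DataFrame, strata, alpha: float) -> SFDRResult:
    """Apply per-stratum BH at level ``alpha`` and compare with pooled BH.

    ``strata`` must partition the SNPs of ``stats`` (overlap or incomplete
    cover raises).  Within each stratum the stratified decisions coincide
    with BH restricted to that stratum at the same alpha.
    """
    strata = list(strata)
    all_ids = [s for st in strata for s in st.ids]
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("strata overlap")
    if set(all_ids) != set(stats["snp"]):
        raise ValueError("strata must cover exactly the SNPs in the table")

    table = stats[["snp", "p"]].copy()
    table["stratum"] = ""
    table["reject_stratified"] = False
    thresholds = {}
    for stratum in strata:
        mask = table["snp"].isin(stratum.ids).to_numpy()
        flags, p_star = fdr_fixed_rejection(
            table.loc[mask, "p"].to_numpy(), alpha
        )
        table.loc[mask, "stratum"] = stratum.label
        table.loc[mask, "reject_stratified"] = flags
        thresholds[stratum.label] = p_star
    pooled_flags, _ = fdr_fixed_rejection(table["p"].to_numpy(), alpha)
    table["reject_unstratified"] = pooled_flags
    return SFDRResult(
        table=table,
        thresholds=thresholds,
        alpha=alpha,
        n_reject_stratified=int(table["reject_stratified"].sum()),
        n_reject_unstratified=int(table["reject_unstratified"].sum()),
    )


def power_ratio(result: SFDRResult):
    """Stratified / unstratified rejection-count ratio (power surrogate).

    Undefined (NaN, with a logged flag) when unstratified control rejects
    nothing.  A ratio of 4.0 is a 300% increase.
    """
    if result.n_reject_unstratified == 0:
        logger.warning(
            "power ratio undefined: unstratified control rejected 0 SNPs"
        )
        return float("nan")
    return result.n_reject_stratified / result.n_reject_unstratified


def percent_increase(result: SFDRResult):
    ratio = power_ratio(result)
    return (ratio - 1.0) * 100.0


def pruned_rejection_counts(result: SFDRResult, neighborhoods,
                            r2_max: float = 0.2, seed: int = 0):
    """Rejection counts after random LD pruning of the rejected sets."""
    strat_ids = result.table.loc[result.table["reject_stratified"], "snp"]
    unstrat_ids = result.table.loc[result.table["reject_unstratified"], "snp"]
    return (
        len(ld_prune_random(strat_ids, neighborhoods, r2_max, seed)),
        len(ld_prune_random(unstrat_ids, neighborhoods, r2_max, seed)),
    )
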
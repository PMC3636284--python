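"""p/z conversion and intergenic genomic-inflation control.

Summary-statistic tables are pandas DataFrames with columns

    snp    : unique SNP identifier
    chrom  : chromosome label (optional for pure-statistics operations)
    pos    : position (optional likewise)
    z      : signed association z-score
    p      : two-tailed p-value in (0, 1]

plus optional ``sign`` ({+1, -1, 0}), ``maf`` and ``n`` columns.
``normalize_sumstats`` fills in whichever of z/p is missing and validates
consistency; every other function in the package assumes a normalized
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Smallest p-value accepted before conversion to z; smaller values must be
#: clipped by the caller (or via ``normalize_sumstats(..., clip=True)``).
P_FLOOR = 1e-300


def z_to_p(z):
    """Two-tailed p-value of a standard-normal z-score."""
    return 2.0 * sps.norm.sf(np.abs(z))


def p_to_z(p, sign=None):
    """Convert two-tailed p-values to z-scores.

    |z| = Phi^-1(1 - p/2).  ``sign`` (scalar or array of {+1, -1}) signs the
    result; with ``sign=None`` the magnitude is returned and a warning is
    logged, since downstream signed analyses will treat it as positive.

    Raises
    ------
    ValueError
        If any p is 0 (caller must clip at a floor, default ``P_FLOOR``)
        or outside (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0):
        raise ValueError(
            "p-values must be > 0; clip at a positive floor first "
            f"(e.g. {P_FLOOR:g})"
        )
    if np.any(p > 1.0):
        raise ValueError("p-values must be <= 1")
    magnitude = sps.norm.isf(p / 2.0)
    if sign is None:
        logger.warning("p_to_z called without effect signs; returning |z|")
        return magnitude
    sign = np.asarray(sign, dtype=float)
    return np.where(sign < 0, -magnitude, magnitude)


def normalize_sumstats(df: pd.DataFrame, clip: bool = False,
                       p_floor: float = P_FLOOR,
                       tol: float = 1e-6) -> pd.DataFrame:
    """Return a copy with both ``z`` and ``p`` columns populated.

    If both are present their consistency (p == 2*Phi(-|z|)) is checked to
    ``tol``.  Duplicate SNP ids raise.  ``clip=True`` clips p at
    ``p_floor`` before conversion.
    """
    df = df.copy()
    if "snp" not in df.columns:
        raise ValueError("summary-statistic table requires a 'snp' column")
    if df["snp"].duplicated().any():
        dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
        raise ValueError(f"duplicate SNP id in summary statistics: {dup!r}")
    has_z = "z" in df.columns and df["z"].notna().all()
    has_p = "p" in df.columns and df["p"].notna().all()
    if not has_z and not has_p:
        raise ValueError("need a complete 'z' or 'p' column")
    if has_p and clip:
        df["p"] = df["p"].clip(lower=p_floor)
    if has_z and has_p:
        expect = z_to_p(df["z"].to_numpy())
        if not np.allclose(df["p"].to_numpy(), expect, rtol=tol, atol=tol):
            raise ValueError("inconsistent z and p columns (two-tailed)")
    elif has_z:
        df["p"] = z_to_p(df["z"].to_numpy())
    else:
        sign = df["sign"].to_numpy() if "sign" in df.columns else None
        df["z"] = p_to_z(df["p"].to_numpy(), sign=sign)
    return df


@dataclass(frozen=True)
class InflationEstimate:
    """A genomic inflation factor and how it was obtained."""

    lambda_gc: float
    quantile: float
    n_snps: int
    subset: str

    def __post_init__(self):
        if not self.lambda_gc > 0:
            raise ValueError("lambda_gc must be positive")


def estimate_lambda_gc(stats, subset=None, quantile: float = 0.5,
                       subset_label: str | None = None,
                       min_snps: int = 100) -> InflationEstimate:
    """Estimate the genomic inflation factor from z-scores.

    lambda_GC = quantile(z^2) / F^-1_chi2(1)(quantile), default quantile
    the median.  ``stats`` may be a normalized summary table or a plain
    z-score array.  ``subset`` restricts estimation (boolean mask, id
    sequence, or callable on the table); the canonical use is restricting
    to intergenic SNPs so polygenic signal does not contaminate the
    estimate.

    A subset smaller than ``min_snps`` logs a warning; an empty subset
    raises.
    """
    if isinstance(stats, pd.DataFrame):
        table = stats
        if subset is None:
            mask = np.ones(len(table), dtype=bool)
            label = subset_label or "all"
        elif callable(subset):
            mask = np.asarray(subset(table), dtype=bool)
            label = subset_label or "predicate"
        else:
            subset = np.asarray(subset)
            if subset.dtype == bool:
                mask = subset
            else:
                mask = table["snp"].isin(subset).to_numpy()
            label = subset_label or "subset"
        z = table.loc[mask, "z"].to_numpy(dtype=float)
    else:
        z = np.asarray(stats, dtype=float)
        label = subset_label or "all"
    if z.size == 0:
        raise ValueError("empty SNP subset for lambda_GC estimation")
    if z.size < min_snps:
        logger.warning(
            "lambda_GC estimated from only %d SNPs (< %d)", z.size, min_snps
        )
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    lam = np.quantile(z ** 2, quantile) / sps.chi2.ppf(quantile, df=1)
    return InflationEstimate(float(lam), quantile, int(z.size), label)


def apply_inflation_control(stats: pd.DataFrame,
                            est: InflationEstimate) -> pd.DataFrame:
    """Divide test statistics by lambda_GC on the chi-square scale.

    z^2 is divided by lambda_GC, i.e. z <- z / sqrt(lambda_GC) with signs
    preserved; p-values are recomputed from the corrected z.  lambda_GC < 1
    scales statistics upwards (correcting prior over-correction).
    """
    out = stats.copy()
    out["z"] = out["z"].to_numpy() / np.sqrt(est.lambda_gc)
    out["p"] = z_to_p(out["z"].to_numpy())
    return out
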
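"""Unweighted genetic risk score: summation, median split, SD scaling.

The score for one individual is the number of risk alleles carried across
the panel (each SNP contributes its dosage 0/1/2; no GWAS effect-size
weights). Individuals are grouped as low risk (score strictly below the
cut-off) or high risk (score at or above it); the study cut-off of 6 risk
alleles corresponds to the cohort median and can be passed explicitly.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import DomainError

logger = logging.getLogger(__name__)

LOW, HIGH = "low", "high"


def compute_grs(dosages: pd.DataFrame, missing_policy: str = "drop",
                risk_freqs: dict[str, float] | None = None) -> pd.Series:
    """Sum risk-allele dosages across the panel for each sample.

    Parameters
    ----------
    dosages:
        samples x rsids matrix of 0/1/2 dosages with missing values allowed.
    missing_policy:
        ``"drop"`` (default) excludes any sample with a missing dosage;
        ``"impute"`` replaces a missing dosage with its SNP's expected value
        2 x risk-allele frequency (``risk_freqs`` required, score no longer
        integer).

    Returns an integer (or float, under imputation) Series indexed by the
    retained sample ids.
    """
    if missing_policy == "drop":
        complete = dosages.dropna()
        excluded = dosages.index.difference(complete.index)
        if len(excluded):
            logger.warning(
                "%d sample(s) excluded for missing genotypes: %s",
                len(excluded), list(excluded),
            )
        return complete.sum(axis=1).astype(int)
    if missing_policy == "impute":
        if risk_freqs is None:
            raise DomainError("imputation requires per-SNP risk-allele frequencies")
        filled = dosages.astype(float)
        for rsid in filled.columns:
            filled[rsid] = filled[rsid].fillna(2.0 * risk_freqs[rsid])
        return filled.sum(axis=1)
    raise DomainError(f"unknown missing_policy {missing_policy!r}")


def split_by_median(grs: pd.Series, cutoff: float | None = None
                    ) -> tuple[pd.Series, float]:
    """Label each sample low/high risk; the cut-off value itself is HIGH.

    With no explicit ``cutoff`` the sample median is used (standard
    even/odd definition). Returns (labels, cutoff used).
    """
    values = grs.astype(float)
    if cutoff is None:
        if values.nunique() < 2:
            raise DomainError("GRS is constant; no median split possible")
        cutoff = float(values.median())
    labels = pd.Series(np.where(values >= cutoff, HIGH, LOW), index=grs.index,
                       name="grs_group")
    for group in (LOW, HIGH):
        if (labels == group).sum() == 0:
            warnings.warn(f"GRS split at {cutoff} leaves the {group} group empty",
                          stacklevel=2)
    return labels, float(cutoff)


def scale_grs(grs: pd.Series, ddof: int = 1) -> pd.Series:
    """Centre the score and scale to standard-deviation units.

    Sample SD (n-1 denominator) by default; ``ddof=0`` gives the
    population variant.
    """
    values = grs.astype(float)
    sd = values.std(ddof=ddof)
    if not np.isfinite(sd) or sd == 0:
        raise DomainError("GRS standard deviation is zero; cannot scale")
    return ((values - values.mean()) / sd).rename("grs_scaled")


def grs_table(dosages: pd.DataFrame, cutoff: float | None = None,
              missing_policy: str = "drop",
              risk_freqs: dict[str, float] | None = None
              ) -> tuple[pd.DataFrame, float]:
    """Assemble the per-sample score table (grs, grs_group, grs_scaled)."""
    score = compute_grs(dosages, missing_policy=missing_policy, risk_freqs=risk_freqs)
    labels, used_cutoff = split_by_median(score, cutoff)
    scaled = scale_grs(score)
    table = pd.DataFrame({"grs": score, "grs_group": labels, "grs_scaled": scaled})
    return table, used_cutoff
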
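"""Dietary exposures: recall averaging, percent-of-energy conversion and
median dichotomisation.

Each participant contributes three 24-h recalls. Habitual intake is the
arithmetic mean across days; macronutrient exposures are expressed as
percentages of total energy intake (TEI) using Atwater energy densities
(fat and fat subtypes 9 kcal/g, carbohydrate and protein 4 kcal/g), by the
ratio-of-means convention (mean grams over mean energy).

The low/high split assigns values *at or below* the median to the low
group -- the opposite boundary convention from the risk-score split, and
both are deliberate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

logger = logging.getLogger(__name__)

LOW, HIGH = "low", "high"

#: Atwater energy densities, kcal per gram
ENERGY_DENSITY = {
    "fat": 9.0, "sfa": 9.0, "mufa": 9.0, "pufa": 9.0,
    "carb": 4.0, "protein": 4.0,
}

NUTRIENT_COLUMNS = ["fat_g", "sfa_g", "mufa_g", "pufa_g", "carb_g", "protein_g"]

EXPOSURE_COLUMNS = ["fat_pct", "sfa_pct", "mufa_pct", "pufa_pct",
                    "carb_pct", "protein_pct"]


def mean_recalls(recalls: pd.DataFrame, min_days: int = 3) -> pd.DataFrame:
    """Per-sample mean daily energy and nutrient grams.

    Samples with fewer than ``min_days`` recall days are excluded and
    logged.
    """
    counts = recalls.groupby("sample_id")["day"].count()
    keep = counts[counts >= min_days].index
    dropped = counts.index.difference(keep)
    if len(dropped):
        logger.warning(
            "%d sample(s) excluded with fewer than %d recall days: %s",
            len(dropped), min_days, list(dropped),
        )
    cols = ["energy_kcal"] + NUTRIENT_COLUMNS
    return recalls[recalls["sample_id"].isin(keep)].groupby("sample_id")[cols].mean()


def percent_energy(nutrient_g, tei_kcal, energy_density: float):
    """Percentage of total energy intake contributed by a nutrient."""
    nutrient = np.asarray(nutrient_g, dtype=float)
    tei = np.asarray(tei_kcal, dtype=float)
    if np.any(tei <= 0):
        raise DomainError("total energy intake must be strictly positive")
    out = 100.0 * nutrient * energy_density / tei
    return float(out) if out.ndim == 0 else out


def exposure_table(recalls: pd.DataFrame, min_days: int = 3,
                   method: str = "ratio_of_means") -> pd.DataFrame:
    """Build the per-sample exposure table (tei plus one %TEI column per
    macronutrient).

    ``method`` selects the %TEI convention: ``"ratio_of_means"`` (default;
    mean grams over mean energy) or ``"mean_of_ratios"`` (average of the
    three daily percentages).
    """
    if method == "ratio_of_means":
        means = mean_recalls(recalls, min_days=min_days)
        out = pd.DataFrame(index=means.index)
        out["tei"] = means["energy_kcal"]
        for col in NUTRIENT_COLUMNS:
            nutrient = col[:-2]
            out[f"{nutrient}_pct"] = percent_energy(
                means[col], means["energy_kcal"], ENERGY_DENSITY[nutrient]
            )
        return out
    if method == "mean_of_ratios":
        daily = recalls.copy()
        for col in NUTRIENT_COLUMNS:
            nutrient = col[:-2]
            daily[f"{nutrient}_pct"] = percent_energy(
                daily[col], daily["energy_kcal"], ENERGY_DENSITY[nutrient]
            )
        counts = daily.groupby("sample_id")["day"].count()
        keep = counts[counts >= min_days].index
        daily = daily[daily["sample_id"].isin(keep)]
        grouped = daily.groupby("sample_id")
        out = grouped[[f"{c[:-2]}_pct" for c in NUTRIENT_COLUMNS]].mean()
        out.insert(0, "tei", grouped["energy_kcal"].mean())
        return out
    raise ValidationError(f"unknown %TEI method {method!r}")


def dichotomize_exposure(values: pd.Series, median: float | None = None
                         ) -> tuple[pd.Series, float]:
    """Label low (value <= median) / high (value > median).

    Returns (labels, median used); the sample median is used when none is
    given.
    """
    series = values.astype(float)
    if len(series) < 2:
        raise DomainError("need at least two samples to dichotomise")
    if median is None:
        if series.nunique() < 2:
            raise DomainError("exposure is constant; no median split possible")
        median = float(series.median())
    labels = pd.Series(np.where(series <= median, LOW, HIGH), index=values.index,
                       name=f"{values.name}_group" if values.name else "group")
    return labels, float(median)
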
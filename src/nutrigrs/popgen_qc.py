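"""Allele-frequency estimation, Hardy-Weinberg testing and panel QC.

Frequencies are obtained by gene counting. The Hardy-Weinberg equilibrium
(HWE) check is the plain chi-square goodness-of-fit test on the three
genotype classes against expected proportions p^2, 2pq, q^2 with the allele
frequency estimated from the same sample (1 degree of freedom, no
continuity correction by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import SnpPanel, SnpPanelEntry
from .errors import DomainError, QcAbortError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Dosage coding and genotype counting
# ---------------------------------------------------------------------------

def risk_dosage(call: str | None, entry: SnpPanelEntry):
    """Count of risk alleles (0, 1 or 2) in one call; missing propagates."""
    if call is None or call is pd.NA or (isinstance(call, float) and np.isnan(call)):
        return pd.NA
    return sum(1 for allele in call if allele == entry.risk_allele)


def dosage_matrix(genotypes: pd.DataFrame, panel: SnpPanel) -> pd.DataFrame:
    """Samples x rsids matrix of risk-allele dosages (nullable Int64)."""
    out = pd.DataFrame(index=genotypes.index)
    for entry in panel:
        out[entry.rsid] = pd.array(
            [risk_dosage(c, entry) for c in genotypes[entry.rsid]], dtype="Int64"
        )
    return out


def genotype_counts(calls: pd.Series, entry: SnpPanelEntry) -> tuple[int, int, int]:
    """(n_RR, n_RO, n_OO) with R the risk allele; missing calls ignored."""
    n_rr = n_ro = n_oo = 0
    for call in calls:
        d = risk_dosage(call, entry)
        if d is pd.NA:
            continue
        if d == 2:
            n_rr += 1
        elif d == 1:
            n_ro += 1
        else:
            n_oo += 1
    return n_rr, n_ro, n_oo


# ---------------------------------------------------------------------------
# Gene counting and HWE
# ---------------------------------------------------------------------------

def allele_frequencies(counts: tuple[int, int, int]) -> tuple[float, float]:
    """(risk_freq, other_freq) by gene counting from genotype counts."""
    n_rr, n_ro, n_oo = counts
    n = n_rr + n_ro + n_oo
    if n == 0:
        raise DomainError("no non-missing calls; allele frequency undefined")
    risk = (2 * n_rr + n_ro) / (2 * n)
    return risk, 1.0 - risk


@dataclass(frozen=True)
class HweResult:
    chi2: float
    p: float
    defined: bool = True


def hwe_test(counts: tuple[int, int, int], continuity_correction: bool = False) -> HweResult:
    """Chi-square HWE test (1 df) on one SNP's genotype counts.

    Expected counts use the gene-counting frequency estimate p-hat:
    (n p^2, 2 n p q, n q^2). For a monomorphic SNP the test is undefined
    and a flagged no-test result is returned.
    """
    n_rr, n_ro, n_oo = counts
    n = n_rr + n_ro + n_oo
    if n < 1:
        raise DomainError("HWE test needs at least one genotyped sample")
    p_hat, q_hat = allele_frequencies(counts)
    if p_hat in (0.0, 1.0):
        return HweResult(chi2=float("nan"), p=float("nan"), defined=False)
    expected = np.array([n * p_hat**2, 2 * n * p_hat * q_hat, n * q_hat**2])
    observed = np.array([n_rr, n_ro, n_oo], dtype=float)
    dev = np.abs(observed - expected)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2=chi2, p=max(p, 0.0))


# ---------------------------------------------------------------------------
# Panel QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcThresholds:
    """Retention rules: minor-allele frequency strictly above ``min_maf``,
    HWE p strictly above ``min_hwe_p``, per-SNP missingness at most
    ``max_missing``."""

    min_maf: float = 0.05
    min_hwe_p: float = 0.05
    max_missing: float = 0.05


@dataclass(frozen=True)
class SnpQcRecord:
    rsid: str
    n_genotyped: int
    genotype_counts: tuple[int, int, int]
    risk_allele_freq: float
    maf: float
    missing_rate: float
    hwe_chi2: float
    hwe_p: float
    hwe_defined: bool
    passes_qc: bool = True
    reasons: tuple[str, ...] = ()


def snp_qc(genotypes: pd.DataFrame, panel: SnpPanel) -> list[SnpQcRecord]:
    """Per-SNP genotype counts, gene-counting frequencies and HWE statistics."""
    records = []
    n_samples = len(genotypes)
    for entry in panel:
        counts = genotype_counts(genotypes[entry.rsid], entry)
        n = sum(counts)
        missing_rate = 1.0 - n / n_samples if n_samples else 1.0
        if n == 0:
            records.append(SnpQcRecord(
                rsid=entry.rsid, n_genotyped=0, genotype_counts=counts,
                risk_allele_freq=float("nan"), maf=float("nan"),
                missing_rate=missing_rate, hwe_chi2=float("nan"),
                hwe_p=float("nan"), hwe_defined=False,
            ))
            continue
        risk_freq, other_freq = allele_frequencies(counts)
        hwe = hwe_test(counts)
        records.append(SnpQcRecord(
            rsid=entry.rsid, n_genotyped=n, genotype_counts=counts,
            risk_allele_freq=risk_freq, maf=min(risk_freq, other_freq),
            missing_rate=missing_rate, hwe_chi2=hwe.chi2, hwe_p=hwe.p,
            hwe_defined=hwe.defined,
        ))
    return records


def qc_filter(
    records: list[SnpQcRecord],
    panel: SnpPanel,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[SnpPanel, pd.DataFrame]:
    """Apply the retention thresholds; return the surviving panel and a report.

    Raises :class:`QcAbortError` (carrying the report) if no SNP survives.
    """
    evaluated = []
    for rec in records:
        reasons = []
        if rec.n_genotyped == 0:
            reasons.append("no genotyped samples")
        else:
            if not (rec.maf > thresholds.min_maf):
                reasons.append(f"maf {rec.maf:.4f} <= {thresholds.min_maf}")
            if not rec.hwe_defined:
                reasons.append("monomorphic; HWE undefined")
            elif not (rec.hwe_p > thresholds.min_hwe_p):
                reasons.append(f"hwe_p {rec.hwe_p:.4g} <= {thresholds.min_hwe_p}")
            if rec.missing_rate > thresholds.max_missing:
                reasons.append(
                    f"missing rate {rec.missing_rate:.4f} > {thresholds.max_missing}"
                )
        evaluated.append(
            SnpQcRecord(**{**rec.__dict__, "passes_qc": not reasons,
                           "reasons": tuple(reasons)})
        )
    report = qc_report(evaluated)
    kept = [r.rsid for r in evaluated if r.passes_qc]
    for rec in evaluated:
        if not rec.passes_qc:
            logger.warning("SNP %s excluded by QC: %s", rec.rsid, "; ".join(rec.reasons))
    if not kept:
        raise QcAbortError("all panel SNPs failed QC", report=report)
    return panel.subset(kept), report


def qc_report(records: list[SnpQcRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        n_rr, n_ro, n_oo = r.genotype_counts
        rows.append({
            "rsid": r.rsid, "n_genotyped": r.n_genotyped,
            "n_RR": n_rr, "n_RO": n_ro, "n_OO": n_oo,
            "risk_allele_freq": r.risk_allele_freq, "maf": r.maf,
            "missing_rate": r.missing_rate,
            "hwe_chi2": r.hwe_chi2, "hwe_p": r.hwe_p,
            "pass": r.passes_qc, "reason": "; ".join(r.reasons),
        })
    return pd.DataFrame(rows)
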
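"""Reading, validation and derivation of the four study input tables.

The analysis consumes four tables:

* a SNP panel (rsid, gene, risk/other allele, reported trait),
* per-individual genotype calls (lab CSV export or biallelic VCF),
* a cohort phenotype table (anthropometry, blood-pressure triplicates,
  fasting lipids in mg/dl),
* three 24-h dietary recall records per individual.

Derived clinical quantities are computed here: BMI from weight and height,
LDL cholesterol by the Friedewald equation, the TAG:HDL ratio, and the
average of repeated blood-pressure readings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FriedewaldValidityError, ValidationError

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call in the CSV dialect
MISSING = "--"

VALID_ALLELES = frozenset("ACGT")

#: TAG bound (mg/dl) above which the Friedewald equation is not considered valid
FRIEDEWALD_TAG_LIMIT = 400.0

COHORT_COLUMNS = [
    "sample_id", "sex", "age", "weight_kg", "height_m", "wc_cm",
    "sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3",
    "tag_mgdl", "tc_mgdl", "hdl_mgdl",
]

RECALL_COLUMNS = [
    "sample_id", "day", "energy_kcal", "fat_g", "sfa_g", "mufa_g",
    "pufa_g", "carb_g", "protein_g",
]


# ---------------------------------------------------------------------------
# SNP panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpPanelEntry:
    """One biallelic SNP with its risk-allele orientation.

    The risk allele is the allele previously reported to associate with an
    adverse lipid level or cardiovascular outcome; dosage coding counts
    copies of this allele.
    """

    rsid: str
    gene: str
    risk_allele: str
    other_allele: str
    reported_trait: str = ""
    source_note: str = ""

    def __post_init__(self):
        for name in ("risk_allele", "other_allele"):
            allele = getattr(self, name)
            if allele not in VALID_ALLELES:
                raise ValidationError(
                    f"{self.rsid}: {name} {allele!r} is not one of A,C,G,T"
                )
        if self.risk_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: risk and other allele are identical")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.risk_allele, self.other_allele))


@dataclass(frozen=True)
class SnpPanel:
    """Ordered collection of :class:`SnpPanelEntry`, unique by rsid."""

    entries: tuple[SnpPanelEntry, ...]

    def __post_init__(self):
        rsids = [e.rsid for e in self.entries]
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise ValidationError(f"duplicate rsid(s) in panel: {sorted(dupes)}")

    @property
    def rsids(self) -> list[str]:
        return [e.rsid for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SnpPanelEntry]:
        return iter(self.entries)

    def __getitem__(self, rsid: str) -> SnpPanelEntry:
        for entry in self.entries:
            if entry.rsid == rsid:
                return entry
        raise KeyError(rsid)

    def subset(self, rsids: Sequence[str]) -> "SnpPanel":
        keep = set(rsids)
        return SnpPanel(tuple(e for e in self.entries if e.rsid in keep))


def read_snp_panel(path: str | Path) -> SnpPanel:
    """Read a SNP panel CSV (columns rsid, gene, risk_allele, other_allele,
    reported_trait, source_note) preserving row order."""
    try:
        df = pd.read_csv(path, dtype=str).fillna("")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"panel file {path} is empty") from exc
    required = {"rsid", "gene", "risk_allele", "other_allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"panel file missing column(s): {sorted(missing)}")
    if df.empty:
        raise ValidationError("panel file contains no SNPs")
    entries = tuple(
        SnpPanelEntry(
            rsid=row["rsid"].strip(),
            gene=row["gene"].strip(),
            risk_allele=row["risk_allele"].strip().upper(),
            other_allele=row["other_allele"].strip().upper(),
            reported_trait=row.get("reported_trait", "").strip(),
            source_note=row.get("source_note", "").strip(),
        )
        for _, row in df.iterrows()
    )
    return SnpPanel(entries)


def write_snp_panel(panel: SnpPanel, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "rsid": e.rsid, "gene": e.gene, "risk_allele": e.risk_allele,
                "other_allele": e.other_allele, "reported_trait": e.reported_trait,
                "source_note": e.source_note,
            }
            for e in panel
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotype table
# ---------------------------------------------------------------------------

def _normalise_call(cell: str, entry: SnpPanelEntry, sample_id: str) -> str | None:
    """Return the canonical (sorted) two-character call or ``None`` for missing.

    Calls are unordered: "CA" and "AC" are the same heterozygote.
    """
    cell = cell.strip().upper()
    if cell in ("", MISSING, "NA", "NN"):
        return None
    if len(cell) != 2:
        raise ValidationError(
            f"sample {sample_id}, {entry.rsid}: call {cell!r} is not a two-allele string"
        )
    for allele in cell:
        if allele not in entry.alleles:
            raise ValidationError(
                f"sample {sample_id}, {entry.rsid}: allele {allele!r} not in panel "
                f"pair {{{entry.risk_allele},{entry.other_allele}}}"
            )
    return "".join(sorted(cell))


def read_genotypes(
    path: str | Path, panel: SnpPanel, dialect: str = "csv"
) -> pd.DataFrame:
    """Read genotype calls into a samples x rsids DataFrame.

    Cells hold canonical two-character allele strings (alphabetically sorted,
    so orientation-free) or ``pd.NA`` for missing calls. Panel rsids absent
    from the file are retained as all-missing columns and logged.

    Parameters
    ----------
    dialect:
        ``"csv"`` for the one-row-per-sample lab export (``--`` = missing) or
        ``"vcf"`` for a biallelic-SNP VCF matched on the ID field.
    """
    if dialect == "csv":
        return _read_genotypes_csv(path, panel)
    if dialect == "vcf":
        return _read_genotypes_vcf(path, panel)
    raise ValidationError(f"unknown genotype dialect {dialect!r}")


def _read_genotypes_csv(path: str | Path, panel: SnpPanel) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError("genotype CSV must have a sample_id column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id(s): {dup}")
    df = df.set_index("sample_id")
    out = pd.DataFrame(index=df.index, columns=panel.rsids, dtype=object)
    for entry in panel:
        if entry.rsid not in df.columns:
            logger.warning("panel rsid %s not present in %s; set to missing", entry.rsid, path)
            out[entry.rsid] = pd.NA
            continue
        out[entry.rsid] = [
            cell if (cell := _normalise_call(str(raw) if raw == raw else "", entry, sid)) is not None
            else pd.NA
            for sid, raw in df[entry.rsid].items()
        ]
    return out


def _read_genotypes_vcf(path: str | Path, panel: SnpPanel) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out = pd.DataFrame(index=pd.Index(samples, name="sample_id"),
                       columns=panel.rsids, dtype=object)
    out[:] = pd.NA
    seen: set[str] = set()
    wanted = set(panel.rsids)
    for variant in vcf:
        if variant.ID not in wanted:
            continue
        if len(variant.ALT) != 1:
            raise ValidationError(f"{variant.ID}: only biallelic SNP records are supported")
        entry = panel[variant.ID]
        alleles = [variant.REF.upper(), variant.ALT[0].upper()]
        calls = []
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                calls.append(pd.NA)
                continue
            pair = alleles[a] + alleles[b]
            calls.append(_normalise_call(pair, entry, samples[i]))
        out[variant.ID] = calls
        seen.add(variant.ID)
    for rsid in wanted - seen:
        logger.warning("panel rsid %s not found in VCF %s; set to missing", rsid, path)
    return out


def write_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    """Write the CSV dialect (``--`` for missing); round-trips with
    :func:`read_genotypes`."""
    genotypes.fillna(MISSING).to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Derived clinical quantities
# ---------------------------------------------------------------------------

def derive_bmi(weight_kg, height_m):
    """Body-mass index, weight (kg) divided by the square of height (m)."""
    weight = np.asarray(weight_kg, dtype=float)
    height = np.asarray(height_m, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise DomainError("weight and height must be strictly positive")
    out = weight / height**2
    return float(out) if out.ndim == 0 else out


def friedewald_ldl(tc_mgdl: float, hdl_mgdl: float, tag_mgdl: float) -> float:
    """LDL cholesterol (mg/dl) by the Friedewald equation, TC - HDL - TAG/5.

    Valid only for TAG <= 400 mg/dl; above that a
    :class:`FriedewaldValidityError` is raised. A negative result is
    returned but flagged with a warning (exclusion is a QC decision).
    """
    if tag_mgdl > FRIEDEWALD_TAG_LIMIT:
        raise FriedewaldValidityError(
            f"TAG {tag_mgdl} mg/dl exceeds the {FRIEDEWALD_TAG_LIMIT:.0f} mg/dl "
            "validity bound of the Friedewald equation"
        )
    ldl = tc_mgdl - hdl_mgdl - tag_mgdl / 5.0
    if ldl < 0:
        warnings.warn(
            f"Friedewald LDL is negative ({ldl:.2f} mg/dl); value retained",
            stacklevel=2,
        )
    return ldl


def aggregate_repeated_measures(readings: Iterable[float]) -> float:
    """Arithmetic mean of repeated readings (e.g. the blood-pressure triplicate)."""
    values = np.asarray(list(readings), dtype=float)
    if values.size == 0:
        raise DomainError("no readings to aggregate")
    return float(values.mean())


# ---------------------------------------------------------------------------
# Cohort phenotype table
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read the cohort phenotype CSV and derive BMI, averaged blood pressure,
    Friedewald LDL and the TAG:HDL ratio.

    Returns a DataFrame indexed by sample_id with columns
    sex, age, weight, height, bmi, wc, sbp, dbp, tag, tc, hdl, ldl,
    tag_hdl_ratio. LDL is left missing (NaN) where TAG exceeds the
    Friedewald validity bound.
    """
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"cohort file missing column(s): {sorted(missing)}")
    if df["sample_id"].astype(str).duplicated().any():
        raise ValidationError("duplicate sample_id in cohort table")
    bad_sex = set(df["sex"].unique()) - {"M", "W"}
    if bad_sex:
        raise ValidationError(f"sex must be coded M/W, found {sorted(bad_sex)}")
    df = df.set_index(df["sample_id"].astype(str))

    out = pd.DataFrame(index=df.index)
    out["sex"] = df["sex"]
    out["age"] = df["age"].astype(float)
    out["weight"] = df["weight_kg"].astype(float)
    out["height"] = df["height_m"].astype(float)
    out["bmi"] = derive_bmi(out["weight"].to_numpy(), out["height"].to_numpy())
    out["wc"] = df["wc_cm"].astype(float)
    out["sbp"] = df[["sbp1", "sbp2", "sbp3"]].astype(float).mean(axis=1)
    out["dbp"] = df[["dbp1", "dbp2", "dbp3"]].astype(float).mean(axis=1)
    for col, src in (("tag", "tag_mgdl"), ("tc", "tc_mgdl"), ("hdl", "hdl_mgdl")):
        out[col] = df[src].astype(float)
        if (out[col] <= 0).any():
            bad = out.index[out[col] <= 0].tolist()
            raise ValidationError(f"{src} must be strictly positive; offending samples: {bad}")

    ldl = np.full(len(out), np.nan)
    for i, (sid, row) in enumerate(out.iterrows()):
        if row["tag"] <= FRIEDEWALD_TAG_LIMIT:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                ldl[i] = friedewald_ldl(row["tc"], row["hdl"], row["tag"])
            for w in caught:
                logger.warning("sample %s: %s", sid, w.message)
        else:
            logger.warning(
                "sample %s: TAG %.1f mg/dl above Friedewald bound; LDL left missing",
                sid, row["tag"],
            )
    out["ldl"] = ldl
    out["tag_hdl_ratio"] = out["tag"] / out["hdl"]
    return out


def write_cohort(cohort_raw: pd.DataFrame, path: str | Path) -> None:
    """Write a raw-schema cohort table (the columns :func:`read_cohort` expects)."""
    cohort_raw.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dietary recalls
# ---------------------------------------------------------------------------

#: tolerance factor for fatty acids left unclassified by the food database
FAT_SUBTYPE_TOLERANCE = 1.05


def read_diet_recalls(path: str | Path) -> pd.DataFrame:
    """Read the 24-h recall CSV (one row per sample-day).

    Validates non-negativity and that SFA + MUFA + PUFA does not exceed
    total fat by more than 5 % (unclassified fatty-acid slack).
    """
    df = pd.read_csv(path)
    missing = set(RECALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"recall file missing column(s): {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    numeric = [c for c in RECALL_COLUMNS if c not in ("sample_id", "day")]
    df[numeric] = df[numeric].astype(float)
    if (df[numeric].to_numpy() < 0).any():
        raise ValidationError("recall quantities must be non-negative")
    if df.duplicated(["sample_id", "day"]).any():
        raise ValidationError("duplicate (sample_id, day) rows in recall table")
    subtype_sum = df["sfa_g"] + df["mufa_g"] + df["pufa_g"]
    bad = subtype_sum > df["fat_g"] * FAT_SUBTYPE_TOLERANCE
    if bad.any():
        rows = df.loc[bad, ["sample_id", "day"]].to_records(index=False).tolist()
        raise ValidationError(
            f"fat subtypes exceed total fat by more than 5 % in rows: {rows}"
        )
    return df
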
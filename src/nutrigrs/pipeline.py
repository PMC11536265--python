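"""Configuration-driven orchestration of the full analysis.

Stage order: read (or simulate) -> SNP QC -> risk score -> dietary
exposures -> descriptive comparisons -> association models -> interaction
screen (fat, carbohydrate, protein x outcomes) -> stratified and
fat-subtype follow-up of significant screens -> multiple-testing
thresholds -> report files.

Every run writes a deterministic file set (descriptives.tsv, qc.tsv,
grs.tsv, exposures.tsv, associations.tsv, interactions.tsv, strata.tsv,
deciles.tsv, run_metadata.json); identical configurations produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assoc_stats, cohort_io, diet_exposures, grs as grs_mod, popgen_qc
from . import synthetic_cohort
from .errors import ConfigError

logger = logging.getLogger(__name__)

DECILE_TRAITS = ("tc", "ldl", "tag", "tag_hdl_ratio")


@dataclass
class PipelineConfig:
    """Exactly one of ``inputs`` (file paths) or ``simulation`` (overrides
    for :class:`~nutrigrs.synthetic_cohort.SimulationConfig`) must be set."""

    inputs: dict | None = None
    simulation: dict | None = None
    seed: int = 0
    alpha: float = 0.05
    outcomes: tuple = assoc_stats.DEFAULT_OUTCOMES
    diet_factors: tuple = assoc_stats.PRIMARY_DIET_FACTORS
    diet_form: str = "continuous"
    grs_cutoff: float | None = None
    qc: popgen_qc.QcThresholds = field(default_factory=popgen_qc.QcThresholds)
    min_stratum_n: int = 10
    force_followup: bool = False
    missing_policy: str = "drop"

    def __post_init__(self):
        if (self.inputs is None) == (self.simulation is None):
            raise ConfigError(
                "configuration must set exactly one of 'inputs' and 'simulation'"
            )
        if self.inputs is not None:
            required = {"panel", "genotypes", "cohort", "recalls"}
            missing = required - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs block missing key(s): {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, seed=seed)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "PipelineConfig":
        raw = dict(raw)
        if seed is not None:
            raw["seed"] = seed
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = popgen_qc.QcThresholds(**raw["qc"])
        for key in ("outcomes", "diet_factors"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**raw)

    def canonical_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["qc"] = dataclasses.asdict(self.qc)
        out["outcomes"] = list(self.outcomes)
        out["diet_factors"] = list(self.diet_factors)
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultSet:
    config: PipelineConfig
    qc_report: pd.DataFrame
    grs_df: pd.DataFrame
    grs_cutoff: float
    exposures: pd.DataFrame
    exposure_medians: dict
    descriptives: pd.DataFrame
    associations: pd.DataFrame
    interactions: pd.DataFrame
    strata: pd.DataFrame
    deciles: pd.DataFrame
    thresholds: dict
    metadata: dict


def _load_tables(config: PipelineConfig):
    if config.simulation is not None:
        sim_raw = dict(config.simulation)
        sim_raw.setdefault("seed", config.seed)
        cov = synthetic_cohort.CovariateParams(**sim_raw.pop("covariates", {}))
        diet = synthetic_cohort.DietParams(**sim_raw.pop("diet", {}))
        effects = synthetic_cohort._default_effects()
        for outcome, overrides in sim_raw.pop("effects", {}).items():
            effects[outcome] = dataclasses.replace(effects[outcome], **overrides)
        sim_cfg = synthetic_cohort.SimulationConfig(
            covariates=cov, diet=diet, effects=effects, **sim_raw
        )
        sim = synthetic_cohort.simulate_cohort(sim_cfg)
        logger.info("simulated cohort of %d samples (seed %d)", sim_cfg.n, sim_cfg.seed)
        return sim_cfg.panel, sim.genotypes, sim.cohort, sim.recalls
    paths = config.inputs
    panel = cohort_io.read_snp_panel(paths["panel"])
    genotypes = cohort_io.read_genotypes(
        paths["genotypes"], panel, dialect=paths.get("dialect", "csv")
    )
    cohort = cohort_io.read_cohort(paths["cohort"])
    recalls = cohort_io.read_diet_recalls(paths["recalls"])
    return panel, genotypes, cohort, recalls


def decile_summary(cohort: pd.DataFrame, grs_series: pd.Series,
                   traits=DECILE_TRAITS) -> pd.DataFrame:
    """Mean trait level per risk-score decile.

    Samples are ordered by (score, sample id) and split into ten
    equal-as-possible groups, which keeps exactly ten rows per trait
    despite the heavy ties of an integer score.
    """
    order = grs_series.sort_values(kind="mergesort").index
    chunks = np.array_split(np.arange(len(order)), 10)
    rows = []
    for trait in traits:
        for d, chunk in enumerate(chunks, start=1):
            ids = order[chunk]
            values = cohort.loc[ids, trait].dropna()
            rows.append({
                "trait": trait, "decile": d, "n": len(ids),
                "grs_mean": grs_series.loc[ids].mean(),
                "mean": values.mean(), "sd": values.std(ddof=1),
            })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> ResultSet:
    panel, genotypes, cohort, recalls = _load_tables(config)
    logger.info("stage read: %d samples, %d panel SNPs", len(cohort), len(panel))

    # --- QC ---
    qc_records = popgen_qc.snp_qc(genotypes, panel)
    panel_kept, qc_report = popgen_qc.qc_filter(qc_records, panel, config.qc)
    logger.info("stage qc: %d/%d SNPs retained", len(panel_kept), len(panel))

    # --- risk score ---
    dosages = popgen_qc.dosage_matrix(genotypes, panel_kept)
    freqs = {r.rsid: r.risk_allele_freq for r in qc_records}
    grs_df, cutoff = grs_mod.grs_table(
        dosages, cutoff=config.grs_cutoff,
        missing_policy=config.missing_policy, risk_freqs=freqs,
    )
    logger.info("stage grs: %d samples scored, cut-off %g", len(grs_df), cutoff)

    # --- exposures ---
    exposures = diet_exposures.exposure_table(recalls)
    medians = {}
    for col in diet_exposures.EXPOSURE_COLUMNS:
        labels, med = diet_exposures.dichotomize_exposure(exposures[col])
        exposures[f"{col[:-4]}_group"] = labels
        medians[col] = med

    # analysis sample: genotyped, phenotyped and with diet data
    ids = cohort.index.intersection(grs_df.index).intersection(exposures.index)
    if len(ids) == 0:
        raise ConfigError("no samples remain after intersecting the three tables")
    cohort = cohort.loc[ids]
    grs_df = grs_df.loc[ids]
    exposures = exposures.loc[ids]
    analysis = cohort.join(exposures)
    logger.info("analysis sample: %d individuals", len(ids))

    # --- descriptives ---
    by_sex = assoc_stats.descriptive_comparisons(analysis, cohort["sex"])
    by_sex.insert(0, "grouping", "sex")
    by_grs = assoc_stats.descriptive_comparisons(analysis, grs_df["grs_group"])
    by_grs.insert(0, "grouping", "grs_group")
    sex_table = pd.crosstab(cohort["sex"], grs_df["grs_group"])
    chi2, chi2_p = assoc_stats.chi_square_2x2(sex_table.to_numpy())
    descriptives = pd.concat([by_sex, by_grs], ignore_index=True)
    descriptives = pd.concat([
        descriptives,
        pd.DataFrame([{"grouping": "grs_group", "variable": "sex (chi2)",
                       "t": chi2, "p": chi2_p, "testable": True}]),
    ], ignore_index=True)

    # --- thresholds ---
    assoc_thr = assoc_stats.bonferroni_threshold(config.alpha, len(config.outcomes))
    n_interaction_tests = len(config.outcomes) * len(config.diet_factors)
    inter_thr = assoc_stats.bonferroni_threshold(config.alpha, n_interaction_tests)

    # --- associations ---
    assoc = assoc_stats.association_analysis(cohort, grs_df, outcomes=config.outcomes)
    associations = pd.DataFrame(
        [assoc[o].summary_row(threshold=assoc_thr.raw) for o in config.outcomes]
    )

    # --- interaction screen + follow-up ---
    inter_rows, strata_rows = [], []
    for factor in config.diet_factors:
        screen = assoc_stats.interaction_analysis(
            cohort, grs_df, exposures, factor,
            outcomes=config.outcomes, diet_form=config.diet_form,
        )
        for outcome in config.outcomes:
            res = screen[outcome]
            row = res.summary_row(threshold=inter_thr.raw)
            row["test_type"] = "primary"
            inter_rows.append(row)
            significant = res.p_interaction < config.alpha
            if significant or config.force_followup:
                labels = exposures[f"{factor[:-4]}_group"]
                strata = assoc_stats.stratified_effects(
                    cohort, grs_df, labels, outcome,
                    min_stratum_n=config.min_stratum_n,
                )
                for name, sres in strata.items():
                    srow = {"outcome": outcome, "exposure": factor,
                            "stratum": name, "n": sres.n, "stable": sres.stable,
                            "note": sres.note}
                    if sres.fit is not None:
                        term = sres.fit.term("grs_high")
                        srow.update(beta=term["beta"], ci_low=term["ci_low"],
                                    ci_high=term["ci_high"], p=term["p"])
                    strata_rows.append(srow)
            if factor == "fat_pct":
                followup = assoc_stats.fat_subtype_followup(
                    cohort, grs_df, exposures, outcome, screen[outcome],
                    alpha=config.alpha, diet_form=config.diet_form,
                    force=config.force_followup,
                )
                for subtype, fres in followup.items():
                    frow = fres.summary_row()
                    frow["test_type"] = "fat_subtype"
                    inter_rows.append(frow)
                    if fres.p_interaction < config.alpha or config.force_followup:
                        labels = exposures[f"{subtype[:-4]}_group"]
                        strata = assoc_stats.stratified_effects(
                            cohort, grs_df, labels, outcome,
                            min_stratum_n=config.min_stratum_n,
                        )
                        for name, sres in strata.items():
                            srow = {"outcome": outcome, "exposure": subtype,
                                    "stratum": name, "n": sres.n,
                                    "stable": sres.stable, "note": sres.note}
                            if sres.fit is not None:
                                term = sres.fit.term("grs_high")
                                srow.update(beta=term["beta"], ci_low=term["ci_low"],
                                            ci_high=term["ci_high"], p=term["p"])
                            strata_rows.append(srow)
    interactions = pd.DataFrame(inter_rows)
    strata_df = pd.DataFrame(strata_rows)

    deciles = decile_summary(cohort, grs_df["grs"])

    thresholds = {
        "alpha": config.alpha,
        "association": {"n_tests": assoc_thr.n_tests, "raw": assoc_thr.raw,
                        "display": assoc_thr.display},
        "interaction": {"n_tests": inter_thr.n_tests, "raw": inter_thr.raw,
                        "display": inter_thr.display},
    }
    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.canonical_dict(),
        "n_samples_analysis": int(len(ids)),
        "n_snps_retained": int(len(panel_kept)),
        "grs_cutoff": float(cutoff),
        "exposure_medians": medians,
        "thresholds": thresholds,
    }
    return ResultSet(
        config=config, qc_report=qc_report, grs_df=grs_df, grs_cutoff=cutoff,
        exposures=exposures, exposure_medians=medians, descriptives=descriptives,
        associations=associations, interactions=interactions, strata=strata_df,
        deciles=deciles, thresholds=thresholds, metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Report writing and serialisation
# ---------------------------------------------------------------------------

def write_report(results: ResultSet, out_dir: str | Path) -> list[Path]:
    """Write the deterministic TSV/JSON file set; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def tsv(df: pd.DataFrame, name: str, header_comment: str | None = None):
        path = out / name
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t", index=False)
        written.append(path)

    tsv(results.qc_report, "qc.tsv")
    tsv(results.grs_df.reset_index(), "grs.tsv",
        header_comment=f"grs_cutoff={results.grs_cutoff:g}")
    medians = ", ".join(f"{k}={v:.6g}" for k, v in results.exposure_medians.items())
    tsv(results.exposures.reset_index(), "exposures.tsv",
        header_comment=f"medians: {medians}")
    tsv(results.descriptives, "descriptives.tsv")
    tsv(results.associations, "associations.tsv",
        header_comment=f"bonferroni_threshold={results.thresholds['association']['display']}")
    tsv(results.interactions, "interactions.tsv",
        header_comment=f"bonferroni_threshold={results.thresholds['interaction']['display']}")
    tsv(results.strata, "strata.tsv")
    tsv(results.deciles, "deciles.tsv")

    meta_path = out / "run_metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(results.metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written.append(meta_path)
    return written


def result_bundle(results: ResultSet) -> dict:
    """JSON-serialisable bundle from which the report can be rewritten."""
    def frame(df):
        return json.loads(df.to_json(orient="table", index=False))

    return {
        "metadata": results.metadata,
        "thresholds": results.thresholds,
        "grs_cutoff": results.grs_cutoff,
        "exposure_medians": results.exposure_medians,
        "tables": {
            "qc_report": frame(results.qc_report),
            "grs": frame(results.grs_df.reset_index()),
            "exposures": frame(results.exposures.reset_index()),
            "descriptives": frame(results.descriptives),
            "associations": frame(results.associations),
            "interactions": frame(results.interactions),
            "strata": frame(results.strata),
            "deciles": frame(results.deciles),
        },
    }


def write_bundle(results: ResultSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(result_bundle(results), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def report_from_bundle(path: str | Path, out_dir: str | Path) -> list[Path]:
    """Rewrite the TSV report files from a saved result bundle."""
    with open(path) as fh:
        bundle = json.load(fh)

    def frame(key):
        return pd.DataFrame(bundle["tables"][key]["data"])

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    mapping = {
        "qc_report": "qc.tsv", "grs": "grs.tsv", "exposures": "exposures.tsv",
        "descriptives": "descriptives.tsv", "associations": "associations.tsv",
        "interactions": "interactions.tsv", "strata": "strata.tsv",
        "deciles": "deciles.tsv",
    }
    for key, name in mapping.items():
        p = out / name
        frame(key).to_csv(p, sep="\t", index=False)
        written.append(p)
    meta = out / "run_metadata.json"
    with open(meta, "w") as fh:
        json.dump(bundle["metadata"], fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written.append(meta)
    return written
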
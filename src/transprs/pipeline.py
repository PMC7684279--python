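"""End-to-end orchestration: simulate/read -> QC -> harmonize -> prune ->
score -> associate/survive, driven by a config mapping (YAML-compatible).

Every stage writes its artifacts under the output directory and records
variant counts, so the run log reconciles exactly: variants out of each
stage equal variants in minus logged exclusions. All randomness funnels
through the single seed recorded in the manifest; two runs with the same
config and seed produce byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .prs import DEFAULT_GRID, ThresholdGrid, prs_profile
from .prune import PruneConfig, prune_report, prune_window
from .qc import QcThresholds, harmonize, variant_qc
from .simulate import (DISCOVERY_TRAITS, SimulationConfig,
                       generate_fixture_set)
from .stats import (anova_from_summaries, code_groups, group_trend,
                    interaction_test, km_logrank, late_initiation_rates,
                    pearson_chi2, results_table, scan_thresholds)

logger = logging.getLogger("transprs")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Either ``simulate`` (keyword overrides for
    :class:`~transprs.simulate.SimulationConfig`) or ``inputs`` (paths to
    ``sumstats`` per trait, ``dosages`` + ``dialect``, ``phenotypes``)
    must be provided.
    """

    output_dir: str = "pipeline_out"
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    prune: PruneConfig = field(default_factory=PruneConfig)
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    traits: tuple = tuple(DISCOVERY_TRAITS)
    #: phenotype columns entered as covariates in an *additional*,
    #: adjusted scan per analysis (e.g. ("age", "sex")); the unadjusted
    #: scan is always emitted
    covariates: tuple = ()
    strict: bool = True

    def __post_init__(self):
        if isinstance(self.qc, Mapping):
            self.qc = QcThresholds(**{**self.qc, "drop_chroms":
                                      frozenset(self.qc.get("drop_chroms",
                                                            ("Y", "MT")))})
        if isinstance(self.prune, Mapping):
            self.prune = PruneConfig(**self.prune)
        if not isinstance(self.grid, ThresholdGrid):
            self.grid = ThresholdGrid(tuple(self.grid))
        self.covariates = tuple(self.covariates)
        unknown = set(self.covariates) - set(gio.PHENOTYPE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown covariate column(s): {sorted(unknown)}")
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs a 'simulate' or an 'inputs' block")
        if self.inputs is not None:
            for key in ("sumstats", "dosages", "phenotypes"):
                if key not in self.inputs:
                    raise ValueError(f"inputs block lacks {key!r}")
            for trait, path in self.inputs["sumstats"].items():
                if not Path(path).exists():
                    raise ValueError(f"missing sumstats file for {trait}: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _target_outcome(trait: str, pheno: pd.DataFrame):
    """(mask, y, model) for the target-side analysis matching a trait."""
    if trait == "initiation":
        mask = pheno["ever_smoker"].notna().to_numpy()
        y = pheno.loc[mask, "ever_smoker"].to_numpy(float)
        return mask, y, "logistic"
    ever = (pheno["ever_smoker"] == 1).to_numpy()
    if trait == "age_initiation":
        mask = ever & pheno["age_initiation"].notna().to_numpy()
        y = np.log(pheno.loc[mask, "age_initiation"].to_numpy(float))
        return mask, y, "linear"
    if trait == "quantity":
        mask = ever & pheno["cpd"].notna().to_numpy()
        return mask, pheno.loc[mask, "cpd"].to_numpy(float), "linear"
    if trait == "cessation":
        mask = ever & pheno["current_smoker"].notna().to_numpy()
        return mask, pheno.loc[mask, "current_smoker"].to_numpy(float), "logistic"
    raise ValueError(f"unknown trait {trait!r}")


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Execute every stage; returns the manifest of written result files."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    counts = []
    try:
        # ---- stage: inputs -------------------------------------------------
        if config.simulate is not None:
            sim_cfg = SimulationConfig(**{**config.simulate,
                                          "seed": config.seed})
            fixdir = outdir / "fixtures"
            logger.info("simulating fixture set into %s", fixdir)
            generate_fixture_set(sim_cfg, fixdir, traits=config.traits)
            sumstat_paths = {t: fixdir / f"sumstats_{t}.tsv"
                             for t in config.traits}
            dosage_path, dialect = fixdir / "target.dosage.tsv", "dosage-tsv"
            pheno_path = fixdir / "phenotypes.tsv"
        else:
            sumstat_paths = {t: Path(p)
                             for t, p in config.inputs["sumstats"].items()}
            dosage_path = Path(config.inputs["dosages"])
            dialect = config.inputs.get("dialect", "dosage-tsv")
            pheno_path = Path(config.inputs["phenotypes"])

        sumstats = {t: gio.read_summary_stats(p, strict=config.strict)
                    for t, p in sumstat_paths.items()}
        panel = gio.read_dosages(dosage_path, dialect)
        pheno = gio.read_phenotypes(pheno_path, strict=config.strict)
        pheno = pheno.set_index("sample_id").loc[panel.samples].reset_index()
        logger.info("loaded %d samples x %d variants, %d traits",
                    panel.n_samples, panel.n_variants, len(sumstats))

        # ---- stage: QC -----------------------------------------------------
        n_in = panel.n_variants
        kept_ids, qc_log = variant_qc(panel, config.qc)
        qcdir = outdir / "qc"
        qcdir.mkdir(exist_ok=True)
        qc_log.to_csv(qcdir / "exclusions.tsv", sep="\t", index=False)
        (qcdir / "kept_ids.txt").write_text("\n".join(kept_ids) + "\n")
        panel = panel.subset_variants(kept_ids)
        counts.append({"stage": "qc", "n_in": n_in, "n_out": len(kept_ids),
                       "n_excluded": len(qc_log)})
        logger.info("QC kept %d/%d variants", len(kept_ids), n_in)

        # ---- stage: harmonize ---------------------------------------------
        harmonized = {}
        for trait, ss in sumstats.items():
            h = harmonize(ss, panel.variants)
            harmonized[trait] = h
            n_ok = int(h["aligned_weight"].notna().sum())
            counts.append({"stage": f"harmonize:{trait}", "n_in": len(h),
                           "n_out": n_ok, "n_excluded": len(h) - n_ok})

        # ---- stage: prune (once, on the full QC-passing panel) ------------
        # priority: smallest discovery p across traits keeps the SNP most
        # informative for any score
        pmin = pd.concat([h.set_index("variant_id")["p_value"]
                          for h in harmonized.values()], axis=1).min(axis=1)
        kept = prune_window(panel, config.prune,
                            priorities=pmin if config.prune.priority ==
                            "p-value" else None)
        prdir = outdir / "prune"
        prdir.mkdir(exist_ok=True)
        (prdir / "kept_ids.txt").write_text("\n".join(kept) + "\n")
        prune_report(panel, kept).to_csv(prdir / "report.tsv", sep="\t",
                                         index=False)
        counts.append({"stage": "prune", "n_in": panel.n_variants,
                       "n_out": len(kept),
                       "n_excluded": panel.n_variants - len(kept)})
        logger.info("pruning kept %d/%d variants", len(kept), panel.n_variants)
        panel = panel.subset_variants(kept)

        # ---- stage: score --------------------------------------------------
        tables = {}
        profiles = {}
        for trait, h in harmonized.items():
            profile = prs_profile(panel, h, config.grid)
            profiles[trait] = profile
            tables[f"profile_{trait}"] = profile.to_frame()
            tables[f"snp_counts_{trait}"] = pd.DataFrame({
                "threshold": list(profile.cutoffs),
                "n_snps": profile.snp_counts})

        # ---- stage: association scans --------------------------------------
        groups = pheno["group"].to_numpy()
        cov_all = (pheno[list(config.covariates)]
                   if config.covariates else None)
        for trait, profile in profiles.items():
            mask, y, model = _target_outcome(trait, pheno)
            if len(np.unique(y)) >= 2:
                sub = _subset_profile(profile, mask)
                res, best = scan_thresholds(sub, y, model=model)
                tables[f"assoc_{trait}"] = results_table(res)
                if cov_all is not None:
                    res_a, _ = scan_thresholds(
                        sub, y, covariates=cov_all[mask].reset_index(drop=True),
                        model=model)
                    tables[f"assoc_{trait}_adjusted"] = results_table(res_a)
            # diagnosis three-group trend scan
            res_dx, best_dx = scan_thresholds(profile, code_groups(groups),
                                              model="linear")
            tables[f"assoc_diagnosis_{trait}"] = results_table(res_dx)
            if cov_all is not None:
                res_dxa, _ = scan_thresholds(profile, code_groups(groups),
                                             covariates=cov_all,
                                             model="linear")
                tables[f"assoc_diagnosis_{trait}_adjusted"] = \
                    results_table(res_dxa)
            _, summary = group_trend(profile.column(best_dx.threshold), groups)
            summary.insert(0, "threshold", best_dx.threshold)
            tables[f"group_summary_{trait}"] = summary
            # PRS x smoking-status interaction on case/control risk
            cc = groups != "FR"
            status = (pheno["ever_smoker"].to_numpy(float) == 1)[cc]
            diag = (groups[cc] == "SCZ").astype(float)
            prs_cc = profile.column(best_dx.threshold)[cc]
            try:
                p_int = interaction_test(prs_cc, status, diag)
                note = ""
            except ValueError as e:
                p_int, note = np.nan, str(e)
            tables[f"interaction_{trait}"] = pd.DataFrame(
                [{"threshold": best_dx.threshold, "p_value": p_int,
                  "note": note}])

        # ---- stage: survival and demographic tests -------------------------
        ever = pheno["ever_smoker"] == 1
        t_surv = np.where(ever, pheno["age_initiation"], pheno["age"])
        ok = ~pd.isna(t_surv)
        surv = km_logrank(t_surv[ok].astype(float), ever.to_numpy()[ok],
                          groups[ok])
        curve_frames = []
        for g, c in surv.curves.items():
            c = c.copy()
            c.insert(0, "group", g)
            curve_frames.append(c)
        tables["survival_curves"] = pd.concat(curve_frames, ignore_index=True)
        tables["survival_test"] = pd.DataFrame([{
            "statistic": surv.statistic, "df": surv.df,
            "p_value": surv.p_value, "note": surv.test_error or ""}])
        rates, p_late, note = late_initiation_rates(pheno)
        tables["late_initiation"] = rates.assign(adjusted_p=p_late,
                                                 note=note or "")
        tables["demographic_tests"] = _demographic_tests(pheno)

        # ---- write ----------------------------------------------------------
        manifest = gio.write_results(tables, outdir / "results")
        pd.DataFrame(counts).to_csv(outdir / "stage_counts.tsv", sep="\t",
                                    index=False)
        seed_note = pd.DataFrame([{"seed": config.seed,
                                   "n_result_files": len(manifest)}])
        seed_note.to_csv(outdir / "run_info.tsv", sep="\t", index=False)
        logger.info("pipeline finished in %.1f s; %d result tables",
                    time.time() - t0, len(manifest))
        return manifest
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _subset_profile(profile, mask: np.ndarray):
    from .prs import PrsProfile
    return PrsProfile([s for s, m in zip(profile.samples, mask) if m],
                      profile.cutoffs, profile.scores[mask],
                      profile.snp_counts, profile.standardized)


def _demographic_tests(pheno: pd.DataFrame) -> pd.DataFrame:
    """Contingency and summary-ANOVA tests over the diagnostic groups."""
    rows = []
    by = pheno.groupby("group")

    def table(cols_fn):
        return [cols_fn(by.get_group(g)) for g in ("HC", "FR", "SCZ")
                if g in by.groups]

    try:
        t = table(lambda d: [(d["ever_smoker"] == 1).sum(),
                             (d["ever_smoker"] == 0).sum()])
        stat, df, p = pearson_chi2(t)
        rows.append({"test": "chi2_ever_never", "statistic": stat,
                     "df": df, "p_value": p})
    except ValueError:
        pass
    try:
        t = table(lambda d: [(d["current_smoker"] == 1).sum(),
                             (d["current_smoker"] == 0).sum()])
        stat, df, p = pearson_chi2(t)
        rows.append({"test": "chi2_current_former", "statistic": stat,
                     "df": df, "p_value": p})
    except ValueError:
        pass
    try:
        t = table(lambda d: [(d["sex"] == "M").sum(), (d["sex"] == "F").sum()])
        stat, df, p = pearson_chi2(t)
        rows.append({"test": "chi2_sex", "statistic": stat, "df": df,
                     "p_value": p})
    except ValueError:
        pass
    for name, col, subset in (("anova_age_initiation", "age_initiation", True),
                              ("anova_cpd", "cpd", True),
                              ("anova_age", "age", False)):
        try:
            summaries = []
            for g in ("HC", "FR", "SCZ"):
                if g not in by.groups:
                    continue
                d = by.get_group(g)
                v = d.loc[d["ever_smoker"] == 1, col] if subset else d[col]
                v = v.dropna()
                summaries.append((len(v), v.mean(), v.std(ddof=1)))
            f, dfb, dfw, p = anova_from_summaries(summaries)
            rows.append({"test": name, "statistic": f, "df": dfb,
                         "p_value": p})
        except ValueError:
            pass
    return pd.DataFrame(rows, columns=["test", "statistic", "df", "p_value"])
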
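"""End-to-end orchestration: simulate -> score -> prep -> diversity ->
associate -> differential abundance -> cluster -> validate index.

``run_all`` executes every stage in dependency order on a synthetic
cohort, writes each stage's tables under an output directory, and
returns a machine-readable report with per-stage counts and the headline
statistics (alpha-diversity slope, PERMANOVA R^2, number of significant
species, cluster count, pooled hazard ratio).  The whole run is
deterministic under the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, cluster as cluster_mod, da as da_mod, diversity
from . import prep, scoring, simulate, survival
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


def adjustment_matrix(phenotypes: pd.DataFrame,
                      include_bmi: bool = False) -> pd.DataFrame:
    """The study's confounder set for microbiome models: sex, age,
    energy intake, smoking status and microbiome-altering medication,
    plus BMI for exposures other than the index or the anthropometric
    components."""
    cov = pd.DataFrame({
        "sex_man": (phenotypes["sex"] == "man").astype(float),
        "age": phenotypes["age"].astype(float),
        "energy": phenotypes["energy"].astype(float),
        "smoker": (phenotypes["smoking"] == "smoker").astype(float),
        "medication": phenotypes["medication"].astype(float),
    }, index=phenotypes.index)
    if include_bmi:
        cov["bmi"] = phenotypes["bmi"].astype(float)
    return cov


def survival_adjustment_matrix(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Confounders for the Cox models: sex, age, energy and smoking."""
    return pd.DataFrame({
        "sex_man": (phenotypes["sex"] == "man").astype(float),
        "age": phenotypes["age"].astype(float),
        "energy": phenotypes["energy"].astype(float),
        "smoker": (phenotypes["smoking"] == "smoker").astype(float),
    }, index=phenotypes.index)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "crcmicro_run"
    seed: int = 0
    simulation: simulate.SimulationConfig | None = None
    min_reads: int = prep.DEFAULT_MIN_READS
    min_prevalence: float = prep.DEFAULT_MIN_PREVALENCE
    min_mean_relabund: float = prep.DEFAULT_MIN_MEAN_RELABUND
    n_perm: int = assoc.DEFAULT_N_PERM
    fdr_level: float = 0.05
    run_survival: bool = True
    run_beta: bool = True

    def __post_init__(self):
        if not 0 < self.fdr_level < 1:
            raise ConfigurationError("fdr_level must lie in (0, 1)")
        if self.simulation is None:
            self.simulation = simulate.SimulationConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            planted = sim_raw.pop("planted_taxa", None)
            if planted is not None:
                sim_raw["planted_taxa"] = [
                    simulate.PlantedTaxon(**p) for p in planted]
            if "depth_range" in sim_raw:
                sim_raw["depth_range"] = tuple(sim_raw["depth_range"])
            sim_raw.setdefault("seed", cfg.seed)
            cfg.simulation = simulate.SimulationConfig(**sim_raw)
        return cfg


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    report: dict = {"seed": config.seed, "stages": {}}

    def stage(name, **info):
        logger.info("stage %s: %s", name, info)
        report["stages"][name] = {"status": "complete", **info}

    # -- simulate -----------------------------------------------------
    pheno = simulate.generate_phenotypes(sim)
    pheno.to_csv(out / "phenotypes.tsv", sep="\t")
    stage("simulate", n_participants=len(pheno))

    # -- score --------------------------------------------------------
    scores = scoring.compute_index(pheno)
    scores.to_csv(out / "index_scores.tsv", sep="\t")
    index = scores["total"].to_numpy()
    stage("score", median_index=float(np.median(index)),
          quintile_sizes=np.bincount(scores["quintile"])[1:].tolist())

    # -- microbiome + prep -------------------------------------------
    table, tree, truth = simulate.generate_microbiome(pheno, index, sim)
    prep.write_feature_table(table, out / "counts.tsv")
    tree.write(str(out / "tree.nwk"))
    truth.hazard_log_hr = sim.hazard_log_hr
    truth.to_json(out / "ground_truth.json")

    qc = prep.qc_filter_samples(table, config.min_reads)
    filtered = prep.filter_rare_species(qc, config.min_prevalence,
                                        config.min_mean_relabund)
    props = prep.relative_abundance(filtered)
    stage("prep", samples_after_qc=qc.n_samples,
          taxa_after_filter=filtered.n_taxa)

    kept = filtered.data.index
    pheno_k = pheno.loc[kept]
    scores_k = scores.loc[kept]
    index_k = scores_k["total"].to_numpy()
    cov = adjustment_matrix(pheno_k)

    # -- diversity ----------------------------------------------------
    alpha = diversity.shannon(filtered)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    alpha_fit = assoc.ols_adjusted(alpha.to_numpy(), index_k, cov,
                                   standardize=False, exposure_name="index")
    stage("alpha", beta=alpha_fit.beta, se=alpha_fit.se, p=alpha_fit.p)

    report["alpha_beta"] = alpha_fit.beta
    report["alpha_p"] = alpha_fit.p

    perm_r2 = perm_p = None
    if config.run_beta:
        dm = diversity.weighted_unifrac(props, tree)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            out / "weighted_unifrac.tsv", sep="\t")
        perm = assoc.permanova(dm, index_k, cov, n_perm=config.n_perm,
                               seed=config.seed, term="index")
        disp = assoc.beta_dispersion(dm, scores_k["quintile"].to_numpy(),
                                     n_perm=config.n_perm, seed=config.seed,
                                     dimensions=10)
        design = pd.concat(
            [pd.Series(index_k, index=kept, name="index"), cov], axis=1)
        rda = assoc.dbrda(dm, design, n_perm=config.n_perm, seed=config.seed)
        ordi = assoc.pcoa(dm)
        extreme = scores_k["quintile"].isin(
            [1, scores_k["quintile"].max()]).to_numpy()
        ff = assoc.factor_fit(
            ordi.coordinates.to_numpy()[extreme][:, :2],
            scores_k["quintile"].to_numpy()[extreme],
            n_perm=config.n_perm, seed=config.seed)
        stage("beta", permanova_r2=perm.r2, permanova_p=perm.p_value,
              dispersion_p=disp.p_value,
              constrained_proportion=rda.constrained_proportion,
              dbrda_p=rda.p_value, factorfit_p=ff.p_value)
        perm_r2, perm_p = perm.r2, perm.p_value
        report["permanova_r2"] = perm.r2
        report["dbrda_constrained_pct"] = 100 * rda.constrained_proportion

    # -- differential abundance --------------------------------------
    da_table = da_mod.sensitivity_screen(filtered, index_k, cov)
    da_table.to_csv(out / "differential_abundance.tsv", sep="\t")
    selected = da_table.index[(da_table["q"] < config.fdr_level)
                              & da_table["sensitivity_pass"]]
    stage("da", n_taxa_tested=int((~da_table["p"].isna()).sum()),
          n_significant=int((da_table["q"] < config.fdr_level).sum()),
          n_passed_screen=len(selected))
    report["n_da_significant"] = len(selected)

    # -- clustering ---------------------------------------------------
    if len(selected) >= 3:
        assignment, tree_link, _ = cluster_mod.assign_clusters(
            filtered, list(selected))
        assoc_table = cluster_mod.cluster_association(
            filtered, assignment, index_k, cov)
        assignment.labels.to_csv(out / "cluster_assignment.tsv", sep="\t")
        assoc_table.to_csv(out / "cluster_associations.tsv", sep="\t")
        clr = cluster_mod.clr_transform(filtered)
        heat = clr[assignment.labels.index].T
        heat.insert(0, "cluster", assignment.labels)
        heat.to_csv(out / "heatmap_table.tsv", sep="\t")
        stage("cluster", k=assignment.k,
              n_significant_clusters=int(assoc_table["significant"].sum()))
        report["n_clusters"] = assignment.k
    else:
        stage("cluster", skipped="fewer than 3 screened taxa")

    # -- survival validation ------------------------------------------
    if config.run_survival:
        cohorts = simulate.generate_multicohort(sim)
        betas, variances, rows = [], [], []
        for i, cohort in enumerate(cohorts, 1):
            cov_s = survival_adjustment_matrix(cohort)
            design = pd.concat(
                [cohort["index_total"].rename("index"), cov_s], axis=1)
            fit = survival.cox_fit(cohort["time"], cohort["event"], design)
            betas.append(fit.beta[0])
            variances.append(fit.se[0] ** 2)
            rows.append({"cohort": i, "n": len(cohort),
                         "events": fit.n_events,
                         "log_hr": fit.beta[0], "se": fit.se[0]})
        meta = survival.meta_pool(betas, variances)
        pd.DataFrame(rows).to_csv(out / "cohort_cox.tsv", sep="\t",
                                  index=False)
        pooled = cohorts[0]
        quint = survival.quintile_model(
            pooled["time"], pooled["event"], pooled["quintile"],
            survival_adjustment_matrix(pooled))
        trend = survival.trend_test(
            pooled["time"], pooled["event"], pooled["quintile"],
            pooled["index_total"], survival_adjustment_matrix(pooled))
        quint.to_csv(out / "quintile_hr.tsv", sep="\t")
        stage("validate_index", pooled_hr=meta.pooled_hr,
              pooled_ci=list(meta.ci()), tau2=meta.tau2,
              p_heterogeneity=meta.p_heterogeneity,
              p_trend=float(trend.p_value[0]))
        report["pooled_hr"] = meta.pooled_hr
        report["p_heterogeneity"] = meta.p_heterogeneity

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
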
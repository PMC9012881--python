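"""Config-driven orchestration of the full analysis.

Stages run in the order the analysis dictates: metabolome preprocessing and
pre/post-NF labeling, unsupervised statistics and univariate screening,
sPLS-DA signature extraction, microbiome QC and diversity, serum-stool
integration by zero-sum sparse log-contrast regression, and the two
sensitivity re-tests (bacteremia-excluded; last-pre/first-post).  A single
global seed fans out to per-stage seeds through a fixed spawn order
(0 simulate, 1 impute, 2 permanova, 3 sPLS-DA, 4 microbiome, 5 integration,
6 sensitivity), so any stage can be re-run in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import integration, metabolome, microbiome, multivariate, splsda, synthetic

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "impute", "permanova", "splsda", "microbiome", "integration",
           "sensitivity")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage 31-bit seeds spawned from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(c.generate_state(1)[0] % (2**31))
        for name, c in zip(_STAGES, children)
    }


@dataclass
class Thresholds:
    """All analysis thresholds, defaulting to the study's stated values."""

    detectability_min_fraction: float = 0.5
    impute_noise_sd_fraction: float = 0.01
    log_concentrations: bool = True
    asv_min_prevalence: float = 0.10
    sample_min_reads: int = 5000
    sample_min_copies: int = 1000
    genus_min_prevalence: float = 0.20
    max_lag_days: int = 3
    cv_folds: int = 10
    n_bootstraps: int = 100
    stability_threshold: float = 0.90
    n_permutations: int = 999
    splsda_keepx_grid: tuple[int, ...] = (5, 10, 15, 20, 30, 50)
    splsda_ncomp: int = 1
    splsda_stability_repeats: int = 10
    clr_pseudocount: float = 0.5

    def validate(self) -> None:
        for name in ("detectability_min_fraction", "asv_min_prevalence",
                     "genus_min_prevalence", "stability_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("cv_folds", "n_bootstraps", "n_permutations", "max_lag_days",
                     "splsda_ncomp", "splsda_stability_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulateBlock:
    """Synthetic-cohort settings used when no input paths are given."""

    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    n_metabolites: int = 300
    n_signature: int = 15
    shift_log2fc: float = 1.5
    detection_floor_quantile: float = 0.10
    n_genera: int = 20
    n_linked_metabolites: int = 3
    association_nonzeros: int = 3


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "nfomics_out"
    inputs: dict | None = None          # paths: metabolome, counts, taxonomy, metadata
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc, data, ctx):
            names = {f.name for f in dataclasses.fields(dc)}
            unknown = set(data) - names
            if unknown:
                raise ValueError(f"unknown config keys in {ctx}: {sorted(unknown)}")
            return data

        data = dict(build(cls, raw, "top level"))
        if "thresholds" in data:
            data["thresholds"] = Thresholds(
                **{k: (tuple(v) if isinstance(v, list) else v)
                   for k, v in build(Thresholds, data["thresholds"], "thresholds").items()}
            )
        if "simulate" in data:
            sim = dict(build(SimulateBlock, data["simulate"], "simulate"))
            if "cohort" in sim:
                sim["cohort"] = synthetic.CohortConfig(
                    **{k: (tuple(v) if isinstance(v, list) else v)
                       for k, v in build(
                           synthetic.CohortConfig, sim["cohort"], "simulate.cohort"
                       ).items()}
                )
            data["simulate"] = SimulateBlock(**sim)
        cfg = cls(**data)
        cfg.thresholds.validate()
        return cfg


# ---------------------------------------------------------------------------
# data loading / simulation
# ---------------------------------------------------------------------------

def load_or_simulate(config: PipelineConfig):
    """Return (metadata, metabolome matrix, counts, taxonomy, truth-or-None)."""
    if config.inputs:
        paths = config.inputs
        meta = pd.read_csv(paths["metadata"], sep="\t")
        values = metabolome.read_metabolite_tsv(paths["metabolome"])
        counts = microbiome.read_count_table(paths["counts"])
        taxonomy = microbiome.read_taxonomy(paths["taxonomy"])
        return meta, values, counts, taxonomy, None

    sim = config.simulate
    seeds = stage_seeds(config.seed)
    met_truth = synthetic.MetabolomeTruth(
        n_metabolites=sim.n_metabolites,
        signature_ids=tuple(range(sim.n_signature)),
        shift_log2fc=sim.shift_log2fc,
        detection_floor_quantile=sim.detection_floor_quantile,
    )
    B = synthetic.default_association_matrix(
        sim.n_genera,
        list(range(min(sim.n_linked_metabolites, sim.n_signature))),
        nonzeros_per_column=sim.association_nonzeros,
        seed=seeds["simulate"],
    )
    mic_truth = synthetic.MicrobiomeTruth(
        n_genera=sim.n_genera, association_matrix=B
    )
    cohort = synthetic.generate_cohort(
        dataclasses.replace(sim.cohort, seed=seeds["simulate"]),
        met_truth,
        mic_truth,
    )
    return cohort.sample_metadata, cohort.metabolome, cohort.counts, cohort.taxonomy, cohort


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write artifacts; returns the run report."""
    t0 = time.time()
    thr = config.thresholds
    seeds = stage_seeds(config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "thresholds": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(thr).items()
        },
        "stages": {},
    }

    def stage(name):
        logger.info("stage %s (%.1fs elapsed)", name, time.time() - t0)
        return report["stages"].setdefault(name, {})

    # ---- inputs -----------------------------------------------------------
    meta, values, counts, taxonomy, cohort = load_or_simulate(config)
    serum_meta = meta[meta["type"] == "serum"].reset_index(drop=True)
    stool_meta = meta[meta["type"] == "stool"].reset_index(drop=True)
    nf_days = meta.drop_duplicates("patient_id").set_index("patient_id")["nf_day"]
    rec = stage("inputs")
    rec.update(
        n_patients=int(meta["patient_id"].nunique()),
        n_serum=len(serum_meta), n_stool=len(stool_meta),
        n_metabolites=values.shape[1], n_asvs=counts.shape[1],
    )

    # ---- metabolome prep --------------------------------------------------
    groups = metabolome.assign_nf_groups(serum_meta, nf_days)
    filtered = metabolome.filter_detectability(values, thr.detectability_min_fraction)
    imputed = metabolome.impute_half_min(
        filtered, thr.impute_noise_sd_fraction, seed=seeds["impute"]
    )
    analysis_matrix = metabolome.log_transform(imputed) if thr.log_concentrations else imputed
    rec = stage("metabolome_prep")
    rec.update(
        n_metabolites_in=values.shape[1],
        n_metabolites_detectable=filtered.shape[1],
        n_pre=int((groups == metabolome.PRE).sum()),
        n_post=int((groups == metabolome.POST).sum()),
    )
    groups.to_frame().to_csv(outdir / "groups.tsv", sep="\t")
    metabolome.write_metabolite_tsv(imputed, outdir / "metabolome_imputed.tsv")

    # ---- multivariate stats ----------------------------------------------
    bc = multivariate.bray_curtis_matrix(imputed)
    perm_group = multivariate.permanova(
        bc, groups.reindex(imputed.index), n_perm=thr.n_permutations,
        seed=seeds["permanova"],
    )
    patient_of = serum_meta.set_index("sample_id")["patient_id"]
    perm_patient = multivariate.permanova(
        bc, patient_of.reindex(imputed.index), n_perm=thr.n_permutations,
        seed=seeds["permanova"] + 1,
    )
    volcano = multivariate.welch_volcano(
        analysis_matrix, groups, values_are_log=thr.log_concentrations
    )
    volcano.to_csv(outdir / "volcano.tsv", sep="\t")
    scores, _, evr = multivariate.pca(analysis_matrix)
    scores.iloc[:, :2].to_csv(outdir / "pca_scores.tsv", sep="\t")
    significant = volcano.index[volcano["q"] < 0.05]
    if len(significant) >= 2:
        _, leaf_order = multivariate.hierarchical_cluster(analysis_matrix[significant])
        pd.Series(leaf_order, name="sample_id").to_csv(
            outdir / "cluster_leaf_order.tsv", sep="\t", index=False
        )
    rec = stage("multivariate_stats")
    rec.update(
        permanova_group_r2=perm_group.r2, permanova_group_p=perm_group.p_value,
        permanova_patient_r2=perm_patient.r2,
        n_significant=int(len(significant)),
        pc1_pc2_variance=float(evr.iloc[:2].sum()),
    )

    # ---- sPLS-DA ----------------------------------------------------------
    y = groups.reindex(analysis_matrix.index).to_numpy()
    grid = [k for k in thr.splsda_keepx_grid if k <= analysis_matrix.shape[1]]
    ncomp, keepx, _ = splsda.tune_splsda(
        analysis_matrix, y, grid, ncomp_max=thr.splsda_ncomp,
        folds=thr.cv_folds, seed=seeds["splsda"],
    )
    stab = splsda.stability_select_splsda(
        analysis_matrix, y, keepx, ncomp=ncomp,
        threshold=thr.stability_threshold, folds=thr.cv_folds,
        repeats=thr.splsda_stability_repeats, seed=seeds["splsda"],
    )
    signature = stab.index[stab["stable"]].tolist()
    auc, roc, _ = splsda.loocv_auc(analysis_matrix, y, keepx, ncomp=ncomp)
    stab.to_csv(outdir / "splsda_stability.tsv", sep="\t")
    roc.to_csv(outdir / "roc.tsv", sep="\t", index=False)
    rec = stage("splsda")
    rec.update(
        ncomp=ncomp, keepX=list(map(int, keepx)),
        signature=signature, signature_size=len(signature),
        loocv_auc=float(auc),
    )

    # ---- microbiome prep --------------------------------------------------
    counts_f = microbiome.filter_asvs_samples(
        counts, min_asv_prevalence=thr.asv_min_prevalence,
        min_reads=thr.sample_min_reads, min_copies=thr.sample_min_copies,
    )
    stool_groups = metabolome.assign_nf_groups(
        stool_meta[stool_meta["sample_id"].isin(counts_f.index)], nf_days
    )
    srs = microbiome.srs_normalize(counts_f, seed=seeds["microbiome"])
    alpha, alpha_p = microbiome.alpha_diversity_compare(srs, stool_groups)
    _, aitchison = microbiome.clr_aitchison(counts_f, thr.clr_pseudocount)
    perm_beta = multivariate.permanova(
        aitchison, stool_groups.reindex(counts_f.index),
        n_perm=thr.n_permutations, seed=seeds["microbiome"],
    )
    genus = microbiome.aggregate_genera(counts_f, taxonomy)
    alpha.to_frame().to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    rec = stage("microbiome_prep")
    rec.update(
        n_asvs_in=counts.shape[1], n_asvs_kept=counts_f.shape[1],
        n_stool_in=counts.shape[0], n_stool_kept=counts_f.shape[0],
        alpha_wilcoxon_p=float(alpha_p),
        beta_permanova_r2=perm_beta.r2, beta_permanova_p=perm_beta.p_value,
        n_genera=genus.shape[1],
    )

    # ---- integration ------------------------------------------------------
    assoc, pairs, _ = integration.run_integration(
        serum_meta, stool_meta, imputed, genus,
        metabolites=signature,
        max_lag_days=thr.max_lag_days,
        min_prevalence=thr.genus_min_prevalence,
        pseudocount=thr.clr_pseudocount,
        folds=thr.cv_folds,
        n_bootstraps=thr.n_bootstraps,
        threshold=thr.stability_threshold,
        seed=seeds["integration"],
    )
    assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    rec = stage("integration")
    rec.update(n_pairs=len(pairs), **integration.association_summary(assoc))

    # ---- sensitivity ------------------------------------------------------
    if signature:
        bact = None
        if "bacteremia" in meta.columns:
            bact = meta.drop_duplicates("patient_id").set_index("patient_id")["bacteremia"]
        elif cohort is not None:
            bact = cohort.skeleton.patients["bacteremia"]
        if bact is not None:
            sens1, sens2 = sensitivity_analyses(
                analysis_matrix, serum_meta, groups, nf_days, bact, signature,
                values_are_log=thr.log_concentrations,
            )
            sens1.to_csv(outdir / "sensitivity_no_bacteremia.tsv", sep="\t")
            sens2.to_csv(outdir / "sensitivity_last_first.tsv", sep="\t")
            rec = stage("sensitivity")
            rec.update(
                n_flagged_patients=int(bact.sum()),
                analysis1_n_significant=int((sens1["p"] < 0.05).sum()),
                analysis2_n_significant=int((sens2["p"] < 0.05).sum()),
            )
            if int(bact.sum()) == 0:
                rec["note"] = "no flagged patients: analysis 1 equals the main analysis"

    report["runtime_seconds"] = round(time.time() - t0, 2)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def sensitivity_analyses(
    analysis_matrix: pd.DataFrame,
    serum_meta: pd.DataFrame,
    groups: pd.Series,
    nf_days: pd.Series,
    bacteremia: pd.Series,
    signature: list[str],
    values_are_log: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two exploratory re-tests of the signature metabolites.

    Analysis 1 repeats the Welch tests after excluding patients flagged with
    bloodstream infection.  Analysis 2 keeps only each patient's last pre-NF
    and first post-NF sample.  Both return per-metabolite Welch p-values.
    """
    if not signature:
        raise ValueError("signature metabolite list is empty")
    X = analysis_matrix[signature]
    patient_of = serum_meta.set_index("sample_id")["patient_id"]

    keep_patients = bacteremia.index[~bacteremia.astype(bool)]
    mask1 = patient_of.reindex(X.index).isin(keep_patients).to_numpy()
    sens1 = multivariate.welch_volcano(
        X.loc[mask1], groups, values_are_log=values_are_log
    )[["log2fc", "t", "p"]]

    meta = serum_meta.set_index("sample_id").loc[X.index].copy()
    meta["group"] = groups.reindex(X.index)
    keep_ids = []
    for pid, grp in meta.groupby("patient_id"):
        pre = grp[grp["group"] == metabolome.PRE]
        post = grp[grp["group"] == metabolome.POST]
        if not pre.empty:
            keep_ids.append(pre["day"].idxmax())
        if not post.empty:
            keep_ids.append(post["day"].idxmin())
    sens2 = multivariate.welch_volcano(
        X.loc[keep_ids], groups, values_are_log=values_are_log
    )[["log2fc", "t", "p"]]
    return sens1, sens2
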
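"""Synthetic longitudinal paired-omics cohorts with known ground truth.

Emulates a biorepository study of hospitalized chemotherapy patients: serum
and stool are collected on a twice-weekly grid (with a one-day scheduling
window) from admission until end of follow-up; each patient may develop
neutropenic fever (NF) on some day, splitting their samples into pre- and
post-NF groups.  The generator plants two kinds of signal that the analysis
pipeline is meant to recover:

* a pre/post-NF mean shift on a designated subset of serum metabolites
  (the "signature"), with concentrations drawn log-normally and censored
  below a per-metabolite detection floor; and
* genus-to-metabolite associations of log-contrast form: selected serum
  metabolites are perturbed by ``z . b`` where ``z`` is the log relative
  genus abundance of the nearest preceding stool sample and ``b`` is a
  sparse coefficient vector summing to zero.

Stool taxon tables are multinomial draws (at variable depth) from a
log-normal genus composition model, with each genus split across a few
amplicon sequence variants (ASVs).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

_PATHWAYS = (
    "Amino Acid",
    "Lipid",
    "Nucleotide",
    "Carbohydrate",
    "Cofactors and Vitamins",
    "Xenobiotics",
    "Peptide",
    "Energy",
)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# configuration / truth records
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design parameters for the simulated cohort.

    Defaults mirror the source study's shape: follow-up to day 28, two
    collection days per week with a +/-1-day window, fever onset uniform on
    day -3..20 relative to chemotherapy start, and 3 of 36 patients never
    febrile.
    """

    n_patients: int = 36
    followup_days: int = 28
    sampling_days_per_week: int = 2
    nf_day_range: tuple[int, int] = (-3, 20)
    frac_never_nf: float = 3 / 36
    frac_bacteremia: float = 17 / 36
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if self.followup_days < 7:
            raise ConfigurationError("followup_days must be >= 7")
        lo, hi = self.nf_day_range
        if lo > hi:
            raise ConfigurationError("nf_day_range lower bound exceeds upper")
        if not 0 <= self.frac_never_nf <= 1:
            raise ConfigurationError("frac_never_nf must lie in [0, 1]")
        if not 0 <= self.frac_bacteremia <= 1:
            raise ConfigurationError("frac_bacteremia must lie in [0, 1]")
        if self.sampling_days_per_week < 1 or self.sampling_days_per_week > 7:
            raise ConfigurationError("sampling_days_per_week must be in 1..7")


@dataclass
class MetabolomeTruth:
    """Ground truth for the serum metabolome generator.

    ``shift_log2fc`` is the post-NF minus pre-NF difference of log2 mean
    concentration applied to each signature metabolite; ``detection_floor_quantile``
    is the fraction of each metabolite's values censored as missing (below
    its empirical detection floor).
    """

    n_metabolites: int = 300
    signature_ids: tuple[int, ...] = ()
    shift_log2fc: float = 1.5
    detection_floor_quantile: float = 0.10
    base_log_mean: float = 2.0
    base_log_sd: float = 1.0

    def validate(self) -> None:
        if self.n_metabolites < 1:
            raise ConfigurationError("n_metabolites must be >= 1")
        if any(i < 0 or i >= self.n_metabolites for i in self.signature_ids):
            raise ConfigurationError("signature_ids outside metabolite index set")
        if not math.isfinite(self.shift_log2fc):
            raise ConfigurationError("shift_log2fc must be finite")
        if not 0 <= self.detection_floor_quantile < 1:
            raise ConfigurationError("detection_floor_quantile must lie in [0, 1)")


@dataclass
class MicrobiomeTruth:
    """Ground truth for the stool microbiome and its metabolite links.

    ``association_matrix`` maps metabolite index -> coefficient vector over
    genera; every column must sum to zero exactly (the generative model is
    the same log-contrast form the analysis fits).  ``genus_log_mean`` /
    ``genus_log_sd`` parameterize the log-normal composition model; when
    ``genus_log_mean`` is None a fixed geometric decay of base abundances is
    used so a handful of genera dominate, as in real stool communities.
    """

    n_genera: int = 20
    asv_per_genus: int = 3
    association_matrix: dict[int, np.ndarray] = field(default_factory=dict)
    depth_range: tuple[int, int] = (5000, 50000)
    genus_log_mean: np.ndarray | None = None
    genus_log_sd: float = 1.0
    noise_sd: float = 0.5  # additive Gaussian noise (log scale) on linked metabolites

    def validate(self) -> None:
        if self.n_genera < 2:
            raise ConfigurationError("n_genera must be >= 2")
        if self.asv_per_genus < 1:
            raise ConfigurationError("asv_per_genus must be >= 1")
        lo, hi = self.depth_range
        if lo > hi or lo < 1:
            raise ConfigurationError("invalid depth_range")
        for met, col in self.association_matrix.items():
            col = np.asarray(col, dtype=float)
            if col.shape != (self.n_genera,):
                raise ConfigurationError(
                    f"association column for metabolite {met} has wrong length"
                )
            if abs(col.sum()) > 1e-12:
                raise ConfigurationError(
                    f"association column for metabolite {met} does not sum to zero"
                )
            if np.count_nonzero(col) == 1:
                raise ConfigurationError(
                    "a single nonzero coefficient cannot satisfy the zero-sum constraint"
                )

    def resolved_log_mean(self) -> np.ndarray:
        if self.genus_log_mean is not None:
            mu = np.asarray(self.genus_log_mean, dtype=float)
            if mu.shape != (self.n_genera,):
                raise ConfigurationError("genus_log_mean has wrong length")
            return mu
        # geometric decay of base abundance: ~2 decades between most and
        # least abundant genus
        return np.linspace(2.5, -2.5, self.n_genera)


def default_association_matrix(
    n_genera: int,
    metabolite_ids: list[int] | tuple[int, ...],
    nonzeros_per_column: int = 3,
    magnitude: float = 1.0,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Build a sparse zero-sum coefficient matrix for the forward model.

    Each column gets ``nonzeros_per_column`` nonzero genera: one positive of
    ``+magnitude`` and the rest splitting ``-magnitude`` equally, so the
    column sums to zero exactly.  Genera are drawn without replacement per
    column.
    """
    if nonzeros_per_column < 2:
        raise ConfigurationError("need >= 2 nonzeros per column for zero-sum")
    rng = np.random.default_rng(seed)
    B: dict[int, np.ndarray] = {}
    for met in metabolite_ids:
        col = np.zeros(n_genera)
        picks = rng.choice(n_genera, size=nonzeros_per_column, replace=False)
        col[picks[0]] = magnitude
        col[picks[1:]] = -magnitude / (nonzeros_per_column - 1)
        B[int(met)] = col
    return B


# ---------------------------------------------------------------------------
# cohort skeleton
# ---------------------------------------------------------------------------

@dataclass
class CohortSkeleton:
    """Patients, fever-onset days, infection flags and the sample schedule."""

    patients: pd.DataFrame   # index patient_id; columns nf_day (float, NaN=never), bacteremia (bool)
    samples: pd.DataFrame    # columns sample_id, patient_id, day, type ('serum'|'stool')
    config: CohortConfig

    @property
    def serum_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["type"] == "serum"].reset_index(drop=True)

    @property
    def stool_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["type"] == "stool"].reset_index(drop=True)


@dataclass
class SyntheticCohort:
    """A complete simulated cohort: metadata, both omics tables, and truth."""

    skeleton: CohortSkeleton
    metabolome: pd.DataFrame       # serum samples x metabolites, NaN = below detection
    pathways: pd.Series            # metabolite -> pathway annotation
    counts: pd.DataFrame           # stool samples x ASVs, integer counts
    taxonomy: pd.Series            # asv_id -> genus
    metabolome_truth: MetabolomeTruth
    microbiome_truth: MicrobiomeTruth

    @property
    def sample_metadata(self) -> pd.DataFrame:
        meta = self.skeleton.samples.copy()
        meta["nf_day"] = meta["patient_id"].map(self.skeleton.patients["nf_day"])
        return meta


def _week_offsets(per_week: int) -> list[int]:
    if per_week == 2:
        return [0, 3]  # Mon/Thu
    return sorted({round(7 * i / per_week) for i in range(per_week)})


def generate_cohort_skeleton(config: CohortConfig) -> CohortSkeleton:
    """Draw patients, NF onset days, and the jittered sample schedule.

    Scheduled days sit on the weekly grid (Mon/Thu for the default two per
    week); each serum and stool collection is independently shifted by a
    uniform draw from {-1, 0, +1} and clipped to the follow-up window.  The
    number of never-NF patients is ``round(frac_never_nf * n_patients)``;
    the remainder draw an onset day uniformly from ``nf_day_range``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_patients
    patient_ids = [f"P{i:03d}" for i in range(n)]
    n_never = int(round(config.frac_never_nf * n))
    never = set(rng.choice(n, size=n_never, replace=False).tolist())
    lo, hi = config.nf_day_range
    nf_days = np.array(
        [np.nan if i in never else float(rng.integers(lo, hi + 1)) for i in range(n)]
    )
    n_bact = int(round(config.frac_bacteremia * n))
    bact = np.zeros(n, dtype=bool)
    bact[rng.choice(n, size=n_bact, replace=False)] = True

    offsets = _week_offsets(config.sampling_days_per_week)
    grid = [
        7 * w + o
        for w in range(config.followup_days // 7 + 1)
        for o in offsets
        if 7 * w + o <= config.followup_days
    ]

    rows = []
    for i, pid in enumerate(patient_ids):
        for kind in ("serum", "stool"):
            jitter = rng.integers(-1, 2, size=len(grid))
            days = np.clip(np.asarray(grid) + jitter, 0, config.followup_days)
            for j, day in enumerate(sorted(set(days.tolist()))):
                rows.append(
                    {
                        "sample_id": f"{pid}_{kind[:2].upper()}{j:02d}",
                        "patient_id": pid,
                        "day": int(day),
                        "type": kind,
                    }
                )
    samples = pd.DataFrame(rows)
    patients = pd.DataFrame(
        {"nf_day": nf_days, "bacteremia": bact}, index=pd.Index(patient_ids, name="patient_id")
    )
    return CohortSkeleton(patients=patients, samples=samples, config=config)


# ---------------------------------------------------------------------------
# serum metabolome
# ---------------------------------------------------------------------------

def _post_mask(skeleton: CohortSkeleton, serum: pd.DataFrame) -> np.ndarray:
    nf = serum["patient_id"].map(skeleton.patients["nf_day"])
    return (serum["day"].to_numpy() >= nf.to_numpy()) & ~nf.isna().to_numpy()


def apply_detection_floor(
    values: pd.DataFrame, quantile: float
) -> pd.DataFrame:
    """Censor each metabolite below its empirical ``quantile`` as missing."""
    if quantile <= 0:
        return values.copy()
    floors = values.quantile(quantile, axis=0)
    out = values.mask(values.lt(floors, axis=1))
    return out


def generate_metabolome(
    skeleton: CohortSkeleton,
    truth: MetabolomeTruth,
    seed: int,
    apply_floor: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the serum concentration matrix (samples x metabolites).

    Concentrations are log-normal; signature metabolites have their log-mean
    shifted by ``shift_log2fc * ln 2`` in post-NF samples.  With
    ``apply_floor`` the lowest ``detection_floor_quantile`` of each
    metabolite's values are censored to missing.  Returns the matrix and a
    per-metabolite pathway annotation.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    serum = skeleton.serum_samples
    n, m = len(serum), truth.n_metabolites
    log_vals = rng.normal(truth.base_log_mean, truth.base_log_sd, size=(n, m))
    post = _post_mask(skeleton, serum)
    if truth.signature_ids:
        ids = np.asarray(truth.signature_ids, dtype=int)
        log_vals[np.ix_(post, ids)] += truth.shift_log2fc * math.log(2)
    met_ids = [f"M{j:04d}" for j in range(m)]
    values = pd.DataFrame(np.exp(log_vals), index=serum["sample_id"].to_numpy(), columns=met_ids)
    values.index.name = "sample_id"
    pathways = pd.Series(
        rng.choice(_PATHWAYS, size=m), index=met_ids, name="pathway"
    )
    if apply_floor:
        values = apply_detection_floor(values, truth.detection_floor_quantile)
    return values, pathways


# ---------------------------------------------------------------------------
# stool microbiome + linked metabolite adjustments
# ---------------------------------------------------------------------------

def _genus_names(n: int) -> list[str]:
    return [f"g{j:02d}" for j in range(n)]


def sample_compositions(
    truth: MicrobiomeTruth, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample genus relative abundances from the log-normal model."""
    mu = truth.resolved_log_mean()
    log_ab = rng.normal(mu, truth.genus_log_sd, size=(n_samples, truth.n_genera))
    ab = np.exp(log_ab)
    return ab / ab.sum(axis=1, keepdims=True)


def counts_from_compositions(
    rel: np.ndarray,
    truth: MicrobiomeTruth,
    rng: np.random.Generator,
    sample_ids: list[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Multinomial ASV counts at a random depth per sample.

    Each genus is split across ``asv_per_genus`` ASVs with fixed Dirichlet
    weights (drawn once per cohort), so genus-level aggregation recovers the
    generating composition in expectation.
    """
    G, k = truth.n_genera, truth.asv_per_genus
    genus = _genus_names(G)
    split = rng.dirichlet(np.ones(k), size=G)  # G x k
    asv_ids = [f"ASV_{g}_{a}" for g in genus for a in range(k)]
    taxonomy = pd.Series(
        [g for g in genus for _ in range(k)], index=asv_ids, name="genus"
    )
    probs = (rel[:, :, None] * split[None, :, :]).reshape(len(rel), G * k)
    lo, hi = truth.depth_range
    depths = rng.integers(lo, hi + 1, size=len(rel))
    counts = np.vstack(
        [rng.multinomial(d, p / p.sum()) for d, p in zip(depths, probs)]
    )
    table = pd.DataFrame(counts, index=sample_ids, columns=asv_ids)
    table.index.name = "sample_id"
    return table, taxonomy


def generate_microbiome(
    skeleton: CohortSkeleton,
    m_truth: MicrobiomeTruth,
    metabolome: pd.DataFrame,
    seed: int,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Draw stool ASV counts and apply linked metabolite adjustments.

    For every metabolite column in the association matrix, each serum sample
    that pairs with a stool sample (nearest preceding within 3 days — the
    same convention the integration stage uses) has its log concentration
    augmented by ``z . b + noise`` where ``z`` is the stool sample's true
    log relative genus abundance vector.

    Returns (counts, taxonomy, adjusted metabolome).
    """
    from .integration import pair_samples  # shared pairing convention

    m_truth.validate()
    rng = np.random.default_rng(seed)
    stool = skeleton.stool_samples
    rel = sample_compositions(m_truth, len(stool), rng)
    counts, taxonomy = counts_from_compositions(
        rel, m_truth, rng, stool["sample_id"].tolist()
    )

    adjusted = metabolome.copy()
    if m_truth.association_matrix:
        pairs = pair_samples(skeleton.serum_samples, stool, max_lag_days=3)
        stool_pos = {sid: i for i, sid in enumerate(stool["sample_id"])}
        Z = np.log(rel)
        for _, pair in pairs.iterrows():
            z = Z[stool_pos[pair["stool_id"]]]
            for met_idx, b in m_truth.association_matrix.items():
                col = adjusted.columns[met_idx]
                delta = float(z @ b) + rng.normal(0.0, m_truth.noise_sd)
                cur = adjusted.at[pair["serum_id"], col]
                if pd.notna(cur):
                    adjusted.at[pair["serum_id"], col] = cur * math.exp(delta)
    return counts, taxonomy, adjusted


def generate_cohort(
    config: CohortConfig,
    met_truth: MetabolomeTruth | None = None,
    mic_truth: MicrobiomeTruth | None = None,
) -> SyntheticCohort:
    """End-to-end cohort generation.

    The detection floor is applied after the microbiome-linked adjustments
    so the censoring fraction refers to the final concentration values.
    Seeds for the three stages are spawned deterministically from
    ``config.seed``.
    """
    met_truth = met_truth or MetabolomeTruth()
    mic_truth = mic_truth or MicrobiomeTruth()
    ss = np.random.SeedSequence(config.seed)
    s_skel, s_met, s_mic = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    skeleton = generate_cohort_skeleton(
        dataclasses.replace(config, seed=s_skel)
    )
    values, pathways = generate_metabolome(skeleton, met_truth, s_met, apply_floor=False)
    counts, taxonomy, values = generate_microbiome(skeleton, mic_truth, values, s_mic)
    values = apply_detection_floor(values, met_truth.detection_floor_quantile)
    return SyntheticCohort(
        skeleton=skeleton,
        metabolome=values,
        pathways=pathways,
        counts=counts,
        taxonomy=taxonomy,
        metabolome_truth=met_truth,
        microbiome_truth=mic_truth,
    )


def simulate_log_contrast_dataset(
    n_samples: int,
    truth: MicrobiomeTruth,
    seed: int,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Cross-sectional benchmark for the association stage.

    Generates ``n_samples`` stool communities from the composition model and,
    for every metabolite column in the association matrix, a response
    ``y = z . b + N(0, noise_sd)`` from the TRUE log relative abundances.
    Returns (ASV counts, taxonomy, responses DataFrame keyed 'M<idx>').
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    ids = [f"S{i:04d}" for i in range(n_samples)]
    rel = sample_compositions(truth, n_samples, rng)
    counts, taxonomy = counts_from_compositions(rel, truth, rng, ids)
    Z = np.log(rel)
    ys = {}
    for met_idx, b in truth.association_matrix.items():
        ys[f"M{met_idx:04d}"] = Z @ np.asarray(b, float) + rng.normal(
            0.0, truth.noise_sd, size=n_samples
        )
    responses = pd.DataFrame(ys, index=pd.Index(ids, name="sample_id"))
    return counts, taxonomy, responses


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as plain TSV/YAML files (empty cell = missing)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metabolome": outdir / "metabolome.tsv",
        "counts": outdir / "counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "sample_metadata.tsv",
        "truth": outdir / "truth.yaml",
    }
    cohort.metabolome.to_csv(paths["metabolome"], sep="\t")
    cohort.counts.to_csv(paths["counts"], sep="\t")
    cohort.taxonomy.rename_axis("asv_id").to_csv(paths["taxonomy"], sep="\t")
    cohort.sample_metadata.to_csv(paths["metadata"], sep="\t", index=False)
    truth = {
        "metabolome": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cohort.metabolome_truth).items()
        },
        "microbiome": {
            "n_genera": cohort.microbiome_truth.n_genera,
            "asv_per_genus": cohort.microbiome_truth.asv_per_genus,
            "depth_range": list(cohort.microbiome_truth.depth_range),
            "genus_log_sd": cohort.microbiome_truth.genus_log_sd,
            "noise_sd": cohort.microbiome_truth.noise_sd,
            "association_matrix": {
                int(k): [float(x) for x in v]
                for k, v in cohort.microbiome_truth.association_matrix.items()
            },
        },
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cohort.skeleton.config).items()
        },
    }
    paths["truth"].write_text(yaml.safe_dump(truth, sort_keys=False))
    return paths
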
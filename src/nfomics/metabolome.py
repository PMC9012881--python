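"""Serum metabolome preprocessing and pre/post-fever group labeling.

Samples are labeled pre- or post-NF by comparing the collection day with the
patient's fever-onset day (a sample collected on the onset day counts as
post-NF; patients who never developed fever contribute pre-NF samples).
Metabolites detectable in less than half of the samples are dropped, and
remaining missing values are imputed with half the metabolite's minimum
observed value plus a small Gaussian jitter to avoid ties downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PRE, POST = "pre-NF", "post-NF"


def assign_nf_groups(samples: pd.DataFrame, nf_days: pd.Series) -> pd.Series:
    """Label each sample pre-NF or post-NF.

    ``samples`` needs columns sample_id, patient_id, day; ``nf_days`` maps
    patient_id to fever-onset day (NaN for never-febrile patients, whose
    samples are all pre-NF).  A sample collected on the onset day itself is
    post-NF.
    """
    nf = samples["patient_id"].map(nf_days)
    post = (samples["day"].to_numpy() >= nf.to_numpy()) & nf.notna().to_numpy()
    labels = pd.Series(
        np.where(post, POST, PRE),
        index=samples["sample_id"].to_numpy(),
        name="group",
    )
    labels.index.name = "sample_id"
    return labels


def filter_detectability(matrix: pd.DataFrame, min_fraction: float = 0.5) -> pd.DataFrame:
    """Drop metabolites detected in fewer than ``min_fraction`` of samples.

    Detection fraction exactly equal to the threshold is retained
    ("detectable in at least half").  Column order is preserved.
    """
    if matrix.empty:
        raise ValueError("empty metabolite matrix")
    frac = matrix.notna().mean(axis=0)
    keep = frac >= min_fraction
    if not keep.any():
        logger.warning("detectability filter removed every metabolite")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("detectability filter removed %d metabolites", dropped)
    return matrix.loc[:, keep]


def impute_half_min(
    matrix: pd.DataFrame, noise_sd_fraction: float = 0.01, seed: int = 0
) -> pd.DataFrame:
    """Half-minimum imputation with Gaussian jitter.

    Each missing cell becomes ``0.5 * min(observed)`` for that metabolite
    plus N(0, (noise_sd_fraction * 0.5 * min)^2), truncated at zero.
    Observed cells are untouched.  Deterministic for a fixed seed.
    """
    if matrix.isna().all(axis=0).any():
        bad = matrix.columns[matrix.isna().all(axis=0)].tolist()
        raise ValueError(
            f"metabolites with no observed values {bad[:5]}...: "
            "run filter_detectability first"
        )
    if not matrix.isna().any().any():
        return matrix.copy()
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    half_min = 0.5 * matrix.min(axis=0)
    for col in matrix.columns[matrix.isna().any(axis=0)]:
        miss = matrix[col].isna()
        base = half_min[col]
        fill = base + rng.normal(0.0, noise_sd_fraction * base, size=int(miss.sum()))
        out.loc[miss, col] = np.maximum(fill, 0.0)
    return out


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform of a complete, positive concentration matrix."""
    if (matrix <= 0).any().any():
        raise ValueError("log transform requires strictly positive values")
    return np.log(matrix)


def read_metabolite_tsv(path) -> pd.DataFrame:
    """Read the samples x metabolites TSV dialect (empty cell = missing)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metabolite_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")
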
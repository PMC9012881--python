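"""Stool count-table QC, depth normalization, and diversity.

Covers the 16S downstream steps this pipeline consumes: ASV/sample
filtering, genus aggregation, depth normalization by scaling with ranked
subsampling (SRS), inverse-Simpson alpha diversity with a rank-sum group
comparison, and CLR/Aitchison beta diversity.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


def filter_asvs_samples(
    table: pd.DataFrame,
    copies_per_ml: pd.Series | None = None,
    min_asv_prevalence: float = 0.10,
    min_reads: int = 5000,
    min_copies: int = 1000,
) -> pd.DataFrame:
    """Drop rare ASVs and low-yield samples.

    ASVs present (count > 0) in fewer than ``min_asv_prevalence`` of samples
    are removed; prevalence is computed on the table as given, before sample
    removal.  Samples with fewer than ``min_reads`` total reads, or fewer
    than ``min_copies`` 16S copies/mL when that measurement is supplied, are
    removed (exclusion is strict: a sample at exactly the threshold stays).
    """
    if table.empty:
        raise ValueError("empty count table")
    prevalence = (table > 0).mean(axis=0)
    keep_asv = prevalence >= min_asv_prevalence
    depth = table.sum(axis=1)
    keep_sample = depth >= min_reads
    if copies_per_ml is not None:
        copies = copies_per_ml.reindex(table.index)
        keep_sample &= copies >= min_copies
    elif min_copies > 0:
        logger.warning("16S copies/mL not supplied; copy-number filter skipped")
    out = table.loc[keep_sample, keep_asv]
    if out.shape[0] == 0:
        raise ValueError("sample filters removed every sample")
    logger.info(
        "filter: %d/%d ASVs, %d/%d samples retained",
        keep_asv.sum(), table.shape[1], keep_sample.sum(), table.shape[0],
    )
    return out


def aggregate_genera(table: pd.DataFrame, taxonomy: pd.Series) -> pd.DataFrame:
    """Sum ASV counts within genera; unassigned ASVs are dropped (logged)."""
    genus = taxonomy.reindex(table.columns)
    unassigned = genus.isna()
    if unassigned.any():
        logger.info("dropping %d ASVs without genus assignment", int(unassigned.sum()))
    kept = table.loc[:, ~unassigned.to_numpy()]
    return kept.T.groupby(genus.dropna()).sum().T


def srs_normalize(
    table: pd.DataFrame, target_depth: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Scaling with ranked subsampling to a common depth.

    Per sample, counts are scaled by ``target_depth / depth`` and split into
    integer and fractional parts; the residual counts needed to reach the
    target exactly are assigned one-by-one to taxa in order of descending
    fractional part, breaking ties by a seeded random order.  Every output
    row sums to ``target_depth`` exactly.  Default target is the minimum
    sample depth.
    """
    depths = table.sum(axis=1).to_numpy()
    if target_depth is None:
        target_depth = int(depths.min())
    if (depths < target_depth).any():
        raise ValueError("target_depth exceeds the depth of at least one sample")
    rng = np.random.default_rng(seed)
    X = table.to_numpy(dtype=float)
    out = np.zeros_like(X, dtype=np.int64)
    for i in range(X.shape[0]):
        scaled = X[i] * (target_depth / depths[i])
        ints = np.floor(scaled).astype(np.int64)
        frac = scaled - ints
        residual = int(target_depth - ints.sum())
        if residual > 0:
            # descending fractional part, ties broken by seeded random keys
            tiebreak = rng.random(len(frac))
            order = np.lexsort((tiebreak, -frac))
            ints[order[:residual]] += 1
        out[i] = ints
        assert ints.sum() == target_depth
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def inverse_simpson(table: pd.DataFrame) -> pd.Series:
    """Per-sample inverse Simpson index 1 / sum(p_i^2) on relative abundances."""
    p = table.div(table.sum(axis=1), axis=0)
    return (1.0 / (p**2).sum(axis=1)).rename("inverse_simpson")


def alpha_diversity_compare(
    table: pd.DataFrame, groups: pd.Series,
    pre_label: str = "pre-NF", post_label: str = "post-NF",
) -> tuple[pd.Series, float]:
    """Inverse Simpson per sample plus a two-sided Wilcoxon rank-sum p-value."""
    alpha = inverse_simpson(table)
    g = groups.reindex(table.index)
    a = alpha[(g == pre_label).to_numpy()]
    b = alpha[(g == post_label).to_numpy()]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one sample")
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return alpha, float(p)


def closed_proportions(table: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Zero-replaced proportions that are exactly scale invariant.

    The pseudocount is applied on the proportion scale, scaled so a sample at
    the reference depth (median observed depth) gets exactly ``pseudocount``
    added to each raw count.  Multiplying one sample's counts by any constant
    leaves its proportions unchanged.
    """
    X = table.to_numpy(dtype=float)
    depth = X.sum(axis=1)
    if (depth <= 0).any():
        raise ValueError("samples with zero depth cannot be closed")
    ref = float(np.median(depth))
    alpha = pseudocount / ref  # pseudo-proportion per taxon
    p = X / depth[:, None]
    p = (p + alpha) / (1.0 + alpha * X.shape[1])
    return pd.DataFrame(p, index=table.index, columns=table.columns)


def clr_transform(table: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio abundances (rows sum to zero)."""
    p = np.log(closed_proportions(table, pseudocount))
    return p.sub(p.mean(axis=1), axis=0)


def clr_aitchison(
    table: pd.DataFrame, pseudocount: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CLR matrix and the Aitchison distance (Euclidean on CLR rows)."""
    clr = clr_transform(table, pseudocount)
    D = squareform(pdist(clr.to_numpy(), metric="euclidean"))
    return clr, pd.DataFrame(D, index=table.index, columns=table.index)


# ---------------------------------------------------------------------------
# io
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x taxa count table from TSV, or BIOM when available."""
    path = Path(path)
    if path.suffix == ".biom":
        try:
            import biom
        except ImportError as exc:  # pragma: no cover
            raise ImportError("BIOM input requires the biom-format package") from exc
        t = biom.load_table(str(path))
        return pd.DataFrame(
            t.matrix_data.toarray().T.astype(np.int64),
            index=t.ids("sample"),
            columns=t.ids("observation"),
        )
    return pd.read_csv(path, sep="\t", index_col=0).astype(np.int64)


def read_taxonomy(path: str | Path) -> pd.Series:
    """Read an (asv_id, genus) TSV mapping."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["genus"].to_numpy(), index=df["asv_id"].to_numpy(), name="genus")
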
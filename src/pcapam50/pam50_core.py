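"""Upper-quartile normalization, ER-balanced median centering, and
nearest-centroid classification against the five intrinsic-subtype profiles.

Classification correlates each sample's panel profile with each centroid
(Spearman by default, Pearson by flag) and assigns the argmax subtype.
Centering subtracts, for each gene, the median computed over an ER-balanced
subset only, from every sample in the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import MIN_PANEL_GENES, SUBTYPE_ORDER, CentroidSet, ExpressionMatrix
from .ihc_subtyping import IHCSubtype

logger = logging.getLogger(__name__)

UNCLASSIFIABLE = "unclassifiable"

DEFAULT_UQ_TARGET = 1000.0


@dataclass
class SubtypeCall:
    sample_id: str
    label: str  # one of SUBTYPE_ORDER or "unclassifiable"
    correlations: dict[str, float]  # subtype -> correlation in [-1, 1]


@dataclass
class ERBalancedSubset:
    """Equal-sized ER-negative / ER-positive sample sets used for centering."""

    er_neg_sample_ids: list[str]
    er_pos_sample_ids: list[str]
    provenance: str  # primary / secondary / tertiary
    seed: int

    def __post_init__(self) -> None:
        if len(self.er_neg_sample_ids) != len(self.er_pos_sample_ids):
            raise ValueError(
                f"unbalanced subset: {len(self.er_neg_sample_ids)} ER- vs "
                f"{len(self.er_pos_sample_ids)} ER+"
            )
        if set(self.er_neg_sample_ids) & set(self.er_pos_sample_ids):
            raise ValueError("ER- and ER+ subset members overlap")

    @property
    def sample_ids(self) -> list[str]:
        return self.er_neg_sample_ids + self.er_pos_sample_ids


def upper_quartile_normalize(
    m: ExpressionMatrix, target_value: float = DEFAULT_UQ_TARGET
) -> ExpressionMatrix:
    """Scale each sample so the 75th percentile of its nonzero genes hits target.

    The percentile uses linear interpolation between order statistics. Missing
    values are excluded; an all-zero sample is an error.
    """
    if target_value <= 0:
        raise ValueError("target_value must be positive")
    df = m.data.copy()
    for sid in df.columns:
        col = df[sid].to_numpy(dtype=float)
        nonzero = col[(col > 0) & ~np.isnan(col)]
        if nonzero.size == 0:
            raise ValueError(f"sample {sid!r} has no nonzero expression")
        uq = float(np.percentile(nonzero, 75))
        df[sid] = col * (target_value / uq)
    return ExpressionMatrix(df)


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1); requires nonnegative input."""
    vals = m.data.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("log2 transform requires nonnegative values")
    return ExpressionMatrix(pd.DataFrame(np.log2(vals + 1.0), index=m.data.index, columns=m.data.columns))


def median_center(m: ExpressionMatrix, subset: ERBalancedSubset) -> ExpressionMatrix:
    """Subtract per-gene medians of the balanced subset from ALL samples."""
    missing = [s for s in subset.sample_ids if s not in m.data.columns]
    if missing:
        raise ValueError(f"subset samples absent from matrix: {missing[:5]}")
    medians = np.nanmedian(m.data[subset.sample_ids].to_numpy(dtype=float), axis=1)
    centered = m.data.to_numpy(dtype=float) - medians[:, None]
    return ExpressionMatrix(pd.DataFrame(centered, index=m.data.index, columns=m.data.columns))


def _corr_matrix(profiles: np.ndarray, centroids: np.ndarray, method: str) -> np.ndarray:
    """Column-profile x centroid correlation matrix.

    profiles: genes x n_samples, centroids: genes x 5. Spearman is Pearson on
    per-column average ranks. Columns with zero variance yield NaN.
    """
    if method == "spearman":
        profiles = np.apply_along_axis(rankdata, 0, profiles)
        centroids = np.apply_along_axis(rankdata, 0, centroids)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    p = profiles - profiles.mean(axis=0)
    c = centroids - centroids.mean(axis=0)
    p_norm = np.sqrt((p**2).sum(axis=0))
    c_norm = np.sqrt((c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (p.T @ c) / np.outer(p_norm, c_norm)
    corr[:, c_norm == 0] = np.nan
    corr[p_norm == 0, :] = np.nan
    return corr


def classify(
    m_centered: ExpressionMatrix,
    centroids: CentroidSet,
    method: str = "spearman",
    min_shared_genes: int = MIN_PANEL_GENES,
) -> list[SubtypeCall]:
    """Nearest-centroid calls: per sample, the subtype with maximal correlation.

    Ties are broken by the fixed priority order Basal, Her2, LumA, LumB,
    Normal (logged); a constant sample profile is unclassifiable. Missing
    values are excluded pairwise. min_shared_genes can be lowered for toy
    panels but defaults to the production threshold.
    """
    shared = [g for g in centroids.gene_ids if g in m_centered.data.index]
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} genes shared with centroids; >={min_shared_genes} required"
        )
    prof = m_centered.data.loc[shared].to_numpy(dtype=float)
    cent = centroids.profiles.loc[shared].to_numpy(dtype=float)
    sample_ids = m_centered.sample_ids

    calls: list[SubtypeCall] = []
    has_nan = np.isnan(prof).any(axis=0)
    clean = ~has_nan
    corr = np.full((len(sample_ids), len(SUBTYPE_ORDER)), np.nan)
    if clean.any():
        corr[clean] = _corr_matrix(prof[:, clean], cent, method)
    for j in np.nonzero(has_nan)[0]:
        mask = ~np.isnan(prof[:, j])
        if mask.sum() >= min_shared_genes:
            corr[j] = _corr_matrix(prof[mask, j][:, None], cent[mask], method)[0]

    for i, sid in enumerate(sample_ids):
        corrs = {s: float(corr[i, k]) for k, s in enumerate(SUBTYPE_ORDER)}
        if np.isnan(corr[i]).all():
            calls.append(SubtypeCall(sid, UNCLASSIFIABLE, corrs))
            continue
        best = np.nanmax(corr[i])
        winners = [s for k, s in enumerate(SUBTYPE_ORDER) if corr[i, k] == best]
        if len(winners) > 1:
            logger.warning(
                "sample %s: correlation tie among %s; keeping %s", sid, winners, winners[0]
            )
        calls.append(SubtypeCall(sid, winners[0], corrs))
    return calls


def build_primary_subset(
    ihc: Sequence[IHCSubtype], seed: int
) -> ERBalancedSubset:
    """IHC-based balanced subset: ER- = all TN and HER2+ cases, ER+ = an equal
    count drawn uniformly without replacement from LA, LB1, LB2."""
    er_neg = [s.sample_id for s in ihc if s.label in ("TN", "HER2+")]
    er_pos_pool = sorted(s.sample_id for s in ihc if s.label in ("LA", "LB1", "LB2"))
    if not er_neg:
        raise ValueError("no TN or HER2+ cases; cannot build ER-balanced subset")
    if len(er_pos_pool) < len(er_neg):
        raise ValueError(
            f"ER+ pool ({len(er_pos_pool)}) smaller than ER- pool ({len(er_neg)})"
        )
    rng = np.random.default_rng(seed)
    er_pos = list(rng.choice(er_pos_pool, size=len(er_neg), replace=False))
    return ERBalancedSubset(
        er_neg_sample_ids=list(er_neg),
        er_pos_sample_ids=[str(s) for s in er_pos],
        provenance="primary",
        seed=seed,
    )
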
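"""PCA over the gene panel and the PC1 misclassification-scan ER cutoff.

The first principal component of the panel matrix separates most ER-positive
from ER-negative cases. Its sign is fixed so that the IHC ER-positive class
mean lies at or below the ER-negative class mean, and a cutoff is chosen on
PC1 by minimizing the summed misclassification percentage

    Px = (Rx / R + Nx / N) * 100

where Rx counts ER-positive cases with PC1 >= x and Nx counts ER-negative
cases with PC1 < x.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

ER_POS = "pos"
ER_NEG = "neg"


@dataclass
class PCAResult:
    pc1_coords: dict[str, float]
    explained_variance_ratio_pc1: float
    orientation_flipped: bool


@dataclass
class PxScan:
    candidate_points: np.ndarray
    px_values: np.ndarray
    cutoff: float
    R: int
    N: int
    Rx_at_cutoff: int
    Nx_at_cutoff: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.candidate_points, "px": self.px_values})


def run_pca(m: ExpressionMatrix, ihc_er: Mapping[str, str]) -> PCAResult:
    """Sample-space PCA (genes as features, per-gene mean centering only).

    The reflection ambiguity of PC1 is resolved with the ER class means:
    after orientation the mean PC1 of ER-positive samples is <= that of
    ER-negative samples. Requires both ER classes to be represented.
    """
    if m.shape[1] < 3 or m.shape[0] < 2:
        raise ValueError("need at least 3 samples and 2 genes for PCA")
    labeled = {s: v for s, v in ihc_er.items() if v in (ER_POS, ER_NEG)}
    classes = set(labeled.values())
    if classes != {ER_POS, ER_NEG}:
        raise ValueError(f"both ER classes required for orientation, got {sorted(classes)}")

    x = m.values.T  # samples x genes
    if np.isnan(x).any():
        # pairwise-complete PCA is out of contract; impute per-gene mean
        col_mean = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x = x.copy()
        x[idx] = np.take(col_mean, idx[1])
    pca = PCA(n_components=1, svd_solver="full")
    pc1 = pca.fit_transform(x)[:, 0]
    evr = float(pca.explained_variance_ratio_[0])

    coords = dict(zip(m.sample_ids, pc1.astype(float)))
    pos_mean = np.mean([coords[s] for s, v in labeled.items() if v == ER_POS and s in coords])
    neg_mean = np.mean([coords[s] for s, v in labeled.items() if v == ER_NEG and s in coords])
    flipped = bool(pos_mean > neg_mean)
    if flipped:
        coords = {s: -c for s, c in coords.items()}
    return PCAResult(coords, evr, flipped)


def compute_px(
    x: float, pc1_coords: Mapping[str, float], ihc_er: Mapping[str, str]
) -> float:
    """Misclassification percentage at point x; boundary: ER+ counted at >= x,
    ER- counted strictly below x. Range [0, 200]."""
    pos = [pc1_coords[s] for s, v in ihc_er.items() if v == ER_POS and s in pc1_coords]
    neg = [pc1_coords[s] for s, v in ihc_er.items() if v == ER_NEG and s in pc1_coords]
    R, N = len(pos), len(neg)
    if R < 1 or N < 1:
        raise ValueError(f"need both ER classes (R={R}, N={N})")
    rx = sum(1 for c in pos if c >= x)
    nx = sum(1 for c in neg if c < x)
    return (rx / R + nx / N) * 100.0


def find_cutoff(
    pc1_coords: Mapping[str, float],
    ihc_er: Mapping[str, str],
    candidates: np.ndarray | None = None,
) -> PxScan:
    """Scan Px over candidate points and return the minimizing cutoff.

    Px is a step function changing only at observed coordinates, so the
    default candidate set — every observed PC1 value, the midpoint between
    each consecutive pair, and one sentinel beyond each extreme — attains the
    exact minimum that any finite grid can only approximate. Ties go to the
    smallest candidate.
    """
    labeled = {s: v for s, v in ihc_er.items() if v in (ER_POS, ER_NEG) and s in pc1_coords}
    pos = [pc1_coords[s] for s, v in labeled.items() if v == ER_POS]
    neg = [pc1_coords[s] for s, v in labeled.items() if v == ER_NEG]
    R, N = len(pos), len(neg)
    if R < 1 or N < 1:
        raise ValueError(f"need both ER classes (R={R}, N={N})")

    if candidates is None:
        observed = np.unique(np.asarray(pos + neg, dtype=float))
        mids = (observed[:-1] + observed[1:]) / 2.0
        candidates = np.concatenate(
            [[observed[0] - 1.0], observed, mids, [observed[-1] + 1.0]]
        )
        candidates = np.unique(candidates)
    else:
        candidates = np.unique(np.asarray(candidates, dtype=float))
    if candidates.size == 0:
        raise ValueError("empty candidate set")

    pos_a = np.asarray(pos)
    neg_a = np.asarray(neg)
    rx = (pos_a[None, :] >= candidates[:, None]).sum(axis=1)
    nx = (neg_a[None, :] < candidates[:, None]).sum(axis=1)
    px = (rx / R + nx / N) * 100.0
    best = int(np.argmin(px))  # argmin returns the first = smallest candidate
    return PxScan(
        candidate_points=candidates,
        px_values=px,
        cutoff=float(candidates[best]),
        R=R,
        N=N,
        Rx_at_cutoff=int(rx[best]),
        Nx_at_cutoff=int(nx[best]),
    )


def split_by_cutoff(
    pc1_coords: Mapping[str, float], cutoff: float
) -> tuple[set[str], set[str]]:
    """(left, right) partition of samples: right side is PC1 >= cutoff,
    matching the boundary inclusivity of the Rx count."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    left = {s for s, c in pc1_coords.items() if c < cutoff}
    right = {s for s, c in pc1_coords.items() if c >= cutoff}
    return left, right
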
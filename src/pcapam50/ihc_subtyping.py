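"""Clinical (IHC) subtype assignment and the MKI67 expression surrogate.

Marker conventions: ER/PR positive means nuclear staining strictly above 1%,
HER2 is negative for IHC 0/1+, positive for 3+, and arbitrated by FISH at 2+,
Ki67 is positive at >=15% staining. Cohorts without Ki67 IHC can separate LA
from LB1 with an MKI67 expression cutoff placed where the LA and LB1 density
curves of a harmonized reference cohort intersect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gaussian_kde

from .io_formats import ClinicalRecord, ExpressionMatrix

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
MISSING = "missing"
SURROGATE_POSITIVE = "surrogate_positive"
SURROGATE_NEGATIVE = "surrogate_negative"

IHC_LABELS = ("TN", "HER2+", "LA", "LB1", "LB2")
UNASSIGNABLE = "unassignable"

ER_PR_PCT_THRESHOLD = 1.0  # strictly greater-than
KI67_PCT_THRESHOLD = 15.0  # greater-or-equal


@dataclass
class MarkerStatuses:
    sample_id: str
    er: str
    pr: str
    her2: str
    ki67: str


@dataclass
class IHCSubtype:
    sample_id: str
    label: str  # one of IHC_LABELS or "unassignable"
    er_status: str
    pr_status: str
    her2_status: str
    ki67_status: str


@dataclass
class MKI67Cutoff:
    """An MKI67 expression threshold substituting for Ki67 IHC."""

    cutoff_value: float
    reference_cohort_id: str
    bandwidth: str | float
    search_interval: tuple[float, float]


def _hormone_status(value, threshold: float) -> str:
    if value is None:
        return MISSING
    if isinstance(value, str):
        return value if value in (POSITIVE, NEGATIVE) else MISSING
    return POSITIVE if float(value) > threshold else NEGATIVE


def call_marker_status(
    record: ClinicalRecord,
    er_pr_pct_threshold: float = ER_PR_PCT_THRESHOLD,
    ki67_pct_threshold: float = KI67_PCT_THRESHOLD,
) -> MarkerStatuses:
    """Resolve raw IHC fields into positive/negative/missing marker statuses."""
    er = _hormone_status(record.er_ihc, er_pr_pct_threshold)
    pr = _hormone_status(record.pr_ihc, er_pr_pct_threshold)

    if record.her2_ihc is None:
        her2 = MISSING
    elif record.her2_ihc in ("0", "1+"):
        her2 = NEGATIVE
    elif record.her2_ihc == "3+":
        her2 = POSITIVE
    elif record.her2_ihc == "2+":
        if record.her2_fish == "amplified":
            her2 = POSITIVE
        elif record.her2_fish == "not_amplified":
            her2 = NEGATIVE
        else:
            her2 = MISSING
    else:  # pragma: no cover - read_clinical validates the domain
        her2 = MISSING

    if record.ki67_pct is None:
        ki67 = MISSING
    else:
        ki67 = POSITIVE if float(record.ki67_pct) >= ki67_pct_threshold else NEGATIVE
    return MarkerStatuses(record.sample_id, er, pr, her2, ki67)


def call_ihc_subtype(statuses: MarkerStatuses) -> IHCSubtype:
    """Map marker statuses to TN / HER2+ / LA / LB1 / LB2.

    Any combination not covered by those definitions (for example ER-/PR+,
    or a missing marker needed to decide) is labeled unassignable.
    """
    er, pr, her2, ki67 = statuses.er, statuses.pr, statuses.her2, statuses.ki67
    ki67_pos = ki67 in (POSITIVE, SURROGATE_POSITIVE)
    ki67_neg = ki67 in (NEGATIVE, SURROGATE_NEGATIVE)

    label = UNASSIGNABLE
    if er == NEGATIVE and pr == NEGATIVE and her2 == NEGATIVE:
        label = "TN"
    elif er == NEGATIVE and pr == NEGATIVE and her2 == POSITIVE:
        label = "HER2+"
    elif er == POSITIVE and her2 == POSITIVE:
        label = "LB2"
    elif er == POSITIVE and her2 == NEGATIVE and ki67_neg:
        label = "LA"
    elif er == POSITIVE and her2 == NEGATIVE and ki67_pos:
        label = "LB1"
    return IHCSubtype(statuses.sample_id, label, er, pr, her2, ki67)


def assign_ihc_subtypes(
    records: Iterable[ClinicalRecord],
    er_pr_pct_threshold: float = ER_PR_PCT_THRESHOLD,
    ki67_pct_threshold: float = KI67_PCT_THRESHOLD,
) -> list[IHCSubtype]:
    return [
        call_ihc_subtype(
            call_marker_status(r, er_pr_pct_threshold, ki67_pct_threshold)
        )
        for r in records
    ]


# ---------------------------------------------------------------------------
# MKI67 surrogate
# ---------------------------------------------------------------------------

_MIN_GROUP = 10
_GRID_POINTS = 4001


def _kde(values: np.ndarray, bandwidth: str | float):
    bw = bandwidth if bandwidth != "silverman" else "silverman"
    return gaussian_kde(values, bw_method=bw)


def derive_mki67_cutoff(
    reference: ExpressionMatrix,
    reference_labels: Sequence,
    mki67_gene_id: str = "MKI67",
    bandwidth: str | float = "silverman",
    reference_cohort_id: str = "reference",
) -> MKI67Cutoff:
    """Place the LA/LB1 threshold where their MKI67 density curves intersect.

    The pooled LA+LB1 mixture curve crosses the LA curve and the LB1 curve at
    the same abscissa where the two group densities are equal (up to mixture
    weights), so the equality point between the two modes is used: it is the
    same target and better conditioned than intersecting against the mixture.
    """
    labels = {s.sample_id: s.label for s in reference_labels}
    if mki67_gene_id not in reference.data.index:
        raise ValueError(f"gene {mki67_gene_id!r} absent from reference matrix")
    row = reference.data.loc[mki67_gene_id]

    def group_values(name: str) -> np.ndarray:
        ids = [sid for sid, lab in labels.items() if lab == name and sid in row.index]
        vals = row[ids].to_numpy(dtype=float)
        return vals[~np.isnan(vals)]

    la = group_values("LA")
    lb1 = group_values("LB1")
    if len(la) < _MIN_GROUP or len(lb1) < _MIN_GROUP:
        raise ValueError(
            f"need >={_MIN_GROUP} LA and LB1 reference samples, got {len(la)} and {len(lb1)}"
        )

    kde_la = _kde(la, bandwidth)
    kde_lb1 = _kde(lb1, bandwidth)
    pooled_sd = float(np.concatenate([la, lb1]).std())
    lo = min(la.min(), lb1.min()) - 3 * max(la.std(), lb1.std())
    hi = max(la.max(), lb1.max()) + 3 * max(la.std(), lb1.std())
    grid = np.linspace(lo, hi, _GRID_POINTS)
    mode_la = grid[np.argmax(kde_la(grid))]
    mode_lb1 = grid[np.argmax(kde_lb1(grid))]
    if mode_la >= mode_lb1 or lb1.mean() - la.mean() < 0.2 * pooled_sd:
        raise ValueError(
            f"groups not ordered: LA mode {mode_la:.4g} / mean {la.mean():.4g} vs "
            f"LB1 mode {mode_lb1:.4g} / mean {lb1.mean():.4g}"
        )

    def diff(x: float) -> float:
        return float(kde_la(x)[0] - kde_lb1(x)[0])

    # first LA/LB1 density crossing at or beyond the LA mode; with broad
    # overlapping groups it may sit past the nominal LB1 mode
    inner = np.linspace(mode_la, hi, _GRID_POINTS)
    signs = np.sign(kde_la(inner) - kde_lb1(inner))
    crossings = np.nonzero(np.diff(signs) != 0)[0]
    if len(crossings) == 0:
        raise ValueError("no density crossing above the LA mode")
    i = crossings[0]
    cutoff = float(brentq(diff, inner[i], inner[i + 1]))
    return MKI67Cutoff(
        cutoff_value=cutoff,
        reference_cohort_id=reference_cohort_id,
        bandwidth=bandwidth,
        search_interval=(float(mode_la), float(hi)),
    )


def apply_mki67_surrogate(
    target: ExpressionMatrix,
    cutoff: MKI67Cutoff,
    er_pos_her2_neg_samples: Iterable[str],
    mki67_gene_id: str = "MKI67",
) -> dict[str, str]:
    """Ki67 surrogate statuses for ER+/HER2- samples; other samples untouched.

    The boundary is inclusive: MKI67 exactly at the cutoff is surrogate
    positive, mirroring the >=15% Ki67 IHC convention.
    """
    if mki67_gene_id not in target.data.index:
        raise ValueError(f"gene {mki67_gene_id!r} absent from target matrix")
    row = target.data.loc[mki67_gene_id]
    out: dict[str, str] = {}
    for sid in er_pos_her2_neg_samples:
        if sid not in row.index:
            raise ValueError(f"sample {sid!r} absent from target matrix")
        value = float(row[sid])
        if np.isnan(value):
            out[sid] = MISSING
        else:
            out[sid] = (
                SURROGATE_POSITIVE if value >= cutoff.cutoff_value else SURROGATE_NEGATIVE
            )
    return out
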
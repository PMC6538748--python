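"""Three-stage iterative subtyping pipeline and concordance summaries.

Stage 1 (conventional): center on the IHC-derived primary ER-balanced subset
and classify. Stage 2 (intermediate): find the PC1 cutoff minimizing ER
misclassification, build a secondary subset from samples whose PC1 side
agrees with IHC, re-center and re-classify. Stage 3 (refined): build a
tertiary subset from the intermediate Basal and LumA calls only — no IHC
information enters this stage — then produce the final calls.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    SUBTYPE_ORDER,
    CentroidSet,
    ClinicalRecord,
    ExpressionMatrix,
    calls_table,
    write_calls,
)
from .ihc_subtyping import (
    IHCSubtype,
    MKI67Cutoff,
    apply_mki67_surrogate,
    assign_ihc_subtypes,
    call_ihc_subtype,
    call_marker_status,
    derive_mki67_cutoff,
)
from .pam50_core import (
    ERBalancedSubset,
    SubtypeCall,
    build_primary_subset,
    classify,
    log2_transform,
    median_center,
    upper_quartile_normalize,
)
from .pca_er import ER_NEG, ER_POS, PCAResult, PxScan, find_cutoff, run_pca, split_by_cutoff

logger = logging.getLogger(__name__)

#: IHC class -> matching intrinsic class for consistency counting.
#: IHC LB1 and LB2 both match intrinsic LumB; intrinsic Normal never matches.
DEFAULT_MATCHING = {
    "TN": "Basal",
    "HER2+": "Her2",
    "LA": "LumA",
    "LB1": "LumB",
    "LB2": "LumB",
}

IHC_ROW_ORDER = ("TN", "HER2+", "LA", "LB1", "LB2")


class StageError(RuntimeError):
    """A pipeline stage failed; message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    seed: int = 0
    corr_method: str = "spearman"  # or "pearson"
    upper_quartile: bool = True
    uq_target: float = 1000.0
    log2: bool = True
    er_pr_pct_threshold: float = 1.0
    ki67_pct_threshold: float = 15.0
    mki67_gene_id: str = "MKI67"
    mki67_cutoff: float | None = None  # pre-derived surrogate threshold, if any
    kde_bandwidth: str | float = "silverman"

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "corr_method": self.corr_method,
            "upper_quartile": self.upper_quartile,
            "uq_target": self.uq_target,
            "log2": self.log2,
            "er_pr_pct_threshold": self.er_pr_pct_threshold,
            "ki67_pct_threshold": self.ki67_pct_threshold,
            "mki67_gene_id": self.mki67_gene_id,
            "mki67_cutoff": self.mki67_cutoff,
            "kde_bandwidth": self.kde_bandwidth,
        }


@dataclass
class ConcordanceTable:
    counts: pd.DataFrame  # rows = IHC classes, columns = intrinsic classes
    consistency_percent: float
    matching: dict[str, str]

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class SubtypeCallSet:
    sample_ids: list[str]
    ihc_labels: dict[str, str]
    conventional: dict[str, SubtypeCall]
    intermediate: dict[str, SubtypeCall]
    refined: dict[str, SubtypeCall]
    subsets: dict[str, ERBalancedSubset]
    pca: PCAResult | None
    px_scan: PxScan | None
    config: PipelineConfig
    seed: int
    mki67_cutoff: MKI67Cutoff | None = None
    concordance_conventional: ConcordanceTable | None = None
    concordance_refined: ConcordanceTable | None = None

    @property
    def pc1_coords(self) -> dict[str, float]:
        return self.pca.pc1_coords if self.pca is not None else {}


def stage_seed(pipeline_seed: int, stage: str) -> int:
    """Deterministic per-stage seed so stage reruns are reproducible."""
    digest = hashlib.sha256(f"{pipeline_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


def ihc_er_map(ihc: Sequence[IHCSubtype]) -> dict[str, str]:
    """IHC ER classes for the PC1 scan: LA/LB1/LB2 positive, TN/HER2+ negative."""
    out: dict[str, str] = {}
    for s in ihc:
        if s.label in ("LA", "LB1", "LB2"):
            out[s.sample_id] = ER_POS
        elif s.label in ("TN", "HER2+"):
            out[s.sample_id] = ER_NEG
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_conventional(
    m: ExpressionMatrix,
    ihc: Sequence[IHCSubtype],
    centroids: CentroidSet,
    seed: int,
    corr_method: str = "spearman",
) -> tuple[dict[str, SubtypeCall], ERBalancedSubset]:
    subset = build_primary_subset(ihc, seed)
    centered = median_center(m, subset)
    calls = classify(centered, centroids, corr_method)
    return {c.sample_id: c for c in calls}, subset


def _balanced_draw(
    er_neg_pool: Sequence[str],
    er_pos_pool: Sequence[str],
    provenance: str,
    seed: int,
) -> ERBalancedSubset:
    """Draw equal-sized halves; if the ER+ pool is the smaller one, cap the
    subset at the smaller pool size with a warning instead of failing."""
    if not er_neg_pool or not er_pos_pool:
        raise ValueError(
            f"{provenance} subset: empty pool (ER- {len(er_neg_pool)}, ER+ {len(er_pos_pool)})"
        )
    rng = np.random.default_rng(seed)
    size = min(len(er_neg_pool), len(er_pos_pool))
    if len(er_pos_pool) < len(er_neg_pool):
        logger.warning(
            "%s subset: ER+ pool (%d) smaller than ER- pool (%d); capping at %d",
            provenance,
            len(er_pos_pool),
            len(er_neg_pool),
            size,
        )
        er_neg = list(rng.choice(sorted(er_neg_pool), size=size, replace=False))
    else:
        er_neg = list(er_neg_pool)
    er_pos = list(rng.choice(sorted(er_pos_pool), size=size, replace=False))
    return ERBalancedSubset(
        er_neg_sample_ids=[str(s) for s in er_neg],
        er_pos_sample_ids=[str(s) for s in er_pos],
        provenance=provenance,
        seed=seed,
    )


def run_intermediate(
    m: ExpressionMatrix,
    ihc: Sequence[IHCSubtype],
    centroids: CentroidSet,
    pca_result: PCAResult,
    px_scan: PxScan,
    seed: int,
    corr_method: str = "spearman",
) -> tuple[dict[str, SubtypeCall], ERBalancedSubset]:
    """Secondary subset from PC1/IHC agreement: ER- = TN and HER2+ cases on the
    right of the cutoff, ER+ = an equal draw from luminal cases on the left."""
    left, right = split_by_cutoff(pca_result.pc1_coords, px_scan.cutoff)
    er_neg_pool = [s.sample_id for s in ihc if s.label in ("TN", "HER2+") and s.sample_id in right]
    er_pos_pool = [
        s.sample_id for s in ihc if s.label in ("LA", "LB1", "LB2") and s.sample_id in left
    ]
    subset = _balanced_draw(er_neg_pool, er_pos_pool, "secondary", seed)
    centered = median_center(m, subset)
    calls = classify(centered, centroids, corr_method)
    return {c.sample_id: c for c in calls}, subset


def run_refined(
    m: ExpressionMatrix,
    intermediate_calls: Mapping[str, SubtypeCall],
    centroids: CentroidSet,
    seed: int,
    corr_method: str = "spearman",
) -> tuple[dict[str, SubtypeCall], ERBalancedSubset]:
    """Tertiary subset from the intermediate calls only: ER- = all Basal calls,
    ER+ = an equal draw from LumA calls. IHC never enters this stage."""
    basal = [s for s, c in intermediate_calls.items() if c.label == "Basal"]
    luma = [s for s, c in intermediate_calls.items() if c.label == "LumA"]
    if not basal or not luma:
        raise ValueError(
            f"tertiary subset needs Basal and LumA intermediate calls "
            f"(got {len(basal)} Basal, {len(luma)} LumA)"
        )
    subset = _balanced_draw(basal, luma, "tertiary", seed)
    centered = median_center(m, subset)
    calls = classify(centered, centroids, corr_method)
    return {c.sample_id: c for c in calls}, subset


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _derive_ihc(
    m_norm: ExpressionMatrix,
    clinical: Sequence[ClinicalRecord],
    config: PipelineConfig,
) -> list[IHCSubtype]:
    """IHC labels, using the MKI67 surrogate for ER+/HER2- samples whose Ki67
    IHC is missing when a surrogate cutoff is configured."""
    statuses = [
        call_marker_status(r, config.er_pr_pct_threshold, config.ki67_pct_threshold)
        for r in clinical
    ]
    if config.mki67_cutoff is not None:
        needs = [
            s.sample_id
            for s in statuses
            if s.er == "positive"
            and s.her2 == "negative"
            and s.ki67 == "missing"
            and s.sample_id in m_norm.data.columns
        ]
        if needs:
            cutoff = MKI67Cutoff(
                cutoff_value=config.mki67_cutoff,
                reference_cohort_id="configured",
                bandwidth=config.kde_bandwidth,
                search_interval=(float("-inf"), float("inf")),
            )
            surrogate = apply_mki67_surrogate(m_norm, cutoff, needs, config.mki67_gene_id)
            for s in statuses:
                if s.sample_id in surrogate:
                    s.ki67 = surrogate[s.sample_id]
    return [call_ihc_subtype(s) for s in statuses]


def run_pipeline(
    m: ExpressionMatrix,
    clinical: Sequence[ClinicalRecord],
    centroids: CentroidSet,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> SubtypeCallSet:
    """Normalize, derive IHC subtypes, then run the three stages end to end."""
    config = config or PipelineConfig()
    try:
        m_norm = upper_quartile_normalize(m, config.uq_target) if config.upper_quartile else m
        if config.log2:
            m_norm = log2_transform(m_norm)
        panel = m_norm.subset_genes(centroids.gene_ids)
    except Exception as exc:
        raise StageError(f"normalization: {exc}") from exc

    try:
        known = set(m.sample_ids)
        ihc = [s for s in _derive_ihc(m_norm, clinical, config) if s.sample_id in known]
    except Exception as exc:
        raise StageError(f"ihc_subtyping: {exc}") from exc

    try:
        conventional, primary = run_conventional(
            panel, ihc, centroids, stage_seed(config.seed, "conventional"), config.corr_method
        )
    except Exception as exc:
        raise StageError(f"conventional: {exc}") from exc

    try:
        er_map = ihc_er_map(ihc)
        pca = run_pca(panel, er_map)
        scan = find_cutoff(pca.pc1_coords, er_map)
    except Exception as exc:
        raise StageError(f"pca_cutoff: {exc}") from exc

    try:
        intermediate, secondary = run_intermediate(
            panel, ihc, centroids, pca, scan,
            stage_seed(config.seed, "intermediate"), config.corr_method,
        )
    except Exception as exc:
        raise StageError(f"intermediate: {exc}") from exc

    try:
        refined, tertiary = run_refined(
            panel, intermediate, centroids,
            stage_seed(config.seed, "refined"), config.corr_method,
        )
    except Exception as exc:
        raise StageError(f"refined: {exc}") from exc

    ihc_labels = {s.sample_id: s.label for s in ihc}
    callset = SubtypeCallSet(
        sample_ids=list(m.sample_ids),
        ihc_labels=ihc_labels,
        conventional=conventional,
        intermediate=intermediate,
        refined=refined,
        subsets={"primary": primary, "secondary": secondary, "tertiary": tertiary},
        pca=pca,
        px_scan=scan,
        config=config,
        seed=config.seed,
    )
    assignable = {s: l for s, l in ihc_labels.items() if l in IHC_ROW_ORDER}
    if assignable:
        callset.concordance_conventional = concordance(
            assignable, {s: c.label for s, c in conventional.items()}
        )
        callset.concordance_refined = concordance(
            assignable, {s: c.label for s, c in refined.items()}
        )
    if out_dir is not None:
        write_outputs(callset, out_dir)
    return callset


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def concordance(
    ihc_labels: Mapping[str, str],
    intrinsic_labels: Mapping[str, str],
    matching: Mapping[str, str] | None = None,
) -> ConcordanceTable:
    """Cross-tabulate IHC vs intrinsic labels and compute the consistency
    percentage over the matched-pair map (TN-Basal, HER2+-Her2, LA-LumA,
    LB1/LB2-LumB; Normal calls never match)."""
    matching = dict(matching or DEFAULT_MATCHING)
    shared = [
        s
        for s in ihc_labels
        if s in intrinsic_labels
        and ihc_labels[s] in IHC_ROW_ORDER
        and intrinsic_labels[s] in SUBTYPE_ORDER
    ]
    if not shared:
        raise ValueError("no samples with both an IHC class and an intrinsic call")
    counts = pd.DataFrame(
        0, index=list(IHC_ROW_ORDER), columns=list(SUBTYPE_ORDER), dtype=int
    )
    for s in shared:
        counts.loc[ihc_labels[s], intrinsic_labels[s]] += 1
    matched = sum(int(counts.loc[r, matching[r]]) for r in IHC_ROW_ORDER if r in matching)
    consistency = 100.0 * matched / len(shared)
    return ConcordanceTable(counts=counts, consistency_percent=consistency, matching=matching)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_outputs(callset: SubtypeCallSet, out_dir: str | Path) -> None:
    """calls.tsv, subsets.tsv, px_scan.tsv, concordance tables, run_metadata.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_calls(callset, out / "calls.tsv")

    rows = []
    for name, subset in callset.subsets.items():
        for side, ids in (
            ("er_neg", subset.er_neg_sample_ids),
            ("er_pos", subset.er_pos_sample_ids),
        ):
            for sid in ids:
                rows.append({"subset": name, "er_side": side, "sample_id": sid})
    pd.DataFrame(rows, columns=["subset", "er_side", "sample_id"]).to_csv(
        out / "subsets.tsv", sep="\t", index=False
    )

    if callset.px_scan is not None:
        callset.px_scan.to_frame().to_csv(
            out / "px_scan.tsv", sep="\t", index=False, float_format="%.17g"
        )
    for name, table in (
        ("concordance_conventional.tsv", callset.concordance_conventional),
        ("concordance_refined.tsv", callset.concordance_refined),
    ):
        if table is not None:
            table.counts.to_csv(out / name, sep="\t", index_label="ihc_subtype")

    meta = {
        "package_version": __version__,
        "config": callset.config.to_dict(),
        "seed": callset.seed,
        "stage_seeds": {s: stage_seed(callset.seed, s) for s in ("conventional", "intermediate", "refined")},
        "pc1_cutoff": None if callset.px_scan is None else float(callset.px_scan.cutoff),
        "pc1_orientation_flipped": None if callset.pca is None else callset.pca.orientation_flipped,
        "explained_variance_ratio_pc1": (
            None if callset.pca is None else callset.pca.explained_variance_ratio_pc1
        ),
        "consistency_conventional_pct": (
            None
            if callset.concordance_conventional is None
            else callset.concordance_conventional.consistency_percent
        ),
        "consistency_refined_pct": (
            None
            if callset.concordance_refined is None
            else callset.concordance_refined.consistency_percent
        ),
    }
    with open(out / "run_metadata.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
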
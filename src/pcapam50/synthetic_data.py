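"""Ground-truth cohort simulator for exercising every pipeline stage offline.

Expression is generated on log2 scale as centroid profile + Gaussian noise and
exponentiated to a count-like nonnegative scale, so upper-quartile
normalization and the log2 flag are exercised. Clinical IHC fields are filled
consistently with the generating subtype; the IHC hormone-receptor status is
flipped with a tunable discordance probability, and the MKI67 gene is elevated
in LumB-truth samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import SUBTYPE_ORDER, CentroidSet, ClinicalRecord, ExpressionMatrix
from .pcapam50_driver import PipelineConfig, run_pipeline

logger = logging.getLogger(__name__)

DEFAULT_PROPORTIONS = {
    "Basal": 0.17,
    "Her2": 0.08,
    "LumA": 0.40,
    "LumB": 0.25,
    "Normal": 0.10,
}

#: log2-scale offset lifting profiles onto a positive count-like range
LOG_BASELINE = 6.0
#: baseline log2 MKI67 level before the LumB shift
MKI67_BASELINE = 2.0
#: fraction of LumB-truth samples flagged HER2+ on IHC (the LB2 class)
LB2_FRACTION = 0.3

#: centroid geometry: LumA-LumB correlation, Normal's luminal-mean loading,
#: Normal's private-noise amplitude
_AB_CORR = 0.95
_NORMAL_LUMINAL = 0.30
_NORMAL_NOISE = 0.15

#: MKI67 coupling to a sample's proliferation score (its noise projection on
#: the LumB-minus-LumA axis), as a multiple of mki67_shift
_MKI67_PROLIF_COUPLING = 1.0

#: a LumA draw whose displacement along the LumA->LumB axis exceeds this
#: (absolute log2 units) is relabeled LumB: high-proliferation luminal tumors
#: are luminal B by definition, even when their profile leans LumA. The
#: threshold is absolute, so relabeling vanishes in the noiseless limit.
_LUMB_RELABEL_OFFSET = 0.38


@dataclass
class SimConfig:
    n_samples: int = 300
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    noise_sd: float = 0.3
    er_discordance_rate: float = 0.1
    mki67_shift: float = 1.5
    ki67_ihc_available: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype proportions sum to {total}, expected 1")
        if set(self.subtype_proportions) != set(SUBTYPE_ORDER):
            raise ValueError(f"proportions must cover exactly {SUBTYPE_ORDER}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.er_discordance_rate <= 0.5:
            raise ValueError("er_discordance_rate must be in [0, 0.5]")


@dataclass
class SimCohort:
    expression: ExpressionMatrix  # centroid genes + MKI67
    clinical: list[ClinicalRecord]
    truth: pd.DataFrame  # sample_id, subtype, er_expression, ihc_er_flipped

    @property
    def truth_subtype(self) -> dict[str, str]:
        return dict(zip(self.truth["sample_id"], self.truth["subtype"]))


def make_centroids(n_genes: int = 50, separation: float = 1.0, seed: int = 0) -> CentroidSet:
    """Five synthetic centroid profiles with the panel's broad correlation
    structure: LumA and LumB strongly correlated, Basal (and to a lesser
    degree Her2) anti-correlated with the luminals, Normal a damped luminal
    mean. separation scales all profiles; 0 collapses them to one point."""
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    rng = np.random.default_rng(seed)
    # orthonormal direction basis (scaled to per-gene unit variance) so the
    # centroid correlation structure is exact for every seed
    basis, _ = np.linalg.qr(rng.normal(size=(n_genes, 5)))
    u, v, h, b, w = (basis[:, k] * np.sqrt(n_genes) for k in range(5))

    luma = u
    lumb = _AB_CORR * u + np.sqrt(1 - _AB_CORR**2) * v
    basal = -0.70 * u + np.sqrt(1 - 0.70**2) * b
    her2 = -0.50 * u + np.sqrt(1 - 0.50**2) * h
    # Normal-like sits between the weakly expressed state and the luminal
    # mean, so over-centered luminal samples drift toward it
    normal = _NORMAL_LUMINAL * (luma + lumb) / 2.0 + _NORMAL_NOISE * w

    profiles = pd.DataFrame(
        separation
        * np.column_stack([basal, her2, luma, lumb, normal]),
        index=[f"G{i:04d}" for i in range(1, n_genes + 1)],
        columns=list(SUBTYPE_ORDER),
    )
    return CentroidSet(profiles)


def _er_truth(subtype: str, rng: np.random.Generator) -> bool:
    if subtype in ("LumA", "LumB"):
        return True
    if subtype in ("Basal", "Her2"):
        return False
    return bool(rng.random() < 0.5)  # Normal-like: coin flip for bookkeeping


def simulate_cohort(centroids: CentroidSet, cfg: SimConfig) -> SimCohort:
    """Draw a cohort with known truth; deterministic for a fixed SimConfig."""
    rng = np.random.default_rng(cfg.seed)
    names = list(SUBTYPE_ORDER)
    probs = np.array([cfg.subtype_proportions[s] for s in names])
    subtypes = rng.choice(names, size=cfg.n_samples, p=probs)
    sample_ids = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]

    genes = centroids.gene_ids
    prof = centroids.profiles
    log_expr = np.empty((len(genes) + 1, cfg.n_samples))
    mki67_row = len(genes)

    # proliferation axis: unit vector from the LumA toward the LumB centroid
    ab_axis = prof["LumB"].to_numpy() - prof["LumA"].to_numpy()
    ab_norm = float(np.linalg.norm(ab_axis))
    ab_axis = ab_axis / ab_norm if ab_norm > 0 else np.zeros_like(ab_axis)

    records: list[ClinicalRecord] = []
    truth_rows = []
    for j, (sid, sub) in enumerate(zip(sample_ids, subtypes)):
        noise = rng.normal(0.0, cfg.noise_sd, len(genes))
        # expression is anchored on the drawn profile; the truth label (and
        # all clinical fields) follow the proliferation relabel below
        log_expr[:mki67_row, j] = prof[sub].to_numpy() + LOG_BASELINE + noise
        prolif_offset = float(noise @ ab_axis)
        if sub == "LumA" and prolif_offset > _LUMB_RELABEL_OFFSET:
            sub = "LumB"
        # MKI67 rises with the LumB shift and with the sample's own
        # proliferation score, so boundary cases leaning LumB carry more MKI67
        prolif_z = prolif_offset / cfg.noise_sd
        mki67 = MKI67_BASELINE + LOG_BASELINE + rng.normal(0.0, cfg.noise_sd)
        mki67 += cfg.mki67_shift * _MKI67_PROLIF_COUPLING * prolif_z
        if sub == "LumB":
            mki67 += cfg.mki67_shift
        log_expr[mki67_row, j] = mki67

        er_true = _er_truth(sub, rng)
        flipped = bool(rng.random() < cfg.er_discordance_rate)
        er_ihc = er_true ^ flipped

        # HER2 IHC: Her2-truth samples positive; a fixed fraction of LumB-truth
        # samples positive (the LB2 clinical class); all others negative.
        if sub == "Her2":
            her2 = "3+"
        elif sub == "LumB" and rng.random() < LB2_FRACTION:
            her2 = "3+"
        else:
            her2 = "0"

        # Ki67 staining: high for LumB/Basal/Her2 truth, low for LumA/Normal.
        ki67 = 30.0 + rng.normal(0, 3) if sub in ("LumB", "Basal", "Her2") else 5.0 + rng.normal(0, 2)
        ki67 = float(np.clip(ki67, 0.0, 100.0))

        records.append(
            ClinicalRecord(
                sample_id=sid,
                er_ihc="positive" if er_ihc else "negative",
                pr_ihc="positive" if er_ihc else "negative",
                her2_ihc=her2,
                her2_fish=None,
                ki67_pct=ki67 if cfg.ki67_ihc_available else None,
            )
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "subtype": sub,
                "er_expression": "positive" if er_true else "negative",
                "ihc_er_flipped": flipped,
            }
        )

    counts = np.exp2(log_expr)
    data = pd.DataFrame(counts, index=genes + ["MKI67"], columns=sample_ids)
    return SimCohort(
        expression=ExpressionMatrix(data),
        clinical=records,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# discordance experiment
# ---------------------------------------------------------------------------


def truth_consistency(calls: Mapping[str, str], truth_subtype: Mapping[str, str]) -> float:
    """Percent of non-Normal-truth samples whose call equals the generating
    subtype."""
    scored = [s for s, t in truth_subtype.items() if t != "Normal" and s in calls]
    if not scored:
        raise ValueError("no non-Normal samples to score")
    hits = sum(1 for s in scored if calls[s] == truth_subtype[s])
    return 100.0 * hits / len(scored)


def discordance_experiment(
    cfg: SimConfig | None = None,
    n_replicates: int = 50,
    centroid_genes: int = 50,
    centroid_separation: float = 1.0,
    centroid_seed: int = 0,
) -> pd.DataFrame:
    """Repeatedly simulate + run the pipeline; per replicate record the
    conventional-vs-truth and refined-vs-truth consistency, the number of
    conventional-LumA -> refined-LumB switches, and mean log2 MKI67 of
    switched vs stable-LumA samples.

    The centroid panel is a fixture held fixed across replicates (like a
    published centroid table); only the cohorts vary with the seed.
    """
    if n_replicates < 10:
        raise ValueError("need at least 10 replicates")
    cfg = cfg or SimConfig()
    centroids = make_centroids(centroid_genes, centroid_separation, seed=centroid_seed)

    rows = []
    for rep in range(n_replicates):
        rep_cfg = replace(cfg, seed=cfg.seed + 1000 * (rep + 1))
        cohort = simulate_cohort(centroids, rep_cfg)
        callset = run_pipeline(
            cohort.expression,
            cohort.clinical,
            centroids,
            PipelineConfig(seed=rep_cfg.seed),
        )
        truth = cohort.truth_subtype
        conv = {s: c.label for s, c in callset.conventional.items()}
        refi = {s: c.label for s, c in callset.refined.items()}

        mki67 = np.log2(cohort.expression.data.loc["MKI67"] + 1.0)
        switched = [s for s in conv if conv[s] == "LumA" and refi.get(s) == "LumB"]
        stable_la = [s for s in conv if conv[s] == "LumA" and refi.get(s) == "LumA"]
        rows.append(
            {
                "replicate": rep,
                "seed": rep_cfg.seed,
                "conventional_consistency": truth_consistency(conv, truth),
                "refined_consistency": truth_consistency(refi, truth),
                "n_luma_to_lumb": len(switched),
                "mean_mki67_switched": float(mki67[switched].mean()) if switched else np.nan,
                "mean_mki67_stable_luma": float(mki67[stable_la].mean()) if stable_la else np.nan,
            }
        )
    return pd.DataFrame(rows)


def experiment_summary(table: pd.DataFrame) -> dict[str, float]:
    delta = table["refined_consistency"] - table["conventional_consistency"]
    with_switch = table.dropna(subset=["mean_mki67_switched", "mean_mki67_stable_luma"])
    elevated = (
        (with_switch["mean_mki67_switched"] > with_switch["mean_mki67_stable_luma"]).sum()
    )
    return {
        "median_conventional_consistency": float(table["conventional_consistency"].median()),
        "median_refined_consistency": float(table["refined_consistency"].median()),
        "median_delta": float(delta.median()),
        "median_n_switched": float(table["n_luma_to_lumb"].median()),
        "frac_reps_mki67_elevated": float(elevated / len(table)),
    }


def write_cohort(cohort: SimCohort, centroids: CentroidSet, out_dir: str | Path) -> None:
    from .io_formats import write_centroids, write_clinical, write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, out / "expression.tsv")
    write_clinical(cohort.clinical, out / "clinical.tsv")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    write_centroids(centroids, out / "centroids.tsv")
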
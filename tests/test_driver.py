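import filecmp

import numpy as np
import pandas as pd
import pytest

from pcapam50.ihc_subtyping import IHCSubtype
from pcapam50.pam50_core import log2_transform, upper_quartile_normalize
from pcapam50.pca_er import find_cutoff, run_pca
from pcapam50.pcapam50_driver import (
    PipelineConfig,
    StageError,
    concordance,
    ihc_er_map,
    run_conventional,
    run_intermediate,
    run_pipeline,
    run_refined,
    stage_seed,
)
from pcapam50.synthetic_data import SimConfig, simulate_cohort, truth_consistency


def panel_of(cohort, centroids):
    m = log2_transform(upper_quartile_normalize(cohort.expression))
    return m.subset_genes(centroids.gene_ids)


def ihc_from_truth(cohort):
    """IHC labels straight from the simulator's clinical records."""
    from pcapam50.ihc_subtyping import assign_ihc_subtypes

    return assign_ihc_subtypes(cohort.clinical)


class TestConventional:
    def test_concordant_cohort_recovers_truth(self, concordant_cohort, centroids):
        panel = panel_of(concordant_cohort, centroids)
        calls, subset = run_conventional(
            panel, ihc_from_truth(concordant_cohort), centroids, seed=0
        )
        labels = {s: c.label for s, c in calls.items()}
        assert truth_consistency(labels, concordant_cohort.truth_subtype) >= 95.0

    def test_determinism(self, cohort, centroids):
        panel = panel_of(cohort, centroids)
        ihc = ihc_from_truth(cohort)
        calls_a, _ = run_conventional(panel, ihc, centroids, seed=3)
        calls_b, _ = run_conventional(panel, ihc, centroids, seed=3)
        assert {s: c.label for s, c in calls_a.items()} == {
            s: c.label for s, c in calls_b.items()
        }

    def test_no_er_negative_cases_errors(self, cohort, centroids):
        panel = panel_of(cohort, centroids)
        ihc = [
            IHCSubtype(s, "LA", "positive", "positive", "negative", "negative")
            for s in panel.sample_ids
        ]
        with pytest.raises(ValueError):
            run_conventional(panel, ihc, centroids, seed=0)


class TestIntermediate:
    def scan_inputs(self, cohort, centroids):
        panel = panel_of(cohort, centroids)
        ihc = ihc_from_truth(cohort)
        er = ihc_er_map(ihc)
        pca = run_pca(panel, er)
        scan = find_cutoff(pca.pc1_coords, er)
        return panel, ihc, pca, scan

    def test_er_neg_pool_restricted_to_right_side(self, cohort, centroids):
        panel, ihc, pca, scan = self.scan_inputs(cohort, centroids)
        _, subset = run_intermediate(panel, ihc, centroids, pca, scan, seed=0)
        for sid in subset.er_neg_sample_ids:
            assert pca.pc1_coords[sid] >= scan.cutoff
        for sid in subset.er_pos_sample_ids:
            assert pca.pc1_coords[sid] < scan.cutoff

    def test_tn_left_of_cutoff_excluded(self, cohort, centroids):
        panel, ihc, pca, scan = self.scan_inputs(cohort, centroids)
        # move one TN sample far left of the cutoff
        tn = next(s.sample_id for s in ihc if s.label == "TN")
        pca.pc1_coords[tn] = scan.cutoff - 100.0
        _, subset = run_intermediate(panel, ihc, centroids, pca, scan, seed=0)
        assert tn not in subset.er_neg_sample_ids

    def test_small_er_pos_pool_caps_with_warning(self, cohort, centroids, caplog):
        panel, ihc, pca, scan = self.scan_inputs(cohort, centroids)
        luminal = [s for s in ihc if s.label in ("LA", "LB1", "LB2")]
        keep = {s.sample_id for s in luminal[:5]}
        trimmed = [
            s
            for s in ihc
            if s.label in ("TN", "HER2+") or s.sample_id in keep
        ]
        with caplog.at_level("WARNING"):
            _, subset = run_intermediate(panel, trimmed, centroids, pca, scan, seed=0)
        assert len(subset.er_neg_sample_ids) == len(subset.er_pos_sample_ids) <= 5
        assert any("capping" in r.message for r in caplog.records)

    def test_empty_pool_errors(self, cohort, centroids):
        panel, ihc, pca, scan = self.scan_inputs(cohort, centroids)
        no_luminal = [s for s in ihc if s.label in ("TN", "HER2+")]
        with pytest.raises(ValueError, match="pool"):
            run_intermediate(panel, no_luminal, centroids, pca, scan, seed=0)


class TestRefined:
    def test_tertiary_balance(self, pipeline_result):
        tert = pipeline_result.subsets["tertiary"]
        n = len(tert.er_neg_sample_ids)
        assert n == len(tert.er_pos_sample_ids) > 0
        inter = pipeline_result.intermediate
        assert all(inter[s].label == "Basal" for s in tert.er_neg_sample_ids)
        assert all(inter[s].label == "LumA" for s in tert.er_pos_sample_ids)

    def test_refined_ignores_ihc(self, cohort, centroids, pipeline_result):
        # permuting IHC labels after the intermediate stage leaves refined
        # calls unchanged: run_refined consumes intermediate calls only
        panel = panel_of(cohort, centroids)
        seed = stage_seed(pipeline_result.seed, "refined")
        again, _ = run_refined(panel, pipeline_result.intermediate, centroids, seed)
        assert {s: c.label for s, c in again.items()} == {
            s: c.label for s, c in pipeline_result.refined.items()
        }

    def test_no_basal_errors(self, cohort, centroids, pipeline_result):
        panel = panel_of(cohort, centroids)
        no_basal = {
            s: c for s, c in pipeline_result.intermediate.items() if c.label != "Basal"
        }
        with pytest.raises(ValueError, match="Basal"):
            run_refined(panel, no_basal, centroids, seed=0)

    def test_refined_close_to_conventional_on_concordant_cohort(
        self, concordant_cohort, centroids
    ):
        cs = run_pipeline(
            concordant_cohort.expression,
            concordant_cohort.clinical,
            centroids,
            PipelineConfig(seed=11),
        )
        conv = {s: c.label for s, c in cs.conventional.items()}
        refi = {s: c.label for s, c in cs.refined.items()}
        agree = np.mean([conv[s] == refi[s] for s in conv])
        # pinned from a seeded run (94.7%): the generator keeps a switchable
        # proliferation tail, so the two stages disagree on a few percent
        # even without any IHC discordance
        assert agree >= 0.93


class TestPipeline:
    def test_smoke_on_60_sample_fixture(self, small_cohort, centroids):
        cs = run_pipeline(
            small_cohort.expression, small_cohort.clinical, centroids, PipelineConfig(seed=5)
        )
        for stage in ("conventional", "intermediate", "refined"):
            calls = getattr(cs, stage)
            assert set(calls) == set(small_cohort.expression.sample_ids)
        assert cs.px_scan is not None
        assert cs.concordance_conventional is not None

    def test_byte_identical_outputs_same_seed(self, small_cohort, centroids, tmp_path):
        for d in ("a", "b"):
            run_pipeline(
                small_cohort.expression,
                small_cohort.clinical,
                centroids,
                PipelineConfig(seed=9),
                out_dir=tmp_path / d,
            )
        for name in ("calls.tsv", "subsets.tsv", "px_scan.tsv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_stage_tagged_error(self, small_cohort, centroids):
        # all-ER+ clinical table: the conventional stage must fail, tagged
        from pcapam50.io_formats import ClinicalRecord

        clin = [
            ClinicalRecord(r.sample_id, "positive", "positive", "0", None, 5.0)
            for r in small_cohort.clinical
        ]
        with pytest.raises(StageError, match="conventional"):
            run_pipeline(small_cohort.expression, clin, centroids, PipelineConfig(seed=1))

    def test_stage_seeds_differ(self):
        seeds = {stage_seed(0, s) for s in ("conventional", "intermediate", "refined")}
        assert len(seeds) == 3

    def test_mki67_surrogate_path(self, centroids):
        # Ki67 withheld; a cutoff derived from a Ki67-bearing reference cohort
        # (processed on the same scale) must reconstruct the LA/LB1 split
        from pcapam50.ihc_subtyping import assign_ihc_subtypes, derive_mki67_cutoff

        reference = simulate_cohort(centroids, SimConfig(seed=21))
        ref_norm = log2_transform(upper_quartile_normalize(reference.expression))
        cut = derive_mki67_cutoff(
            ref_norm, assign_ihc_subtypes(reference.clinical), reference_cohort_id="sim-ref"
        )

        cohort = simulate_cohort(centroids, SimConfig(seed=3, ki67_ihc_available=False))
        cfg = PipelineConfig(seed=3, mki67_cutoff=cut.cutoff_value)
        cs = run_pipeline(cohort.expression, cohort.clinical, centroids, cfg)
        labels = set(cs.ihc_labels.values())
        assert "LA" in labels and "LB1" in labels

    def test_without_surrogate_no_la_lb1(self, centroids):
        from pcapam50.ihc_subtyping import assign_ihc_subtypes

        cohort = simulate_cohort(centroids, SimConfig(seed=3, ki67_ihc_available=False))
        labels = {s.label for s in assign_ihc_subtypes(cohort.clinical)}
        assert "LA" not in labels and "LB1" not in labels
        assert "unassignable" in labels  # ER+/HER2- without Ki67 stays open


class TestConcordance:
    def test_identity_matching_full_consistency(self):
        ihc = {"a": "TN", "b": "HER2+", "c": "LA", "d": "LB1"}
        intrinsic = {"a": "Basal", "b": "Her2", "c": "LumA", "d": "LumB"}
        table = concordance(ihc, intrinsic)
        assert table.consistency_percent == 100.0
        assert table.total == 4

    def test_printed_toy_75_percent(self):
        # TN->Basal (match), HER2+->Her2 (match), LA->LumB (mismatch),
        # LB1->LumB (match) -> 3/4
        ihc = {"a": "TN", "b": "HER2+", "c": "LA", "d": "LB1"}
        intrinsic = {"a": "Basal", "b": "Her2", "c": "LumB", "d": "LumB"}
        assert concordance(ihc, intrinsic).consistency_percent == 75.0

    def test_lb2_matches_lumb(self):
        assert concordance({"a": "LB2"}, {"a": "LumB"}).consistency_percent == 100.0

    def test_normal_never_matches(self):
        assert concordance({"a": "LA"}, {"a": "Normal"}).consistency_percent == 0.0

    def test_counts_sum_to_colabeled(self, pipeline_result):
        table = pipeline_result.concordance_refined
        n_colabeled = sum(
            1 for s, l in pipeline_result.ihc_labels.items() if l != "unassignable"
        )
        assert table.total == n_colabeled

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError):
            concordance({"a": "TN"}, {"b": "Basal"})


class TestOutputs:
    def test_run_metadata_written(self, small_cohort, centroids, tmp_path):
        import yaml

        run_pipeline(
            small_cohort.expression,
            small_cohort.clinical,
            centroids,
            PipelineConfig(seed=2),
            out_dir=tmp_path,
        )
        meta = yaml.safe_load((tmp_path / "run_metadata.yaml").read_text())
        assert meta["seed"] == 2
        assert "pc1_cutoff" in meta
        assert (tmp_path / "concordance_refined.tsv").exists()
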
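# pcapam50

Iterative PAM50 breast-tumor intrinsic subtyping that replaces the IHC-based
ER-balanced gene-centering subset with a gene-expression-derived one.

Nearest-centroid PAM50 calls are sensitive to how the expression matrix is
gene-centered, and the conventional practice centers on a subset balanced by
IHC ER status — a protein-level measurement that does not always agree with
expression-level ER status. This package runs the classification three times:

1. **conventional** — center on the primary, IHC-derived ER-balanced subset
   (ER− = all TN and HER2+ cases; ER+ = an equal random draw from the
   luminal IHC classes) and classify;
2. **intermediate** — place a cutoff on PC1 of the PAM50 panel by minimizing
   the misclassification statistic `Px = (Rx/R + Nx/N) × 100` over candidate
   points, build a secondary subset from samples whose PC1 side agrees with
   their IHC ER status, re-center, re-classify;
3. **refined** — build a tertiary subset purely from the intermediate calls
   (ER− = Basal calls, ER+ = an equal draw from LumA calls; no IHC enters
   this stage), center, and produce the final calls.

Also included: IHC subtype rules (TN / HER2+ / LA / LB1 / LB2 from ER, PR,
HER2 ± FISH, Ki67), an MKI67 expression surrogate for cohorts without Ki67
IHC (threshold at the LA/LB1 kernel-density crossing of a harmonized
reference cohort), upper-quartile normalization, concordance tables, and a
fully seeded synthetic-cohort generator so every stage is testable offline.

## CLI

Simulate a cohort, then subtype it:

```sh
pcapam50 simulate --out sim/ --seed 5
pcapam50 run --expr sim/expression.tsv --clinical sim/clinical.tsv \
             --centroids sim/centroids.tsv --out results/ --seed 5
```

`run` options: `--corr spearman|pearson` (default spearman), `--log2/--no-log2`
and `--uq/--no-uq` preprocessing toggles, `--mki67-cutoff FLOAT` to enable the
Ki67 surrogate, `--config YAML` for any other pipeline key. Exit codes:
0 success, 2 validation error, 3 stage failure.

Outputs in the `--out` directory:

| file | contents |
|---|---|
| `calls.tsv` | per sample: `sample_id`, `ihc_subtype`, `conventional_label`, `intermediate_label`, `refined_label`, five per-centroid correlations per stage (`<stage>_r_<subtype>`), `pc1` |
| `subsets.tsv` | membership of the primary/secondary/tertiary ER-balanced subsets |
| `px_scan.tsv` | the scanned (x, Px) curve on PC1 |
| `concordance_conventional.tsv`, `concordance_refined.tsv` | IHC × intrinsic contingency tables |
| `run_metadata.yaml` | config, seeds, PC1 cutoff, consistency percentages |

Expression input is a TSV/CSV of nonnegative values, genes in rows by default
(`orientation` flag in the API), restricted or restrictable to the centroid
panel; the centroid table is gene column + five subtype columns (aliases
LA/LumA, LB/LumB, HER2-enriched/Her2 accepted). Sample order is never
reordered by any reader.

## Python API

```python
from pcapam50 import (
    read_expression, read_clinical, read_centroids,
    PipelineConfig, run_pipeline,
)

m = read_expression("expression.tsv")
clinical = read_clinical("clinical.tsv")
centroids = read_centroids("centroids.tsv")
calls = run_pipeline(m, clinical, centroids, PipelineConfig(seed=1), out_dir="out/")
print(calls.concordance_refined.consistency_percent)
```

Module map: `io_formats` (tables I/O), `ihc_subtyping` (marker rules +
MKI67 surrogate), `pam50_core` (normalization, centering, classification),
`pca_er` (PC1 + Px cutoff scan), `pcapam50_driver` (three-stage pipeline,
concordance), `synthetic_data` (cohort simulator and the seeded
discordance-repair experiment).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact Px hand
cases, grid-oracle equivalence of the cutoff search, centroid
self-classification, centering contract, noiseless recovery, the seeded
50-replicate discordance-repair experiment, the MKI67 cutoff analytic limit,
byte-level determinism, and the IHC information-flow check). The full suite
runs in well under a minute.

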
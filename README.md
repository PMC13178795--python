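# evimpute

Decision-making pipeline for handling missing values in two-population
extracellular-vesicle (EV) label-free proteomics intensity matrices.

Given a wide protein x sample abundance matrix (two populations, equal
replicate counts), the pipeline:

1. **excludes** proteins in which more than half the values are missing
   (adjustable threshold);
2. **median-ratio normalizes** the retained matrix so every sample's
   median protein ratio is 1;
3. **tests** whether proteins with one population entirely missing occur
   more often than placement combinatorics predict (for 3 of 6 samples
   the chance probability is 2/20 = 10 %), using a two-sided exact
   Fisher test on the observed-vs-expected 2x2 table;
4. on a positive test, **floor-replaces** those one-population-absent
   values with the lowest count value `1` (preserving presence/absence
   contrast); otherwise pools them into the imputation set;
5. **imputes** all remaining missing values with an iterative
   random-forest scheme (mean-initialize, per-column forests, missForest
   stopping rule), with proteins as observations and samples as the
   imputed variables;
6. emits a complete, **provenance-tagged** final dataset (every cell
   marked `observed` / `replaced` / `imputed`), a per-protein
   differential table (log2 fold change, pooled-variance t-test,
   Benjamini-Hochberg q-values) and a machine-readable run report;
7. optionally tests a protein list for **marker enrichment** against an
   ExoCarta-style membership list and stated universe sizes.

An opt-in *rescue* mode recovers excluded proteins whose missingness
splits as one full population plus a single cell on the other side
(floor-replace the full side, forest-impute the single cell).

## CLI

```bash
# full pipeline
evimpute -v run --input matrix.csv --design design.csv \
    --threshold 0.5 --alpha 0.05 --seed 42 --trees 100 \
    --rescue --out results/run1/

# synthetic data with controlled per-category missingness
evimpute simulate --n-complete 400 --n-imputable 900 --n-one-pop 300 \
    --n-excluded 400 --seed 7 --out sim/

# marker enrichment for a protein list
evimpute enrich --proteins final_proteins.txt --markers exocarta.txt \
    --n-db 8877 --n-universe 21880
```

`run` writes `final_dataset.tsv`, `provenance.tsv`, `volcano.tsv` and
`report.json` into `--out`. Inputs may be CSV, TSV or XLSX (first column
protein IDs; sample columns are selected by name, extra annotation
columns are ignored; empty cells and `NaN`/`NA` tokens parse as
missing).

## Library

```python
from evimpute import (
    SampleDesign, read_abundance_matrix, PipelineConfig, run_pipeline,
)

design = SampleDesign.from_populations({"FBS": ["F1", "F2", "F3"],
                                        "MILK": ["M1", "M2", "M3"]})
matrix = read_abundance_matrix("matrix.csv", design)
result = run_pipeline(matrix, PipelineConfig())
result.provenance.data      # completed matrix
result.volcano              # differential table
result.report.to_dict()     # run report
```

Modules map one-to-one onto the pipeline stages: `matrix_io`,
`missingness` (profiling, configuration combinatorics, exact Fisher
test, decision), `normalization`, `imputation`, `differential`,
`enrichment`, `simulate` (synthetic fixtures with ground truth),
`pipeline`/`cli`.

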
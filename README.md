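# somatlas

SOM-based expression cartography for transcriptomics. A genes × samples
expression matrix is projected onto a two-dimensional lattice of
*metagenes* (a Kohonen self-organizing map); each sample is then rendered
as a color-coded mosaic portrait. Connected groups of jointly over- or
underexpressed lattice nodes are segmented into *spots*, functionally
annotated by hypergeometric gene-set overrepresentation, and used for
downstream analysis: metagene-based top-list filtering (fold change,
variance, shrinkage-t local FDR), hierarchical clustering, ICA, pairwise
correlation maps, entropy specificity scoring, and a second-level SOM that
maps samples onto a metasample grid. A zoom-in mode re-trains the whole
pipeline on a sample subset.

## Command line

```sh
# generate a planted-module synthetic data set (TSV + annotation + GMT)
somatlas simulate --out sim --seed 42

# full pipeline: preprocess -> SOM -> portraits/maps -> spots ->
# enrichment -> filtering -> downstream -> second-level SOM
somatlas run --expression sim/expression.tsv --scale log10 \
    --annotation sim/annotation.tsv --gmt sim/gene_sets.gmt \
    --out results_run --grid-x 20 --grid-y 20 --seed 42

# re-train on a sample subset (re-centered within the subset)
somatlas zoom --expression sim/expression.tsv --scale log10 \
    --out results_run --samples sample_00,sample_01,sample_02,sample_03

# enrichment-only and filtering-only entry points
somatlas enrich --expression sim/expression.tsv --gmt sim/gene_sets.gmt --out enrich_out
somatlas filter --expression sim/expression.tsv --criterion fc --n 100 --out top.csv
```

Every run writes `config.yaml`, `log.txt`, the codebook/assignment CSVs
and one directory per stage (`portraits/`, `maps/`, `spots/`,
`enrichment/`, `filtering/`, `downstream/`, `second_level/`). Runs are
deterministic given the config and `--seed` (default 42). A YAML config
can be passed with `--config`; flags override its fields.

## Input formats

- expression matrix: TSV with a header row of sample ids and gene ids in
  the first column (GCT 1.2 also accepted); declare the scale as
  `linear`, `log10` or `centered`
- gene sets: GMT (`name TAB description TAB members...`); the description
  field may carry a GO-branch tag (`bp`/`mf`/`cc`)
- sample annotation: two-column TSV `sample_id TAB category`

## Python API sketch

```python
import somatlas as sa

matrix = sa.read_expression_matrix("expression.tsv", "log10")
centered = sa.center_profiles(matrix)
som = sa.train_som(centered, sa.SOMGrid(60, 60), seed=42)

from somatlas.portraits_maps import sample_portrait, summary_maps
from somatlas.spot_analysis import global_spots, spot_expression
over, under = summary_maps(som)
spots = global_spots(som, over, "over")
```

## Notes

- Raw probe calibration and detection calls are out of scope; input is
  assumed to be summarized expression values. A floor + present-fraction
  filter and standard quantile normalization are available as stand-ins.
- The WAD and log-log portrait contrasts affect rendering only, never
  downstream statistics.
- The shrinkage-t local-FDR filter is a self-contained variant with its
  own calibration tests (pure-null and planted-signal).
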
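# dhscreen

Screening pipeline for gene- and cell-type-specific enhancer candidates
from DNase I hypersensitive site (DHS) panels, with dual-luciferase
reporter scoring, expression screening and external-evidence annotation.

The pipeline mirrors a four-stage screening strategy:

1. **Expression screen** — RPKM normalization of read-count matrices,
   up-regulation calls against a reference condition, and qPCR-style
   relative quantification (2^-ddCt) with per-condition t-tests.
2. **Specificity classification** — DHS peaks from a multi-cell-type
   panel are merged into candidate sites inside a locus domain (70 kb
   upstream of the TSS to 20 kb downstream of the poly(A) site) and
   classified as target-specific, putative target-specific (subdued
   presence in at most two non-target cell types), or non-specific.
3. **Reporter scoring** — firefly/renilla well ratios are rolled up per
   construct; the decision tree calls minimal-promoter enhancers (fold
   >= 5, i.e. log2 >= 2.32), own-promoter enhancers (two-group one-way
   ANOVA, p < 0.01 plus a mean increase), and cell-type-specific
   enhancers (positive in the target line, negative in all controls).
4. **Evidence annotation** — conservation / FAIRE / histone-mark / TF
   tracks are joined by interval overlap, a site x TF cluster-score
   matrix is built and k-means-classed, and the screen summary counts
   are emitted.

A transcription of the published 23-site candidate table ships with the
package (`dhscreen/data/table1.tsv`) and drives a *call-replay* mode, so
the decision tree and summaries can be exercised without raw
luminescence or sequencing data. A synthetic-data module generates every
input format with planted ground truth for end-to-end testing.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(fixture replay counts, evidence summary, threshold transform,
brute-force oracles, calibration and determinism properties).

## CLI

```bash
dhscreen simulate --seed 1 --n-genes 5 --out sim/       # synthetic inputs
dhscreen classify-dhs --gene-models sim/gene_models.tsv \
    --peaks-dir sim/peaks --out sites.tsv               # specificity calls
dhscreen score-reporter --plate sim/plate.tsv --out calls.tsv
dhscreen annotate --tracks-dir sim/tracks --candidates cands.bed --out ev.tsv
dhscreen summarize --out summary.json                   # packaged fixture replay
dhscreen run --config config.yaml                       # full pipeline
dhscreen emit-fixture --out table1.tsv
```

A pipeline YAML config lists input paths (`gene_models`, `peaks_dir`,
`counts`, `qpcr`, `plate`, `tracks_dir` or `replay_table`), the output
directory and thresholds (`fold_threshold: 5`, `alpha: 0.01`,
`subdued_ratio: 0.5`, `upstream: 70000`, `downstream: 20000`, `k: 3`).
Stages with absent inputs are skipped and recorded in
`run_report.json`.

## Conventions

All coordinates are 0-based half-open; BED is read natively and the
GTF-subset reader converts on load. "Upstream" is strand-aware. No
multiple-testing correction is applied across sites, mirroring the
original screen; this is flagged in the run metadata.
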
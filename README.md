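# cnkit

A library and command-line toolkit for multi-scale copy-number (CN) track
analysis and clinical-style review plots:

- **Track format** — tab-separated index and track tables (`chrom`, `start`,
  `end`, `N` plus optional `sd`, `gc`, `label`), with deterministic writers
  and validating readers. Adapters import SEG / bedGraph / ratio-table
  caller output (log2 ratios become linear CN via `CN = 2 * 2**log2ratio`)
  and refFlat / GTF annotations to exon-level records.
- **Multi-resolution binning** — fixed-size tilings (1 Mb / 50 kb / 5 kb by
  default) plus an irregular bait-level grid; overlap-width-proportional
  aggregation (count-conserving) and re-binning of caller output to every
  display scale.
- **Robust CN estimation** — library-size scaling by median ratio, GC
  correction by stratified running medians, a per-bin median/MAD reference
  model (`ref_sd = 1.4826 * MAD`) robust to tumour samples in the cohort,
  CN and error estimation, sample-vs-sample ratio mode, and robust-CV QC
  summaries.
- **Contextual filters** — per-assay blacklists (flag, never delete),
  per-disease gene whitelists, canonical-transcript filtering, and overflow
  flagging against a display ceiling.
- **Rendering** — deterministic static SVG/PNG/PDF of the stacked
  genome / region / detail panels with cytoband ideogram, error bars,
  overflow triangles, segment/breakpoint/BAF overlays, gene zoom and a
  tabular feature report. Same inputs always give byte-identical SVG.
- **Simulation** — synthetic reference cohorts and test samples with
  planted CNV segments, a smooth GC-bias field and Poisson (optionally
  overdispersed) noise, including four named presets
  (`germline_exon_del`, `hyperdiploid`, `ctdna_focal_amp`, `lowpass_wgs`).

## CLI

```sh
# simulate a cohort with a planted single-exon deletion
cnkit simulate --preset germline_exon_del --out sim/

# run the full pipeline: binning at all scales, cohort reference, CN tables
cnkit build --chrom-sizes sim/chrom.sizes --targets sim/targets.bed \
    --scales genome=1000000,arm=200000,region=50000 \
    --out build/ sim/counts_*.tsv

# render the three-panel view for the test sample
cnkit render --index build/index.tsv --sample test --out view.svg

# ratio mode: sample vs sample (or vs a group median)
cnkit compare --index sim/index.tsv --sample-a test --sample-b ref01 \
    --resolution target --out ratio.tsv

# import an existing caller's SEG output, re-binned to each scale
cnkit build --caller calls.seg --dialect seg \
    --chrom-sizes hg19.chrom.sizes --out imported/

cnkit reference --chrom-sizes sim/chrom.sizes --out ref.tsv sim/counts_ref*.tsv
cnkit qc --chrom-sizes sim/chrom.sizes sim/counts_*.tsv
cnkit validate build/index.tsv build/cn_*.tsv
```

## Conventions

Coordinates are 0-based half-open everywhere internally and in the track
dialect; 1-based formats (SEG, GTF) are converted at the I/O boundary.
Chromosome names are normalized by stripping a leading `chr`. Missing
values are explicit (`NaN` / empty field) and rendered as gaps, never
interpolated.
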
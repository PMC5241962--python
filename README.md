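# cghcnv

Gene-centric copy-number-variation discovery from two-channel aCGH
intensities, designed for species **without a contiguous reference genome**.
Instead of segmenting a genome, probes are tiled within gene sequences and
CNVs are called per gene by probe voting:

1. **Probe selection** — design-time quality filters: raw ≥ 2× background in
   ≥ 6 of 10 pilot datasets, sense/antisense dedup by mean intensity,
   ≥ 6 probes and > 500 bp covered per gene, 200/100 bp minimum spacing.
2. **Normalization** — per-array M/A computation from background-subtracted
   channels, robust LOESS dye-bias correction on the M-A plot, GC-wave
   removal, and a linear probe-composition correction.
3. **Calibration** — the detection operating point (probe threshold `tau`,
   consistent-sign significant-probe fraction `frac`) is chosen on
   self-self (null) hybridizations so that the empirical FDR stays ≪ 1%.
   Defaults: `tau = |log2(4/3)| ≈ 0.415`, `frac = 0.83`.
4. **Calling** — a probe is significant when `|M| > tau` (strict); a gene is
   a CNV when the majority-sign significant count reaches
   `ceil(frac · n_probes)`; called genes with `|median M| > 3` are flagged
   presence/absence variations (PAV).
5. **Cohort summaries** — per-family call matrices, common/infrequent
   frequency classes, sharing/core sets across families, ANOVA + Tukey HSD
   on per-individual counts, and genetic-map reports (per-LG counts,
   adjacent cM distances, 1-cM clusters, KS density comparison).

A fully deterministic **simulator** generates probe panels, full-sib
families with Mendelian CNV transmission, and two-channel intensities with
dye bias, GC waves and Gaussian noise — plus ground-truth tables — so every
stage is testable end to end without external data.

## CLI

All inputs/outputs are plain TSV (see `cghcnv/io.py` docstring for the
schemas); vendor scanner exports are not parsed — convert generic two-color
exports to the `intensities.tsv` schema first.

```sh
# simulate a family plus 9 self-self arrays
cghcnv simulate --config cfg.toml --out-dir sim/ --self-self 9

# design-time probe selection from pilot hybridizations
cghcnv select-probes --intensities pilot.tsv --probes probes.tsv \
    --out kept_probes.tsv --report report.json

# normalization -> corrected log2 ratios
cghcnv normalize --intensities sim/intensities.tsv --arrays sim/arrays.tsv \
    --probes sim/probes.tsv --out ratios.tsv

# self-self FDR grid search; writes the chosen parameters as TOML
cghcnv calibrate --ratios ratios.tsv --arrays sim/arrays.tsv \
    --probes sim/probes.tsv --intensities sim/intensities.tsv \
    --out grid.tsv --choose params.toml

# gene CNV calls
cghcnv call --ratios ratios.tsv --probes sim/probes.tsv \
    --params params.toml --out calls.tsv --untested untested.tsv

# family/cohort summaries (map.tsv optional)
cghcnv cohort --calls calls.tsv --arrays sim/arrays.tsv \
    --intensities sim/intensities.tsv --map map.tsv --out-dir cohort/
```

Configuration is flat TOML with `[detection]`, `[normalize]` and
`[simulate]` tables; every subcommand accepts `--config`.

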
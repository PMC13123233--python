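# ergflash

A flash-electroretinogram (ERG) analysis pipeline for mouse dystrophinopathy
models, together with a calibrated synthetic cohort generator that makes the
whole chain verifiable by parameter recovery — no recorded data required.

The pipeline implements the classic full-field flash ERG quantification
scheme:

* **Averaging & artifact handling** — stimulus-locked sweeps are averaged per
  eye × condition; an optional robust (median + MAD) peak-to-peak rule
  rejects artifact sweeps offline.
* **Oscillatory-potential isolation** — each averaged trace is split in the
  frequency domain into a slow (OP-removed) waveform and the isolated OPs by
  a zero-phase DFT bin partition. The cutoff is either fixed (50 Hz,
  default) or adaptive (spectral minimum in 30–60 Hz with fixed fallback).
  The split is exactly conservative: `slow + ops` reproduces the input.
* **Component measurement** — baseline from the 16 ms pre-flash window;
  a-wave = baseline-to-trough within 50 ms of onset (with a detection
  threshold); b-wave = a-trough-to-peak (or baseline-to-peak when no a-wave
  exists); OP amplitude = maximal single-sided Fourier magnitude in
  60–100 Hz. Implicit times are sub-sample refined by local parabolic
  interpolation.
* **Littermate normalization** — amplitudes as % of the wild-type group mean
  at the same flash strength (WT mean = 100 %), implicit times as ms
  difference from the WT mean, then pooled across flash strengths.
* **Group statistics** — two-way mixed ANOVA for the dark-adapted series
  (Mauchly sphericity; Greenhouse–Geisser for severe violations, ε < 0.75,
  else Huynh–Feldt; Bonferroni vs Tukey post-hoc) and one-way ANOVA for the
  light-adapted flash (Levene → Welch → Games-Howell escalation).
* **Synthetic cohorts** — dark-adapted responses at five flash strengths
  (−3.7…0.3 log cd·s/m²) plus one light-adapted flash, built from gamma-
  kernel a/b components, a 60–100 Hz OP wavelet, Naka–Rushton intensity–
  response growth, flash-dependent latencies, animal/eye random effects and
  per-sweep Gaussian noise. Genotype presets (WT, mdx, mdx5Cv, mdx2Cv,
  mdx52, dmd-null) specify *measurement-scale* effect targets, and a
  calibration step solves internal model factors so the pipeline's own
  noise-free measurements hit those targets exactly.

## Tests

```bash
python -m pytest -q          # full suite, incl. acceptance criteria
```

`tests/test_acceptance.py` runs the end-to-end parameter-recovery checks:
paper-scale cohorts at 10 seeds per genotype must recover the preset effect
sizes within ±3 percentage points (amplitudes; ±4 for OPs) / ±1.5 ms
(implicit times) in at least 9 of 10 seeds.

## Command line

```bash
# simulate a seeded mdx2Cv cohort + matched WT littermates
ergflash simulate --genotype mdx2Cv --seed 1 --out sim/

# run the full analysis chain on waveform tables
ergflash analyze sim/waveforms_mutant_mdx2Cv.csv sim/waveforms_wt_mdx2Cv.csv \
    --out results/ --unit eye
```

`analyze` writes `measures.csv` (per eye × condition component measures),
`normalized.csv`, `stats.json` (ANOVA results with the full correction
trail), `model_summary.csv`/`.txt`, and a `manifest.json` with content
digests of all inputs and outputs. Exit codes: 0 ok, 2 usage/config error,
3 data-integrity error.

Waveform tables are long-format CSV/TSV with columns
`animal_id, eye_id, genotype, adaptation, flash_strength, sweep,
sample_index, voltage_uv, onset_index, sampling_rate` (µV, 512 Hz × 250 ms
records by default; stimulus onset must be given via `onset_index`).

## Package layout

| module | contents |
| --- | --- |
| `ergflash.data_model` | domain types, protocol table, config, table I/O |
| `ergflash.processing` | artifact rejection, averaging, spectra, OP split |
| `ergflash.quantify` | a/b-wave and OP measurement |
| `ergflash.cohort` | normalization, pooling, ANOVA decision tree |
| `ergflash.synth` | waveform model, genotype presets, calibration, cohorts |
| `ergflash.pipeline` | end-to-end orchestration and parameter recovery |
| `ergflash.cli` | `ergflash simulate` / `ergflash analyze` |
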
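# fictloc

Analysis pipeline for in-vitro fictive-locomotion experiments, covering the
three recording modalities of such studies and a seeded synthetic generator
so that every stage can be validated by parameter recovery without any
external data:

- **ventral_root** — rectification + leaky integration (50 ms time
  constant), MAD-threshold burst detection, per-burst
  frequency/duration/amplitude, 0.5-min time-course normalization against a
  10-min pre-control period, and 5-min steady-state epoch comparisons.
- **calcium** — per-ROI ΔF/F conversion (baseline = minimum 10-frame mean
  within the first minute), exponential-envelope bleach correction, and
  threshold-based Ca²⁺ transient detection.
- **phase** — transient phasing onto the locomotor cycle (onset-to-onset),
  circular mean / resultant length, the Rayleigh uniformity test (Z = nR̄²
  with the standard series p approximation), and per-region coupled
  fractions.
- **patch_clamp** — spike detection, dV/dt (10 mV/ms) onsets, half-width,
  mAHP and inter-spike AHP amplitudes, rheobase, depolarizing block
  (≥100 ms silence after repetitive firing), maximum firing, input
  resistance from voltage-clamp step families, holding-current changes and
  ramp thresholds.
- **stats** — D'Agostino-Pearson-gated test selection: paired t /
  Wilcoxon signed-rank, repeated-measures ANOVA + Tukey / Friedman + Dunn
  (Bonferroni), and unpaired t / Mann-Whitney.
- **synthetic_data** — deterministic, seeded generators for all three
  modalities with exact ground truth (burst tables, per-cell preferred
  phases and event times, spike-waveform parameters, f-I curves).
- **pipeline / cli** — study-level orchestration and the `fictloc`
  command-line interface.

## CLI

```bash
fictloc simulate --config scenario.yaml --out demo_data/   # synthetic dataset + ground truth
fictloc vr-analyze --input demo_data/vr.h5 --channel vr \
        --epochs demo_data/epochs.yaml --out-bursts bursts.csv
fictloc ca-dff --input demo_data/rois.csv --transients transients.csv
fictloc ca-phase --bursts bursts.csv --transients transients.csv --out phase.csv
fictloc patch-features --input demo_data/patch.h5 --out features.csv
fictloc compare --input long_table.csv --design repeated --out report.json
fictloc demo --out demo_out/ --seed 0                      # end-to-end demo
```

Trace files are CSV (metadata in leading `# key = value` lines) or HDF5
(one group per channel with `values` + rate/units attributes). Tabular
outputs are CSV, summaries JSON; every run writes a `manifest.json` with
the resolved config, seed and output hashes.

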
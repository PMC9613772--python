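# ktrdiv

Single-cell kinase-translocation-reporter (KTR) dynamics and cell-division
fate: image quantification, tracking, automatic division detection, and the
statistics that link windowed ERK/Akt activity to whether a cell divides.

## The problem

In growth-factor-stimulated epithelial cells (e.g. MCF10A), whether an
individual cell will divide is stochastic even in clonal populations.
Live-cell KTR imaging reads out ERK and Akt kinase activity in each cell as
the cytoplasm/nuclear fluorescence ratio (C/N): active kinase exports the
reporter from the nucleus, raising C/N. Pairing those activity time courses
with the eventual division outcome of the *same* cells asks which features
of signaling dynamics carry information about fate.

`ktrdiv` is a tested, reusable implementation of that computation for
people who have (a) multi-channel time-lapse movies (nuclear marker plus
one or two KTR channels), or (b) pre-quantified per-cell C/N trace tables —
plus a first-class synthetic-data generator so the whole pipeline can be
exercised against known ground truth without any external data.

## The method

1. **Quantification** — flatfield/background correction, nuclear
   segmentation, construction of a perinuclear "cytoring" extending 10 px
   from the nuclear mask, and per-cell `C/N = mean(ring) / mean(nucleus)`.
2. **Tracking** — optimal per-frame-pair assignment on centroid distance
   with a displacement gate; tracks shorter than the full time course are
   filtered out.
3. **Division detection** — mitosis produces a steep transient C/N drop;
   the detector finds the earliest prominent relative drop (default
   >= 35% over <= 2 frames), truncates the trace 5 timepoints before it,
   and classifies each cell as dividing, non-dividing (present >= 48 h at
   15-min sampling, >= 41.67 h at 5-min), or excluded.
4. **Statistics** — per-cell median activity in the 8.5–40 h post-stimulus
   window; right-tailed Wilcoxon rank-sum (dividing vs non-dividing);
   binomial/logit GLM `divided ~ median_ERK + median_Akt`; pooled per-class
   ERK–Akt Pearson r over all cell-time points with a 1000-rep
   multivariate-normal resampling band (5th–95th percentiles, rounded up
   to 0.01); and a perturbation-based 2-node crosstalk statistic
   (windowed difference of median trajectories + cell bootstrap).

See `docs/methods.md` for the model, parameter defaults and design notes.

## Worked example

Simulate a 200-cell experiment (48 h at 15-min sampling, growth factor at
1 h) and run the full trace-level analysis:

```python
import json
import ktrdiv as kd

cfg = kd.SimConfig(n_cells=200, seed=0)
cells, traces = kd.simulate_cell_population(cfg)
analysis = kd.analyze_traces(traces, cfg.sampling_interval_h, null_band_seed=0)
print(json.dumps(analysis.to_report(), indent=2))
```

Output (abridged):

```
{
  "n_dividing": 99,
  "n_nondividing": 101,
  "n_excluded": 0,
  "ranksum": {
    "akt": {"W": 11647.0, "p": 1.69e-05, "n_div": 99, "n_nondiv": 101},
    "erk": {"W": 13501.0, "p": 2.03e-18, "n_div": 99, "n_nondiv": 101}
  },
  "correlations": {
    "dividing":     {"r": 0.218, "n_points": 6587,  "band": [0.20, 0.24]},
    "non-dividing": {"r": 0.631, "n_points": 12827, "band": [0.63, 0.65]}
  },
  "logit": {
    "params":  {"intercept": -7.31, "erk": 5.91, "akt": 0.31},
    "pvalues": {"intercept": 8.4e-10, "erk": 5.8e-11, "akt": 0.70},
    "converged": true
  }
}
```

Reading it: 99 of 200 simulated cells divided and all were recovered by the
drop detector. Dividing cells have significantly higher windowed median
activity in both channels (right-tailed rank-sum), more so for ERK; in the
bivariate logistic regression only the ERK median is significant; and the
pooled ERK–Akt correlation is much lower in dividing cells (r = 0.218 over
6,587 cell-time points) than in non-dividing cells (r = 0.631 over 12,827),
with disjoint resampling bands — the generator was configured with exactly
this structure, and the pipeline recovers it.

The movie-level interface is symmetrical:

```python
rc = kd.RenderConfig()
movie = kd.render_timelapse(cells, rc, cfg)        # (frames, 3, H, W)
analysis = kd.analyze_movie(movie, cfg.sampling_interval_h)
```

A CLI wraps the same stages:

```bash
ktrdiv simulate --seed 0 --out sim/
ktrdiv quantify --nuclear sim/nuclear.tif --ktr sim/erk.tif --ktr sim/akt.tif \
                --ring-width 10 --out measurements.csv
ktrdiv detect   --tracks sim/traces.csv --channel akt --out calls.csv --qc-dir qc/
ktrdiv stats    --traces sim/traces.csv --window 8.5 40 --seed 0 --out report/
```

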
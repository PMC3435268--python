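# pacpipe

Phase-amplitude coupling analysis of multichannel cortical surface
potentials. The pipeline separates the power spectrum into a spectrum-wide
("broadband") component — a correlate of aggregate population activity —
and band-limited rhythms, then quantifies how the broadband amplitude is
entrained on the phase of low-frequency rhythms, how that entrainment
changes between movement and rest, how rhythms cohere across the array,
and how spatial maps of different measures overlap.

## What it computes

- **Preprocessing** — common average reference (CAR) with automatic
  channel rejection; movement/rest event extraction from finger-position
  traces (`pacpipe.preprocess`).
- **Spectral estimators** — Hann-tapered PSD snapshots per 1 s epoch,
  5-cycle Morlet dynamic spectra, and zero-phase Butterworth + Hilbert
  analytic band signals (`pacpipe.spectral`).
- **Broadband decoupling** — eigen-decomposition of normalized log-PSDs
  into principal spectral components (PSCs); the 1st PSC's projection
  gives the broadband timecourse, the 2nd–4th capture rhythms; a
  65–135 Hz band-power envelope is available as a fast approximation
  (`pacpipe.broadband`).
- **Coupling** — phase-binned broadband means (K = 24 bins), the
  frequency × phase "coupling palette" (1–50 Hz), complex coupling
  vectors Z_mod·e^{iφ_c}, trial-projected coupling distributions with
  Hotelling-T² significance, and signed-r² condition contrasts
  (`pacpipe.coupling`).
- **Coherence** — seed-referenced complex phase coherence over rest
  epochs with phase-lag projection, exposing the π-shifted coherence
  artifact introduced by CAR (`pacpipe.coherence`).
- **Statistics** — signed r² (point-biserial convention) and a
  permutation spatial-overlap metric with exact enumeration for small
  arrays (`pacpipe.stats`).
- **Synthetic data** — a generator producing sessions with imposed
  1/f^χ broadband, rhythms, phase-amplitude coupling, a cued
  finger-movement task (2 s movement / 2 s rest), and somatotopic
  broadband gains; used as positive/negative control for every stage
  (`pacpipe.synthetic`).

## CLI

All stages are exposed through one executable:

```bash
# generate a synthetic session (YAML mirrors SyntheticConfig)
pacpipe synth --config synth.yaml --out session.h5

# CAR + event extraction
pacpipe preprocess session.h5 --out clean.h5

# individual stages
pacpipe spectra   clean.h5 --channel ch0 --out psd.csv
pacpipe broadband clean.h5 --channel ch0 --out broadband.csv
pacpipe couple    clean.h5 --channel ch0 --out palette.csv
pacpipe cohere    clean.h5 --seed-channel ch0 --out coherence.csv
pacpipe overlap   map_a.csv map_b.csv --n-perm 100000

# everything: six result tables + palettes + manifest.json
pacpipe run clean.h5 --config pipeline.yaml --out results/

# negative control: coupling false-positive rate on noise channels
pacpipe control --n-channels 50 --out control.json
```

Sessions are stored in an HDF5 container (`/samples`, `/rate`,
`/channels`, `/events`, `/finger_traces`); EDF/EDF+ files and delimited
numeric tables can be imported via `pacpipe.load_session(path,
format=...)`. All result tables are CSV.

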
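# Configuration file schema

CLI commands that accept `--config` read a YAML file.  All keys are
optional; omitted keys fall back to the defaults documented in
`docs/methods.md`.

```yaml
sim:                       # simulator ranges (pureshift.simkit.SimConfig)
  acq:                     # chunked acquisition geometry
    spectral_width_hz: 4000.0
    chunk_len: 64          # complex points per chunk
    n_chunks: 93           # total chunks; chunk_len*n_chunks <= n_ft
    n_ft: 8192             # Fourier transform length after zero filling
  n_peaks_range: [3, 25]   # inclusive bounds on peaks per spectrum
  freq_window_fraction: 0.9
  min_separation_bins: 2
  amp_range: [0.02, 1.0]   # log-uniform; ratio = dynamic-range cap
  lw_range_hz: [1.0, 6.0]  # full Lorentzian linewidth at half height
  phase_range_rad: [0.0, 0.0]
  sigma_rel_range: [0.0, 0.05]   # noise std relative to max |FID|
```

Every run writes `<output>.manifest.json` recording the command, the fully
resolved configuration, the master seed and SHA-256 digests of all inputs
and outputs; replaying the command with the same seed reproduces the
digests on one device.
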
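# perceptmeg

Synthetic-phantom simulation and artefact analysis for concurrent
deep-brain-stimulation telemetry and MEG recordings.

The package reproduces, in silico, the interference structure that a
sensing-enabled DBS stimulator imprints on three MEG system types —
a 275-channel cryogenic axial-gradiometer system (19.2 kHz), a
306-channel magnetometer + planar-gradiometer system (5 kHz), and a
62-channel OPM array (6 kHz) — across its operating conditions
(telemetry open/closed, two streaming protocols, bipolar/monopolar
stimulation, implant movement, communicator proximity), and provides
the analysis chain used to characterize that interference and to work
with the stimulator's own LFP stream:

* **`perceptmeg.simulate`** — multichannel MEG + LFP generation:
  shaped noise floors, mains/intrinsic peaks, telemetry tones and
  combs, charge-balanced biphasic pulse trains projected through a
  current dipole, SQUID step jumps, OPM modulation-tone
  intermodulation, clock offset/drift injection. Ground truth is kept
  in a `truth` block for testing.
* **`perceptmeg.spectral`** — Welch amplitude spectral densities
  (3 s Hann segments, 50% overlap) with flat-segment / step-jump
  rejection.
* **`perceptmeg.peaks`** — narrowband peak detection over a
  running-median baseline, comb-fundamental estimation,
  intermodulation-product prediction, and artefact-source
  classification.
* **`perceptmeg.alignment`** — MEG/LFP clock alignment from
  stimulation toggling (with a jump-robust log-|derivative| transform),
  tap transients, or ECG cross-correlation; affine clock-map fitting
  and band-limited resampling.
* **`perceptmeg.forward` / `perceptmeg.coherence`** — analytic
  single-sphere lead fields, 1 s epoching, LFP-referenced
  magnitude-squared coherence with a permuted-reference null and
  family-wise error control, and DICS beamformer coherence images in
  alpha (7–13 Hz) and beta (15–35 Hz) bands on a 10 mm grid.
* **`perceptmeg.io` / `perceptmeg.cli`** — native binary+YAML
  recording format, HDF5/TSV export, and a `perceptmeg` command-line
  pipeline.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` re-runs the full-scale (120 s, full channel
count) generator → detector chains and the statistical property checks;
the rest of the suite uses shrunken sensor arrays and runs in under two
minutes.

## CLI

```sh
perceptmeg simulate --system ctf --condition sensight_streaming \
    --duration 120 --seed 1 --out out/rec
perceptmeg psd out/rec --seglen 3 --clean --out out/spec.h5
perceptmeg peaks out/spec.h5 --prominence 6 --out out/peaks.csv
perceptmeg classify out/peaks.csv
perceptmeg align --meg out/rec --lfp out/rec_lfp --method toggle --out out/map.json
perceptmeg coherence --meg out/rec --lfp out/rec_lfp --map out/map.json \
    --mode sensor --out out/coh.h5
perceptmeg run --system ctf --condition sensight_streaming --seed 1 --out out/
```

Condition names: `empty_room`, `quiescent`, `movement`,
`communicator_near`, `sensight_streaming`, `sensight_open`,
`legacy_streaming`, `legacy_open`, `bipolar_stim`, `monopolar_stim`,
`brainsense_zero`, `brainsense_stim` (or a YAML condition file).

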
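# vadistill

Speech detection in environmental audio with knowledge distillation, built
end to end on a NumPy numerical stack:

- **fixtures** — synthetic eco-acoustic audio pools (speech-like harmonic
  clips in two pitch registers, ~40 classes of background event textures,
  frequency-modulated bird whistles, long ambient soundscapes) so the whole
  pipeline runs without any external corpora;
- **dataset_builder** — the preprocessing pipeline: segment soundscapes
  into 3-s / 16 kHz clips, mix in speech/background/bird events at
  controlled SNRs, emit a balanced labeled dataset (default 20,000 clips,
  1:1 speech/non-speech) with stratified 60/20/20 splits, plus a
  playback-style evaluation set across distances (1/5/10/20 m), voice types
  and environments;
- **features** — 128x128 single-channel log-Mel grids (1024-sample Hann
  window, hop 512, 128 Mel bands, per-bin z-normalization), stored in HDF5;
- **models** — a customized VGG11-BN teacher (59,568,769 parameters) and
  four MobileNetV3-style inverted-residual students (block tables in
  `src/vadistill/configs/students.yaml`), with intermediate-layer taps,
  embeddings, and a resource profiler (params / MACs / table-style FLOPs /
  memory / timed inference);
- **distill** — teacher training plus three distillation objectives
  (soft-target with temperature softening, FitNets-style feature hints
  through a learned regressor, relational distance+angle matching), Adam,
  early stopping with patience;
- **evaluate** — F1/AUC, percentile-bootstrap CIs of medians, exact /
  tie-corrected Mann-Whitney U tests, distance-stratified playback reports,
  and cross-method comparison tables;
- **nn** — a compact reverse-mode autodiff engine (conv2d via im2col,
  depthwise convs, fused batch norm, max pooling, SE blocks, Adam) used by
  everything above; no deep-learning framework is required.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion,
including a full end-to-end smoke distillation run (600 clips); the whole
suite is sized for a single CPU.

## CLI

```bash
vadistill --config smoke.yaml run-all          # fixtures -> dataset -> features
                                               # -> teacher -> distillation
                                               # -> comparison -> playback report
vadistill profile --model teacher              # Table-style resource profile
vadistill --config smoke.yaml distill --method soft --model s4
```

Config is YAML (see `RunConfig` in `vadistill/cli.py`); unknown keys are
rejected with the offending key path and exit code 2. Every run directory
receives the fully-resolved config, a JSONL log, manifests, loss curves and
JSON reports. Per-stage seeds derive from the global `--seed` by stable
hashing, and `--no-deterministic` opts out of seeded mode.

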
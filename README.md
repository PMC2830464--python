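# neurofuse

Decision fusion for simulated neural prosthetic decoding.

`neurofuse` simulates cosine-tuned Poisson cortical spike data driven by
random 2-D endpoint trajectories, decodes velocities with three independent
single-modality decoders — a Kalman filter, a population-vector-algorithm
(PVA) variant, and an optimal linear (sliding-window regression) filter —
and fuses their per-timestep velocity estimates with either a Kalman fusion
filter or a feed-forward artificial neural network trained by scaled
conjugate gradient. Decoders are scored by root mean squared error in
velocity space (`E_rms`) under a three-phase protocol: individual-decoder
training, fusion training (with a separate validation set for ANN early
stopping), and final testing on fresh trajectories, with paired one-tailed
and Welch two-tailed T-tests.

## Running the tests

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which runs the full
experiment at protocol scale (50 neurons, 3,000/1,500-step training,
10,000-step fusion training, 150 seeded test trajectories); it takes a few
minutes on one CPU.

## Library quick start

```python
import neurofuse as nf

cfg = nf.ExperimentConfig(n_test_trials=10, base_seed=0)   # all defaults printed by
result = nf.run_experiment(cfg)                            # neurofuse config-template
print(result.stats["mean_e_rms"])
print(result.stats["paired_one_tailed"]["kalman_fusion_vs_kalman"])
```

Every stochastic operation is a pure function of its inputs and an integer
seed; an experiment's base seed deterministically spawns named substreams
(trajectory, tuning, spikes-train, …), so reruns are bit-for-bit
reproducible.

## Command-line interface

```bash
neurofuse config-template > run.yaml         # all defaults, edit as needed
neurofuse simulate --config run.yaml --out-dir data --seed 1
neurofuse train-decoder --decoder kalman --spikes data/spikes.tsv \
    --velocity data/velocity.tsv --out kalman.json
neurofuse decode --model kalman.json --spikes data/spikes.tsv --out est_kalman.tsv
neurofuse fuse-train --method kalman --velocity data/velocity.tsv \
    -e est_kalman.tsv -e est_pva.tsv -e est_linear.tsv --out fusion.json
neurofuse fuse-decode --model fusion.json -e est_kalman.tsv -e est_pva.tsv \
    -e est_linear.tsv --out fused.tsv
neurofuse evaluate --truth data/velocity.tsv --estimate fused.tsv
neurofuse run-experiment --out-dir results --regime high --seed 1
neurofuse topology-search --help             # 12 x 11+1 hidden-unit grid search
```

All tables are tab-separated text with a header row and `#` provenance
comments; trained models are JSON containers of named arrays plus metadata.

## Package layout

| module | contents |
| --- | --- |
| `neurofuse.synthetic` | trajectory generator, cosine-tuning population, Poisson spike simulation |
| `neurofuse.decoders` | Kalman filter, PVA variant, optimal linear filter |
| `neurofuse.fusion` | observation assembly, Kalman fusion, ANN + SCG, topology search |
| `neurofuse.evaluation` | `E_rms`, pointwise error, T-tests, three-phase experiment |
| `neurofuse.io` / `neurofuse.cli` | TSV/JSON/YAML I/O and the `neurofuse` CLI |
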
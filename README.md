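# fearscope

A desk-scale, fully synthetic re-implementation of a miniature-microscope
calcium-imaging and behavior analysis pipeline for three-day auditory-cued
fear conditioning, plus the accompanying slice-physiology (EPSC) metrics and
statistical battery.

Because the original recordings are not required, a seeded synthetic-data
generator produces every input with planted ground truth — experiment
schedules, two-state movement/freezing behavior, fluorescence traces with
stimulus-locked responses, and light-evoked EPSC sweeps — so every analysis
stage is verifiable end to end.

## Modules

| Module | Purpose |
| --- | --- |
| `fearscope.synthetic` | Schedules (habituation / training / recall), semi-Markov behavior model, neuron populations with planted US/tone/movement-ON responders, Hill-saturating EPSC traces |
| `fearscope.deconvolution` | Non-negative sparse AR(1) deconvolution (online pool-adjacent-violators), Z-scoring, AR(1) estimation |
| `fearscope.behavior` | Freezing segmentation (threshold + 0.5 s minimum duration), binned percent freezing, movement-ON events, CS/no-CS epochs |
| `fearscope.classify` | Peri-event Z alignment, responder thresholds (US: Z>1 in [0,1) s; tone/movement: Z>0.2 in [0,0.5) s), confound-trial exclusion, cross-plane duplicate removal |
| `fearscope.state` | Amplitude-weighted event frequency in the four CS x movement states |
| `fearscope.population` | Pooled cell maps, Venn overlaps, responder fractions per day |
| `fearscope.stats` | Chi-square, Kruskal-Wallis + Dunn, Mann-Whitney/Wilcoxon/t tests, mixed RM-ANOVA + Sidak, CI reconstruction, noncentral-F power analysis |
| `fearscope.ephys` | EPSC peak/delay, input-output curves, paired-pulse ratio, AMPA/NMDA and E/I ratios |
| `fearscope.pipeline` / `fearscope.cli` | Orchestration, YAML config, HDF5/CSV/JSON I/O, manifest with checksums |

## CLI

```bash
# full synthetic run (simulate -> deconvolve -> behavior -> classify ->
# state -> population -> stats), reproducible from the config seed:
fearscope run-all --config config.yaml --out runs/demo

# individual stages, with config overrides:
fearscope simulate --config config.yaml --set seed=7 --out runs/demo
fearscope classify --config config.yaml --out runs/demo

# synthetic EPSC metrics:
fearscope ephys --seed 1 --out metrics.json
```

A minimal `config.yaml`:

```yaml
seed: 1
days: [habituation, training, recall]
population:
  n_neurons: 40
  n_us_responders: 6
  n_cs_responders: 4
  n_movon_responders: 4
```

Exit codes: 0 ok, 2 config error, 3 dependency error (missing upstream
stage output), 4 data error. Reruns with the same config are byte-identical
(see `manifest.json` checksums in the run directory).

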
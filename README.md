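# oiload

Estimation of bone–implant interface loads (bending, torsion, axial pullout)
for transhumeral osseointegrated endoprostheses under four prosthesis models
and three amputation levels during high-demand activities of daily living.

The pipeline builds subject-scaled rigid-body arm models, performs virtual
amputation at fractional humeral lengths, substitutes prosthesis
mass-distribution models (pylon + pyramid-adapter connectors), runs
Newton–Euler inverse dynamics over a seeded synthetic motion cohort, and
compares the resulting peak loads statistically and against published
cadaveric failure thresholds.

## Modules

| module | role |
|---|---|
| `oiload.limb_model` | anthropometric segment masses, intact models, virtual amputation, prosthesis presets and attachment |
| `oiload.motion_synth` | seeded synthetic locked-elbow motion trials for six activities; trial CSV round trip |
| `oiload.inverse_dynamics` | interface force/moment via Newton–Euler over the distal chain; resolution into bending/torsion/axial; brute-force point-mass oracle |
| `oiload.load_stats` | peak extraction, mean-of-peaks trial aggregation, percent-of-intact, log-scale mixed models, signed-rank threshold tests |
| `oiload.failure_envelope` | published yield/ultimate thresholds, level mapping, exceedance flags |
| `oiload.sensitivity` | distal mass scaling and COM shifting with peak-ratio reports |
| `oiload.cli_pipeline` | end-to-end study orchestration and the `oiload` CLI |

## CLI

```sh
oiload analyze --seed 42 --out results/study      # full cohort pipeline
oiload simulate --seed 42 --out results/sim       # trial CSVs + manifest
oiload failure --peaks results/study/peaks_aggregated.csv --out results/study
oiload sensitivity --seed 42 --out results/study
oiload all --seed 42 --out results/study
```

All subcommands accept `--config <yaml>` (see `oiload.cli_pipeline.StudyConfig`
for keys), `--seed`, and `--out`. Outputs are CSV/JSON: per-trial and
aggregated peak tables, a peak-summary table (mean ± SD with argmax activity
per model × level × modality), percent-of-intact ranges split
weighted/unweighted, an exceedance report, and a seeded run log. Every output
is a pure function of the master seed.

## Notes

- Synthetic kinematics are qualitative stand-ins for the original
  motion-capture corpus: absolute load magnitudes are not expected to match
  the reference study, but structural properties (prosthesis ranked order,
  level dependence of bending/axial, level invariance of torsion, linear
  mass scaling) are reproduced and tested.
- An optional reader for externally deposited trial CSVs is provided by
  `oiload.motion_synth.read_trial_csv`; nothing in the build requires it.
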
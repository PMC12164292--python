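# digitclock

Quantitative analysis toolkit for digit development built around a
"digit clock" model: every digit owns an autonomous oscillator that lays
down its phalanges and joints inside a conserved developmental stage
window (chicken Hamburger–Hamilton stages 29–36), at a frequency set by
the digit's final phalanx count, until a phalanx–claw transition shuts the
growth zone down — except in clawless digits, where the shutdown is
delayed or absent.

The package implements the full analysis chain plus a ground-truthed
synthetic-data generator, so every stage is testable offline:

| module              | what it does |
|---------------------|--------------|
| `core_phenotype`    | packaged per-digit phenotype table (phalanx count ranges, claw/presence) for an ancestral amniote and 13 study species; stage conventions |
| `clock_sim`         | synthetic data: joint schedules, clock phases, stain intensity profiles, whole-mount-like RGB autopod images, marker on/off call tables, TPM matrices with planted effects |
| `stain_profile`     | distal→proximal stain-OD line profiles from RGB images along polylines (Beer–Lambert OD projected on a purple stain vector) |
| `phase_correlation` | length normalization, within-autopod pairwise Pearson correlation, specimen aggregation, isomorphic-digit ranking |
| `joint_scoring`     | expression-domain detection, most-recent-joint scoring, joint tables, cyclicity classification of on/off stage series |
| `transition_claw`   | phalanx–claw transition calling (clawed / clawless-persistent / reduced), limb synchrony, hyperphalangy flags |
| `candidate_screen`  | digit-vs-rest Welch-t screen on TPM matrices with Benjamini–Hochberg correction and L2FC / 25-TPM cutoffs |
| `cli`               | `digitclock` command-line pipeline |

## CLI

```bash
# ground-truthed synthetic dataset (images, polylines, calls, TPM)
digitclock simulate --out data/ --species bearded_dragon --n-specimens 18 --seed 1

# full pipeline: profiles -> correlation -> joint table -> transitions -> screen
digitclock run --dataset data/ --out reports/

# individual stages
digitclock profile data/images/spec001_forelimb.png data/polylines/spec001_forelimb_digit3.csv \
    --out prof.csv --specimen spec001 --stage 33 --limb forelimb --digit 3
digitclock correlate --profiles-dir reports/profiles --out corr.csv
digitclock score --profiles-dir reports/profiles --out joints.csv
digitclock transition --calls data/calls.csv --out transitions.csv
digitclock screen --tpm data/tpm.tsv --out screen.tsv
```

Options can be preloaded from a YAML config (`--config`); explicit flags
win. Every stochastic stage takes an explicit `--seed` and simulated
datasets carry a deterministic `MANIFEST.json`.

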
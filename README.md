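# eyelab

Colorimetric comparison of wolf and dog eyes plus analysis of how eye
colour shapes human perception of dogs — implemented as a reusable,
fully synthetic-data-driven pipeline.

The package has two arms:

1. **Image colorimetry** — convert 8-bit sRGB eye photographs to CIE
   L\*a\*b\* (D65, 2°), summarize colour over iris/pupil masks with
   specular-highlight exclusion, and compute the per-channel iris–pupil
   contrast `(pupil − iris) / (pupil + iris)`; compare species with
   Welch's t-tests, 95% CIs and Cohen's d.
2. **Perception analysis** — Horn's parallel analysis and
   maximum-likelihood factor analysis (varimax) of ten personality
   rating items, friendliness/maturity scale scoring, paired dark/light
   eye-colour tests, item-level MANOVA, and Gaussian linear mixed models
   of acceptance attitudes with a random intercept per dog image and
   Type III Wald χ² tests.

Because the source photographs and raw ratings are not redistributable,
`eyelab.synthetic_data` renders parametric eye images with exact
ground-truth masks and simulates questionnaire data from a two-factor
latent model under the counterbalanced four-version design — so every
stage runs end to end with no external data.

## Modules

| module               | role |
|----------------------|------|
| `colorimetry`        | sRGB→LAB, mask readers (label PNG / polygon JSON), region means, highlight exclusion, contrast statistic |
| `species_comparison` | Welch's t, Welch–Satterthwaite df, Cohen's d with CI, per-channel species report |
| `psychometrics`      | parallel analysis, ML factor analysis + varimax, item→scale assignment, scale scores |
| `perception_models`  | paired eye-colour tests, item MANOVA (Pillai), acceptance LMMs with Type III Wald χ² |
| `synthetic_data`     | eye-image renderer, counterbalanced design generator, latent-model rating simulator |
| `io_cli`             | run configuration, report bundle, breed-standard tally, command line |

## Command line

```bash
eyelab simulate-eyes --n-wolves 22 --n-dogs 81 --seed 0 --out scratch/eyes
eyelab contrast --images scratch/eyes --out scratch/contrast.csv
eyelab compare-species --contrast scratch/contrast.csv --out scratch/welch.csv

eyelab simulate-ratings --n-participants 76 --seed 0 --out scratch/ratings.csv
eyelab factor --ratings scratch/ratings.csv --out scratch/loadings.csv
eyelab perception --ratings scratch/ratings.csv --out-dir scratch/perception

eyelab tally-standards          # packaged breed-standard table
eyelab run-all --out scratch/full --seed 0   # both arms, full report bundle
```

Every output CSV carries the configuration hash and seed in a header
comment; reruns with the same configuration are byte-identical.

## Notes

- The packaged breed-standard table (`eyelab/data/breed_standards.csv`)
  is a documented stand-in: breed names are placeholders and only the
  per-registry totals and dark-recommendation counts are meaningful.
- Contrast values on the signed a/b channels are not bounded to [−1, 1]
  and are flagged (not returned as ±∞) when the channel denominator is
  below the configured floor.
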
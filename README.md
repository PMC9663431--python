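# numprod

Analysis pipeline for **instructed number-production experiments**:
trial-structured single-unit recordings from a task in which an animal
(e.g., a crow pecking a touchscreen) is shown an instruction stimulus
cueing a target number *n* ∈ {1..5}, holds the impending count through a
motor-planning delay, and then produces exactly *n* actions. The package
is aimed at systems neuroscientists who want the full behavioral and
population-level analysis chain for this task family — and a synthetic
session generator with ground truth, so every stage can be validated
without access to recordings.

## What it computes

**Behavior.** Bell-shaped performance curves P(produced = k | target = n)
per stimulus protocol; percent correct = correct/(correct + errors) with
SEM over sessions; analytic chance levels 1/(n+2) (a guesser can emit any
count in {0..n+1}, since the trial aborts at n+1 actions); one-sided
t-tests against chance; median first-response latencies.

**Single-unit selectivity.** Sliding two-factor ANOVA (number × protocol,
200 ms window, 10 ms step, p < 0.01) on planning-period firing rates; a
unit is number-selective when ≥ 11 consecutive bins (≥ 300 ms) show a
number main effect with no protocol effect or interaction. Tuning curves
are min-max normalized between the most- and least-preferred number;
population curves are averaged by preferred value and by numerical
distance. Error-trial contrasts (Wilcoxon signed-rank) test whether
preferred-number firing drops when the animal miscounts.

**Population decoding.** One-vs-one linear SVM on pseudo-populations
(per-unit trial draws aligned by class), 10-fold cross-validation,
features z-scored with training-fold statistics only, shuffled-label
nulls, confusion matrices; variants decode across stimulus protocols,
generalize from correct to error trials, and predict trial outcome
(correct / −1 error / +1 error).

**Information dynamics.** Time-resolved ω² percent explained variance,

    ω² = (SS_term − df·MS_error) / (SS_total + MS_error) × 100,

per ANOVA term with a shuffled-label baseline (50 shuffles × 20 resamples
= 1000 null evaluations); cross-temporal SVM generalization matrices
(train at one time bin, test at all others); and a two-stage cluster
permutation test that separates a *static* code (off-diagonal
generalization blocks) from a *dynamic* code (diagonal-confined
accuracy).

## Worked example

```python
from numprod import (PopulationSpec, BehaviorParams, generate_session,
                     percent_correct, analyze_session, decode_numbers,
                     DecodingSpec)

spec = PopulationSpec(n_units=40, tuned_fraction=0.4, peak_gain_range=(10, 25), seed=2)
session, truth = generate_session(spec, BehaviorParams(trials_per_cell=30), seed=2)

print(percent_correct(session, ("target_number",))[["target_number", "mean"]])
results = analyze_session(session)
print(sum(r.selective for r in results), "of", len(results), "units number-selective")
dec = decode_numbers(session, DecodingSpec(resamples=20, shuffle_resamples=20, seed=0))
print(f"decoding {dec.mean_accuracy:.3f} vs null {dec.null_mean:.3f}")
```

prints

```
   target_number       mean
0              1  98.333333
1              2  92.500000
2              3  67.500000
3              4  55.000000
4              5  42.500000
14 of 40 units number-selective
decoding 0.749 vs null 0.213
```

Percent correct declines with the target number (the numerical size
effect of the approximate number system); 14/40 units pass the
selective-interval criterion (the generator tuned 16); and the
pseudo-population decodes the impending count at 75% versus the ~20%
shuffled-label chance for five classes.

The same stages are available as CLI subcommands:

```bash
numprod simulate --units 60 --tuned-frac 0.24 --seed 1 --out sessions/
numprod behavior --sessions sessions/ --out results/behavior
numprod selectivity --sessions sessions/ --out results/selectivity
numprod decode --sessions sessions/ --mode auto --resamples 100 --out results/decode
numprod pev --sessions sessions/ --out results/pev
numprod crosstemporal --sessions sessions/ --out results/ct
```

## Layout

- `numprod.session` — session container, CSV/JSON on-disk format, sliding-window binning
- `numprod.synth` — behavior model + inhomogeneous-Poisson units + ground truth
- `numprod.behavior` — performance curves, chance levels, tests
- `numprod.selectivity` — inclusion, sliding ANOVA, intervals, tuning, error contrasts
- `numprod.decoding` — pseudo-population SVM decoding variants
- `numprod.dynamics` — ω² PEV, cross-temporal decoding, cluster permutation test
- `numprod.cli` — `numprod` command-line front end

See `docs/methods.md` for the modeling choices, parameter defaults, and
known limitations.
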
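# restdecode

Decoding eyes-closed (EC) vs eyes-open (EO) resting states from patterns
of fractional amplitude of low-frequency fluctuation (fALFF), with a
synthetic resting-state BOLD generator so the whole pipeline can be
exercised and calibrated without scanner data.

## The problem

Resting-state fMRI shows systematic differences in the amplitude of
spontaneous low-frequency BOLD oscillations between the eyes-closed and
eyes-open states, most prominently in sensorimotor cortex. `restdecode`
implements the multivariate analysis that turns this observation into a
decoder: per-region fALFF features, paired nonparametric feature
selection, and a linear support-vector classifier whose held-out
accuracy and ROC quantify how directly the amplitude pattern reflects
the behavioural state. It is aimed at researchers who want a tested,
reproducible reference implementation of this analysis — and a
controlled synthetic test bed for its statistical behaviour.

## Method

For a detrended series x(t) sampled at TR, with one-sided amplitude
spectrum a(f) = sqrt(power):

- **ALFF** = Σ a(f) over 0.01 ≤ f < 0.08 Hz,
- **fALFF** = ALFF / Σ a(f) over 0 < f ≤ 1/(2·TR) (DC excluded), a
  dimensionless fraction in [0, 1],

computed per region of a 160-ROI meta-analytic template grouped into
six functional modules, and normalized by each recording's global mean.
For each ROI the paired EC−EO differences across subjects enter a
Wilcoxon signed-rank test,

    Z = (W⁺ − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 − Σ(t³−t)/48),

signed so that Z > 0 means EC exceeds EO. Four selection criteria —
|Z| > 1.96, Z > 1.96, Z > 2.25, Z < −1.96 — define discriminative
patterns. Samples (one feature vector per subject per condition,
EC = +1, EO = −1) are split per condition into equal halves; a linear
SVM (C = 1) is trained on one half and evaluated on the other
(accuracy, ROC/AUC).

The synthetic generator emits 24-subject × 2-condition cohorts
(TR = 2 s, 240 volumes, first 10 discarded by the pipeline) in which
designated "effect" ROIs carry a larger low-frequency amplitude under
EC, on top of 1/f and white noise — ground truth for every stage.

## Worked example

```python
import restdecode as rd

template = rd.dosenbach160_template()
cfg = rd.SimulationConfig(seed=1)          # 24 subjects, planted EC>EO effect
cohort = rd.simulate_cohort(cfg, template)  # 48 recordings
tables = rd.falff_feature_table(cohort, template)
scores = rd.score_all_rois(tables["EC"], tables["EO"], template)
summary, _ = rd.run_criterion_comparison(tables["EC"], tables["EO"], scores)
print(summary[["criterion", "n_rois", "accuracy", "auc"]].to_string(index=False))
```

prints

```
 criterion  n_rois   accuracy      auc
|Z| > 1.96      30 100.000000 1.000000
  Z > 1.96      11 100.000000 1.000000
  Z > 2.25      11 100.000000 1.000000
 Z < -1.96      19  83.333333 0.979167
```

All 10 planted effect ROIs are recovered (they fill the Z > 1.96
pattern); the other |Z| > 1.96 members are ROIs whose *normalized*
fALFF is pushed downward under EC because the planted effect inflates
the EC global mean — they form the 19-ROI negative pattern. The
positive-direction patterns decode perfectly at this effect size while
the negative pattern is markedly weaker, reproducing the qualitative
ordering seen with the four criteria on real data.

The built-in 28-region worked-example table (the published
discriminative pattern with its Z values) is validated by:

```
restdecode validate-fixture
```

which checks the 28/21/13/7 pattern counts and the 86% sensorimotor
share of the Z > 1.96 pattern, and exits non-zero on any mismatch.

The same stages are available as CLI subcommands
(`restdecode simulate | falff | select | decode | run`), driven by
flags or a YAML config; `run` writes a self-contained artifact
directory (feature tables, Z report, patterns, decoding results, ROC
points, log) that is byte-identical across reruns of the same config.

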
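# vaval — verbal-autopsy cause-of-death coding and validation

`vaval` is a Python toolkit for validating probabilistic verbal-autopsy
(VA) cause-of-death coders against a gold standard such as the complete
diagnostic autopsy (CDA). It is aimed at epidemiologists and
mortality-surveillance researchers who need the full computational chain
behind such a validation: an InterVA-style Bayesian coder, the
individual-level and population-level agreement metrics, a
Dirichlet-resampling design that stress-tests those metrics across many
cause compositions, and a synthetic cohort generator so the whole
pipeline runs without access to restricted individual death records.

## The model and the metrics

**Coder.** Given a probbase — a prior P₀(c) over K causes and
conditional probabilities P(iᵢ | c) of each symptom indicator given each
cause — the posterior for a death is

    P(c | data) ∝ P₀(c) · ∏ over indicators answered "yes" of P(i | c),

computed in the log domain under conditional independence; negative and
unrecorded indicators are ignored. Malaria/HIV prevalence settings
rescale tagged priors. Up to three causes are reported (an absolute
threshold for the top cause, a relative one for the rest); unreported
posterior mass is "non-conclusive".

**Individual level.** The coder's top cause is cross-tabulated against
the gold cause: per-cause TP/TN/FP/FN with sensitivity, specificity, PPV
and NPV; Cohen's kappa κ = (p₀ − pₑ)/(1 − pₑ); and the chance-corrected
concordance CCC = (sensⱼ − 1/K)/(1 − 1/K), averaged unweighted over
observed causes.

**Population level.** Cause-specific mortality fractions (CSMFs) use
partial-likelihood weighting for the coder (each reported cause credited
with its likelihood, residual mass to non-conclusive) and certain single
causes for the gold standard. Compositional agreement is the CSMF
accuracy

    CSMFA = 1 − Σⱼ |estⱼ − trueⱼ| / (2 · (1 − minⱼ trueⱼ)),

and its chance-corrected form (CSMFA − b)/(1 − b), where b is the median
CSMFA of uniformly random allocation (empirical by default; the analytic
large-K constant 1 − 1/e is available).

**Resampling design.** 500 cause compositions per study group are drawn
from an uninformative symmetric Dirichlet; the cohort (records together
with their coder outputs) is resampled to each composition and CCC /
CSMFA / CCCSMFA are summarised by their medians, so results do not hinge
on the one composition the cohort happened to have.

See `docs/methods.md` for assumptions, edge rules and design decisions.

## Worked example

Per-cause metrics from published one-vs-rest counts (a neonatal
infectious-cause row: TP=25, TN=2, FP=12, FN=2):

```python
from vaval.individual_metrics import ConfusionCounts, binary_metrics

m = binary_metrics(ConfusionCounts("infections", tp=25, tn=2, fp=12, fn=2))
print(m.display())
```

```
{'sensitivity': 93, 'specificity': 14, 'ppv': 68, 'npv': 50}
```

i.e. the coder found 93% of infectious deaths but only 14% of
non-infectious deaths were ruled out, 68% of infectious calls were
right, and a negative call was right half the time.

A synthetic cohort scored end-to-end — here with a deliberately noisy
coder (half correct, half uniform misclassification) on the adult group:

```python
from vaval import (SimulationSpec, make_probbase, simulate_cohort,
                   default_cause_dictionary, ValidationConfig, validate_group)
from vaval.synthetic_data import simulate_va_outputs, uniform_kernel, identity_kernel

dictionary = default_cause_dictionary()
spec = SimulationSpec(seed=7)
probbase = make_probbase(dictionary, spec.n_indicators, spec.signal_strength, seed=7)
records = simulate_cohort(spec, probbase, dictionary)
adults = [r for r in records if r.group.value == "other_adult"]
causes = dictionary.for_group(adults[0].group)
kernel = 0.5 * identity_kernel(causes) + 0.5 * uniform_kernel(causes)
outputs = simulate_va_outputs(adults, kernel, spec, seed=7)
s = validate_group(adults, outputs, dictionary, ValidationConfig(n_draws=500, seed=7))
print(s.per_cause.to_string(index=False))
print(f"kappa={s.kappa:.3f}  median CCC={s.median_ccc:.3f}  "
      f"median CSMFA={s.median_csmfa:.3f}  median CCCSMFA={s.median_cccsmfa:.3f}")
```

```
              cause  n  TP  TN  FP  FN sensitivity  specificity  ppv  npv
         infections 82  48  26   4  34          59           87   92   43
malignant_neoplasms 20  12  78  14   8          60           85   46   91
     other_diseases 10   5  86  16   5          50           84   24   95
     non_conclusive  0   0  99  13   0         N/A           88    0  100
kappa=0.303  median CCC=0.341  median CSMFA=0.667  median CCCSMFA=-0.030
```

A coder that is right half the time lands at slight-to-fair agreement
individually (κ ≈ 0.30) and, at the population level, no better than
random allocation once chance-corrected (CCCSMFA ≈ 0) — the kind of
dissociation these metrics are designed to expose.

The same pipeline is available from the shell:

```bash
vaval report --seed 7 --draws 500 --out-dir out/
```

writes `table1_individual.csv`, `table2_concordance.csv`,
`table3_infections.csv`, `table4_population.csv`, `draws.csv` and
`flows.csv` (gold-to-predicted flow counts for alluvial diagrams).
`vaval simulate`, `vaval code` and `vaval validate` expose the stages
separately.

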
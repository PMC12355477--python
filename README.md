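# schizodes

Discrete event simulation (DES) for the cost-effectiveness of antipsychotic
treatment sequences in first-episode schizophrenia.

## What this is for

Choosing a first-line antipsychotic trades off relapse prevention against
side-effects (short-term tolerability, tardive dyskinesia, and metabolic
shifts that raise long-term cardio-metabolic risk) and drug cost.
`schizodes` is a patient-level microsimulation for health economists and
HTA analysts that turns a table of per-drug treatment attributes into
10-year quality-adjusted life years (QALYs), costs from a health-service
perspective, incremental cost-effectiveness ratios (ICERs) and
net-monetary-benefit (NMB) rankings, with probabilistic and deterministic
sensitivity analyses.

The model: patients enter stable on a first-line drug and may **relapse**
(exponential time; untreated annual probability converted to a hazard and
multiplied by the drug's relapse risk ratio RR, attenuated by adherence;
long-acting injectables force full adherence), **remit** (fixed 6-month
episode), **discontinue** and develop **tardive dyskinesia** (exponential,
treatment-specific annual probabilities). On relapse they switch line with
probability 0.5; after two consecutive failures the next switch is to
clozapine, the fixed last line. Metabolic shifts (BMI, lipids, glucose,
SBP) apply while on treatment and feed Framingham-type risk equations for
first CHD, stroke and diabetes, converted to event times via a constant
hazard over the score horizon, ρ = −ln(1−risk)/H. Background mortality is
drawn from a life table with each annual death probability adjusted for the
schizophrenia standardised mortality ratio, q′ = 1 − (1−q)^SMR; acute
events carry case-fatality probabilities. Utilities combine additively
with a floor at zero; QALYs and costs are discounted continuously at 3.5%
per year; treatments are compared as NMB = QALYs × WTP − cost over a
willingness-to-pay grid of £0–£100,000/QALY.

The shipped parameter file `src/schizodes/params/illustrative_uk.yaml` is
**illustrative**: values are on the scale of the public UK evidence base
but are not any specific study's inputs. To evaluate a real parameter
workbook, serialise it into the same YAML schema (documented by the
pydantic models in `schizodes.params`) and pass it to the CLI or API.

## Worked example

```python
from schizodes import (builtin_config_path, load_parameter_set,
                       run_base_case, rank_treatments)

pset = load_parameter_set(builtin_config_path("illustrative_uk"))
res = run_base_case(pset, n_patients=200, n_replications=3)  # desk scale
print(res.by_first_line[["qalys_discounted", "total_cost_discounted"]]
      .sort_values("qalys_discounted", ascending=False).round(3))
print(rank_treatments(res, [20_000.0]).sort_values("rank").head(3))
```

Desk-scale output on the illustrative parameters (seed 20200):

```
                  qalys_discounted  total_cost_discounted
first_line
aripiprazole_lai             6.701             156618.431
risperidone_lai              6.697             152733.299
paliperidone_lai             6.690             155071.681
amisulpride                  6.669             152407.642
olanzapine                   6.665             152859.282
...
    wtp        treatment           nmb  rank
20000.0  risperidone_lai -18798.777883     1
20000.0      amisulpride -19026.137442     2
20000.0       olanzapine -19551.660530     3
```

Each run simulates all 90 ordered (first-line, second-line) sequences of
the ten candidate drugs, with clozapine fixed third; a first-line result is
the equal-weight mean over its nine sequences. The `qalys_discounted`
column is mean per-patient discounted QALYs over ten years;
`total_cost_discounted` is the mean discounted cost in 2020 GBP; `nmb` is
the net monetary benefit at the stated willingness-to-pay, so at
£20,000/QALY risperidone-LAI is the most cost-effective first line *under
these illustrative inputs*, with long-acting injectables gaining QALYs
through enforced full adherence and cheap orals (amisulpride, olanzapine)
gaining on cost.

The same analyses are available from the shell:

```bash
schizodes simulate --config illustrative_uk --outdir out --n-patients 200 --n-reps 3
schizodes psa --config illustrative_uk --n-draws 100 --outdir out
schizodes dsa --config illustrative_uk --pair amisulpride olanzapine --outdir out
schizodes scenario --config illustrative_uk --horizon 5 --outdir out
```

Every command writes CSVs plus a JSON manifest (config hash, seed, package
version) that makes the run reproducible.

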
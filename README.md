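# corrlit

Tools for mining, auditing and modelling the Pearson correlation
coefficients published in a scientific literature.

Meta-research on effect sizes asks what correlations a field actually
reports: how large they are, how they depend on sample size, whether claimed
significance is consistent with the reported numbers, and what the observed
distribution implies for planning new studies. `corrlit` implements that
chain end to end:

* **Text mining** of reports like `r(34) = .52, p < .01` from plain article
  text, with the documented blind spots of real extraction pipelines
  (line breaks, subscripts, verbal reports) reproduced faithfully and a
  ground-truth recall harness.
* **Exact correlation statistics** under the bivariate-normal model: the
  p-value from r and df via t = r√df/√(1−r²); the critical |r| at any
  (df, α, sidedness); the null density f₀(r|df) ∝ (1−r²)^((df−2)/2) and the
  expected magnitude of non-significant correlations if the null were true;
  exact statistical power from Hotelling's non-null density of r; and the
  smallest N reaching a target power.
* **Distribution summaries**: quartiles of |r| overall and by stratum,
  cumulative quartile curves by maximum df, rolling block medians,
  normal-interval bootstrap CIs for medians, yearly Spearman |r|-vs-df
  associations.
* **A significance-consistency audit** flagging records whose claimed
  significance conflicts with their own r and N.
* **A synthetic-literature generator** with known ground truth (mixture of
  null and non-null effects, heavy-tailed sample sizes, significance-driven
  text emphasis, misreporting), used throughout the tests.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from corrlit import (GeneratorConfig, generate_records, render_corpus,
                     validate_extraction, stratified_summary,
                     percentile_summary, audit_summary,
                     required_n, PowerQuery)

records, truth = generate_records(GeneratorConfig(n_studies=200, seed=1))
print(len(records))                                   # 9571

s = percentile_summary(records.abs_r_values())
print(round(s.q25, 2), round(s.q50, 2), round(s.q75, 2))   # 0.06 0.15 0.27

by_loc = stratified_summary(records, ("location",))
# text emphasis: in-text correlations are larger and more often significant
# location=TABLE: n=8818, median |r| = 0.14, 53% significant
# location=TEXT:  n=753,  median |r| = 0.22, 79% significant

report = audit_summary(records)
print(report.label_counts["TOO_SMALL_FOR_SIG"],       # 17
      report.label_counts["TOO_LARGE_FOR_NONSIG"])    # 27  (misreport suspects)
print(report.unspecified_significant_two_sided,       # 161 of 274 unspecified
      report.n_unspecified)                           # records are significant

corpus = render_corpus(records, seed=2)
val = validate_extraction(corpus)
print(round(val.recall, 3), val.n_false_positive)     # 0.934 0
# misses: {'linebreak': 15, 'verbal': 21, 'subscript': 14}

print(required_n(PowerQuery(r=0.3)))                  # 84
print(required_n(PowerQuery(r=0.17)))                 # 269
```

Reading the output: the generator plants a small misreporting rate, and the
audit recovers exactly the flipped labels that cross the significance
boundary; the extraction recall of 0.934 reflects the adversarial share of
the default format mix (line-broken, subscripted and verbal reports are
undetectable by design); and moving the planning effect size from a
conventional "medium" r = 0.3 to the observed median r = 0.17 more than
triples the required sample (84 → 269 under the exact model; see
`docs/methods.md` for the one-participant divergence from the Fisher-z
figure of 268).

A command-line interface wraps the same functions:

```
corrlit simulate --seed 3 --out sim/          # records.csv + corpus/ + truth.json
corrlit extract --in sim/corpus --out mined.csv
corrlit analyze --records sim/records.csv --out report.json --strata location
corrlit audit --records sim/records.csv --out audit.json
corrlit power --r 0.17                        # required N = 269
corrlit pcalc --r 0.17 --n 230                # p = 0.00979569
```

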
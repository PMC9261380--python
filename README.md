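# clockshift

Adapt a blood-trained DNA-methylation aging clock to saliva and buccal
samples — without retraining the clock.

Saliva is a mixture of epithelial cells, immune cells and a few
fibroblasts, and the mix varies wildly between (and within) studies. A
clock trained only on blood reads epithelial methylation as accelerated
aging, so its predictions in saliva can run decades high. `clockshift`
implements the two-stage fix:

1. **Deconvolve** each bulk beta profile against a pure-cell-type
   reference to estimate fractions (Epi, Fib, IC) — via robust partial
   correlation (Huber regression, the default) or constrained projection
   (a non-negative, sum-≤-1 least-squares program solved exactly).
2. **Adjust** the clock's raw predictions with a small elastic-net
   regression on the prediction and the cell fractions. Four schemes are
   compared — `none`, `simple` (prediction only), `delta` (regress the
   residual on composition, subtract it), and `total`
   (CA ~ prediction + Epi + IC) — the latter two optionally in
   transformed-age space, where `f(x) = ln((x+1)/21)` below age 20 and
   `(x+1)/21 − 1` above. Hyperparameters come from a grid search
   (`l1_ratio ∈ {0.00…0.99}`, `alpha ∈ {1e-5…1e-1, 0, 1, 10, 100}`)
   scored by leave-one-study-out (LOSO) mean absolute error, so the
   selected model is the one that transfers across cohorts.

The published total-age adjustment is built in: in years,
`adjusted = 0.85·pred − 11.54·Epi + 10.56·IC − 15.76`, which implies a
fully epithelial sample is over-aged by 11.54 + 15.76 = **27.3 years**
regardless of the raw prediction. A synthetic cohort generator and a
stand-in blood-domain clock make every stage testable offline; the real
clock is pluggable (anything mapping beta profiles to years).

## Worked example

```python
from clockshift import (SyntheticCohortConfig, simulate_pipeline_inputs,
                        intersect_probes, estimate_fractions_rpc,
                        evaluate_schemes)

sim = simulate_pipeline_inputs(SyntheticCohortConfig(seed=0))
beta, ref = intersect_probes(sim["beta"], sim["reference"])
fractions = estimate_fractions_rpc(beta, ref)
report = evaluate_schemes(sim["predictions"], sim["annotations"], fractions)

for r in report.results:
    label = r.scheme + (" (transformed)" if r.transformed else "")
    print(f"{label:22s} CV MAE {r.cv_mae:6.2f} years")
g = report.gain_analysis
print(f"IC vs gain: Pearson r = {g.pearson_r:.2f}, "
      f"worsened = {100 * g.fraction_worsened:.1f}% of samples")
```

prints

```
baseline               CV MAE  22.01 years
none                   CV MAE  18.60 years
simple                 CV MAE   7.05 years
simple (transformed)   CV MAE   7.06 years
delta                  CV MAE   5.17 years
total                  CV MAE   3.07 years
total (transformed)    CV MAE   2.46 years
IC vs gain: Pearson r = -0.71, worsened = 1.7% of samples
```

Reading the table: the raw clock (`none`, 18.6 y) is useless on this
three-study cohort whose mean immune-cell fractions span 0.10–0.80.
Rescaling predictions alone (`simple`) helps; using composition
(`delta`, `total`) helps much more; and the transformed total-age
adjuster — the same functional form as the published model — cuts the
error to 2.46 y, about 13% of the unadjusted error. The gain analysis
shows the improvement concentrates in immune-poor (epithelial-rich)
samples, with under 2% of samples made worse.

The same pipeline runs from the shell:

```sh
clockshift simulate --seed 0 --out-dir sim/
clockshift deconvolve --beta sim/beta.tsv --reference sim/reference.tsv \
    --method rpc --out sim/fractions.tsv
clockshift fit --scheme total --transform-age \
    --predictions sim/predictions.tsv --annotations sim/annotations.tsv \
    --fractions sim/fractions.tsv --out model.json
clockshift apply --model published:untransformed \
    --predictions sim/predictions.tsv --fractions sim/fractions.tsv \
    --out adjusted.tsv
clockshift evaluate --predictions sim/predictions.tsv \
    --annotations sim/annotations.tsv --fractions sim/fractions.tsv \
    --out-dir report/
```

All tabular I/O is plain TSV/CSV (beta matrices probes × samples,
annotations with `sample_id, age, study_id, tissue`, fractions rows on
the simplex); fitted models serialize to flat JSON.

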
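# screenrisk

Bayesian post-test disease-risk calculator and population simulator for
genetic screening of rare diseases.

## The problem

Population-wide genetic screening reports a *marker* — a pathogenic variant
or variant set — not a disease. For a rare disease, the probability of ever
manifesting it after a positive screening test can be strikingly low even
when the marker is fully penetrant, because false positives from the assay
swamp the handful of true carriers. This package computes that post-test
risk exactly from five inputs, for screening and targeted-testing scenarios
in Huntington's disease (*HTT*), amyotrophic lateral sclerosis (*SOD1*,
*FUS*, *C9orf72*) and phenylketonuria (*PAH*), and for any scenario you
configure. It is written for statistical geneticists, screening-programme
modellers, and anyone who needs to put a defensible number on "what does a
positive result actually mean?".

## The model

For disease D, marker M, and a test T asserting the presence of M, the five
inputs are the pre-test disease probability P(D), the marker frequency
among affected people P(M|D), the penetrance P(D|M), and the assay's
analytic sensitivity P(T|M) and specificity P(T′|M′). All events are
binary, and D is conditionally independent of T given M. The chain is

```
P(M)    = P(D) · P(M|D) / P(D|M)                      marker prevalence
P(D|M′) = P(D) · (1 − P(M|D)) / (1 − P(M))            risk without marker
P(T)    = P(T|M)·P(M) + (1 − P(T′|M′))·(1 − P(M))     positive-test rate
P(M|T)  = P(M) · P(T|M) / P(T)                         (Bayes)
P(M|T′) = P(M) · (1 − P(T|M)) / (1 − P(T))
P(D|T)  = P(D|M)·P(M|T)  + P(D|M′)·(1 − P(M|T))       post-test risk
P(D|T′) = P(D|M)·P(M|T′) + P(D|M′)·(1 − P(M|T′))
```

On top of the single-scenario chain the package provides sequential
confirmatory testing (the screen's posterior becomes the next stage's
prior), penetrance estimation from population marker frequency, Monte Carlo
propagation of 95% confidence intervals on the inputs, parameter sweeps,
and a stratified-binomial population simulator that serves as a brute-force
oracle for every closed-form result.

## Worked example

Screening a general population for the fully penetrant *HTT* repeat
expansion (lifetime risk 0.000410) with a short-read sequencing assay
(sensitivity 0.99, specificity 0.90):

```python
from screenrisk import ScreeningScenario, evaluate_scenario, variant_test

scenario = ScreeningScenario(
    prior_disease=0.000410,
    marker_freq_affected=1.0,   # every affected person carries the expansion
    penetrance=1.0,             # every carrier manifests in a normal lifespan
    test=variant_test("STRE"),  # sensitivity 0.99, specificity 0.90
)
result = evaluate_scenario(scenario)
print(f"P(T)    = {result.prob_positive:.6f}")
print(f"P(D|T)  = {result.disease_given_positive:.6f}")
print(f"P(D|T') = {result.disease_given_negative:.2e}")
print(f"RR      = {result.relative_risk:.1f}")
```

prints

```
P(T)    = 0.100365
P(D|T)  = 0.004044
P(D|T') = 4.56e-06
RR      = 887.4
```

About 10% of the population screens positive — almost all false positives —
so a positive result carries only a 0.4% lifetime risk of Huntington's
disease despite complete penetrance, while a negative result is essentially
exonerating (887-fold risk ratio). The same assay used as a *targeted* test
in someone with an affected parent (prior 0.5) gives P(D|T) = 0.908.

The same machinery from the shell:

```
screenrisk table1                 # all ten packaged case-study scenarios
screenrisk evaluate -p 0.000410 -m 1 -k 1 -s 0.99 -c 0.90
screenrisk chain -p 0.00333 -m 0.0635 -k 0.439 -s 0.99 -c 0.90 \
    --confirm-sensitivity 0.95 --confirm-specificity 0.98
screenrisk simulate -p 0.00333 -m 0.0635 -k 0.439 -s 0.99 -c 0.90 \
    -n 1000000 --seed 1
```

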
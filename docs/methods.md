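# Methods

## Model and assumptions

The package evaluates post-test disease risk for a binary disease D, binary
marker M and binary test result T. Three structural assumptions carry all
of the algebra:

1. **Binary events.** Having-or-later-manifesting disease is a single
   event; severity, age at onset, and phenotype variability are not
   modelled.
2. **Conditional independence of D and T given M.** The assay sees only
   genotype; once marker status is known, the test result adds nothing
   about disease. Post-test risk is therefore the convex combination
   P(D|T) = P(D|M)·P(M|T) + P(D|M′)·(1 − P(M|T)).
3. **Population-level parameters.** P(D), P(M|D) and P(D|M) describe one
   population; ancestry differences in marker frequency or penetrance must
   be handled by separate scenarios.

Marker prevalence is derived, not supplied: P(M) = P(D)·P(M|D)/P(D|M).
This makes the five inputs over-determined in corners of parameter space,
and two validity constraints are enforced at scenario construction:

* P(D)·P(M|D) ≤ P(D|M), else the implied P(M) exceeds 1;
* the implied P(D|M′) = P(D)(1 − P(M|D))/(1 − P(M)) must not exceed 1
  (violated e.g. by P(D) = 1 with incomplete penetrance).

Both are checked with 1e-12 slack to absorb floating-point representation
error. A penetrance *below* the prior (a protective or null marker) leaves
every formula well defined and is accepted with a warning rather than
rejected, since parameter sweeps may legitimately cross that region.

## Parameters

| parameter | meaning | typical range in the case studies |
|---|---|---|
| `prior_disease` | pre-test P(D): lifetime risk for screening; elevated (0.5 for an at-risk offspring, 1/6 after a positive metabolic screen) for targeted/confirmatory testing | 1e-4 … 0.5 |
| `marker_freq_affected` | P(M|D) among affected people | 5e-4 … 1 |
| `penetrance` | P(D|M) over a normal lifespan | 0.44 … 1 |
| `sensitivity`, `specificity` | analytic validity of the genotyping assay for the marker itself, not clinical validity for the disease | see profiles |

The packaged variant-type profiles summarise short-read sequencing
genotyping benchmarks: SNV (0.9996, 0.9995), indel (0.9962, 0.9971), short
tandem repeat expansion STRE (0.99, 0.90), CNV deletion (0.289, 0.959), CNV
duplication (0.1020, 0.9233). The STRE profile's 0.90 specificity is what
drives the low post-test risks in the *HTT* and *C9orf72* screening
scenarios.

## Sequential (confirmatory) testing

`chain_confirmatory` re-runs the chain per stage: stage k's prior is stage
k−1's **unrounded** P(D|T), with P(M|D) and penetrance carried over and the
confirmatory assay's sensitivity/specificity substituted. Chaining the
printed (3-significant-figure) posterior instead shifts the cross-stage
relative risk in its third figure, so full precision is used throughout.
The cross-stage relative risk Ω divides the final stage's positive-branch
risk by the *first* stage's negative-branch risk. For a non-genetic first
test (the tandem-MS metabolic screen in the phenylketonuria case),
`chain_external_prior` takes the first test's positive-branch posterior and
negative-branch risk as given numbers; the metabolic assay itself is not
modelled.

**Stage-wise chaining is not joint two-test inference.** Re-deriving
P(M) from the updated prior at each stage treats the screen positives as a
fresh population in which the original P(M|D)/P(D|M) relationship holds
anew. Under the alternative — each individual keeps their marker status and
the second test is conditionally independent of the first given M — the
double-positive posterior follows from multiplying likelihood ratios and is
substantially **higher** (for the *C9orf72* sequencing→PCR case: 0.084
joint vs 0.020 stage-wise; the two agree only for an uninformative second
test). The stage-wise form is the package's primary semantics because it is
what the case-study confirmation rows compute; it is the conservative
choice when confirmatory assays share error modes with the screen, whereas
the joint form assumes strictly independent error mechanisms. The simulator
exposes both (`simulate_two_tests(..., resample_marker=True/False)`), and
the test suite checks each against its own closed form.

## Uncertainty propagation

95% CIs on inputs are propagated by Monte Carlo. Each uncertain parameter
is drawn from a logit-normal with mean logit(point) and spread chosen so
the 2.5/97.5 quantiles match the stated bounds — the logit scale respects
[0, 1] support; nothing stronger is claimed for the shape. Parameters are
sampled independently: the covariance between P(M|D) and penetrance
estimated from the same cohorts is ignored, which tends to overstate the
output interval width. Draws violating the validity constraints are
discarded and counted (clipping would bias the interval toward the
constraint boundary); more than 50% discarded aborts with an error. With
all intervals degenerate the summary equals the point evaluation exactly,
and results are bit-reproducible for a fixed seed and draw count.

Penetrance can also be estimated by inverting the prevalence identity,
P(D|M) = P(D)·P(M|D)/P(M), with population marker frequency P(M) as input;
a result above 1 is rejected as inconsistent inputs.

## Simulator

`simulate_population` realises the generative factorisation directly:
M ~ Bernoulli(P(M)); D|M ~ Bernoulli(P(D|M)), D|M′ ~ Bernoulli(P(D|M′));
T|M ~ Bernoulli(sens), T|M′ ~ Bernoulli(1 − spec). Draws are stratified
binomials (marker count, then disease and test counts within strata) — the
count table's distribution is identical to per-individual simulation but
costs O(1) draws, so n = 1e8 is cheap. Empirical estimates are exact cell
ratios; a zero-count conditioning event yields NaN, never 0/0 → 0. A
single seeded `numpy` generator per call; no global state.

What the simulator does and does not emulate: it realises exactly the
binary-event model above, so agreement (tests require every estimate within
4 binomial standard errors of the closed form, at n = 2e5–4e6 across ~35
scenario/estimate combinations) validates the algebra and the code, not the
model's adequacy for real screening data — no genotyping error correlation,
no family structure or inheritance (the 0.5 targeted prior is an input, not
simulated meiosis), no age structure, no ancestry stratification.

## Numerical conventions

* All arithmetic in double precision; rounding to 3 significant figures is
  a display/reporting convention only (`round_sig`).
* Relative risk with a zero denominator: `inf` (and `nan` for 0/0) rather
  than an exception — the limit is meaningful.
* Validity slack 1e-12 on both construction constraints; conservation
  identities (the three laws of total probability) hold to 1e-12 and are
  property-tested on 1,000 random valid scenarios.
* Published-value regression: 24 of the 32 case-study output cells match
  exactly at 3 significant figures; 8 cells whose printed values reflect
  rounding of inputs or intermediates upstream of the printed table (the
  negative-branch risks of the *C9orf72* and PKU-confirmation rows, the
  *SOD1* A5V and *FUS*-all positive branches, the *FUS*-ClinVar negative
  branch and relative risk, and the PKU-screening relative risk, printed
  with a typographic thousands separator as "4.961") are compared at
  relative tolerance 5e-3; every deviation is ≤ 0.3%.
* Problem sizes in the default suite — 1e6 draws per scenario for the
  simulator cross-checks, 4e6 for the two-test chain, 2e4 for CI
  propagation — were chosen so each empirical standard error is at least an
  order of magnitude below the effect being checked.

## Known limitations

Oligogenic and polygenic architectures, pleiotropy, genetic/environmental
modifiers, repeat-length–onset correlation, intermediate-length repeat
alleles, and disease severity are all outside the model. The confidence
intervals consumed by the uncertainty module are taken as given (their
construction method is not re-derived), and the PKU metabolic screen's
operating characteristics enter only as two fixed numbers. Analytic
sensitivity/specificity are genome-wide heuristics; real accuracy varies by
locus and pipeline.
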
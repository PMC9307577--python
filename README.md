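# narranet

Narrative event networks for naturalistic memory research: build semantic
and causal event networks from movie annotations, score event centrality,
and test how centrality shapes recall behavior and intersubject neural
signatures.

## The scientific problem

When people watch and later recount movies, some events are remembered by
almost everyone and others by almost no one. One strong predictor is an
event's position in the *narrative network* of its movie: a weighted
graph whose nodes are events and whose edges are either

- **semantic similarity** — the cosine between sentence-embedding vectors
  of the events' text descriptions (one vector per event, averaged across
  annotators), or
- **causal relatedness** — the proportion of human coders who judged an
  event pair causally linked.

An event's **centrality** is its weighted degree
`d_i = Σ_j w_ij`, normalized by the movie's degree sum and z-scored
within movie. High-centrality events (top 40% within movie) are recalled
more often than low-centrality events (bottom 40%), and centrality also
modulates neural measures during encoding and recall:

- **pISC** (intersubject pattern correlation): the correlation between one
  participant's event-specific activation pattern and each other
  participant's pattern of the same event, averaged over partners.
  Inference is by event-label randomization (shuffle which events are
  "matching"), with the add-one convention `p = (b + 1)/(m + 1)`, so 1000
  permutations bottom out at `p = 1/1001 ≈ .000999`.
- **RSA**: the correlation between the lower triangles of the neural
  cross-event similarity matrix and the embedding similarity matrix.
- **Boundary responses**: hippocampus-like BOLD time courses locked to
  event offsets (−2..15 TRs, baseline = the 2 pre-boundary TRs), whose
  post-offset amplitude (10–13 TRs) can mediate the centrality → recall
  effect (quasi-Bayesian ACME).
- **ISFC**: event-wise intersubject functional connectivity between two
  regions (each participant's series vs. the average of everyone else's),
  correlated with centrality across events.

Behavioral effects are tested with a mixed-effects logistic regression of
event recall on semantic and causal z-centrality with crossed participant
and movie random intercepts (likelihood-ratio χ²(1) tests per predictor),
implemented here as a Laplace-approximation ML fitter validated against
lme4.

Everything runs on a seeded synthetic-data generator that emulates the
study design (10 movies × 20 events, 3 annotators, 13 causal coders, 15
participants, 512-d embeddings, TR = 1.5 s) with planted effect sizes, so
the whole pipeline is testable without any downloads.

## Worked example

Run the full synth-then-analyze pipeline at study scale:

```bash
narranet run --seed 0 --out demo/
```

or from Python:

```python
from narranet.pipeline import run_pipeline
manifest = run_pipeline({"seed": 0, "n_permutations": 1000}, "demo/")
```

Selected numbers this run prints (from `demo/behavior_stats.json`,
`neural_stats.json`, `timecourse_stats.json`):

```
centrality-recall r: 0.343 (n = 200 events)      # planted positive effect
high vs low recall:  t(14) = 7.02, mean diff 0.102
GLMM: semantic β = 0.169 (χ²(1) = 11.65), causal β = 0.440 (χ²(1) = 82.42)
serial position:     F(2, 18) = 0.01, p = 0.99   # no primacy/recency planted
pISC (movie):  pmc 0.120, evc 0.295, both p = .000999
pISC (recall): pmc 0.060, evc 0.011, both p = .000999
high-low pISC: pmc +0.022 (p = .001), evc -0.009 (p = .18)
ISFC-centrality r = 0.447 (28 events ≥ 22.5 s), p = .017
mediation ACME = -0.0001, 95% CI [-0.0021, 0.0019]   # no mediation planted
```

Reading these: the generator planted positive semantic (β = .17) and
causal (β = .38) recall effects, a positive centrality modulation of
shared signal in the "pmc" region and a negative one in "evc", and
ISFC coupling rising with centrality — all recovered with the right sign
and magnitude. The serial-position F, the RSA correlation (null: the
default generator plants no cross-event similarity structure), and the
mediation ACME (null: recall is generated from centrality only) sit at
their null values, as they should.

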
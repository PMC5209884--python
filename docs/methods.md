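# Methods

## The model

`bdxo` represents a diagnostic-accuracy study as a typed instance graph.
Nodes are individuals (persons, populations, samples), processes (test
performances, executions, computations), information artifacts (2×2
tables, indicator estimates) and dispositions; edges are drawn from a
closed vocabulary of seventeen relations (`instance_of`, `is_a`,
`part_of`, `participates_in`, `has_specified_input`,
`has_specified_output`, `has_specified_value`, `has_probability_value`,
`is_about`, and the six `{se,sp,ppv,npv}_of_test` / `_for_disease`
relations plus their prevalence-free analogues). The closed vocabulary is
deliberate: validation and serialization can then be strict, and any
predicate outside it is an error rather than silently carried data.

Three tiers of "sensitivity" (and likewise for specificity, predictive
values and prevalence) are kept apart:

* **f₂-style real values** attach to a disposition borne by a population:
  the probability that a random draw among the diseased returns someone
  who *would* test index-positive. Since the counterfactual "test
  everyone" never happens, the value is carried by an actual entity (the
  disposition, with explicit trigger and realization descriptors) rather
  than by a non-actual proportion.
* **f₃-style reference-linked values** condition on the reference test
  instead of the disease. This is the population quantity a study can
  actually estimate, and it differs from f₂ exactly insofar as the
  reference test is imperfect.
* **f₄-style measurements** are sample proportions from a 2×2 table. They
  carry sampling noise on top of the f₃→f₂ gap.

The estimate data item records value, denominator, confidence interval,
provenance (`inputs`), and aboutness (`is_about` the disposition). The
graph therefore answers, mechanically, both "what was this number computed
from?" and "what is it a claim about?".

## Simulator

A population is a mixture of homogeneous subgroups. Each subgroup has a
size, a diseased fraction, and four latent response probabilities
(index/reference × diseased/healthy). Members inherit the subgroup's
probabilities; a member's two test responses are independent Bernoulli
draws given those probabilities.

Design choices that matter:

* **Deterministic disease counts.** A subgroup of size n with diseased
  fraction q gets exactly round(n·q) diseased members (the first n·q, not
  a binomial draw). Every `true_*` quantity is then an exact arithmetic
  consequence of the spec, so the randomization identity — disposition
  probability equals exhaustively computed proportion — holds exactly, not
  in expectation.
* **Exact f₃ as a ratio of expectations.** Over members i,
  f₃ = Σᵢ p_ref,i·p_index,i / Σᵢ p_ref,i (complements for the specificity
  analogue). With a perfect reference (p_ref = 1 for diseased, 0 for
  healthy) the denominator mass coincides with disease status and f₃ = f₂
  to machine precision.
* **Conditional independence of the two tests given the person.** This is
  the simplest model consistent with person-level latent responses.
  Real paired tests often share error mechanisms; within-person
  correlation, continuous traits with thresholds, and verification bias
  are all outside the model. Passing tests therefore demonstrate the
  bookkeeping and the approximation chain under clean conditions, not
  robustness to those real-data features.
* **Sampling** is simple random sampling without replacement, seeds always
  explicit. "Representativeness" of a sample is an assumption the user
  controls, not something tested statistically.

Shipped configurations: a two-subgroup all-diseased population with
deterministic responses (80 %/20 %, exact sensitivity 0.8); a
1000-person, 10 %-prevalence group whose diseased members respond at 0.15
(so prevalence and sensitivity dispositions get exactly 0.10 and 0.15); a
2 040-person two-stratum study population for 204-patient samples; and a
4 000-person heterogeneous population (prevalence 0.3, stratum
sensitivities 0.7/0.9, reference 0.95/0.05) for convergence experiments.

## Estimation and intervals

Point estimates are the standard sample proportions of the 2×2 table.
Zero denominators raise rather than return a null: the proportions are
undefined there, and silently propagating a placeholder would let an
undefined value flow into pooling.

Confidence intervals are Wilson score intervals by default
(statsmodels' `proportion_confint`), with exact Clopper–Pearson behind a
flag; no continuity correction. Wilson was chosen for its small-n coverage
and because it never leaves [0, 1]. At observed proportions of exactly 0
or 1 the corresponding bound is snapped to 0/1 (the closed form attains it
exactly; floating-point evaluation can miss by ~1 ulp, which would
otherwise violate "the interval contains the point estimate"). Intervals
quantify sampling uncertainty about the reference-linked population value
only; they are not widened for the gap to the disease-linked value, which
is structural, not statistical.

## Bayes engine

The two Bayes equations are evaluated as written; inputs are validated to
[0, 1] and a vanishing denominator (nobody would test positive, or
negative) raises. The consistency check plugs a table's own prevalence,
sensitivity and specificity back into the equations and compares with the
table's direct PPV/NPV; as a pure arithmetic identity, the tolerance is
1e−12 absolute.

## Aggregation

Estimates may be pooled only if (i) all index test classes and (ii) all
reference test classes have a lowest common ancestor in the *declared*
hierarchy, and (iii) the samples' populations have a lowest common
ancestor along declared parent links. Hierarchies are trees (a forest
yields incompatibility); nothing is inferred from test names or similarity
— absent declarations mean no pooling.

Two pooling rules are provided, both auditable: **pooled counts** (sum the
underlying tables' numerators and denominators; exact, the default — equal
to measuring the concatenated sample) and **fixed-effect inverse-variance
pooling on the logit scale**, with a 0.5 continuity correction added to
all cells of a study whenever any input proportion is 0 or 1 (noted in the
output's `method` field). Random-effects and bivariate
sensitivity/specificity meta-analysis are out of scope. The pooled
estimate's provenance lists the input estimate ids, and the graph gains
one computation node with the corresponding input/output edges.

## Serialization

Turtle output is produced by a purpose-built writer so that it is
deterministic and byte-stable: subjects, predicates and objects are
sorted, probabilities and estimate values are decimal literals with 12
significant digits, and entity fields are datatype properties in a single
project namespace. Maps and ordered id-lists (a person's response
probabilities, a population's member list, an execution's process list)
are serialized as JSON string literals rather than blank-node structures,
which keeps output canonical and round-trips exact. Parsing uses rdflib
and is strict: malformed documents, foreign predicates and references to
absent nodes are errors. Serialization refuses invalid graphs outright,
with the validation report in the message.

## Convergence experiments

`run_convergence_experiment` quantifies the sampling leg of the
approximation chain: for each sample size n it draws replicate samples,
runs both tests, and averages |f₄ − f₃|. The reported envelope is the
binomial standard error sqrt(f₃(1 − f₃)/E[#reference-positives]), with
E[#RT+] = n·(mean reference-response probability); for near-binomial
deviations the mean absolute deviation is ≈0.8 standard deviations, so
falling inside one standard error is the expected behaviour, and the mean
deviation should shrink like 1/√n along the grid. Replicates whose f₄
denominator is empty are excluded and counted. The default experiment uses
the 4 000-person heterogeneous population with grid {50, 200, 1000} × 200
replicates, seeds spawned from a single experiment seed — a size at which
the monotone trend is decisive while the full run stays in the seconds
range.

## Known limitations

* One index and one reference test class per simulated population spec;
  multi-test designs require composing populations manually.
* The ill-posedness of a population-free "sensitivity of a test for a
  disease" is represented only negatively: no function of (IT, M) alone is
  offered, by design.
* Confidence intervals for pooled logit estimates are Wald intervals on
  the logit scale; exact small-sample behaviour is not pursued.
* Disposition trigger/realization descriptors are human-readable text,
  not further formalized process classes; relating disposition classes to
  test and disease classes is done through the flat `*_of_test` /
  `*_for_disease` relations kept as primitives.
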
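# bdxo

Bayesian diagnostic indicators of performance — sensitivity, specificity,
positive/negative predictive value and prevalence — modelled as a typed,
serializable instance graph, with estimators, the Bayes equations, a
compatibility-checked pooling step, and a synthetic-population simulator
that realizes the spectrum effect.

## The problem

A study that reports "sensitivity 84 %" is compressing three different
things into one number:

1. **a measurement** — in a sample **s**, among members positive on a
   reference test *RT*, the fraction also positive on the index test *IT*
   (call it f₄(s, IT, RT); with specificity's analogue f′₄);
2. **the population quantity it estimates** — the same fraction over the
   whole target group **g**, had both tests been performed on everyone
   (f₃(g, IT, RT)); and
3. **the "real" sensitivity** — the fraction of *diseased* members of
   **g** who would test positive (f₂(g, IT, M)), which no measurement
   reaches directly because disease status is only operationalized through
   an imperfect reference test.

The real value is population-relative: because subgroups differ in what
drives a positive result (severity, age, biology), the same test has
different sensitivity in differently composed groups — the *spectrum
effect*. `bdxo` keeps the three levels apart and explicit. The "real"
value is attached to a **disposition** borne by the population (the
probability that a random draw among the diseased returns a would-be
positive), measurements produce **estimate** data items that are *about*
that disposition, and everything — tests, executions, 2×2 results,
computations, estimates, dispositions — lives in one instance graph with a
closed relation vocabulary (`instance_of`, `part_of`, `participates_in`,
`has_specified_input/output/value`, `has_probability_value`, `is_about`,
`se_of_test`, ...), serializable to Turtle.

Predictive values obey the Bayes equations

    PPV = Prev·Se / (Prev·Se + (1 − Prev)(1 − Sp))
    NPV = (1 − Prev)·Sp / (Prev(1 − Se) + (1 − Prev)·Sp)

and estimates from separate studies may be pooled only when their index
tests, reference tests and populations subsume under common declared
classes (IT₀, RT₀, g₀) — which the aggregation module checks before it
pools.

## Worked example

A synthetic 2 040-person two-stratum population (early/advanced disease,
index sensitivities 0.75/0.92, near-perfect laboratory reference test); a
204-patient accuracy study is run on a random sample:

```python
from bdxo import (IdFactory, InstanceGraph, TestClass, DiseaseClass,
                  build_population, make_disposition, sample_population,
                  execute_tests, estimate_sensitivity,
                  true_rt_linked_proportion, validate_instance_graph)
from bdxo.fixtures import dipstick_study_spec

ids, graph = IdFactory(), InstanceGraph()
it = TestClass("IT1", role="index", target_disease="M_ALB")
rt = TestClass("RT1", role="reference", target_disease="M_ALB")
for node in (it, rt, DiseaseClass("M_ALB")):
    graph.add_node(node)

pop = build_population(dipstick_study_spec(), ids=ids, graph=graph)
d = make_disposition(pop, "sensitivity", "IT1", "M_ALB", ids=ids, graph=graph)
print("real (f2) sensitivity:", round(d.probability, 4))
print("reference-linked (f3):",
      round(true_rt_linked_proportion(pop, "IT1", "RT1").value, 4))

s = sample_population(pop, 204, seed=42, ids=ids, graph=graph)
execution, table = execute_tests(pop, s, it, rt, seed=43, ids=ids, graph=graph)
print("processes:", len(execution.processes))
print("table: tp=%d fp=%d fn=%d tn=%d" % (table.tp, table.fp, table.fn, table.tn))
est = estimate_sensitivity(table, d, graph=graph, ids=ids)
print("f4 estimate: %.3f  95%% CI [%.3f, %.3f]  (n=%d)"
      % (est.value, est.ci_low, est.ci_high, est.n_denominator))
print("graph valid:", validate_instance_graph(graph).ok)
```

prints

```
real (f2) sensitivity: 0.8407
reference-linked (f3): 0.8144
processes: 408
table: tp=38 fp=9 fn=12 tn=145
f4 estimate: 0.760  95% CI [0.626, 0.857]  (n=50)
graph valid: True
```

Reading it: the population's real sensitivity (average latent response of
its diseased members) is 0.8407; conditioning on the slightly imperfect
reference test pulls the estimable population quantity down to 0.8144; and
one 204-patient study measures 38/50 = 0.760 among its 50 reference-test
positives, with a Wilson interval wide enough to cover both population
values. The 204 patients × 2 tests yield 408 test-process nodes in the
graph, which validates and round-trips through Turtle
(`bdxo.to_turtle` / `bdxo.from_turtle`).

The same flows are scriptable from the shell:

```sh
bdxo bayes --prev 0.1 --se 0.8 --sp 0.9 --json
# {"ppv": 0.4705882352941178, "npv": 0.9759036144578314}
bdxo export --fixture dipstick --out sim.json
bdxo simulate --config sim.json --n 204 --seed 42 --out g.ttl
bdxo validate --graph g.ttl
```

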
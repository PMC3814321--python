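# tloxtrace

Tools for reading **proliferative history** out of a genetic labeling system
based on Cre-mediated recombination between sister chromatids.

## The problem and who this is for

A tandem pair of overlapping loxP sites ("Tlox") placed between two
fluorescent reporters carries a stop codon inside its second unit: the
downstream reporter (tdTomato) stays silent until the array collapses to a
single loxP. Cre cannot recombine the cassette in cis, but after DNA
replication it can cross the cassette over with its sister chromatid. An
*unequal* exchange hands one daughter cell a single-loxP array — switching
the reporter on permanently and heritably — and the other a triple array.
Because activation requires passage through S/G2/M, the labeled fraction of
a population is a cumulative record of how many divisions it has undergone
while Cre was expressed, unlike a BrdU pulse, which reports only the
instantaneous proliferation *rate*.

The package is for quantitative biologists analyzing such experiments (or
planning them): it provides the exact crossover combinatorics, forward
simulators, stage-structured developmental predictions, estimators of
division history from labeled-cell counts, and a synthetic
flow-cytometry-style data generator for validation.

## The model

One crossover between unit *i* on one sister and unit *j* on the other
(uniform over the *n*² pairings, at most one per division, probability *c*
when Cre is active) produces arrays of *i* + *n* − *j* and *j* + *n* − *i*
units; products segregate to daughters at random. The marginal daughter-size
distribution is

    P(n + d) = c (n − |d|) / n²   for 1 ≤ |d| ≤ n − 1
    P(n)     = (1 − c) + c / n

so a daughter of a 2-unit cell is labeled with probability *c*/4 — at most
25% per cycle. Multiplicity states {1, 2, 3, …} form a Markov chain with
state 1 absorbing (the exact variant). The field's working approximation
(the simplified variant, default for all headline numbers) treats every
unlabeled cell as a fresh Bernoulli draw each division:

    f(k) = 1 − (1 − p)^k ,   p ≤ 1/4

which gives 25% after one cycle and 43.75% ≈ 44% after two at maximal
activity, and inverts in closed form for inference:
k̂ = ln(1 − f̂)/ln(1 − p). Confidence intervals come from a studentized
bootstrap over mice; group contrasts from an exact mouse-label permutation
test; BrdU positivity from
`cycling_fraction × min(1, (t_s + t_pulse)/t_cycle)`.

## Worked example

```python
from tloxtrace import ModelParams, activation_probability, cumulative_label_fraction

print(activation_probability(2, 1.0))           # 0.25
simp = ModelParams(variant="simplified", p_simplified=0.25)
exact = ModelParams(c=1.0, variant="exact")
for k in range(4):
    print(k, cumulative_label_fraction(k, simp), round(cumulative_label_fraction(k, exact), 4))
```

prints

```
0.25
0 0.0 0.0
1 0.25 0.25
2 0.4375 0.4028
3 0.578125 0.5069
```

A quarter of daughters label in the first cycle; after two cycles the
simplified model reaches 43.75% (the "44%" headline) while the exact chain
reaches 29/72 ≈ 40.3%, because triple-loxP intermediates activate at only
*c*/9 per division. Inference from a synthetic cohort
(`examples/04_infer_history.py`, 3 mice × 10⁴ cells generated at k = 4,
p = 0.13):

```
Estimated Cre-active divisions: k_hat = 3.74 (95% CI 1.55-6.87); truth k = 4
```

The `examples/` directory has one short script per capability: crossover
combinatorics, asynchronous culture time courses, per-stage developmental
predictions for different Cre drivers, history inference, the two-population
permutation test, and the rate-versus-history discordance report. A thin
CLI mirrors the pipeline: `tlox simulate|predict|infer|synth --config
cfg.yaml --out dir` (exit codes: 2 config, 3 data, 4 model error).

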
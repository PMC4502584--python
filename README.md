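# argram — probabilistic activation/recognition grammars

`argram` implements **activation/recognition grammars**: stochastic
context-free grammars (without null symbol) whose terminals are bound to an
environment as **actuators** (they produce output, like an axon) or
**sensors** (they match and consume input, like a dendrite).  Unlike a
traditional grammar, which runs either in generation or in parsing mode, an
activation/recognition grammar can do both *simultaneously* in a single
derivation — a model of neural circuits in which production and recognition
share one description.  The package is aimed at computational
neuroscientists and researchers in grammar-based models of cognition who
want an executable, testable version of this formalism.

A grammar is written in a minimal probability-weighted Wirth notation:

```
A = .3 B | .7 C.  B = DrawSquare.  C = DrawCircle.
```

Rule alternates are separated by `|` and weighted with probabilities
(unweighted alternates are read as equipartition: `A = B | C | D | E.` means
weight ¼ each).  On top of the core engine the package provides:

* **Mixed-mode execution** — depth-first derivation with sensor-gated
  alternate choice: when alternates open with sensors, the matching one is
  taken; otherwise the alternate is sampled by weight.  Sequencing inside a
  rule does not convey temporal order; order is carried by derivation depth
  (number of rule applications), with recognition ahead of production at
  equal depth.
* **Turing completeness in practice** — a Turing-tape environment
  (`Pe P0 P1 Px R L E` actuators, `0 1 x e None` sensors).  The shipped
  transliteration of Turing's first example machine deterministically writes
  the sequence `001011011101111…`.
* **Backtracking recognition** — `recognize()` sums the probability of all
  derivations that consume an input token stream.
* **Self-description** — `describe()`/`decode_description()` encode a
  grammar as another grammar using the quote operator (`QuoteA`,
  `QuotePoint61` for weight .61); `root_grammar()` is the eight-rule fixed
  point that recognizes the linearization of *any* grammar, including its
  own.  `retarget()` implements metaphor (replaying a pattern into a new
  terminal domain via `Unquote`), and `compose()` splices a guest grammar
  into a host at a hook terminal while leaving both components intact.
* **Swarm learning** — `expand_swarm()` builds a grammar whose top-level
  alternates instantiate one template at different probability vectors;
  `select_branch()` picks the branch with maximum average log-likelihood
  (minimum cross-entropy) for a sample; `estimate_weights()` is the
  multinomial MLE; `reinforcement_step()` closes the recognition→production
  loop of the color example.
* **Neural-circuit compilation** — `circuit_graph()` maps nonterminals to
  somata, terminals to dendritic/axonal ports, and alternates to weighted
  synapses; direct self-recursion becomes an **autapse**, longer cycles
  become regular recurrent synapses.  DOT output for both the grammatical
  schema and the circuit.

## Worked example

```
$ argram turing --figures 15
001011011101111

$ argram fixtures /tmp/figs
wrote 31 fixtures to /tmp/figs

$ argram parse /tmp/figs/fig4_a.arg
A = .3 B | .7 C. B = DrawSquare. C = DrawCircle.

$ argram render /tmp/figs/fig5_loop.arg --kind stats
{"somata": 1, "synapses": 2, "autapses": 1, "recurrent": 0, "sensor_ports": 0, "actuator_ports": 1}
```

The first command runs the Turing transliteration until fifteen binary
figures stand on the tape and prints them in tape order.  The last shows the
circuit of `A = DrawSquare A.`: one soma whose recursion is an autapse, plus
one actuator port.

From Python, the metaphor example — a two-square counter retargeted to
circles:

```python
>>> import argram as A
>>> counter = A.parse_grammar("A = B C. B = DrawSquare. C = DrawSquare.")
>>> described = A.retarget(counter, {"DrawSquare": "DrawCircle"})
>>> A.execute_description(described, seed=0)[0]
['DrawCircle', 'DrawCircle']
```

and swarm selection of the orange color (a .61/.39 green/red mixture)
against the three-branch swarm grid:

```python
>>> spec = A.SwarmSpec(
...     template=A.parse_grammar("B = .5 E | .5 F. E = SpotGreenPoint. F = SpotRedPoint."),
...     designated_rule="B",
...     grid=((0.5, 0.5), (0.6, 0.4), (0.9, 0.1)))
>>> sample = A.sample_tokens((0.61, 0.39), ("SpotGreenPoint", "SpotRedPoint"), 1000, seed=42)
>>> A.select_branch(spec, sample)
'branch1'
```

Branch 1 is the (.6, .4) grammar — the branch closest in distribution to
orange.

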
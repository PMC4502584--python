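# Methods

## The formalism

An activation/recognition grammar is a stochastic context-free grammar
without null productions.  Terminals carry a *direction*: actuators produce
an output event, sensors match and consume an input event.  The same
derivation may do both, which is what lets one description serve production,
recognition, and mixed sensor/actuator behavior.  Nonterminals are purely
structural; each rule's alternates carry probabilities that are normalized
to sum to one at parse time (raw weights are allowed and normalized;
unweighted alternates share the mass equally).

Terminal direction is **declared, not inferred**: a registry maps terminal
names to `sensor`/`actuator`.  The same token can legitimately play both
roles in different grammars — `0` and `1` are tape sensors for the Turing
machine but produced digits in the digit grammars — so digit-producing
fixtures carry a per-grammar registry override.  Rule heads always shadow
registry entries (`R` is "move right" on the tape but an ordinary
nonterminal wherever a rule defines it).

A numeric token opening an alternate is read as a weight when it is
fractional, or when it is an integer that neither the registry nor the rule
heads know.  This keeps `o = 1 R Px L L L o | 0 q.` sensor-led while still
accepting integer weights such as `A = 3 B | 7 C.`.  The residual ambiguity
(an integer that is both a registered terminal and an intended weight) is
resolved in favor of the terminal and documented here; fractional weights
are never ambiguous because symbol names cannot contain a dot.

## Execution semantics

Derivations expand depth-first, left to right.  At each rule:

1. If one or more alternates *begin* with a reachable sensor (directly or
   through one level of nonterminal indirection, covering `Any = 0 | 1`),
   the alternates whose leading sensor currently matches the environment
   are kept and one is sampled among them by renormalized weight.
2. If sensor-led alternates exist but none matches, the non-sensor-led
   alternates remain in play (so `A = SpotX B | DrawY.` produces `Y` when
   no `X` is present).  If *every* alternate is sensor-led and none
   matches, the rule does not apply and the derivation halts.
3. Otherwise the alternate is sampled by weight.

Sensor gating is what lets stochastic choice coexist with deterministic
control: in the Turing grammar every alternate is sensor-led and exactly
one matches per step, so execution is deterministic whatever the seed.

A derivation ends with one of four statuses: `complete` (start symbol fully
expanded), `no_match` (a sensor failed with no viable alternate — the
normal way a recognition loop such as "one square per circle" ends),
`budget` (the rule-application budget, default 10 000, ran out — a *legal*
outcome, since grammars like `A = DrawSquare A.` never terminate), or
`stopped` (a caller-supplied stop condition fired, used by the Turing
driver to stop at a figure count).  Sensor mismatch is a status, not an
exception, because the formalism treats "rules no longer apply" as the
ordinary end of execution.

The trace likelihood is the sum of log-weights of the chosen alternates.
Event *order* is a separate, declarative notion: the number of rule
applications from the start symbol to a terminal orders events (fewer
first), and at equal depth recognition precedes production; remaining pairs
are unordered.  We apply the recognition-ahead-of-production clause to
same-depth pairs only — its scope is genuinely open, and the narrow reading
is the one that does not contradict depth ordering.

### Recognition

`recognize()` is a bounded backtracking search that sums the probability of
**all** accepting derivations (a summed rather than max-derivation
likelihood; the choice is open and the sum is the natural probabilistic
semantics).  A shortest-yield bound (the fewest tokens each nonterminal
must consume) prunes states that cannot finish, which makes recognition of
sensor-rich grammars — including the root grammar on long linearizations —
fast and left-recursion-safe.  Grammars with non-consuming unit cycles
(`N = N | …`) have infinitely many accepting derivations; the search then
stops at the budget and flags the result indeterminate.  This is a
deliberate limitation: a chart parser is out of scope, and no grammar in
the shipped corpus is pathological.

The root grammar's `Symbol` and `Weight` terminals are *class* sensors:
`Weight` matches any dotted-decimal token, `Symbol` any other token.
`linearize()` always formats weights with a decimal point (`0.5`, `1.0`) so
the two classes are disjoint, and always emits a weight token per alternate
— the root grammar requires one even where the written notation omits it.

### Turing environment

The tape is a sparse map from integer positions to symbols, unbounded in
both directions, head starting at 0.  `Pe/P0/P1/Px` overwrite the scanned
cell, `E` blanks it, `R/L` move the head; sensors match the scanned symbol,
`None` matching blank.  Figures are recovered by symbol class (cells
holding `0`/`1` in position order), not by square parity, so no
F/E-square bookkeeping is hard-coded.  The engine's actuator history is
exposed so tests can compare it step for step with an independent
table-driven machine built from the same quintuples.

## Self-description

`describe()` encodes a grammar with the quote operator: the top rule
sequences one branch per described rule; a branch emits the quoted head
then a payload rule; payloads list `QuotePointNN` weight tokens followed by
quoted symbols, one sub-rule per alternate.  Weight-1 single alternates are
weight-silent.  Fresh nonterminals are allocated deterministically
(A, B, C, …), which makes the generated describing grammars reproduce the
reference descriptions letter for letter in the simple cases and up to
renaming otherwise.

Weight quoting uses two decimal digits by default (`0.61 ↔ QuotePoint61`,
trailing zeros dropped so `0.6 ↔ QuotePoint6`, hundredths left-padded so
`0.01 ↔ QuotePoint01`); a weight outside that precision raises instead of
silently rounding.  Consequently a three-way equipartition (1/3) is not
describable — by design; the encoding is exact or it refuses.

`decode_description()`/`interpret_description()` invert the scheme.  The
interpreter also accepts the folded chain style used in some reference
descriptions, where a trailing nonterminal continues a quoted-symbol chain
(`F = Quote0 J. J = Unquote1 K.`).  After an `Unquote` token the remaining
non-quoted symbols form the *replacement body*; a nonterminal in body
position is an embedded description (a composition guest) when its subtree
decodes as one, a plain sub-grammar otherwise.  One known folding in the
shipped composition figure flattens `B = 0 | 1` into a symbol chain — the
figure's own simplification; grammars generated by `compose()` keep the
weight-explicit form and round-trip exactly.

Unquote execution is event interception: the describing grammar replays the
described derivation (same weights, same seed, hence the same stochastic
choices the described grammar would make) and substitutes intercepted
actuator events with their replacement bodies — emitted tokens for
metaphor, a full guest production per event for composition.  Interception
is keyed by terminal name; mapping two occurrences of the same actuator to
different targets would require occurrence-level keys, which no use case
here needs.

## Swarm learning

"Closest branch" is formalized as maximum average per-token log-likelihood,
i.e. minimum cross-entropy between the sample's empirical distribution and
the branch's terminal distribution.  This is the measure under which the
(.6, .4) branch is closest to a .61/.39 orange sample, and it is
grammar-native: the branch's terminal distribution is computed by
exhaustive enumeration of its derivations.  Ties break to the lowest branch
index.  Weight recovery is the multinomial MLE (relative frequencies),
which is unbiased with standard error √(p(1−p)/n); the tests check the
3-standard-error envelope at n ∈ {100, 1 000, 10 000}.

The reinforcement closure pairs a recognition gate with a description of a
target producer.  The gate triggers when its probability vector is the
maximum-likelihood assignment of its own probabilities to the sample's
terminals (i.e. it beats every relabeling of itself; for two colors: the
sample leans green under a .6-green gate).  This realizes "trigger when the
sample selects this branch" without introducing a distance cutoff that the
formalism does not define.  No convergence criterion is imposed on repeated
refinement — iteration is caller-controlled.

## Circuits

One soma per nonterminal (a bijection), one port per distinct terminal
name, one synapse per (alternate, symbol) pair labeled with the alternate's
weight.  Recurrence is flagged by depth-first back-edge detection from the
start soma: a back edge onto the same soma is an autapse, onto another soma
a *regular* recurrent synapse — so in the two-rule loop exactly the
cycle-closing edge (B→A) is recurrent, not the forward edge.  Edges with
probability below .5 are marked inhibitory in metadata only; no further
synaptic semantics is asserted.  Quoted terminals become projection ports
drawn as dashed edges (the describing circuit projecting onto the described
one).  The grammatical schema rendering truncates recursion after a
nonterminal has been re-entered `depth` times on a path (default 2, depth 0
= start soma alone); the circuit rendering is never truncated, since
recursion is a finite edge there.

## Problem sizes and numerics

Weight normalization and round-trip comparisons use a 1e-9 tolerance;
serialization prints weights in the notation's style (`.3`, `.61`) with
nine-decimal stability.  A weight of exactly 0 is accepted and flagged as a
warning diagnostic (inhibition is low probability, not impossibility).
Stochastic checks use 10 000 productions for the .3/.7 and orange-MLE
frequencies (3 binomial SEs ≈ ±1.4 and ±1.5 points), 1 000 tokens for swarm
selection with 100 replicates (≥95 % correct), and 10 000 paired runs with a
chi-square test at α = 0.01 for the composition/static-substitution
comparison; the Turing engine is checked against the table oracle for at
least 500 primitive operations.  All randomness flows through explicit
integer seeds.

## What the generated data does and does not show

Synthetic samples are i.i.d. categorical token streams and seeded grammar
runs; they exercise the estimators and the engine exactly under the model's
own assumptions.  They do not contain measurement noise, temporal
correlation, or any biophysics (no membrane dynamics, spikes, delays, or
interneuron structure) — passing tests show the formalism and its
implementation are coherent, not that cortex implements them.  Likewise the
circuit graphs are structural claims only.

## Known limitations

* Backtracking recognition can be exponential on pathologically ambiguous
  grammars and cannot decide grammars with non-consuming unit cycles
  (budget + indeterminate flag instead).
* Quote precision is finite-decimal; thirds equipartition is not
  describable.
* Interception is keyed by terminal name, not occurrence.
* Production mode for the root grammar's class terminals (`Symbol`,
  `Weight`) is not given a concrete token sampler; the root grammar is
  exercised in recognition, which is where its fixed-point property lives.
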
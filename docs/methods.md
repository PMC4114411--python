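# Methods

`adlshift` detects shifts in a user's routine behavior from event logs
of discrete actions, the setting of ambient-assisted-living (AAL)
monitoring: a sensorized home reduces raw signals to labeled action
events ("Pill, on", "Water Off", …), routines are represented as
probabilistic models over those actions, and deviations from routine
may signal forgetfulness, changed preferences, or early signs of
conditions such as depression or Alzheimer's disease.  This note
records the model, the algorithmic and numerical choices, and what the
synthetic evaluation does and does not show.

## The behavior model

A *frequent behavior* `f` is a Markov chain over actions: a state set,
an initial distribution `P0`, a row-stochastic transition matrix `P`,
and terminal states (no outgoing transition).  A *path* `ρ` is a
complete start-to-terminal traversal; its likelihood is the product of
its transition probabilities,

    LL(ρ | f) = ∏ₖ Pr(ρₖ → ρₖ₊₁).

An observed episode `C` is scored with the same product under
*complete-path semantics*: the likelihood is zero unless the first
action has positive initial probability, every consecutive pair is a
transition of the chain, and the last action is terminal.  By default
the initial probability gates but is not multiplied in
(`include_initial_prob=False`); with a single certain start state the
two conventions coincide, and no worked scenario distinguishes them.
A length-normalized (geometric-mean) likelihood was considered and
rejected: it does not reproduce the worked branch-probability value
(0.6^(1/8) ≈ 0.94 ≠ 0.6).

Paths are enumerated depth-first from every start state.  Because
probabilities are ≤ 1 the running product is non-increasing along a
walk, so pruning branches that fall below `path_threshold` (default
0.01) is exact, and `max_path_length` (default 100) guarantees
termination on chains with loops.  A chain whose terminal states are
unreachable above the threshold yields an empty path set with a
warning record rather than an exception.

### Pattern states versus action labels

A first-order chain over bare action labels cannot represent a routine
that performs the same action twice with different continuations (the
eating activity opens a cabinet at the start and again before
finishing: a label-level chain would be cyclic and have no terminal
state).  Chain states are therefore *pattern nodes*: when a label
recurs within an episode, its k-th occurrence maps to a distinct state
(`"Cabinet On"`, `"Cabinet On #2"`, …) carrying a `state_actions`
rendering map.  Observed episodes are matched to states by occurrence
order of their labels; chains without repeats are unaffected, and edit
distances are always computed on rendered action labels.  Limitation:
occurrence matching assumes a routine visits repeated occurrences in a
fixed order, which holds for linear patterns but not for arbitrary
graphs with interleaved repeats.

## Shift identification

When `LL(C | f) = 0` for every frequent behavior, the shift from each
behavior is the minimum set of *modifications* turning `C` into one of
its paths, drawn from four classes: insertion (a forgotten action),
deletion (an extra action), substitution (one action done instead of
another) and swap (two actions done in reverse order).

The distance is computed by dynamic programming at unit cost.  The
transposition case uses the unrestricted (last-occurrence) form

    d[m,n] ≤ d[k−1,l−1] + (m−k−1) + (n−l−1) + 1,

where `k`, `l` index the last crossed occurrences of the two symbols:
the material between a transposed pair is deleted/inserted so the pair
becomes adjacent when swapped.  With unit costs this recurrence equals
the true minimum edit-script length over the four operations
(2·w_swap ≥ w_ins + w_del holds), whereas the restricted
"last-two-symbols-crossed" variant is only an upper bound when a
transposed pair is later re-edited (`ca → abc`: 2 operations, not 3).
Both forms reproduce the worked modification counts; the unrestricted
form is used because the package's correctness contract is equality
with edit-script search (verified in the tests by a bidirectional-BFS
oracle, itself cross-checked against an established Levenshtein
implementation on the swap-free restriction).  Matrix boundaries are
the standard `d[m,0] = m`, `d[0,n] = n`.

The backtrace walks from the bottom-right cell, preferring at equal
cost: match > swap > substitution > deletion > insertion.  The order is
a determinism choice; no worked example distinguishes minimal scripts.
Emitted modifications carry positions interpreted sequentially (the
list is a replayable program on the episode), and two postconditions
are enforced before returning: the set size equals the bottom-right
cell, and replaying the set on the episode reproduces the path
exactly.  Set-level comparisons (tests, validation) use the multiset
of (operation, operands), since positions are not part of the
published worked sets.

## Criticality and risk

A criticality mapping `g` assigns each modification a value in [0, 1],
*lower meaning more critical* (a forgotten pill matters more than a
skipped shower).  Rules match exact (op + operands) first, then
op-level wildcards, then a `default_value` of 1.0 (non-critical); swap
operands match in either order.  A modification set aggregates by
minimum by default — the most critical member dominates, so a missed
medication is not diluted by harmless edits — with `product` and
`mean` available (`criticality_aggregation`).  All published values
arise from singleton sets, for which the three agree.

The behavior risk factor is

    φ = (number of modifications) × (1 − Cr),

zero exactly when the behavior matches (no modifications), increasing
in both the count and the severity of the edits.  An episode is flagged
anomalous when even the least risky frequent behavior exceeds
`anomaly_threshold` (default 1.0): closeness to *any* routine is
evidence of normality.  The scorer and threshold are deliberately
simple and exposed in configuration; only the threshold-comparison
contract and the monotonicity requirements constrain them.

The driver (`calculate_shifts`) computes all likelihoods first; on any
positive likelihood it reports that match and skips all edit-distance
work.  Otherwise, per behavior, the path with the fewest modifications
wins, ties broken by higher path likelihood, then lower criticality.

The bundled criticality mapping for the worked morning-ritual scenario
(`criticality_map_michael`) is reconstructed from the two outcomes it
must produce — g(insert 'Pill, on') = 0.2 and g(swap 'Pill, on',
'Breakfast, on') = 0.4 — the underlying full mapping not being
published.

## Learning

`learn_behavior` is a deliberately small frequency-count estimator
standing in for a full behavior-pattern-mining layer (which would also
discover time relations and conditions; both are out of scope here, as
the shift detector consumes only the chain).  Actions present in fewer
than `min_support` (default 0.5) of the episodes are dropped from every
episode before counting, keeping the chain connected.  Retained
episodes are occurrence-encoded, first states and consecutive pairs are
counted, rows are normalized, and terminal states are those never
followed by another action.  Learning is deterministic (counting only)
and its output always satisfies the chain invariants.  Limitation: the
estimator cannot express "optional stop" (a state both terminal and
with successors); episodes that are proper prefixes of others will
score zero.

## Synthetic data and the validation harness

The generator samples episodes by walking a chain (seeded; a walk
exceeding `max_length` is truncated with a warning) and injects
controlled corruptions inverting the four modification classes:
removing an action makes the detector owe an insertion, and so on.
Ground truth is stored as the *repairs* — the detector's perspective —
so it compares directly with a shift report.

The bundled fixtures encode the worked morning-ritual chain (branch
probabilities 0.6/0.4 reconstructed from its two path likelihoods, all
other transitions certain, a single start state) and five linear
activities of daily living — make a phone call (3 actions), wash hands
(2), cook (12), eat (8), clean (2) — modeled as deterministic chains
because they are given as sequences, not probabilities.  Wash-hands
and clean are the same two-action sequence; they are treated as
independent behaviors, so recovery scoring accepts a tie between them.

The *adapted cross-validation* reconstructs an evaluation protocol
around shift identification: per fold, one chain per activity label is
learned from the training episodes; each held-out episode is scored
unperturbed (is it recognized as a path, with a likelihood that
matches direct recomputation?) and with exactly one seeded corruption
(delete, substitute, or swap) injected (does some behavior achieving
the minimum modification count report exactly the ground-truth repair
multiset?).  The reference experiment used logs recorded in an
instrumented apartment; that data is external, so the package's
acceptance surface is this synthetic stand-in: 200 episodes sampled
uniformly from the five chains with a fixed seed, 10 folds.  At these
conditions both rates are 100%.

What this does and does not show: the synthetic corpus has no sensor
noise, no dwell times, no mislabeled actions and no interleaved
activities, and each activity is a deterministic sequence — so the
validation exercises the detection pipeline (learning, enumeration,
distance, backtrace, scoring) end to end, not robustness to the messy
parts of real AAL data, which live in the out-of-scope transformation
layer.

## Numerical choices and problem sizes

- Probability tolerances: 1e-9 absolute for stochasticity invariants;
  threshold comparisons in path pruning use a 1e-9 epsilon so exact
  boundary products are kept.
- Likelihood equality in the validation harness: 1e-12 absolute.
- Test oracles: edit distances are checked exhaustively for all pairs
  of lengths ≤ 3 over a 4-letter alphabet and on seeded random pairs
  up to length 6 (exhausting length 6 outright would mean tens of
  millions of pairs for no additional structure); path enumeration is
  checked against brute-force sequence generation on chains of ≤ 6
  states; parameter recovery uses 1000 sampled episodes of a known
  5-state chain (tolerance 0.05 element-wise).
- All randomness flows through seeded `numpy` generators; identical
  seeds give byte-identical outputs, including through the CLI.

## Known limitations

- First-order chains with occurrence-indexed states cover linear and
  branching routines; routines where repeated actions occur in
  variable order are not representable.
- Unit edit costs: criticality weights are applied after extraction,
  never inside the distance matrix, so the minimal script is not
  criticality-aware.
- The risk factor ignores path likelihood; whether it should is an
  open modeling question, and the scorer is pluggable for that reason.
- Anomaly thresholding is per-episode; no temporal aggregation across
  days (online operation is out of scope).
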
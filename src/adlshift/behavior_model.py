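"""Markov-chain models of frequent user behaviors.

A *frequent behavior* is a recurring routine of one user (e.g. a morning
ritual) represented as a Markov chain over discrete actions.  An action
is an atomic labeled event of the form ``"<entity>, <state>"`` such as
``"Pill, on"``.  The chain has an initial distribution ``P0`` over start
states, a transition matrix ``P`` and a set of terminal states (states
with no outgoing transition).  A complete start-to-terminal traversal of
the chain is a *path*: one concrete realization of the routine.

This module provides the chain representation, the likelihood of an
observed action sequence under a chain, and depth-first enumeration of
all sufficiently likely paths.

States versus action labels
---------------------------
In most chains every state *is* an action label.  When a routine
performs the same action more than once (e.g. opening a cabinet twice
while eating), each occurrence is a distinct node of the pattern; such
chains carry a ``state_actions`` mapping from state name to the action
label it emits, and observed episodes are matched to states by
occurrence order of their labels.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

PROB_TOL = 1e-9
#: suffix pattern used for repeated-occurrence states, e.g. "Cabinet On #2"
_OCC_SUFFIX = " #"


class InvalidInputError(ValueError):
    """An operation received an empty or out-of-contract input."""


class ModelValidationError(ValueError):
    """A FrequentBehavior violates its stochasticity invariants."""


class InvalidPathError(ValueError):
    """A sequence submitted as a path is not a traversal of the chain."""


_WS_RUN = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Trim and collapse internal whitespace; labels stay case-sensitive."""
    out = _WS_RUN.sub(" ", str(label).strip())
    if not out:
        raise InvalidInputError("action label is empty")
    return out


@dataclass(frozen=True, eq=False)
class Action:
    """An atomic labeled event.

    Equality and hashing use the (normalized) label only; the optional
    timestamp orders events within an episode and plays no role in any
    of the algorithms.
    """

    label: str
    timestamp: object = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", normalize_label(self.label))

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Action):
            return self.label == other.label
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.label)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Action({self.label!r})"


@dataclass(frozen=True)
class BehaviorEpisode:
    """An ordered sequence of actions.

    ``kind`` distinguishes an observed episode (a current behavior C)
    from a path of a chain.  ``truncated`` marks episodes cut off at a
    sampling length cap.
    """

    actions: tuple[Action, ...]
    kind: str = "observed"
    episode_id: str | None = None
    truncated: bool = False

    @classmethod
    def from_labels(
        cls,
        labels: Iterable[str],
        kind: str = "observed",
        episode_id: str | None = None,
        truncated: bool = False,
    ) -> "BehaviorEpisode":
        return cls(
            actions=tuple(Action(lbl) for lbl in labels),
            kind=kind,
            episode_id=episode_id,
            truncated=truncated,
        )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.actions)

    def __len__(self) -> int:
        return len(self.actions)

    def __iter__(self):
        return iter(self.actions)


EpisodeLike = Union[BehaviorEpisode, Sequence[str], Sequence[Action]]


def episode_labels(episode: EpisodeLike) -> tuple[str, ...]:
    """Normalized label sequence of an episode-like object."""
    if isinstance(episode, BehaviorEpisode):
        return episode.labels
    out = []
    for item in episode:
        if isinstance(item, Action):
            out.append(item.label)
        else:
            out.append(normalize_label(item))
    return tuple(out)


def occurrence_states(labels: Sequence[str]) -> tuple[str, ...]:
    """Map each label occurrence within one sequence to a distinct state name.

    The first occurrence of a label keeps the bare label; the k-th
    (k >= 2) becomes ``"<label> #k"``.  Chains whose states are plain
    labels are unaffected because no matching sequence repeats a label.
    """
    seen: Counter[str] = Counter()
    out = []
    for lbl in labels:
        seen[lbl] += 1
        out.append(lbl if seen[lbl] == 1 else f"{lbl}{_OCC_SUFFIX}{seen[lbl]}")
    return tuple(out)


@dataclass(frozen=True)
class FrequentBehavior:
    """A frequent behavior: a Markov chain over discrete actions.

    Fields mirror the chain definition: ``states``, initial distribution
    ``initial_probs`` (P0), transition probabilities ``transitions``
    keyed by (from, to), and ``terminal_states`` (no outgoing edge).
    ``state_actions`` maps state names to emitted action labels for
    chains that visit the same action more than once; ``None`` means
    states are action labels.
    """

    id: str
    states: tuple[str, ...]
    initial_probs: Mapping[str, float]
    transitions: Mapping[tuple[str, str], float]
    terminal_states: frozenset[str]
    state_actions: Mapping[str, str] | None = None

    @classmethod
    def from_edges(
        cls,
        id: str,
        initial_probs: Mapping[str, float],
        edges: Iterable[tuple[str, str, float]],
        state_actions: Mapping[str, str] | None = None,
        states: Sequence[str] | None = None,
    ) -> "FrequentBehavior":
        """Build a chain from (from, to, probability) edges.

        Terminal states are derived as the states with no outgoing edge
        of positive probability.  ``states`` fixes state order (and may
        declare isolated states); otherwise order of first appearance
        is used.
        """
        transitions: dict[tuple[str, str], float] = {}
        order: list[str] = list(states) if states is not None else []
        seen = set(order)

        def _add(state: str) -> None:
            if state not in seen:
                seen.add(state)
                order.append(state)

        for s in initial_probs:
            _add(s)
        for frm, to, p in edges:
            _add(frm)
            _add(to)
            transitions[(frm, to)] = float(p)
        has_out = {frm for (frm, _), p in transitions.items() if p > 0}
        terminal = frozenset(s for s in order if s not in has_out)
        return cls(
            id=id,
            states=tuple(order),
            initial_probs=dict(initial_probs),
            transitions=transitions,
            terminal_states=terminal,
            state_actions=dict(state_actions) if state_actions else None,
        )

    # -- state/label mapping -------------------------------------------------

    def action_label(self, state: str) -> str:
        if self.state_actions is None:
            return state
        return self.state_actions.get(state, state)

    def render(self, states: Sequence[str]) -> tuple[str, ...]:
        """Action-label sequence emitted by a state sequence."""
        return tuple(self.action_label(s) for s in states)

    def encode_labels(self, labels: Sequence[str]) -> tuple[str, ...] | None:
        """Map an action-label sequence onto chain states.

        For plain chains this is the identity.  For occurrence-indexed
        chains the i-th occurrence of a label within the sequence maps
        to the i-th state emitting that label (in state order); returns
        ``None`` when some occurrence has no corresponding state.
        """
        if self.state_actions is None:
            return tuple(labels)
        by_label: dict[str, list[str]] = {}
        for s in self.states:
            by_label.setdefault(self.action_label(s), []).append(s)
        seen: Counter[str] = Counter()
        out = []
        for lbl in labels:
            idx = seen[lbl]
            seen[lbl] += 1
            candidates = by_label.get(lbl, [])
            if idx >= len(candidates):
                return None
            out.append(candidates[idx])
        return tuple(out)

    # -- chain queries -------------------------------------------------------

    def transition_prob(self, frm: str, to: str) -> float:
        return float(self.transitions.get((frm, to), 0.0))

    def successors(self, state: str) -> list[tuple[str, float]]:
        return [
            (to, p) for (frm, to), p in self.transitions.items() if frm == state and p > 0
        ]


def validate_behavior(behavior: FrequentBehavior) -> list[str]:
    """Check the chain invariants; returns violation descriptions (never raises).

    Checked: probabilities in [0, 1]; initial distribution sums to 1;
    every transition endpoint declared; every non-terminal row sums to
    1; terminal states have no outgoing probability mass.
    """
    v: list[str] = []
    states = set(behavior.states)

    for s, p in behavior.initial_probs.items():
        if s not in states:
            v.append(f"initial state {s!r} is not a declared state")
        if not (0.0 <= p <= 1.0):
            v.append(f"initial probability of {s!r} is {p}, outside [0, 1]")
    total0 = sum(behavior.initial_probs.values())
    if abs(total0 - 1.0) > PROB_TOL:
        v.append(f"initial probabilities sum to {total0}, expected 1")

    row_sums: dict[str, float] = {}
    for (frm, to), p in behavior.transitions.items():
        if frm not in states:
            v.append(f"transition from undeclared state {frm!r}")
        if to not in states:
            v.append(f"transition to undeclared state {to!r}")
        if not (0.0 <= p <= 1.0):
            v.append(f"transition probability {frm!r} -> {to!r} is {p}, outside [0, 1]")
        if p > 0:
            row_sums[frm] = row_sums.get(frm, 0.0) + p

    for s in behavior.states:
        out_sum = row_sums.get(s, 0.0)
        if s in behavior.terminal_states:
            if out_sum > PROB_TOL:
                v.append(f"terminal state {s!r} has outgoing probability {out_sum}")
        elif abs(out_sum - 1.0) > PROB_TOL:
            v.append(f"outgoing probabilities of {s!r} sum to {out_sum}, expected 1")
    return v


def _require_valid(behavior: FrequentBehavior) -> None:
    violations = validate_behavior(behavior)
    if violations:
        raise ModelValidationError(
            f"behavior {behavior.id!r} is invalid: " + "; ".join(violations)
        )


def episode_likelihood(
    episode: EpisodeLike,
    behavior: FrequentBehavior,
    include_initial_prob: bool = False,
) -> float:
    """Likelihood of an observed episode under a frequent behavior.

    The likelihood is the product of the transition probabilities over
    consecutive action pairs, under complete-path semantics: it is zero
    when the first action has zero initial probability, when any action
    is not a state of the chain, when any consecutive pair is not a
    transition, or when the episode does not end at a terminal state.
    With ``include_initial_prob`` the initial probability of the first
    action is multiplied in as well (off by default: the initial
    distribution only gates).
    """
    labels = episode_labels(episode)
    if not labels:
        raise InvalidInputError("episode is empty")
    _require_valid(behavior)

    enc = behavior.encode_labels(labels)
    if enc is None:
        return 0.0
    states = set(behavior.states)
    if any(s not in states for s in enc):
        return 0.0
    p0 = float(behavior.initial_probs.get(enc[0], 0.0))
    if p0 <= 0.0:
        return 0.0
    if enc[-1] not in behavior.terminal_states:
        return 0.0
    ll = p0 if include_initial_prob else 1.0
    for frm, to in zip(enc, enc[1:]):
        t = behavior.transition_prob(frm, to)
        if t <= 0.0:
            return 0.0
        ll *= t
    return ll


def path_likelihood(path: EpisodeLike, behavior: FrequentBehavior) -> float:
    """Likelihood of a path: product of its transition probabilities.

    The path must be a traversal of the chain (every consecutive pair a
    positive-probability transition); otherwise ``InvalidPathError``.
    """
    labels = episode_labels(path)
    if not labels:
        raise InvalidInputError("path is empty")
    enc = behavior.encode_labels(labels)
    if enc is None or any(s not in set(behavior.states) for s in enc):
        raise InvalidPathError(f"path visits actions unknown to behavior {behavior.id!r}")
    ll = 1.0
    for frm, to in zip(enc, enc[1:]):
        t = behavior.transition_prob(frm, to)
        if t <= 0.0:
            raise InvalidPathError(
                f"{frm!r} -> {to!r} is not a transition of behavior {behavior.id!r}"
            )
        ll *= t
    return ll


@dataclass
class PathSet:
    """All complete paths of a chain above a likelihood threshold.

    Paths are sorted by decreasing likelihood (ties: lexicographic by
    labels) so that downstream tie-breaking prefers likelier paths.
    """

    paths: tuple[tuple[BehaviorEpisode, float], ...]
    threshold: float
    max_length: int
    warnings: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)


def enumerate_paths(
    behavior: FrequentBehavior,
    threshold: float = 0.01,
    max_length: int = 100,
) -> PathSet:
    """Depth-first enumeration of complete start-to-terminal paths.

    Branches whose running likelihood product falls below ``threshold``
    are pruned — sound because probabilities are at most 1, so the
    product never increases along a path.  ``max_length`` caps path
    length, guaranteeing termination on chains with loops.  A chain
    with no reachable terminal state yields an empty PathSet carrying a
    warning record (not an exception).
    """
    if not (0.0 < threshold <= 1.0):
        raise InvalidInputError(f"threshold must be in (0, 1], got {threshold}")
    if max_length < 1:
        raise InvalidInputError(f"max_length must be >= 1, got {max_length}")
    _require_valid(behavior)

    eps = PROB_TOL
    found: list[tuple[BehaviorEpisode, float]] = []

    def dfs(state: str, seq: list[str], ll: float) -> None:
        if state in behavior.terminal_states:
            found.append(
                (BehaviorEpisode.from_labels(behavior.render(seq), kind="path"), ll)
            )
            return
        if len(seq) >= max_length:
            return
        for nxt, p in behavior.successors(state):
            nll = ll * p
            if nll + eps >= threshold:
                seq.append(nxt)
                dfs(nxt, seq, nll)
                seq.pop()

    for start, p0 in behavior.initial_probs.items():
        if p0 > 0:
            dfs(start, [start], 1.0)

    found.sort(key=lambda pair: (-pair[1], pair[0].labels))
    warnings: tuple[str, ...] = ()
    if not found:
        warnings = (
            f"behavior {behavior.id!r}: no terminal state reachable within "
            f"threshold {threshold} and max_length {max_length}",
        )
    return PathSet(
        paths=tuple(found), threshold=threshold, max_length=max_length, warnings=warnings
    )
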
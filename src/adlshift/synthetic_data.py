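"""Episode simulation, controlled perturbation, and built-in fixtures.

The generator samples episodes from a frequent-behavior chain and
injects controlled corruptions that invert the four modification
classes: to make the detector report ``insert(a)`` the generator
removes ``a`` from the episode, and so on.  Ground truth is therefore
expressed as the *repairs* the detector should recover, directly
comparable with a shift report.

The fixture registry ships a small worked scenario (one user's morning
ritual with an optional shower branch) and five linear activities of
daily living (phone call, wash hands, cook, eat, clean) used by the
validation harness, together with a reconstructed criticality mapping
for the morning-ritual scenario.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .behavior_model import (
    Action,
    BehaviorEpisode,
    EpisodeLike,
    FrequentBehavior,
    InvalidInputError,
    episode_labels,
    occurrence_states,
)
from .shift_detection import CriticalityEntry, CriticalityMap, Modification

CORRUPTION_OPS = ("insert", "delete", "substitute", "swap")


class FixtureLookupError(KeyError):
    """Unknown fixture name."""


@dataclass
class PerturbationSpec:
    """Controlled corruption of an episode.

    ``counts`` gives fixed numbers of corruptions per operation type
    (keyed by the corruption applied: ``delete`` removes an action,
    ``insert`` adds an extra one, ``substitute`` replaces one, ``swap``
    transposes an adjacent pair).  ``rates`` adds a binomial number of
    corruptions per action.  ``action_pool`` supplies labels for
    insertions and substitutions; ``seed`` fixes the full random
    stream.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    rates: Mapping[str, float] = field(default_factory=dict)
    action_pool: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for op in list(self.counts) + list(self.rates):
            if op not in CORRUPTION_OPS:
                raise InvalidInputError(f"unknown corruption op {op!r}")
        if any(c < 0 for c in self.counts.values()):
            raise InvalidInputError("corruption counts must be >= 0")
        if any(not (0.0 <= r <= 1.0) for r in self.rates.values()):
            raise InvalidInputError("corruption rates must be in [0, 1]")


def sample_episode(
    behavior: FrequentBehavior,
    seed: int | np.random.Generator = 0,
    max_length: int = 100,
    episode_id: str | None = None,
) -> BehaviorEpisode:
    """Sample one episode from a chain.

    The start state is drawn from the initial distribution, successors
    from the transition rows, stopping at a terminal state.  A walk
    exceeding ``max_length`` is truncated, flagged on the episode and
    reported as a warning.  The same seed yields the identical episode.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = sorted(behavior.initial_probs.items())
    state = str(rng.choice([s for s, _ in starts], p=[p for _, p in starts]))
    states = [state]
    truncated = False
    while state not in behavior.terminal_states:
        if len(states) >= max_length:
            truncated = True
            _warnings.warn(
                f"episode sampled from {behavior.id!r} truncated at {max_length} actions",
                stacklevel=2,
            )
            break
        succ = sorted(behavior.successors(state))
        state = str(rng.choice([s for s, _ in succ], p=[p for _, p in succ]))
        states.append(state)
    return BehaviorEpisode.from_labels(
        behavior.render(states), kind="observed", episode_id=episode_id,
        truncated=truncated,
    )


def _corruption_plan(spec: PerturbationSpec, n_actions: int,
                     rng: np.random.Generator) -> list[str]:
    ops: list[str] = []
    for op in CORRUPTION_OPS:
        total = int(spec.counts.get(op, 0))
        rate = float(spec.rates.get(op, 0.0))
        if rate > 0:
            total += int(rng.binomial(n_actions, rate))
        ops.extend([op] * total)
    rng.shuffle(ops)
    return ops


def perturb_episode(
    episode: EpisodeLike, spec: PerturbationSpec
) -> tuple[BehaviorEpisode, list[Modification]]:
    """Apply controlled corruptions; return (episode, ground-truth repairs).

    Corruptions are applied sequentially at seeded random positions.
    Each corruption's inverse is recorded as the repair the detector
    should report: a removed action becomes an ``insert`` repair, an
    added one a ``delete``, a replaced one a ``substitute`` back, and a
    transposed pair a ``swap``.  Repair positions refer to the episode
    state at the moment the corruption was applied; when several
    corruptions interact, the (operation, operands) multiset is the
    authoritative ground truth.  Infeasible requests (a swap on a
    single-action episode, a deletion that would empty it, a
    substitution with an empty action pool) raise ``InvalidInputError``.
    """
    seq = list(episode_labels(episode))
    if not seq:
        raise InvalidInputError("cannot perturb an empty episode")
    rng = np.random.default_rng(spec.seed)
    repairs: list[Modification] = []

    for op in _corruption_plan(spec, len(seq), rng):
        if op == "delete":
            if len(seq) < 2:
                raise InvalidInputError("cannot delete from a single-action episode")
            pos = int(rng.integers(len(seq)))
            removed = seq.pop(pos)
            repairs.append(Modification("insert", (removed,), pos))
        elif op == "insert":
            if not spec.action_pool:
                raise InvalidInputError("insert corruption needs an action pool")
            pos = int(rng.integers(len(seq) + 1))
            extra = str(rng.choice(spec.action_pool))
            seq.insert(pos, extra)
            repairs.append(Modification("delete", (extra,), pos))
        elif op == "substitute":
            pos = int(rng.integers(len(seq)))
            alternatives = [a for a in spec.action_pool if a != seq[pos]]
            if not alternatives:
                raise InvalidInputError(
                    "substitute corruption needs an action pool with an alternative"
                )
            original = seq[pos]
            replacement = str(rng.choice(alternatives))
            seq[pos] = replacement
            repairs.append(Modification("substitute", (replacement, original), pos))
        else:  # swap
            candidates = [i for i in range(len(seq) - 1) if seq[i] != seq[i + 1]]
            if not candidates:
                raise InvalidInputError("no distinct adjacent pair available to swap")
            pos = int(rng.choice(candidates))
            seq[pos], seq[pos + 1] = seq[pos + 1], seq[pos]
            repairs.append(Modification("swap", (seq[pos], seq[pos + 1]), pos))

    kind = episode.kind if isinstance(episode, BehaviorEpisode) else "observed"
    eid = episode.episode_id if isinstance(episode, BehaviorEpisode) else None
    return BehaviorEpisode.from_labels(seq, kind=kind, episode_id=eid), repairs


# ---------------------------------------------------------------------------
# fixtures


def linear_behavior(behavior_id: str, labels: Sequence[str]) -> FrequentBehavior:
    """Deterministic chain realizing exactly one action sequence.

    Repeated occurrences of an action become distinct pattern states so
    that sequences revisiting an action (e.g. opening a cabinet twice)
    still form a linear chain.
    """
    labels = tuple(labels)
    if not labels:
        raise InvalidInputError("a linear behavior needs at least one action")
    states = occurrence_states(labels)
    mapping = {st: lbl for st, lbl in zip(states, labels)}
    needs_mapping = any(st != lbl for st, lbl in mapping.items())
    return FrequentBehavior.from_edges(
        id=behavior_id,
        initial_probs={states[0]: 1.0},
        edges=[(frm, to, 1.0) for frm, to in zip(states, states[1:])],
        state_actions=mapping if needs_mapping else None,
        states=states,
    )


_RHO12 = (
    "Alarm, on", "Bathroom, on", "Shower, on", "Shower, off", "Bathroom, off",
    "Kitchen, on", "Breakfast, on", "Pill, on", "Kitchen, off",
)
_RHO11 = (
    "Alarm, on", "Bathroom, on", "Bathroom, off",
    "Kitchen, on", "Breakfast, on", "Pill, on", "Kitchen, off",
)


def _michael_f1() -> FrequentBehavior:
    """The morning-ritual chain: wake, bathroom with an optional shower
    (probability 0.6), breakfast, daily pill, leave the kitchen.

    Branch probabilities are reconstructed from the two realizable
    path likelihoods (0.6 with the shower, 0.4 without); every other
    transition is certain and the single start state has initial
    probability 1.
    """
    return FrequentBehavior.from_edges(
        id="michael_f1",
        initial_probs={"Alarm, on": 1.0},
        edges=[
            ("Alarm, on", "Bathroom, on", 1.0),
            ("Bathroom, on", "Shower, on", 0.6),
            ("Bathroom, on", "Bathroom, off", 0.4),
            ("Shower, on", "Shower, off", 1.0),
            ("Shower, off", "Bathroom, off", 1.0),
            ("Bathroom, off", "Kitchen, on", 1.0),
            ("Kitchen, on", "Breakfast, on", 1.0),
            ("Breakfast, on", "Pill, on", 1.0),
            ("Pill, on", "Kitchen, off", 1.0),
        ],
    )


def _criticality_map_michael() -> CriticalityMap:
    """Criticality mapping for the morning-ritual scenario.

    Reconstructed from the two published outcomes it must reproduce: a
    forgotten daily pill is highly critical (insert 'Pill, on' -> 0.2)
    and taking the pill before breakfast is moderately critical
    (swap 'Pill, on'/'Breakfast, on' -> 0.4); everything else defaults
    to non-critical (1.0).
    """
    return CriticalityMap(
        entries=(
            CriticalityEntry("insert", ("Pill, on",), 0.2),
            CriticalityEntry("swap", ("Pill, on", "Breakfast, on"), 0.4),
        ),
        default_value=1.0,
    )


_ADL_SEQUENCES: dict[str, tuple[str, ...]] = {
    "adl_phone": ("PhoneBook On", "Phone On", "Phone Off"),
    "adl_wash": ("Water On", "Water Off"),
    "adl_cook": (
        "Cabinet On", "Raisins On", "Oatmeal On", "MeasuringSpoon On", "Bowl On",
        "Sugar On", "Cabinet Off", "Water On", "Water Off", "Pot On",
        "Burner On", "Burner Off",
    ),
    "adl_eat": (
        "Cabinet On", "Medicine On", "Cabinet Off", "Water On", "Water Off",
        "Cabinet On", "Medicine Off", "Cabinet Off",
    ),
    "adl_clean": ("Water On", "Water Off"),
}

ADL_NAMES = tuple(_ADL_SEQUENCES)


def _episode(labels: Sequence[str], kind: str, episode_id: str) -> BehaviorEpisode:
    return BehaviorEpisode.from_labels(labels, kind=kind, episode_id=episode_id)


_FIXTURES = {
    "michael_f1": _michael_f1,
    "C1": lambda: _episode(_RHO12, "observed", "C1"),
    "C2": lambda: _episode(
        tuple(lbl for lbl in _RHO12 if lbl != "Pill, on"), "observed", "C2"
    ),
    "C3": lambda: _episode(
        _RHO12[:6] + ("Pill, on", "Breakfast, on") + _RHO12[8:], "observed", "C3"
    ),
    "rho11": lambda: _episode(_RHO11, "path", "rho11"),
    "rho12": lambda: _episode(_RHO12, "path", "rho12"),
    "criticality_map_michael": _criticality_map_michael,
    **{
        name: (lambda n=name: linear_behavior(n, _ADL_SEQUENCES[n]))
        for name in _ADL_SEQUENCES
    },
}


def load_fixture(name: str):
    """Return a built-in fixture by name.

    Chains: ``michael_f1`` and the five linear ADL chains ``adl_phone``,
    ``adl_wash``, ``adl_cook``, ``adl_eat``, ``adl_clean``.  Episodes:
    the observed behaviors ``C1``/``C2``/``C3`` and the two morning-
    ritual paths ``rho11``/``rho12``.  ``criticality_map_michael`` is
    the scenario's criticality mapping.
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return builder()


def sample_adl_corpus(n_episodes: int, seed: int = 17):
    """Sample a labeled corpus from the five ADL chains (uniform mix).

    Returns an :class:`~adlshift.model_learning.EpisodeCorpus` whose
    labels are the ADL fixture names — the synthetic stand-in used by
    the cross-validation harness.
    """
    from .model_learning import EpisodeCorpus  # deferred: model_learning imports us

    if n_episodes < 1:
        raise InvalidInputError("n_episodes must be >= 1")
    rng = np.random.default_rng(seed)
    chains = {name: load_fixture(name) for name in ADL_NAMES}
    episodes = []
    labels = []
    for i in range(n_episodes):
        name = str(rng.choice(ADL_NAMES))
        episodes.append(
            sample_episode(chains[name], rng, episode_id=f"{name}-{i:04d}")
        )
        labels.append(name)
    return EpisodeCorpus(episodes=tuple(episodes), labels=tuple(labels))
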
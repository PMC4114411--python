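"""Estimation of frequent-behavior chains from episode corpora.

This is a frequency-count stand-in for a full pattern-mining learning
layer: actions below a support threshold are dropped, each retained
episode is mapped onto pattern states (repeated occurrences of an
action within an episode become distinct states, as pattern nodes are
distinct even when they share a label), and transition probabilities
are the empirical frequencies of consecutive state pairs.  The module
also provides the adapted cross-validation harness that scores path
matching and modification recovery on held-out episodes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .behavior_model import (
    BehaviorEpisode,
    EpisodeLike,
    FrequentBehavior,
    InvalidInputError,
    ModelValidationError,
    episode_labels,
    occurrence_states,
    validate_behavior,
)
from .config import RunConfig
from .shift_detection import calculate_shifts, modification_signatures
from .synthetic_data import PerturbationSpec, perturb_episode


class EmptyModelError(ValueError):
    """No action in the corpus reaches the support threshold."""


@dataclass
class EpisodeCorpus:
    """A collection of observed episodes, optionally grouped by behavior.

    ``labels[i]`` is the behavior label (e.g. an ADL name) of
    ``episodes[i]``; ``None`` means the corpus is a single unlabeled
    behavior.
    """

    episodes: tuple[BehaviorEpisode, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.episodes:
            raise InvalidInputError("episode corpus is empty")
        if self.labels is not None and len(self.labels) != len(self.episodes):
            raise InvalidInputError(
                f"{len(self.labels)} labels for {len(self.episodes)} episodes"
            )

    def __len__(self) -> int:
        return len(self.episodes)

    def by_label(self) -> dict[str, list[BehaviorEpisode]]:
        if self.labels is None:
            return {"behavior": list(self.episodes)}
        groups: dict[str, list[BehaviorEpisode]] = {}
        for ep, lab in zip(self.episodes, self.labels):
            groups.setdefault(lab, []).append(ep)
        return groups


def learn_behavior(
    corpus: EpisodeCorpus | Sequence[EpisodeLike],
    min_support: float = 0.5,
    behavior_id: str = "learned",
) -> FrequentBehavior:
    """Estimate a frequent-behavior chain by transition counting.

    Actions appearing in fewer than ``min_support`` of the episodes are
    dropped from every episode before counting (keeping the chain
    connected).  States are occurrence-indexed pattern nodes; the
    initial distribution is the empirical distribution of first states,
    transition rows are normalized pair counts, and terminal states are
    those never followed by another action.  Learning is deterministic:
    it only counts.
    """
    if isinstance(corpus, EpisodeCorpus):
        episodes = [episode_labels(ep) for ep in corpus.episodes]
    else:
        episodes = [episode_labels(ep) for ep in corpus]
    if not episodes:
        raise InvalidInputError("episode corpus is empty")
    if not (0.0 < min_support <= 1.0):
        raise InvalidInputError(f"min_support must be in (0, 1], got {min_support}")

    n = len(episodes)
    containing: Counter[str] = Counter()
    for ep in episodes:
        for lbl in set(ep):
            containing[lbl] += 1
    keep = {lbl for lbl, cnt in containing.items() if cnt / n >= min_support - 1e-12}
    if not keep:
        raise EmptyModelError(
            f"no action reaches support {min_support} in {n} episodes"
        )

    encoded = []
    for ep in episodes:
        filtered = tuple(lbl for lbl in ep if lbl in keep)
        if filtered:
            encoded.append((filtered, occurrence_states(filtered)))

    state_order: list[str] = []
    seen: set[str] = set()
    state_label: dict[str, str] = {}
    first_counts: Counter[str] = Counter()
    pair_counts: Counter[tuple[str, str]] = Counter()
    for labels, states in encoded:
        for lbl, st in zip(labels, states):
            if st not in seen:
                seen.add(st)
                state_order.append(st)
                state_label[st] = lbl
        first_counts[states[0]] += 1
        for frm, to in zip(states, states[1:]):
            pair_counts[(frm, to)] += 1

    n_eps = len(encoded)
    initial_probs = {st: cnt / n_eps for st, cnt in first_counts.items()}
    row_totals: Counter[str] = Counter()
    for (frm, _), cnt in pair_counts.items():
        row_totals[frm] += cnt
    transitions = {
        (frm, to): cnt / row_totals[frm] for (frm, to), cnt in pair_counts.items()
    }
    has_out = {frm for frm, _ in transitions}
    terminal = frozenset(st for st in state_order if st not in has_out)
    needs_mapping = any(st != lbl for st, lbl in state_label.items())

    fb = FrequentBehavior(
        id=behavior_id,
        states=tuple(state_order),
        initial_probs=initial_probs,
        transitions=transitions,
        terminal_states=terminal,
        state_actions=state_label if needs_mapping else None,
    )
    violations = validate_behavior(fb)
    if violations:  # pragma: no cover - counting should always normalize
        raise ModelValidationError(
            f"learned behavior violates invariants: {'; '.join(violations)}"
        )
    return fb


@dataclass
class FoldResult:
    fold: int
    n_test: int
    n_matched: int
    n_recovered: int


@dataclass
class ValidationSummary:
    """Outcome of the adapted k-fold cross-validation.

    ``match_rate``: fraction of unperturbed held-out episodes reported
    as matching a path of the learned model with its likelihood.
    ``recovery_rate``: fraction of singly-perturbed held-out episodes
    whose injected corruption is exactly repaired by the reported
    modification set.
    """

    folds: tuple[FoldResult, ...]
    n_episodes: int
    match_rate: float
    recovery_rate: float


def _matched_ok(report, models_by_id, episode) -> bool:
    """Unperturbed episode correctly identified: positive likelihood,
    zero modifications, and the reported likelihood agrees with a direct
    recomputation under the matched model."""
    if not report.matched:
        return False
    best = report.best
    if best is None or best.likelihood <= 0 or best.modification_count != 0:
        return False
    from .behavior_model import episode_likelihood  # local to avoid cycle at import

    direct = episode_likelihood(episode, models_by_id[best.behavior_id])
    return abs(direct - best.likelihood) <= 1e-12


def _recovered(report, ground_truth) -> bool:
    """Perturbed episode correctly repaired: not a path match, the
    minimum modification count equals the ground-truth repair count,
    and some behavior achieving that minimum reports exactly the
    ground-truth operation multiset (positions ignored)."""
    if report.matched:
        return False
    counts = [
        r.modification_count for r in report.results if r.modification_count is not None
    ]
    if not counts:
        return False
    best_count = min(counts)
    truth = modification_signatures(ground_truth)
    if best_count != len(ground_truth):
        return False
    return any(
        r.modification_count == best_count
        and modification_signatures(r.modifications) == truth
        for r in report.results
    )


def cross_validate(
    corpus: EpisodeCorpus,
    folds: int = 10,
    config: RunConfig | None = None,
    min_support: float = 0.5,
    seed: int = 17,
    shuffle: bool = True,
    corruption_ops: Sequence[str] = ("delete", "substitute", "swap"),
) -> ValidationSummary:
    """Adapted k-fold cross-validation of shift identification.

    Per fold: one chain per behavior label is learned from the training
    episodes, then every held-out episode is scored twice — once as-is
    (path-match identification) and once with a single seeded corruption
    injected (modification recovery).  Fold assignment is round-robin
    over a seeded shuffle of the episode order.
    """
    cfg = config or RunConfig()
    n = len(corpus)
    if folds < 2:
        raise InvalidInputError(f"folds must be >= 2, got {folds}")
    if n < folds:
        raise InvalidInputError(f"corpus of {n} episodes cannot fill {folds} folds")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n) if shuffle else np.arange(n)
    assignment = {int(idx): i % folds for i, idx in enumerate(order)}

    labels = corpus.labels if corpus.labels is not None else ("behavior",) * n
    pool = sorted({lbl for ep in corpus.episodes for lbl in ep.labels})

    fold_results: list[FoldResult] = []
    total_matched = total_recovered = total_test = 0
    for fold in range(folds):
        train_idx = [i for i in range(n) if assignment[i] != fold]
        test_idx = [i for i in range(n) if assignment[i] == fold]
        models_by_id: dict[str, FrequentBehavior] = {}
        for lab in sorted({labels[i] for i in train_idx}):
            group = [corpus.episodes[i] for i in train_idx if labels[i] == lab]
            models_by_id[lab] = learn_behavior(group, min_support, behavior_id=lab)
        F = [models_by_id[lab] for lab in sorted(models_by_id)]

        n_matched = n_recovered = 0
        for i in test_idx:
            episode = corpus.episodes[i]
            report = calculate_shifts(F, episode, config=cfg)
            if _matched_ok(report, models_by_id, episode):
                n_matched += 1

            spec = PerturbationSpec(
                counts={str(rng.choice(list(corruption_ops))): 1},
                action_pool=tuple(pool),
                seed=int(rng.integers(2**31)),
            )
            perturbed, truth = perturb_episode(episode, spec)
            pert_report = calculate_shifts(F, perturbed, config=cfg)
            if _recovered(pert_report, truth):
                n_recovered += 1

        fold_results.append(
            FoldResult(fold=fold, n_test=len(test_idx), n_matched=n_matched,
                       n_recovered=n_recovered)
        )
        total_matched += n_matched
        total_recovered += n_recovered
        total_test += len(test_idx)

    return ValidationSummary(
        folds=tuple(fold_results),
        n_episodes=total_test,
        match_rate=total_matched / total_test,
        recovery_rate=total_recovered / total_test,
    )
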
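"""Shift detection: edit-script comparison of an observed episode against
the paths of every frequent behavior, plus criticality and risk scoring.

When an observed episode has zero likelihood under every frequent
behavior, the shift from each behavior is quantified as the minimum set
of modifications — insertions (a forgotten action), deletions (an extra
action), substitutions (one action done instead of another) and swaps
(two actions done in reverse order) — that transforms the episode into
some sufficiently likely path of the chain.  All four operations have
unit cost; the severity of a modification is applied afterwards through
a domain-expert criticality mapping, and a risk factor combines the
modification count with that severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .behavior_model import (
    BehaviorEpisode,
    EpisodeLike,
    FrequentBehavior,
    InvalidInputError,
    enumerate_paths,
    episode_labels,
    episode_likelihood,
)
from .config import RunConfig

OPS = ("insert", "delete", "substitute", "swap")


class InternalConsistencyError(RuntimeError):
    """A distance matrix, episode and path do not belong together."""


@dataclass(frozen=True)
class Modification:
    """One edit operation.

    ``actions`` holds one label for insert/delete, an ordered pair for
    substitute (replaced -> replacement) and the two transposed labels
    (as they appear in the observed episode) for swap.  ``position`` is
    the 0-based index at which the edit applies when the modifications
    of a set are replayed in list order; for a swap it is the index of
    the left element of the pair.
    """

    op: str
    actions: tuple[str, ...]
    position: int

    def __post_init__(self) -> None:
        if self.op not in OPS:
            raise InvalidInputError(f"unknown modification op {self.op!r}")
        arity = 1 if self.op in ("insert", "delete") else 2
        if len(self.actions) != arity:
            raise InvalidInputError(
                f"{self.op} takes {arity} action(s), got {len(self.actions)}"
            )
        if self.position < 0:
            raise InvalidInputError("modification position must be >= 0")

    def signature(self) -> tuple:
        """Operation identity ignoring position; swap operands are unordered."""
        if self.op == "swap":
            return (self.op, tuple(sorted(self.actions)))
        return (self.op, self.actions)

    def describe(self) -> str:
        if self.op in ("insert", "delete"):
            return f"{self.op} ('{self.actions[0]}')"
        if self.op == "substitute":
            return f"substitute ('{self.actions[0]}' -> '{self.actions[1]}')"
        return f"swap ('{self.actions[0]}', '{self.actions[1]}')"


def modification_signatures(mods: Iterable[Modification]) -> tuple:
    """Sorted multiset of operation signatures, for set-level comparison."""
    return tuple(sorted(m.signature() for m in mods))


def apply_modifications(
    episode: EpisodeLike, mods: Sequence[Modification]
) -> tuple[str, ...]:
    """Replay a modification list (in order) on an episode's labels."""
    seq = list(episode_labels(episode))
    for m in mods:
        if m.op == "insert":
            if m.position > len(seq):
                raise InternalConsistencyError(f"insert position {m.position} out of range")
            seq.insert(m.position, m.actions[0])
        elif m.op == "delete":
            if m.position >= len(seq) or seq[m.position] != m.actions[0]:
                raise InternalConsistencyError(f"delete mismatch at {m.position}")
            del seq[m.position]
        elif m.op == "substitute":
            if m.position >= len(seq) or seq[m.position] != m.actions[0]:
                raise InternalConsistencyError(f"substitute mismatch at {m.position}")
            seq[m.position] = m.actions[1]
        else:  # swap
            if m.position + 1 >= len(seq):
                raise InternalConsistencyError(f"swap position {m.position} out of range")
            seq[m.position], seq[m.position + 1] = seq[m.position + 1], seq[m.position]
    return tuple(seq)


@dataclass
class DistanceMatrix:
    """Dynamic-programming grid for the four-operation edit distance.

    ``values[m, n]`` is the minimum number of modifications turning the
    first ``m`` actions of the observed episode into the first ``n``
    actions of the path; the bottom-right cell is the modification
    count.  The source/target label sequences are kept so the backtrace
    can re-derive which operations achieved each minimum.
    """

    values: np.ndarray
    source: tuple[str, ...]
    target: tuple[str, ...]

    @property
    def distance(self) -> int:
        return int(self.values[-1, -1])


def _transposition(
    a: Sequence[str], b: Sequence[str], m: int, n: int
) -> tuple[int, int] | None:
    """Last crossed occurrence (k, l), 1-based, for the transposition case.

    ``k`` is the largest row < m with ``a[k-1] == b[n-1]`` and ``l`` the
    largest column < n with ``b[l-1] == a[m-1]``: the two symbols that a
    transposition (after deleting what lies between them in the episode
    and inserting what lies between them in the path) would align.
    """
    k = next((i for i in range(m - 1, 0, -1) if a[i - 1] == b[n - 1]), 0)
    l = next((j for j in range(n - 1, 0, -1) if b[j - 1] == a[m - 1]), 0)
    if k and l:
        return k, l
    return None


def build_distance_matrix(C: EpisodeLike, path: EpisodeLike) -> DistanceMatrix:
    """Minimum-modification distance matrix between an episode and a path.

    Unit-cost recurrence over {insert, delete, substitute, swap}: a
    match carries the diagonal; otherwise 1 + min(delete, insert,
    substitute).  The swap case uses the unrestricted adjacent-
    transposition form ``d[k-1, l-1] + (m-k-1) + (n-l-1) + 1`` over the
    last crossed occurrences (k, l): the symbols between the transposed
    pair are deleted/inserted so that the pair becomes adjacent when
    the swap is applied.  With unit costs (2·swap >= insert + delete)
    this equals the minimum length of an edit script built from the
    four operations; the restricted "last two symbols crossed" form is
    only an upper bound when a transposed pair is edited again.
    """
    a = episode_labels(C)
    b = episode_labels(path)
    if not a or not b:
        raise InvalidInputError("episodes submitted to the distance matrix must be non-empty")
    la, lb = len(a), len(b)
    d = np.zeros((la + 1, lb + 1), dtype=np.int64)
    d[:, 0] = np.arange(la + 1)
    d[0, :] = np.arange(lb + 1)
    for m in range(1, la + 1):
        for n in range(1, lb + 1):
            best = d[m - 1, n - 1] + (0 if a[m - 1] == b[n - 1] else 1)
            best = min(best, d[m - 1, n] + 1)  # delete an extra action
            best = min(best, d[m, n - 1] + 1)  # insert a forgotten action
            kl = _transposition(a, b, m, n)
            if kl is not None:
                k, l = kl
                best = min(best, d[k - 1, l - 1] + (m - k - 1) + (n - l - 1) + 1)
            d[m, n] = best
    return DistanceMatrix(values=d, source=a, target=b)


def backtrace_modifications(
    D: DistanceMatrix, C: EpisodeLike, path: EpisodeLike
) -> list[Modification]:
    """Extract a minimum modification set from a distance matrix.

    Walks the matrix from the bottom-right cell, preferring at equal
    cost: match > swap > substitution > deletion > insertion (a fixed
    order so results are deterministic).  The returned list has exactly
    ``D.distance`` modifications and, replayed in order on the observed
    episode, reproduces the path — both are verified before returning.
    """
    a = episode_labels(C)
    b = episode_labels(path)
    if a != D.source or b != D.target:
        raise InternalConsistencyError("distance matrix was built from different sequences")
    rebuilt = build_distance_matrix(a, b)
    if not np.array_equal(rebuilt.values, D.values):
        raise InternalConsistencyError("distance matrix values are inconsistent")

    d = D.values
    mods: list[Modification] = []
    m, n = len(a), len(b)
    while (m, n) != (0, 0):
        cell = d[m, n]
        if m > 0 and n > 0 and a[m - 1] == b[n - 1] and cell == d[m - 1, n - 1]:
            m, n = m - 1, n - 1
            continue
        kl = _transposition(a, b, m, n) if (m > 0 and n > 0) else None
        if kl is not None:
            k, l = kl
            if cell == d[k - 1, l - 1] + (m - k - 1) + (n - l - 1) + 1:
                # delete episode symbols strictly between the transposed pair
                for pos in range(m - 2, k - 1, -1):
                    mods.append(Modification("delete", (a[pos],), pos))
                # the pair is now adjacent at (k-1, k)
                mods.append(Modification("swap", (a[k - 1], a[m - 1]), k - 1))
                # insert the path symbols that belong between the pair
                for j in range(n - 2, l - 1, -1):
                    mods.append(Modification("insert", (b[j],), k))
                m, n = k - 1, l - 1
                continue
        if m > 0 and n > 0 and cell == d[m - 1, n - 1] + 1:
            mods.append(Modification("substitute", (a[m - 1], b[n - 1]), m - 1))
            m, n = m - 1, n - 1
        elif m > 0 and cell == d[m - 1, n] + 1:
            mods.append(Modification("delete", (a[m - 1],), m - 1))
            m = m - 1
        elif n > 0 and cell == d[m, n - 1] + 1:
            mods.append(Modification("insert", (b[n - 1],), m))
            n = n - 1
        else:  # pragma: no cover - unreachable on a consistent matrix
            raise InternalConsistencyError(f"no admissible move at cell ({m}, {n})")

    if len(mods) != D.distance:
        raise InternalConsistencyError(
            f"backtrace produced {len(mods)} modifications, matrix says {D.distance}"
        )
    if apply_modifications(a, mods) != b:
        raise InternalConsistencyError("replaying the modification set does not yield the path")
    return mods


# ---------------------------------------------------------------------------
# criticality and risk


@dataclass(frozen=True)
class CriticalityEntry:
    """One rule of a criticality mapping.

    ``actions=None`` is an operation-level wildcard matching any
    operands.  Values lie in [0, 1]; lower means more critical.
    """

    op: str
    actions: tuple[str, ...] | None
    value: float

    def __post_init__(self) -> None:
        if self.op not in OPS:
            raise InvalidInputError(f"unknown op {self.op!r} in criticality entry")
        if not (0.0 <= self.value <= 1.0):
            raise InvalidInputError(f"criticality value {self.value} outside [0, 1]")

    def matches(self, mod: Modification) -> bool:
        if self.op != mod.op:
            return False
        if self.actions is None:
            return True
        if self.op == "swap":  # a transposition has no canonical operand order
            return tuple(sorted(self.actions)) == tuple(sorted(mod.actions))
        return self.actions == mod.actions


@dataclass
class CriticalityMap:
    """Expert-supplied severity mapping g from modifications to [0, 1].

    Matching is most-specific-wins: an exact (op + operands) entry beats
    an op-level wildcard, which beats ``default_value``.
    """

    entries: tuple[CriticalityEntry, ...] = ()
    default_value: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.default_value <= 1.0):
            raise InvalidInputError(
                f"default criticality {self.default_value} outside [0, 1]"
            )

    def value_for(self, mod: Modification) -> float:
        wildcard: float | None = None
        for entry in self.entries:
            if entry.matches(mod):
                if entry.actions is not None:
                    return entry.value
                if wildcard is None:
                    wildcard = entry.value
        return wildcard if wildcard is not None else self.default_value


def criticality(
    M: Sequence[Modification],
    cmap: CriticalityMap | None = None,
    aggregation: str = "min",
) -> float:
    """Criticality of a modification set.

    Aggregates g over the set; with the default ``min`` the most
    critical member dominates.  An empty set has criticality 1.0 (no
    modification, nothing critical).
    """
    if cmap is None:
        cmap = CriticalityMap()
    if not M:
        return 1.0
    values = [cmap.value_for(m) for m in M]
    if aggregation == "min":
        return min(values)
    if aggregation == "product":
        out = 1.0
        for v in values:
            out *= v
        return out
    if aggregation == "mean":
        return float(sum(values)) / len(values)
    raise InvalidInputError(f"unknown criticality aggregation {aggregation!r}")


def risk_factor(modification_count: int, criticality_value: float) -> float:
    """Behavior risk factor: phi = count * (1 - criticality).

    Zero for a matching behavior (no modifications); grows with the
    number of modifications and with their severity (lower criticality
    value).  Fully non-critical edits (criticality 1) contribute no
    risk.
    """
    if modification_count < 0:
        raise InvalidInputError("modification count must be >= 0")
    if not (0.0 <= criticality_value <= 1.0):
        raise InvalidInputError(f"criticality {criticality_value} outside [0, 1]")
    return float(modification_count) * (1.0 - criticality_value)


# ---------------------------------------------------------------------------
# the driver


@dataclass
class BehaviorShift:
    """Shift of one observed episode from one frequent behavior."""

    behavior_id: str
    likelihood: float
    best_path: tuple[str, ...] | None = None
    path_likelihood: float | None = None
    modifications: tuple[Modification, ...] = ()
    modification_count: int | None = None
    criticality: float | None = None
    risk_factor: float | None = None
    anomalous: bool | None = None
    warnings: tuple[str, ...] = ()


@dataclass
class ShiftReport:
    """Result of comparing one observed episode against all frequent behaviors."""

    episode_id: str | None
    matched: bool
    results: tuple[BehaviorShift, ...]
    anomalous: bool
    warnings: tuple[str, ...] = ()

    @property
    def best(self) -> BehaviorShift | None:
        """The least-shifted behavior: matched one, else minimum
        (modification count, -path likelihood, criticality)."""
        if self.matched:
            for r in self.results:
                if r.likelihood > 0:
                    return r
        scored = [r for r in self.results if r.modification_count is not None]
        if not scored:
            return None
        return min(
            scored,
            key=lambda r: (
                r.modification_count,
                -(r.path_likelihood or 0.0),
                r.criticality if r.criticality is not None else 1.0,
            ),
        )


def calculate_shifts(
    F: Sequence[FrequentBehavior],
    C: EpisodeLike,
    cmap: CriticalityMap | None = None,
    config: RunConfig | None = None,
) -> ShiftReport:
    """Compare an observed episode against every frequent behavior.

    Computes the likelihood of the episode under each chain.  If any
    likelihood is positive the episode is a frequent behavior: the
    report carries that likelihood with zero modifications and no
    edit-distance work is done.  Otherwise every behavior's paths are
    enumerated and, for each behavior, the path needing the fewest
    modifications is selected (ties broken by higher path likelihood,
    then lower criticality); criticality, risk factor and the anomaly
    flag are filled per behavior.  A behavior with no enumerable path
    is skipped with a warning in the report.  The episode is anomalous
    when even the least risky behavior exceeds the anomaly threshold.
    """
    if not F:
        raise InvalidInputError("no frequent behaviors supplied")
    labels = episode_labels(C)
    if not labels:
        raise InvalidInputError("observed episode is empty")
    cfg = config or RunConfig()
    if cmap is None:
        cmap = CriticalityMap()
    episode_id = C.episode_id if isinstance(C, BehaviorEpisode) else None

    likelihoods = [
        episode_likelihood(labels, f, include_initial_prob=cfg.include_initial_prob)
        for f in F
    ]

    if any(ll > 0 for ll in likelihoods):
        results = []
        for f, ll in zip(F, likelihoods):
            if ll > 0:
                results.append(
                    BehaviorShift(
                        behavior_id=f.id,
                        likelihood=ll,
                        best_path=labels,
                        path_likelihood=ll,
                        modifications=(),
                        modification_count=0,
                        criticality=1.0,
                        risk_factor=0.0,
                        anomalous=False,
                    )
                )
            else:
                results.append(BehaviorShift(behavior_id=f.id, likelihood=ll))
        return ShiftReport(
            episode_id=episode_id, matched=True, results=tuple(results), anomalous=False
        )

    results = []
    report_warnings: list[str] = []
    for f, ll in zip(F, likelihoods):
        path_set = enumerate_paths(f, cfg.path_threshold, cfg.max_path_length)
        if not path_set.paths:
            warn = path_set.warnings or (f"behavior {f.id!r}: no paths to compare",)
            report_warnings.extend(warn)
            results.append(BehaviorShift(behavior_id=f.id, likelihood=ll, warnings=warn))
            continue
        best: BehaviorShift | None = None
        best_key: tuple | None = None
        for path_episode, pll in path_set.paths:
            D = build_distance_matrix(labels, path_episode.labels)
            mods = backtrace_modifications(D, labels, path_episode.labels)
            cr = criticality(mods, cmap, cfg.criticality_aggregation)
            key = (D.distance, -pll, cr)
            if best_key is None or key < best_key:
                best_key = key
                best = BehaviorShift(
                    behavior_id=f.id,
                    likelihood=ll,
                    best_path=path_episode.labels,
                    path_likelihood=pll,
                    modifications=tuple(mods),
                    modification_count=D.distance,
                    criticality=cr,
                )
        assert best is not None
        phi = risk_factor(best.modification_count, best.criticality)
        best.risk_factor = phi
        best.anomalous = phi > cfg.anomaly_threshold
        results.append(best)

    phis = [r.risk_factor for r in results if r.risk_factor is not None]
    anomalous = bool(phis) and min(phis) > cfg.anomaly_threshold
    return ShiftReport(
        episode_id=episode_id,
        matched=False,
        results=tuple(results),
        anomalous=anomalous,
        warnings=tuple(report_warnings),
    )
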
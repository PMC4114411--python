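"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the edit
distance is recomputed by bidirectional breadth-first search over edit
scripts, path enumeration by exhaustive generation of label sequences,
and likelihoods by direct probability lookups.
"""

from __future__ import annotations

import itertools

import numpy as np


def edit_neighbors(s: tuple, alphabet, ops=("insert", "delete", "substitute", "swap")):
    """All sequences reachable from ``s`` by one edit operation."""
    out = set()
    if "insert" in ops:
        for i in range(len(s) + 1):
            for a in alphabet:
                out.add(s[:i] + (a,) + s[i:])
    if "delete" in ops:
        for i in range(len(s)):
            out.add(s[:i] + s[i + 1:])
    if "substitute" in ops:
        for i in range(len(s)):
            for a in alphabet:
                if a != s[i]:
                    out.add(s[:i] + (a,) + s[i + 1:])
    if "swap" in ops:
        for i in range(len(s) - 1):
            if s[i] != s[i + 1]:
                out.add(s[:i] + (s[i + 1], s[i]) + s[i + 2:])
    return out


def script_distance(s: tuple, t: tuple, alphabet,
                    ops=("insert", "delete", "substitute", "swap")) -> int:
    """Minimum number of unit-cost edit operations turning s into t.

    Bidirectional BFS; valid because every operation is invertible at
    equal cost (insert/delete are mutual inverses, substitute and swap
    are self-inverse).
    """
    s, t = tuple(s), tuple(t)
    if s == t:
        return 0
    front, back = {s: 0}, {t: 0}
    cur_f, cur_b = {s}, {t}
    while True:
        if len(cur_f) <= len(cur_b):
            grow, other, cur = front, back, cur_f
        else:
            grow, other, cur = back, front, cur_b
        nxt = {}
        for x in cur:
            for n in edit_neighbors(x, alphabet, ops):
                if n not in grow:
                    nxt[n] = grow[x] + 1
        grow.update(nxt)
        if grow is front:
            cur_f = set(nxt)
        else:
            cur_b = set(nxt)
        hits = [grow[n] + other[n] for n in nxt if n in other]
        if hits:
            return min(hits)
        if not nxt:  # pragma: no cover - cannot happen over a shared alphabet
            raise RuntimeError("search exhausted without meeting")


def exhaustive_paths(behavior, threshold: float, max_length: int):
    """All complete start-to-terminal label sequences above threshold,
    by brute-force generation over every state sequence up to the cap."""
    found = []
    for length in range(1, max_length + 1):
        for combo in itertools.product(behavior.states, repeat=length):
            if behavior.initial_probs.get(combo[0], 0.0) <= 0.0:
                continue
            if combo[-1] not in behavior.terminal_states:
                continue
            ll, ok = 1.0, True
            for frm, to in zip(combo, combo[1:]):
                p = behavior.transition_prob(frm, to)
                if p <= 0.0:
                    ok = False
                    break
                ll *= p
            if ok and ll + 1e-9 >= threshold:
                found.append((behavior.render(combo), ll))
    return found


def likelihood_by_lookup(labels, behavior, include_initial_prob=False) -> float:
    """Episode likelihood by direct matrix lookups (plain-label chains only)."""
    labels = tuple(labels)
    states = set(behavior.states)
    if any(lbl not in states for lbl in labels):
        return 0.0
    if behavior.initial_probs.get(labels[0], 0.0) <= 0.0:
        return 0.0
    if labels[-1] not in behavior.terminal_states:
        return 0.0
    ll = behavior.initial_probs[labels[0]] if include_initial_prob else 1.0
    for frm, to in zip(labels, labels[1:]):
        p = behavior.transitions.get((frm, to), 0.0)
        if p <= 0.0:
            return 0.0
        ll *= p
    return ll


def random_dag_chain(rng: np.random.Generator, n_states: int = 5, chain_id: str = "rand"):
    """A random acyclic stochastic chain: edges only go to higher-indexed
    states, so the last state is terminal and every walk halts."""
    from adlshift.behavior_model import FrequentBehavior

    states = [f"s{i}" for i in range(n_states)]
    edges = []
    for i in range(n_states - 1):
        targets = list(range(i + 2, n_states))
        n_out = int(rng.integers(0, min(2, len(targets)) + 1))
        extra = rng.choice(targets, size=n_out, replace=False) if n_out else []
        # always link i -> i+1 so every state is reachable from the start
        chosen = sorted({i + 1, *map(int, extra)})
        probs = rng.dirichlet(np.ones(len(chosen)))
        # renormalize exactly so invariants hold at 1e-9
        probs = probs / probs.sum()
        probs[-1] = 1.0 - probs[:-1].sum()
        for j, p in zip(chosen, probs):
            edges.append((states[i], states[j], float(p)))
    return FrequentBehavior.from_edges(
        id=chain_id, initial_probs={states[0]: 1.0}, edges=edges
    )


def random_loopy_chain(rng: np.random.Generator, n_states: int = 4, chain_id: str = "loopy"):
    """A random chain that may contain loops; the last state is terminal."""
    from adlshift.behavior_model import FrequentBehavior

    states = [f"s{i}" for i in range(n_states)]
    edges = []
    for i in range(n_states - 1):
        targets = [j for j in range(n_states) if j != n_states - 1] + [n_states - 1]
        n_out = int(rng.integers(1, 4))
        chosen = list(rng.choice(targets, size=n_out, replace=False))
        if rng.random() < 0.5 and (n_states - 1) not in chosen:
            chosen[-1] = n_states - 1  # keep the terminal reachable often
        probs = rng.dirichlet(np.ones(len(chosen)))
        probs = probs / probs.sum()
        probs[-1] = 1.0 - probs[:-1].sum()
        for j, p in zip(chosen, probs):
            edges.append((states[i], states[j], float(p)))
    return FrequentBehavior.from_edges(
        id=chain_id, initial_probs={states[0]: 1.0}, edges=edges
    )
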
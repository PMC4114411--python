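"""File formats: event logs, model JSON, criticality maps, reports.

Event logs are CSV (header ``timestamp,entity,state`` with an optional
``episode_id`` and ``behavior`` column; episodes are split on
``episode_id`` change or on blank lines) or JSON-lines records
``{"t": ..., "action": "<entity>, <state>", ...}``.  Models and reports
round-trip through JSON (write ∘ read = identity).
"""

from __future__ import annotations

import dataclasses
import json
import warnings as _warnings
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .behavior_model import (
    BehaviorEpisode,
    FrequentBehavior,
    InvalidInputError,
    normalize_label,
)
from .config import RunConfig
from .model_learning import EpisodeCorpus
from .shift_detection import (
    CriticalityEntry,
    CriticalityMap,
    Modification,
    ShiftReport,
)


class EventLogError(InvalidInputError):
    """Malformed or empty event log; message names the offending line."""


def _label_from_row(entity: object, state: object) -> str:
    entity = "" if entity is None or (isinstance(entity, float) and pd.isna(entity)) else str(entity)
    state = "" if state is None or (isinstance(state, float) and pd.isna(state)) else str(state)
    if not entity.strip():
        raise InvalidInputError("missing entity")
    if state.strip():
        return normalize_label(f"{entity}, {state}")
    return normalize_label(entity)


def _split_label(label: str) -> tuple[str, str]:
    if ", " in label:
        entity, state = label.rsplit(", ", 1)
        return entity, state
    return label, ""


def _coerce_timestamp(value: object):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return pd.to_datetime(value)


def _finalize_episode(rows: list[tuple], episode_id: str | None,
                      path: Path) -> tuple[BehaviorEpisode, str | None]:
    # rows: (timestamp, label, behavior)
    times = [t for t, _, _ in rows]
    if all(t is not None for t in times) and any(
        later < earlier for earlier, later in zip(times, times[1:])
    ):
        _warnings.warn(
            f"{path}: episode {episode_id or '<anonymous>'} has out-of-order "
            "timestamps; sorting",
            stacklevel=3,
        )
        rows = sorted(rows, key=lambda r: r[0])
    behaviors = {b for _, _, b in rows if b}
    behavior = behaviors.pop() if len(behaviors) == 1 else None
    episode = BehaviorEpisode.from_labels(
        [lbl for _, lbl, _ in rows], kind="observed", episode_id=episode_id
    )
    return episode, behavior


def read_event_log(path: str | Path) -> EpisodeCorpus:
    """Read an event log (CSV or JSON-lines, by extension) into a corpus.

    Episodes are split on ``episode_id`` change when that column is
    present, otherwise on blank lines.  Actions are ordered by
    timestamp within an episode (out-of-order rows are sorted with a
    warning).  Raises :class:`EventLogError` naming the line for
    malformed rows and for an empty log.
    """
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        raw = _read_jsonl(path)
    else:
        raw = _read_csv(path)
    if not raw:
        raise EventLogError(f"{path}: event log contains no actions")

    episodes: list[BehaviorEpisode] = []
    behaviors: list[str | None] = []
    current: list[tuple] = []
    current_id: str | None = None
    for record in raw:
        if record is None:  # blank-line delimiter
            if current:
                ep, beh = _finalize_episode(current, current_id, path)
                episodes.append(ep)
                behaviors.append(beh)
                current, current_id = [], None
            continue
        timestamp, label, episode_id, behavior = record
        if current and episode_id != current_id and (episode_id or current_id):
            ep, beh = _finalize_episode(current, current_id, path)
            episodes.append(ep)
            behaviors.append(beh)
            current = []
        current_id = episode_id
        current.append((timestamp, label, behavior))
    if current:
        ep, beh = _finalize_episode(current, current_id, path)
        episodes.append(ep)
        behaviors.append(beh)

    labels = None
    if any(b is not None for b in behaviors):
        labels = tuple(b if b is not None else "" for b in behaviors)
    return EpisodeCorpus(episodes=tuple(episodes), labels=labels)


def _read_csv(path: Path) -> list:
    try:
        df = pd.read_csv(path, skip_blank_lines=False, dtype=str)
    except pd.errors.EmptyDataError:
        raise EventLogError(f"{path}: event log is empty") from None
    required = {"timestamp", "entity", "state"}
    missing = required - set(df.columns)
    if missing:
        raise EventLogError(f"{path}: missing columns {sorted(missing)}")
    records: list = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        if row.isna().all():
            records.append(None)
            continue
        try:
            label = _label_from_row(row["entity"], row["state"])
            timestamp = _coerce_timestamp(row["timestamp"])
        except (InvalidInputError, ValueError) as exc:
            raise EventLogError(f"{path}: malformed row at line {line_no}: {exc}") from None
        episode_id = row.get("episode_id")
        episode_id = None if pd.isna(episode_id) else str(episode_id)
        behavior = row.get("behavior")
        behavior = None if pd.isna(behavior) else str(behavior)
        records.append((timestamp, label, episode_id, behavior))
    return records


def _read_jsonl(path: Path) -> list:
    records: list = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                records.append(None)
                continue
            try:
                obj = json.loads(line)
                label = normalize_label(obj["action"])
                timestamp = _coerce_timestamp(obj.get("t"))
            except (KeyError, ValueError, TypeError) as exc:
                raise EventLogError(
                    f"{path}: malformed record at line {line_no}: {exc}"
                ) from None
            episode_id = obj.get("episode_id")
            episode_id = None if episode_id is None else str(episode_id)
            behavior = obj.get("behavior")
            behavior = None if behavior is None else str(behavior)
            records.append((timestamp, label, episode_id, behavior))
    return records


def write_event_log(corpus: EpisodeCorpus, path: str | Path) -> None:
    """Write a corpus as event-log CSV (with ``episode_id``, and a
    ``behavior`` column when the corpus is grouped)."""
    path = Path(path)
    rows = []
    for i, episode in enumerate(corpus.episodes):
        episode_id = episode.episode_id or f"ep{i:05d}"
        behavior = corpus.labels[i] if corpus.labels is not None else None
        for t, action in enumerate(episode.actions):
            entity, state = _split_label(action.label)
            row = {
                "timestamp": action.timestamp if action.timestamp is not None else t,
                "entity": entity,
                "state": state,
                "episode_id": episode_id,
            }
            if behavior is not None:
                row["behavior"] = behavior
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# models


def model_to_dict(behavior: FrequentBehavior) -> dict[str, Any]:
    out: dict[str, Any] = {
        "id": behavior.id,
        "states": list(behavior.states),
        "initial_probs": dict(behavior.initial_probs),
        "transitions": [
            {"from": frm, "to": to, "p": p}
            for (frm, to), p in behavior.transitions.items()
        ],
        "terminal_states": sorted(behavior.terminal_states),
    }
    if behavior.state_actions is not None:
        out["state_actions"] = dict(behavior.state_actions)
    return out


def model_from_dict(data: Mapping[str, Any]) -> FrequentBehavior:
    return FrequentBehavior(
        id=str(data["id"]),
        states=tuple(data["states"]),
        initial_probs={str(k): float(v) for k, v in data["initial_probs"].items()},
        transitions={
            (str(t["from"]), str(t["to"])): float(t["p"]) for t in data["transitions"]
        },
        terminal_states=frozenset(data["terminal_states"]),
        state_actions=(
            {str(k): str(v) for k, v in data["state_actions"].items()}
            if data.get("state_actions")
            else None
        ),
    )


def write_models(
    behaviors: FrequentBehavior | Sequence[FrequentBehavior], path: str | Path
) -> None:
    if isinstance(behaviors, FrequentBehavior):
        payload: Any = model_to_dict(behaviors)
    else:
        payload = [model_to_dict(b) for b in behaviors]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


write_model = write_models


def read_models(path: str | Path) -> list[FrequentBehavior]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if isinstance(data, list):
        return [model_from_dict(d) for d in data]
    return [model_from_dict(data)]


def read_model(path: str | Path) -> FrequentBehavior:
    models = read_models(path)
    if len(models) != 1:
        raise InvalidInputError(f"{path} holds {len(models)} models, expected exactly 1")
    return models[0]


# ---------------------------------------------------------------------------
# criticality maps


def read_criticality_map(path: str | Path) -> CriticalityMap:
    """Load a criticality map: either a JSON list of
    ``{"op", "actions"?, "value"}`` entries or an object with
    ``entries`` and ``default_value``."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if isinstance(data, list):
        entries_data, default = data, 1.0
    else:
        entries_data = data.get("entries", [])
        default = float(data.get("default_value", 1.0))
    entries = []
    for i, entry in enumerate(entries_data):
        try:
            actions = entry.get("actions")
            entries.append(
                CriticalityEntry(
                    op=str(entry["op"]),
                    actions=tuple(normalize_label(a) for a in actions)
                    if actions is not None
                    else None,
                    value=float(entry["value"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise InvalidInputError(
                f"{path}: invalid criticality entry {i}: {exc}"
            ) from None
    return CriticalityMap(entries=tuple(entries), default_value=default)


def write_criticality_map(cmap: CriticalityMap, path: str | Path) -> None:
    payload = {
        "default_value": cmap.default_value,
        "entries": [
            {"op": e.op, "actions": list(e.actions) if e.actions is not None else None,
             "value": e.value}
            for e in cmap.entries
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# reports


def report_to_dict(report: ShiftReport) -> dict[str, Any]:
    return {
        "episode_id": report.episode_id,
        "matched": report.matched,
        "anomalous": report.anomalous,
        "warnings": list(report.warnings),
        "results": [
            {
                "behavior_id": r.behavior_id,
                "likelihood": r.likelihood,
                "best_path": list(r.best_path) if r.best_path is not None else None,
                "path_likelihood": r.path_likelihood,
                "modifications": [dataclasses.asdict(m) for m in r.modifications],
                "modification_count": r.modification_count,
                "criticality": r.criticality,
                "risk_factor": r.risk_factor,
                "anomalous": r.anomalous,
                "warnings": list(r.warnings),
            }
            for r in report.results
        ],
    }


def write_report(
    reports: ShiftReport | Sequence[ShiftReport],
    path: str | Path,
    config: RunConfig | None = None,
    text_path: str | Path | None = None,
) -> None:
    """Write shift reports as JSON (with a run header recording config,
    seed and library version) and optionally a text rendering."""
    if isinstance(reports, ShiftReport):
        reports = [reports]
    cfg = config or RunConfig()
    payload = {
        "adlshift_version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "reports": [report_to_dict(r) for r in reports],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    if text_path is not None:
        text = "\n".join(render_report_text(r) for r in reports)
        Path(text_path).write_text(text, encoding="utf-8")


def render_report_text(report: ShiftReport) -> str:
    """Human-readable rendering of one episode's shift report."""
    lines = [f"Episode: {report.episode_id or '<anonymous>'}"]
    if report.matched:
        best = report.best
        lines.append(
            f"  Current behavior matches frequent behavior '{best.behavior_id}' "
            f"with likelihood {best.likelihood:g}."
        )
        lines.append("  No modification is needed.")
    else:
        lines.append("  Current behavior does not match any frequent behavior (likelihood 0).")
        best = report.best
        if best is None:
            lines.append("  No paths were available for comparison.")
        else:
            lines.append(
                f"  Closest frequent behavior: '{best.behavior_id}', path "
                f"{' -> '.join(best.best_path)} (likelihood {best.path_likelihood:g})."
            )
            lines.append(
                f"  Necessary modifications ({best.modification_count}): "
                + (
                    "; ".join(m.describe() for m in best.modifications)
                    if best.modifications
                    else "none"
                )
            )
            lines.append(
                f"  Criticality: {best.criticality:g}   "
                f"Risk factor: {best.risk_factor:g}   "
                f"Anomalous: {'yes' if report.anomalous else 'no'}"
            )
    for warning in report.warnings:
        lines.append(f"  Warning: {warning}")
    return "\n".join(lines) + "\n"
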
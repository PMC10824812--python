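"""Marked point configuration of lesions and event bookkeeping.

The system state at time t is the point measure ν(t) = Σ_i δ_{(q_i, s_i)}
over positions q_i ∈ Q̄ and marks s_i ∈ {X, Y}: X are sub-lethal (repairable)
lesions, Y are lethal ones.  Lesions carry stable integer ids used only for
bookkeeping — they never enter any rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TYPE_X",
    "TYPE_Y",
    "SystemState",
    "EventRecord",
    "apply_event",
    "counts_series",
    "state_to_frame",
    "frame_to_state",
    "events_to_frame",
]

TYPE_X = 0
TYPE_Y = 1
_TYPE_NAMES = {TYPE_X: "X", TYPE_Y: "Y"}
_TYPE_CODES = {"X": TYPE_X, "Y": TYPE_Y}

#: consumed-X / produced stoichiometry of each jump channel
CHANNEL_STOICHIOMETRY = {
    "repair": (1, 0, 0),       # (consumed X, produced X, produced Y)
    "death": (1, 0, 1),
    "pair_lethal": (2, 0, 1),
    "pair_repair": (2, 0, 0),
    "dose": (0, None, None),   # dose produces ξ^X + ξ^Y lesions
}


@dataclass(frozen=True)
class EventRecord:
    """One jump of the process: which channel fired, what it consumed/made."""

    time: float
    channel: str
    consumed_ids: tuple[int, ...]
    produced: tuple[tuple[int, np.ndarray], ...]  # (type code, position)

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_STOICHIOMETRY:
            raise ValueError(f"unknown channel {self.channel!r}")
        nx, px, py = CHANNEL_STOICHIOMETRY[self.channel]
        if len(self.consumed_ids) != nx:
            raise ValueError(f"{self.channel} must consume {nx} lesions")
        if px is not None:
            got_x = sum(1 for t, _ in self.produced if t == TYPE_X)
            got_y = sum(1 for t, _ in self.produced if t == TYPE_Y)
            if (got_x, got_y) != (px, py):
                raise ValueError(
                    f"{self.channel} must produce {px} X and {py} Y lesions"
                )


@dataclass(frozen=True)
class SystemState:
    """Lesion configuration ν at one time point (array-of-structs layout)."""

    time: float
    ids: np.ndarray          # (N,) int64, unique
    types: np.ndarray        # (N,) int8, TYPE_X / TYPE_Y
    positions: np.ndarray    # (N, d) float
    next_id: int

    @classmethod
    def empty(cls, dimension: int, time: float = 0.0) -> "SystemState":
        return cls(
            time=time,
            ids=np.empty(0, dtype=np.int64),
            types=np.empty(0, dtype=np.int8),
            positions=np.empty((0, dimension)),
            next_id=0,
        )

    @classmethod
    def from_positions(
        cls,
        x_positions: np.ndarray,
        y_positions: np.ndarray | None = None,
        time: float = 0.0,
    ) -> "SystemState":
        """Build a state from raw X (and optionally Y) position arrays."""
        xp = np.atleast_2d(np.asarray(x_positions, float))
        if xp.size == 0:
            xp = xp.reshape(0, xp.shape[-1] if xp.ndim == 2 else 2)
        yp = (
            np.atleast_2d(np.asarray(y_positions, float))
            if y_positions is not None and len(np.atleast_1d(y_positions))
            else np.empty((0, xp.shape[1] if xp.size else 2))
        )
        pos = np.vstack([xp, yp]) if xp.size or yp.size else xp
        n_x, n_y = len(xp), len(yp)
        types = np.concatenate(
            [np.full(n_x, TYPE_X, np.int8), np.full(n_y, TYPE_Y, np.int8)]
        )
        return cls(
            time=time,
            ids=np.arange(n_x + n_y, dtype=np.int64),
            types=types,
            positions=pos,
            next_id=n_x + n_y,
        )

    @property
    def n_total(self) -> int:
        return len(self.ids)

    @property
    def n_x(self) -> int:
        return int(np.count_nonzero(self.types == TYPE_X))

    @property
    def n_y(self) -> int:
        return int(np.count_nonzero(self.types == TYPE_Y))

    def positions_of(self, type_code: int) -> np.ndarray:
        return self.positions[self.types == type_code]

    def validate(self) -> None:
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("lesion ids are not distinct")
        if len(self.ids) and self.next_id <= int(self.ids.max()):
            raise ValueError("next_id must exceed every existing id")


class StateConsistencyError(RuntimeError):
    """An event referenced lesions the state does not hold — a simulator bug."""


def apply_event(state: SystemState, event: EventRecord) -> SystemState:
    """Apply one jump to the configuration, returning the new state.

    Consumed ids must exist and be of type X; produced lesions get fresh ids.
    """
    ids, types, pos = state.ids, state.types, state.positions
    keep = np.ones(len(ids), bool)
    for cid in event.consumed_ids:
        idx = np.flatnonzero(ids == cid)
        if idx.size != 1:
            raise StateConsistencyError(f"consumed id {cid} not present exactly once")
        if types[idx[0]] != TYPE_X:
            raise StateConsistencyError(f"consumed lesion {cid} is not of type X")
        keep[idx[0]] = False
    new_ids = [ids[keep]]
    new_types = [types[keep]]
    new_pos = [pos[keep]]
    nid = state.next_id
    for tcode, q in event.produced:
        new_ids.append(np.array([nid], np.int64))
        new_types.append(np.array([tcode], np.int8))
        new_pos.append(np.atleast_2d(np.asarray(q, float)))
        nid += 1
    return SystemState(
        time=event.time,
        ids=np.concatenate(new_ids),
        types=np.concatenate(new_types),
        positions=np.vstack(new_pos),
        next_id=nid,
    )


def counts_series(initial: SystemState, events: list[EventRecord]) -> pd.DataFrame:
    """Piecewise-constant (N^X, N^Y) count paths from replaying an event log.

    The first row is the initial state; each subsequent row is the count
    immediately after an event.
    """
    n_x, n_y = initial.n_x, initial.n_y
    rows = [(initial.time, n_x, n_y)]
    last_t = initial.time
    for ev in events:
        if ev.time < last_t:
            raise StateConsistencyError("event log is not time-ordered")
        last_t = ev.time
        nx_cons, px, py = CHANNEL_STOICHIOMETRY[ev.channel]
        n_x -= nx_cons
        if px is None:
            n_x += sum(1 for t, _ in ev.produced if t == TYPE_X)
            n_y += sum(1 for t, _ in ev.produced if t == TYPE_Y)
        else:
            n_x += px
            n_y += py
        if n_x < 0 or n_y < 0:
            raise StateConsistencyError("negative lesion count while replaying log")
        rows.append((ev.time, n_x, n_y))
    return pd.DataFrame(rows, columns=["t_h", "n_x", "n_y"])


# ---------------------------------------------------------------------------
# plain-text schemas (snapshot and event-log CSV)

def state_to_frame(state: SystemState, track_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Snapshot CSV schema: t_h, id, type, x_um, y_um[, z_um][, track_id]."""
    d = state.positions.shape[1] if state.positions.size else 2
    cols = {"t_h": np.full(state.n_total, state.time)}
    cols["id"] = state.ids
    cols["type"] = [_TYPE_NAMES[int(t)] for t in state.types]
    for k, name in enumerate(["x_um", "y_um", "z_um"][:d]):
        cols[name] = state.positions[:, k] if state.positions.size else np.empty(0)
    frame = pd.DataFrame(cols)
    if track_ids is not None:
        frame["track_id"] = track_ids
    return frame


def frame_to_state(frame: pd.DataFrame) -> SystemState:
    axes = [c for c in ("x_um", "y_um", "z_um") if c in frame.columns]
    ids = frame["id"].to_numpy(np.int64)
    return SystemState(
        time=float(frame["t_h"].iloc[0]) if len(frame) else 0.0,
        ids=ids,
        types=np.array([_TYPE_CODES[t] for t in frame["type"]], np.int8),
        positions=frame[axes].to_numpy(float),
        next_id=int(ids.max()) + 1 if len(ids) else 0,
    )


def events_to_frame(events: list[EventRecord]) -> pd.DataFrame:
    """Event-log CSV schema: t_h, channel, consumed_ids, produced."""
    rows = []
    for ev in events:
        produced = ";".join(
            f"{_TYPE_NAMES[int(t)]}:" + ":".join(f"{x:.9g}" for x in np.atleast_1d(q))
            for t, q in ev.produced
        )
        rows.append(
            {
                "t_h": ev.time,
                "channel": ev.channel,
                "consumed_ids": ";".join(str(i) for i in ev.consumed_ids),
                "produced": produced,
            }
        )
    return pd.DataFrame(rows, columns=["t_h", "channel", "consumed_ids", "produced"])
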
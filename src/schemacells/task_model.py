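"""Canonical representation of the dual figure-of-eight odor-sequence task.

The task interleaves two "virtual mazes", each a fixed loop of eight odor
trials organized as two four-trial subsequences (a, b).  Serial positions
P1 and P2 within a subsequence are nonrewarded (correct response: no-go);
P3 and P4 are rewarded (correct response: go).  A session consists of
alternating blocks of trials on the two mazes.

This module defines the session/trial data model, the canonical odor
layout, and plain-text (CSV) readers and writers for session data, plus an
optional single-file HDF5 container.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POSITIONS = ("P1", "P2", "P3", "P4")
SUBSEQUENCES = ("a", "b")

#: Canonical within-trial event order.  well_entry/outcome may be absent
#: (no-go trials); all events present must be strictly increasing.
EVENT_ORDER = (
    "light_on",
    "poke",
    "odor_on",
    "unpoke",
    "well_entry",
    "outcome",
    "trial_end",
)

TRIALS_CSV_COLUMNS = [
    "trial_index",
    "maze_id",
    "subsequence",
    "position",
    "odor_id",
    "rewarded",
    "response",
    "correct",
    *EVENT_ORDER,
]


class SessionValidationError(ValueError):
    """A trial or session violates the task-structure invariants."""


@dataclass(frozen=True)
class SessionDesign:
    """Structure of a session: odor layout per maze and the block plan.

    ``maze_definitions`` maps maze id -> {subsequence -> list of four
    ``(odor_id, rewarded)`` pairs}.  ``block_plan`` is the ordered list of
    ``(maze_id, n_trials)`` blocks; ``trials_per_type`` is the planned
    trial count for each of the 8 trial types per maze.
    """

    maze_definitions: dict[str, dict[str, list[tuple[str, bool]]]]
    block_plan: list[tuple[str, int]]
    trials_per_type: int = 20

    def __post_init__(self) -> None:
        for maze_id, subseqs in self.maze_definitions.items():
            if set(subseqs) != set(SUBSEQUENCES):
                raise SessionValidationError(
                    f"maze {maze_id!r}: expected subsequences {SUBSEQUENCES}, got {sorted(subseqs)}"
                )
            for sub, pairs in subseqs.items():
                if len(pairs) != 4:
                    raise SessionValidationError(
                        f"maze {maze_id!r} subsequence {sub!r}: expected 4 positions, got {len(pairs)}"
                    )
                rewards = [bool(r) for _, r in pairs]
                if rewards != [False, False, True, True]:
                    raise SessionValidationError(
                        f"maze {maze_id!r} subsequence {sub!r}: reward pattern must be "
                        f"(-,-,+,+), got {rewards}"
                    )
        total = sum(n for _, n in self.block_plan)
        expected = self.trials_per_type * 8 * len(self.maze_definitions)
        if total != expected:
            raise SessionValidationError(
                f"block plan covers {total} trials but trials_per_type={self.trials_per_type} "
                f"requires {expected}"
            )

    @property
    def maze_ids(self) -> list[str]:
        return list(self.maze_definitions)

    @property
    def n_trials(self) -> int:
        return sum(n for _, n in self.block_plan)

    def rewarded(self, maze_id: str, subsequence: str, position: str) -> bool:
        idx = POSITIONS.index(position)
        return bool(self.maze_definitions[maze_id][subsequence][idx][1])

    def odor(self, maze_id: str, subsequence: str, position: str) -> str:
        idx = POSITIONS.index(position)
        return self.maze_definitions[maze_id][subsequence][idx][0]


@dataclass
class TrialRecord:
    """One trial: labels plus event timestamps (seconds).

    ``event_times`` contains a subset of :data:`EVENT_ORDER`;
    ``well_entry``/``outcome`` are absent on no-go trials.
    ``within_type_index`` is the 1-based ordinal of this trial among
    same-(maze, subsequence, position) trials in the session.
    """

    trial_index: int
    maze_id: str
    subsequence: str
    position: str
    odor_id: str
    rewarded: bool
    response: str  # "go" | "nogo"
    correct: bool
    event_times: dict[str, float] = field(default_factory=dict)
    within_type_index: int = 0

    @property
    def type_key(self) -> str:
        return f"{self.subsequence}{self.position}"

    def validate(self, design: SessionDesign | None = None) -> None:
        if self.position not in POSITIONS:
            raise SessionValidationError(
                f"trial {self.trial_index}: unknown position {self.position!r}"
            )
        if self.response not in ("go", "nogo"):
            raise SessionValidationError(
                f"trial {self.trial_index}: response must be go|nogo, got {self.response!r}"
            )
        times = [
            (name, self.event_times[name])
            for name in EVENT_ORDER
            if name in self.event_times and not math.isnan(self.event_times[name])
        ]
        for (n0, t0), (n1, t1) in zip(times, times[1:]):
            if not t1 > t0:
                raise SessionValidationError(
                    f"trial {self.trial_index}: event {n1!r} ({t1}) not after {n0!r} ({t0})"
                )
        if design is not None:
            expect = design.rewarded(self.maze_id, self.subsequence, self.position)
            if bool(self.rewarded) != expect:
                raise SessionValidationError(
                    f"trial {self.trial_index}: rewarded={self.rewarded} inconsistent with design "
                    f"for ({self.maze_id}, {self.subsequence}, {self.position})"
                )
            if not 1 <= self.within_type_index <= design.trials_per_type:
                raise SessionValidationError(
                    f"trial {self.trial_index}: within_type_index {self.within_type_index} "
                    f"outside [1, {design.trials_per_type}]"
                )


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (seconds) for one unit."""

    unit_id: str
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        if self.timestamps.size and np.any(np.diff(self.timestamps) < 0):
            raise ValueError(f"unit {self.unit_id}: timestamps must be nondecreasing")
        if self.timestamps.size and self.timestamps[0] < 0:
            raise ValueError(f"unit {self.unit_id}: timestamps must be nonnegative")


def make_default_design(trials_per_type: int = 20) -> SessionDesign:
    """The canonical two-maze, ten-odor design.

    Maze 1 uses odors 0-4 (subsequence a: 0-,1-,2+,2+; b: 0-,1-,3+,4+)
    and maze 2 the mirror layout on odors 5-9.  The default block plan is
    four alternating 80-trial blocks (320 trials total); other
    ``trials_per_type`` values scale the block length accordingly.
    """

    def seqs(o: list[str]) -> dict[str, list[tuple[str, bool]]]:
        return {
            "a": [(o[0], False), (o[1], False), (o[2], True), (o[2], True)],
            "b": [(o[0], False), (o[1], False), (o[3], True), (o[4], True)],
        }

    maze_definitions = {
        "maze1": seqs([str(i) for i in range(5)]),
        "maze2": seqs([str(i) for i in range(5, 10)]),
    }
    block = 4 * trials_per_type  # each maze appears in 2 blocks
    plan = [("maze1", block), ("maze2", block), ("maze1", block), ("maze2", block)]
    return SessionDesign(maze_definitions, plan, trials_per_type)


def enumerate_trial_types(design: SessionDesign, maze_id: str) -> list[str]:
    """The pinned ordering of a maze's 8 trial-type keys.

    Order is subsequence a P1..P4 then b P1..P4; every downstream matrix
    and 72-element profile uses this order.
    """
    if maze_id not in design.maze_definitions:
        raise KeyError(f"unknown maze {maze_id!r}")
    return [f"{sub}{pos}" for sub in SUBSEQUENCES for pos in POSITIONS]


def assign_within_type_indices(trials: list[TrialRecord]) -> None:
    """Set 1-based within_type_index per (maze, type) in trial order, in place."""
    counters: dict[tuple[str, str], int] = {}
    for tr in sorted(trials, key=lambda t: t.trial_index):
        key = (tr.maze_id, tr.type_key)
        counters[key] = counters.get(key, 0) + 1
        tr.within_type_index = counters[key]


# ---------------------------------------------------------------------------
# Columnar text (CSV) serialization
# ---------------------------------------------------------------------------

def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for tr in trials:
        row = {
            "trial_index": tr.trial_index,
            "maze_id": tr.maze_id,
            "subsequence": tr.subsequence,
            "position": tr.position,
            "odor_id": tr.odor_id,
            "rewarded": int(tr.rewarded),
            "response": tr.response,
            "correct": int(tr.correct),
        }
        for ev in EVENT_ORDER:
            row[ev] = tr.event_times.get(ev, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=TRIALS_CSV_COLUMNS)


def frame_to_trials(frame: pd.DataFrame, design: SessionDesign | None = None) -> list[TrialRecord]:
    trials = []
    for i, row in frame.iterrows():
        try:
            events = {
                ev: float(row[ev])
                for ev in EVENT_ORDER
                if ev in row and pd.notna(row[ev])
            }
            tr = TrialRecord(
                trial_index=int(row["trial_index"]),
                maze_id=str(row["maze_id"]),
                subsequence=str(row["subsequence"]),
                position=str(row["position"]),
                odor_id=str(row["odor_id"]),
                rewarded=bool(int(row["rewarded"])),
                response=str(row["response"]),
                correct=bool(int(row["correct"])),
                event_times=events,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SessionValidationError(f"trials row {i}: malformed ({exc})") from exc
        trials.append(tr)
    assign_within_type_indices(trials)
    for tr in trials:
        tr.validate(design)
    return trials


def write_session(trials_path, spikes_path, trials: list[TrialRecord],
                  spikes: list[SpikeTrain]) -> None:
    """Write trials and spikes as the canonical CSV schema."""
    trials_to_frame(trials).to_csv(trials_path, index=False)
    frames = [
        pd.DataFrame({"unit_id": st.unit_id, "timestamp": st.timestamps})
        for st in spikes
    ]
    spike_frame = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["unit_id", "timestamp"])
    )
    spike_frame.to_csv(spikes_path, index=False)


def read_session(trials_path, spikes_path,
                 design: SessionDesign | None = None
                 ) -> tuple[list[TrialRecord], list[SpikeTrain]]:
    """Read and validate a session from the canonical CSV pair.

    Invariant violations raise :class:`SessionValidationError` naming the
    offending trial or row.
    """
    trials = frame_to_trials(pd.read_csv(trials_path), design)
    sf = pd.read_csv(spikes_path)
    spikes = [
        SpikeTrain(str(unit_id), np.sort(group["timestamp"].to_numpy(float)))
        for unit_id, group in sf.groupby("unit_id", sort=True)
    ]
    return trials, spikes


# ---------------------------------------------------------------------------
# Optional single-file HDF5 container (same logical layout)
# ---------------------------------------------------------------------------

def write_session_h5(path, trials: list[TrialRecord], spikes: list[SpikeTrain]) -> None:
    import h5py

    frame = trials_to_frame(trials)
    with h5py.File(path, "w") as f:
        g = f.create_group("trials")
        for col in frame.columns:
            data = frame[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)
        s = f.create_group("spikes")
        for st in spikes:
            s.create_dataset(st.unit_id, data=st.timestamps)


def read_session_h5(path, design: SessionDesign | None = None
                    ) -> tuple[list[TrialRecord], list[SpikeTrain]]:
    import h5py

    with h5py.File(path, "r") as f:
        cols = {}
        for col, ds in f["trials"].items():
            arr = ds[()]
            if arr.dtype.kind == "S":
                arr = arr.astype(str)
            cols[col] = arr
        frame = pd.DataFrame(cols)[TRIALS_CSV_COLUMNS]
        spikes = [
            SpikeTrain(unit_id, ds[()]) for unit_id, ds in sorted(f["spikes"].items())
        ]
    return frame_to_trials(frame, design), spikes
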
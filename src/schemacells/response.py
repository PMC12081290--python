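"""Peri-event responses: smoothed binned rates, epoch rate matrices, profiles.

Each trial is carved into nine 500-ms epochs anchored to task events
(ITIa, light, poke, odor, unpoke, choice, outcome, postout, ITIb).  Spike
counts are taken in 100-ms bins and smoothed with a 50-ms-s.d. Gaussian
kernel; an epoch's firing rate is the smoothed spike mass falling inside
its window divided by the 500-ms duration.  Per-maze trials-by-epoch
matrices and 72-element trial-type profiles (8 types x 9 epochs, type-major
in the pinned ordering) are the substrate of all downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr  # standard normal CDF, vectorized

from .task_model import (
    SessionDesign,
    SpikeTrain,
    TrialRecord,
    enumerate_trial_types,
)

EPOCH_NAMES = (
    "ITIa", "light", "poke", "odor", "unpoke",
    "choice", "outcome", "postout", "ITIb",
)
EPOCH_DURATION_S = 0.5


@dataclass(frozen=True)
class EpochDefinition:
    """One 500-ms epoch window: ``[anchor+offset, anchor+offset+0.5)``.

    ``fallback_anchor``/``fallback_offset_s`` apply when the anchor event
    is absent (no-go and unrewarded trials).  The chained epochs postout
    and ITIb are anchored to the end of the preceding epoch's window.
    """

    name: str
    anchor: str
    offset_s: float = 0.0
    duration_s: float = EPOCH_DURATION_S
    fallback_anchor: str | None = None
    fallback_offset_s: float = 0.0


DEFAULT_EPOCHS: tuple[EpochDefinition, ...] = (
    EpochDefinition("ITIa", "light_on", -0.5),
    EpochDefinition("light", "light_on"),
    EpochDefinition("poke", "poke"),
    EpochDefinition("odor", "odor_on"),
    EpochDefinition("unpoke", "unpoke"),
    EpochDefinition("choice", "well_entry", fallback_anchor="trial_end"),
    # No reward delivered: the outcome window follows the choice fallback
    # window so the two stay disjoint, mirroring rewarded trials.
    EpochDefinition("outcome", "outcome", fallback_anchor="trial_end",
                    fallback_offset_s=0.5),
    EpochDefinition("postout", "outcome_end"),
    EpochDefinition("ITIb", "postout_end"),
)


class EpochAnchorError(ValueError):
    """Neither the anchor nor its fallback is present on a trial."""


def epoch_windows(trial: TrialRecord,
                  epoch_defs: tuple[EpochDefinition, ...] = DEFAULT_EPOCHS
                  ) -> np.ndarray:
    """Start/end times of the nine epoch windows for one trial, shape (9, 2).

    Windows are half-open ``[start, end)``; ``outcome_end``/``postout_end``
    virtual anchors chain postout and ITIb off the outcome window.
    """
    ends: dict[str, float] = {}
    out = np.empty((len(epoch_defs), 2), dtype=float)
    for i, ed in enumerate(epoch_defs):
        if ed.anchor in trial.event_times:
            t0 = trial.event_times[ed.anchor] + ed.offset_s
        elif ed.anchor in ends:
            t0 = ends[ed.anchor] + ed.offset_s
        elif ed.fallback_anchor is not None and ed.fallback_anchor in trial.event_times:
            t0 = trial.event_times[ed.fallback_anchor] + ed.fallback_offset_s
        else:
            raise EpochAnchorError(
                f"trial {trial.trial_index}: epoch {ed.name!r} has no anchor "
                f"({ed.anchor!r}) and no usable fallback"
            )
        out[i] = (t0, t0 + ed.duration_s)
        ends[f"{ed.name}_end"] = t0 + ed.duration_s
    return out


def smooth_binned_rate(spikes: np.ndarray, window: tuple[float, float],
                       bin_ms: float = 100.0, kernel_sd_ms: float = 50.0
                       ) -> np.ndarray:
    """Binned, Gaussian-smoothed firing-rate trace (Hz per bin) on a window.

    Counts spikes in ``bin_ms`` bins, convolves with a Gaussian kernel of
    s.d. ``kernel_sd_ms`` (truncated at 4 s.d.), and corrects for kernel
    mass lost past the window edges by renormalizing each bin by the kernel
    mass that remains inside the window.  Total smoothed count over the
    window therefore matches the raw count up to edge leakage of spikes
    near the boundary.
    """
    if bin_ms <= 0 or kernel_sd_ms <= 0:
        raise ValueError("bin_ms and kernel_sd_ms must be positive")
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must have positive length")
    spikes = np.asarray(spikes, dtype=float)
    bin_s = bin_ms / 1000.0
    n_bins = max(1, int(round((t1 - t0) / bin_s)))
    edges = t0 + bin_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(spikes, bins=edges)

    sd_bins = kernel_sd_ms / bin_ms
    radius = max(1, int(np.ceil(4 * sd_bins)))
    x = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (x / sd_bins) ** 2)
    kernel /= kernel.sum()

    smoothed = np.convolve(counts, kernel, mode="same")
    edge_mass = np.convolve(np.ones(n_bins), kernel, mode="same")
    smoothed = smoothed / edge_mass
    return smoothed / bin_s


def _gaussian_mass_in_windows(spikes: np.ndarray, windows: np.ndarray,
                              kernel_sd_ms: float) -> np.ndarray:
    """Smoothed spike mass per window: sum over spikes of the Gaussian
    (s.d. ``kernel_sd_ms``) probability mass inside ``[start, end)``."""
    sd = kernel_sd_ms / 1000.0
    masses = np.zeros(len(windows))
    if spikes.size == 0:
        return masses
    for i, (t0, t1) in enumerate(windows):
        lo = np.searchsorted(spikes, t0 - 5 * sd)
        hi = np.searchsorted(spikes, t1 + 5 * sd)
        if hi > lo:
            s = spikes[lo:hi]
            masses[i] = np.sum(ndtr((t1 - s) / sd) - ndtr((t0 - s) / sd))
    return masses


def epoch_rates(spikes: np.ndarray | SpikeTrain, trial: TrialRecord,
                epoch_defs: tuple[EpochDefinition, ...] = DEFAULT_EPOCHS,
                smoothing: bool = True, kernel_sd_ms: float = 50.0
                ) -> np.ndarray:
    """Firing rate (Hz) in each of the trial's nine epoch windows.

    With ``smoothing`` (default) the rate is the Gaussian-smoothed spike
    mass in the window divided by its duration; ``smoothing=False`` uses
    raw counts (the oracle path).
    """
    ts = spikes.timestamps if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    windows = epoch_windows(trial, epoch_defs)
    durations = windows[:, 1] - windows[:, 0]
    if smoothing:
        mass = _gaussian_mass_in_windows(ts, windows, kernel_sd_ms)
    else:
        mass = np.array([
            np.searchsorted(ts, t1) - np.searchsorted(ts, t0) for t0, t1 in windows
        ], dtype=float)
    return mass / durations


@dataclass
class EpochRateMatrix:
    """Per-unit, per-maze trials x 9-epoch firing rates with trial labels.

    Rows are grouped by trial type in the pinned order (subsequence a
    P1..P4 then b P1..P4) and sorted by within-type index; with the full
    default session this is 160 rows (8 types x 20 trials).
    """

    unit_id: str
    maze_id: str
    values: np.ndarray  # (n_trials, 9)
    labels: pd.DataFrame  # columns: type_key, subsequence, position, rewarded, within_type_index
    epochs: tuple[str, ...] = EPOCH_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.epochs):
            raise ValueError("values must be (n_trials, n_epochs)")
        if len(self.labels) != len(self.values):
            raise ValueError("labels/values row mismatch")

    @property
    def type_keys(self) -> list[str]:
        seen: list[str] = []
        for k in self.labels["type_key"]:
            if k not in seen:
                seen.append(k)
        return seen

    def trials_per_type(self) -> dict[str, int]:
        return self.labels["type_key"].value_counts().to_dict()

    def to_csv(self, path) -> None:
        frame = self.labels.copy()
        frame.insert(0, "maze_id", self.maze_id)
        frame.insert(0, "unit_id", self.unit_id)
        for j, ep in enumerate(self.epochs):
            frame[ep] = self.values[:, j]
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EpochRateMatrix":
        frame = pd.read_csv(path)
        epochs = tuple(c for c in frame.columns if c in EPOCH_NAMES)
        labels = frame[["type_key", "subsequence", "position", "rewarded",
                        "within_type_index"]].reset_index(drop=True)
        return cls(
            unit_id=str(frame["unit_id"].iloc[0]),
            maze_id=str(frame["maze_id"].iloc[0]),
            values=frame[list(epochs)].to_numpy(float),
            labels=labels,
            epochs=epochs,
        )


@dataclass
class TrialTypeProfile:
    """Mean-rate vector over trial types x epochs for one unit in one maze.

    With the full nine epochs this is the 72-element profile; entry
    ``n_epochs*t + e`` (type-major, epoch-minor in the pinned ordering) is
    the mean rate of trial type ``t`` in epoch ``e``.  Epoch-subset
    analyses (e.g. the early-trial ITIa..odor window) carry fewer epochs.
    """

    unit_id: str
    maze_id: str
    values: np.ndarray  # (8 * n_epochs,)
    epochs: tuple[str, ...] = EPOCH_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != 8 * len(self.epochs):
            raise ValueError(
                f"profile must have {8 * len(self.epochs)} entries "
                f"(8 types x {len(self.epochs)} epochs), got {self.values.size}")

    def as_matrix(self) -> np.ndarray:
        """(8 types, n_epochs) view of the profile."""
        return self.values.reshape(8, len(self.epochs))

    def to_csv(self, path, type_keys: list[str] | None = None) -> None:
        keys = type_keys or [f"{s}{p}" for s in ("a", "b")
                             for p in ("P1", "P2", "P3", "P4")]
        frame = pd.DataFrame(self.as_matrix(), columns=list(self.epochs))
        frame.insert(0, "type_key", keys)
        frame.insert(0, "maze_id", self.maze_id)
        frame.insert(0, "unit_id", self.unit_id)
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialTypeProfile":
        frame = pd.read_csv(path)
        epochs = tuple(c for c in frame.columns
                       if c not in ("unit_id", "maze_id", "type_key"))
        return cls(str(frame["unit_id"].iloc[0]), str(frame["maze_id"].iloc[0]),
                   frame[list(epochs)].to_numpy(float).ravel(), epochs)


def build_epoch_matrix(spikes: SpikeTrain, trials: list[TrialRecord],
                       design: SessionDesign, maze_id: str,
                       epoch_defs: tuple[EpochDefinition, ...] = DEFAULT_EPOCHS,
                       trials_per_type: int | None = None,
                       smoothing: bool = True,
                       correct_only: bool = False) -> EpochRateMatrix:
    """Epoch-rate matrix for one unit on one maze's completed trials.

    Trials without a nosepoke are excluded (most epochs would lack
    anchors); error trials are included unless ``correct_only`` is set.
    ``trials_per_type`` caps rows per type (the first N by within-type
    index), e.g. 15 for the 120x9 ensemble-decoding matrix.  Raises
    ``ValueError`` naming any trial type with no usable trials.
    """
    order = enumerate_trial_types(design, maze_id)
    by_type: dict[str, list[TrialRecord]] = {k: [] for k in order}
    for tr in trials:
        if tr.maze_id != maze_id or "poke" not in tr.event_times:
            continue
        if correct_only and not tr.correct:
            continue
        by_type[tr.type_key].append(tr)

    missing = [k for k, v in by_type.items() if not v]
    if missing:
        raise ValueError(f"maze {maze_id!r}: no completed trials for type(s) {missing}")

    rows, label_rows = [], []
    for key in order:
        group = sorted(by_type[key], key=lambda t: t.within_type_index)
        if trials_per_type is not None:
            if len(group) < trials_per_type:
                raise ValueError(
                    f"type {key!r} has {len(group)} trials, needs {trials_per_type}"
                )
            group = group[:trials_per_type]
        for tr in group:
            rows.append(epoch_rates(spikes, tr, epoch_defs, smoothing=smoothing))
            label_rows.append({
                "type_key": key,
                "subsequence": tr.subsequence,
                "position": tr.position,
                "rewarded": int(tr.rewarded),
                "within_type_index": tr.within_type_index,
            })
    return EpochRateMatrix(
        unit_id=spikes.unit_id,
        maze_id=maze_id,
        values=np.vstack(rows),
        labels=pd.DataFrame(label_rows),
    )


def build_profile(matrix: EpochRateMatrix) -> TrialTypeProfile:
    """Mean-rate 72-profile: per-type arithmetic mean of the matrix rows."""
    keys = matrix.type_keys
    if len(keys) != 8:
        raise ValueError(f"matrix covers {len(keys)} trial types, expected 8")
    means = np.vstack([
        matrix.values[(matrix.labels["type_key"] == k).to_numpy()].mean(axis=0)
        for k in keys
    ])
    return TrialTypeProfile(matrix.unit_id, matrix.maze_id, means.ravel(),
                            matrix.epochs)


def profile_from_values(values: np.ndarray, labels: pd.DataFrame) -> np.ndarray:
    """Flat type-by-epoch profile from raw (..., n, 9) values and labels.

    Rows are grouped per ``type_key`` (order of first appearance, the
    pinned order for matrices built here) and averaged; supports a
    leading batch dimension, which the shuffle engine uses.
    """
    type_col = labels["type_key"].to_numpy()
    groups = [np.flatnonzero(type_col == k) for k in pd.unique(type_col)]
    means = np.stack([values[..., rows, :].mean(axis=-2) for rows in groups],
                     axis=-2)
    return means.reshape(*values.shape[:-2], len(groups) * values.shape[-1])
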
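"""Synthetic sessions and Poisson-spiking units with known ground truth.

The generator emulates the dual figure-of-eight odor-sequence task: 320
trials in 4 alternating 80-trial blocks over two mazes (8 trial types per
maze, 20 trials each by default), realistic event spacing (500-ms nosepoke
before odor onset, 0.4-1.5-s reward delay, 4-s/6-s intertrial intervals
after correct/error trials), and units whose expected firing rate in each
epoch window follows a multiplicative tuning model:

    rate(type t, epoch e) = baseline * epoch_gain[e] * position_gain[p(t)]
                            * (reward_gain if t rewarded else 1)

A maze-generalization mixing weight ``gamma`` interpolates, for maze 2,
between this shared profile (gamma=1: identical tuning in both mazes) and
an independent maze-specific profile (gamma=0).  Spikes are inhomogeneous
Poisson: per-epoch Poisson counts placed uniformly within the epoch
window, plus a baseline-rate process between epochs.  All generation is a
pure function of (specs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .response import epoch_windows
from .task_model import (
    POSITIONS,
    SUBSEQUENCES,
    SessionDesign,
    SpikeTrain,
    TrialRecord,
    assign_within_type_indices,
    enumerate_trial_types,
)


@dataclass
class BehaviorSpec:
    """Behavioral parameters of the simulated rat.

    ``p_correct`` is the per-position probability of a correct response
    (default 0.9, a well-trained level); ``latency_means`` gives the mean
    well-approach latency (s) keyed by (current trial rewarded, next trial
    rewarded) — anticipation of upcoming reward speeds responding.
    Latencies are log-normal (strictly positive, right-skewed).
    ITIs are 4 s after correct trials and 6 s after errors; the reward is
    delivered after a random 0.4-1.5-s delay.
    """

    p_correct: dict[str, float] = field(
        default_factory=lambda: {p: 0.9 for p in POSITIONS})
    latency_means: dict[tuple[bool, bool], float] = field(
        default_factory=lambda: {
            (False, False): 1.2, (False, True): 1.1,
            (True, False): 1.0, (True, True): 0.9,
        })
    latency_cv: float = 0.3
    iti_correct_s: float = 4.0
    iti_error_s: float = 6.0
    reward_delay_range_s: tuple[float, float] = (0.4, 1.5)
    poke_latency_mean_s: float = 1.0
    unpoke_delay_mean_s: float = 0.3
    nogo_timeout_s: float = 2.0

    def __post_init__(self) -> None:
        for p, v in self.p_correct.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"p_correct[{p}] must be in [0,1]")
        for name in ("iti_correct_s", "iti_error_s", "poke_latency_mean_s",
                     "unpoke_delay_mean_s", "nogo_timeout_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.reward_delay_range_s
        if not 0 < lo <= hi:
            raise ValueError("reward_delay_range_s must be positive and ordered")


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    sigma2 = np.log(1.0 + cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def generate_session(design: SessionDesign,
                     behavior: BehaviorSpec | None = None,
                     seed: int | np.random.Generator = 0) -> list[TrialRecord]:
    """Simulate one session's trials with event times.

    The block order is drawn from the two permitted alternations (maze 1
    first or maze 2 first).  Within a block, trials follow the maze's
    fixed loop: subsequence a P1..P4 then b P1..P4, repeated.
    """
    behavior = behavior or BehaviorSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    plan = list(design.block_plan)
    if rng.random() < 0.5:  # the other permitted order: swap maze roles
        maze_ids = design.maze_ids
        swap = {maze_ids[0]: maze_ids[1], maze_ids[1]: maze_ids[0]}
        plan = [(swap[m], n) for m, n in plan]

    # Trial-type sequence for the whole session
    seq: list[tuple[str, str, str]] = []
    for maze_id, n_trials in plan:
        loop = [(maze_id, sub, pos) for sub in SUBSEQUENCES for pos in POSITIONS]
        if n_trials % len(loop):
            raise ValueError("block length must be a multiple of 8")
        seq.extend(loop * (n_trials // len(loop)))

    rewarded_seq = [design.rewarded(m, s, p) for m, s, p in seq]
    trials: list[TrialRecord] = []
    t = 1.0
    for i, (maze_id, sub, pos) in enumerate(seq):
        rewarded = rewarded_seq[i]
        correct = bool(rng.random() < behavior.p_correct[pos])
        response = "go" if (rewarded == correct) else "nogo"

        ev = {"light_on": t}
        ev["poke"] = ev["light_on"] + _lognormal(
            rng, behavior.poke_latency_mean_s, behavior.latency_cv)
        ev["odor_on"] = ev["poke"] + 0.5  # stable 500-ms nosepoke starts odor
        ev["unpoke"] = ev["odor_on"] + 0.5 + _lognormal(
            rng, behavior.unpoke_delay_mean_s, behavior.latency_cv)
        if response == "go":
            next_rewarded = rewarded_seq[i + 1] if i + 1 < len(seq) else False
            lat = behavior.latency_means[(rewarded, next_rewarded)]
            ev["well_entry"] = ev["unpoke"] + _lognormal(rng, lat, behavior.latency_cv)
            if rewarded:  # correct go: sucrose after a random delay
                lo, hi = behavior.reward_delay_range_s
                ev["outcome"] = ev["well_entry"] + rng.uniform(lo, hi)
                ev["trial_end"] = ev["outcome"] + 2.0
            else:  # false alarm: house lights off immediately, no reward
                ev["trial_end"] = ev["well_entry"] + 0.05
        else:  # no-go: lights extinguished after the timeout
            ev["trial_end"] = ev["unpoke"] + behavior.nogo_timeout_s
        iti = behavior.iti_correct_s if correct else behavior.iti_error_s
        t = ev["trial_end"] + iti

        trials.append(TrialRecord(
            trial_index=i + 1,
            maze_id=maze_id,
            subsequence=sub,
            position=pos,
            odor_id=design.odor(maze_id, sub, pos),
            rewarded=rewarded,
            response=response,
            correct=correct,
            event_times=ev,
        ))
    assign_within_type_indices(trials)
    return trials


@dataclass
class TuningSpec:
    """Generative firing parameters of one synthetic unit.

    ``gamma`` is the maze-generalization mixing weight: maze 1 fires by
    the shared multiplicative profile; maze 2's expected (8 x 9) rate
    table is ``gamma * shared + (1 - gamma) * maze_specific_profile``.
    ``rate_jitter_cv`` adds per-trial multiplicative log-normal rate
    jitter on top of Poisson spiking (0 = pure Poisson).
    """

    unit_id: str
    baseline_rate: float = 5.0
    epoch_gain: np.ndarray = field(default_factory=lambda: np.ones(9))
    reward_gain: float = 1.0
    position_gain: np.ndarray = field(default_factory=lambda: np.ones(4))
    gamma: float = 1.0
    maze_specific_profile: np.ndarray | None = None  # (72,) Hz
    rate_jitter_cv: float = 0.0

    def __post_init__(self) -> None:
        self.epoch_gain = np.asarray(self.epoch_gain, dtype=float)
        self.position_gain = np.asarray(self.position_gain, dtype=float)
        if self.epoch_gain.shape != (9,) or self.position_gain.shape != (4,):
            raise ValueError("epoch_gain must have 9 entries and position_gain 4")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if (self.baseline_rate < 0 or self.reward_gain < 0
                or np.any(self.epoch_gain < 0) or np.any(self.position_gain < 0)):
            raise ValueError("rates and gains must be nonnegative")
        if self.maze_specific_profile is not None:
            self.maze_specific_profile = np.asarray(
                self.maze_specific_profile, dtype=float).ravel()
            if self.maze_specific_profile.size != 72:
                raise ValueError("maze_specific_profile must have 72 entries")
            if np.any(self.maze_specific_profile < 0):
                raise ValueError("maze_specific_profile must be nonnegative")

    def shared_profile(self, design: SessionDesign, maze_id: str) -> np.ndarray:
        """(8, 9) expected-rate table from the multiplicative tuning model."""
        keys = enumerate_trial_types(design, maze_id)
        table = np.empty((8, 9))
        for t, key in enumerate(keys):
            sub, pos = key[0], key[1:]
            g = self.position_gain[POSITIONS.index(pos)]
            if design.rewarded(maze_id, sub, pos):
                g = g * self.reward_gain
            table[t] = self.baseline_rate * self.epoch_gain * g
        return table

    def expected_rates(self, design: SessionDesign, maze_id: str) -> np.ndarray:
        """(8 types, 9 epochs) expected firing rate (Hz) in this maze."""
        maze_index = design.maze_ids.index(maze_id)
        shared = self.shared_profile(design, maze_id)
        if maze_index == 0 or self.gamma == 1.0 or self.maze_specific_profile is None:
            return shared
        specific = self.maze_specific_profile.reshape(8, 9)
        return self.gamma * shared + (1.0 - self.gamma) * specific

    def to_dict(self) -> dict:
        return {
            "unit_id": self.unit_id,
            "baseline_rate": self.baseline_rate,
            "epoch_gain": self.epoch_gain.tolist(),
            "reward_gain": self.reward_gain,
            "position_gain": self.position_gain.tolist(),
            "gamma": self.gamma,
            "maze_specific_profile": (
                None if self.maze_specific_profile is None
                else self.maze_specific_profile.tolist()),
            "rate_jitter_cv": self.rate_jitter_cv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TuningSpec":
        d = dict(d)
        if d.get("maze_specific_profile") is not None:
            d["maze_specific_profile"] = np.asarray(d["maze_specific_profile"])
        d["epoch_gain"] = np.asarray(d["epoch_gain"])
        d["position_gain"] = np.asarray(d["position_gain"])
        return cls(**d)


def generate_spikes(trials: list[TrialRecord], tuning: TuningSpec,
                    design: SessionDesign,
                    seed: int | np.random.Generator = 0) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train for one unit over a session.

    Expected rate inside each epoch window equals the TuningSpec
    expectation for that (maze, trial type, epoch); the rate between
    windows is the unit's baseline.  Where two windows overlap (rare:
    short reward delays), the later-starting window's rate applies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expected = {m: tuning.expected_rates(design, m) for m in design.maze_ids}
    type_index = {m: {k: i for i, k in enumerate(enumerate_trial_types(design, m))}
                  for m in design.maze_ids}

    # Collect (start, end, rate) pieces across the session.
    starts, ends, rates = [], [], []
    prev_end = 0.0
    for tr in sorted(trials, key=lambda t: t.trial_index):
        win = epoch_windows(tr)
        trial_rates = expected[tr.maze_id][type_index[tr.maze_id][tr.type_key]].copy()
        if tuning.rate_jitter_cv > 0:
            sigma2 = np.log(1.0 + tuning.rate_jitter_cv ** 2)
            trial_rates = trial_rates * rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2))
        # Partition the trial span so later-starting windows take priority.
        order = np.argsort(win[:, 0], kind="stable")
        cursor = max(prev_end, win[order[0], 0])
        if cursor > prev_end:  # baseline gap before the trial's first window
            starts.append(prev_end); ends.append(cursor); rates.append(tuning.baseline_rate)
        for j, k in enumerate(order):
            t0, t1 = win[k]
            t0 = max(t0, cursor)
            if j + 1 < len(order):
                t1 = min(t1, win[order[j + 1], 0]) if win[order[j + 1], 0] > t0 else t0
            if t1 > t0:
                starts.append(t0); ends.append(t1); rates.append(trial_rates[k])
                cursor = t1
            # baseline gap before the next window
            if j + 1 < len(order) and win[order[j + 1], 0] > cursor:
                starts.append(cursor); ends.append(win[order[j + 1], 0])
                rates.append(tuning.baseline_rate)
                cursor = win[order[j + 1], 0]
        prev_end = cursor

    starts = np.asarray(starts); ends = np.asarray(ends); rates = np.asarray(rates)
    counts = rng.poisson(rates * (ends - starts))
    total = int(counts.sum())
    if total == 0:
        return SpikeTrain(tuning.unit_id, np.empty(0))
    seg = np.repeat(np.arange(len(starts)), counts)
    ts = starts[seg] + rng.random(total) * (ends[seg] - starts[seg])
    return SpikeTrain(tuning.unit_id, np.sort(ts))


DEFAULT_CATEGORY_MIX = (0.4, 0.3, 0.3)  # schema-like, nonschema-like, noncoding-like


def make_tuned_spec(rng: np.random.Generator, unit_id: str, gamma: float,
                    design: SessionDesign) -> TuningSpec:
    """Strongly tuned unit with a variance-matched maze-specific profile."""
    spec = TuningSpec(
        unit_id=unit_id,
        baseline_rate=float(rng.uniform(2.0, 8.0)),
        epoch_gain=rng.lognormal(0.0, 0.6, size=9),
        reward_gain=2.0,
        position_gain=rng.lognormal(0.0, 0.5, size=4),
        gamma=gamma,
    )
    alt = TuningSpec(
        unit_id=unit_id + "_alt",
        baseline_rate=spec.baseline_rate,
        epoch_gain=rng.lognormal(0.0, 0.6, size=9),
        reward_gain=2.0,
        position_gain=rng.lognormal(0.0, 0.5, size=4),
    )
    spec.maze_specific_profile = alt.shared_profile(
        design, design.maze_ids[1]).ravel()
    return spec


def generate_population(design: SessionDesign, n_units: int,
                        category_mix: tuple[float, float, float] = DEFAULT_CATEGORY_MIX,
                        seed: int | np.random.Generator = 0,
                        behavior: BehaviorSpec | None = None,
                        ) -> tuple[list[TrialRecord], list[SpikeTrain], list[TuningSpec]]:
    """One session plus ``n_units`` labeled units drawn from three kinds.

    ``category_mix`` gives the fractions of schema-like units (gamma=1,
    strong tuning), nonschema-like units (gamma ~ U(0.40, 0.60), same
    tuning strength — expected cross-maze r in the 0.4-0.8 band), and
    noncoding-like units (flat tuning).  The returned TuningSpecs carry
    the intended category as ground truth for recovery tests.
    """
    if abs(sum(category_mix) - 1.0) > 1e-9:
        raise ValueError("category_mix fractions must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = generate_session(design, behavior, rng)

    n_schema = int(round(category_mix[0] * n_units))
    n_nonschema = int(round(category_mix[1] * n_units))
    n_noncoding = n_units - n_schema - n_nonschema
    intents = (["schema"] * n_schema + ["nonschema"] * n_nonschema
               + ["noncoding"] * n_noncoding)

    spikes, specs = [], []
    for i, intent in enumerate(intents):
        uid = f"u{i:04d}"
        if intent == "schema":
            spec = make_tuned_spec(rng, uid, gamma=1.0, design=design)
        elif intent == "nonschema":
            spec = make_tuned_spec(rng, uid, gamma=float(rng.uniform(0.40, 0.60)),
                                   design=design)
        else:
            spec = TuningSpec(unit_id=uid, baseline_rate=float(rng.uniform(2.0, 8.0)))
        spec.intended_category = intent  # ground-truth label for recovery tests
        specs.append(spec)
        spikes.append(generate_spikes(trials, spec, design, rng))
    return trials, spikes, specs
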
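"""Schema-cell classification, structured shuffle attribution, selectivity.

A unit's 72-element trial-type x epoch profile is computed in each maze
and the two profiles are Pearson-correlated.  Units with r > 0.8 at
p < 0.01 are schema cells (a generalized task representation); r in
[0.4, 0.8] marks nonschema cells; anything lower (or degenerate) is
noncoding.  Which task factor carries the generalization is attributed by
structured permutation nulls: rates are shuffled within defined strata —
between epochs within each trial; between reward categories within each
(epoch, subsequence); between positions within each (epoch, reward
category) — 1,000 times per maze, profiles and correlations are
recomputed, and a factor is flagged when the observed r exceeds the 99th
percentile of its shuffled distribution.  Per-unit selectivity and
explained variance come from a three-way (epoch, reward, position)
main-effects ANOVA with partial eta-squared per factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .response import EpochRateMatrix, TrialTypeProfile, build_profile, profile_from_values

logger = logging.getLogger(__name__)

CATEGORIES = ("schema", "nonschema", "noncoding")
FACTORS = ("epoch", "reward", "position")


@dataclass
class AnalysisConfig:
    """Thresholds and null-distribution settings for unit classification."""

    r_schema: float = 0.8
    r_noncoding: float = 0.4
    alpha_corr: float = 0.01
    n_shuffles: int = 1000
    shuffle_percentile: float = 99.0
    alpha_anova: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_noncoding < self.r_schema < 1:
            raise ValueError("need 0 < r_noncoding < r_schema < 1")
        if self.n_shuffles < 100:
            raise ValueError("n_shuffles must be at least 100")


@dataclass
class UnitClassification:
    unit_id: str
    r: float
    p_r: float
    category: str
    attribution: dict[str, bool | None] = field(default_factory=dict)
    shuffle_summaries: dict[str, float] = field(default_factory=dict)


@dataclass
class SelectivityResult:
    unit_id: str
    p_values: dict[str, float]
    partial_eta2: dict[str, float]
    preferred: dict[str, str]  # per significant factor: level with max mean rate


# ---------------------------------------------------------------------------
# Cross-maze correlation and categories
# ---------------------------------------------------------------------------

def cross_maze_r(profile1: TrialTypeProfile | np.ndarray,
                 profile2: TrialTypeProfile | np.ndarray) -> tuple[float, float]:
    """Pearson r between the two profiles and its two-sided p-value.

    The p-value is the exact t-transform with n - 2 degrees of freedom
    (70 for the full 72-element profiles).  Zero-variance (degenerate)
    profiles return (nan, nan).
    """
    x = profile1.values if isinstance(profile1, TrialTypeProfile) else np.asarray(profile1, float)
    y = profile2.values if isinstance(profile2, TrialTypeProfile) else np.asarray(profile2, float)
    if x.size != y.size:
        raise ValueError("profiles must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def classify_unit(profile1, profile2, config: AnalysisConfig | None = None) -> str:
    """Category from the cross-maze correlation thresholds.

    schema: r > r_schema and p < alpha; nonschema: r_noncoding <= r <=
    r_schema (or r above r_schema without significance, unreachable at
    n=72); noncoding: r < r_noncoding or a degenerate profile.
    """
    config = config or AnalysisConfig()
    r, p = cross_maze_r(profile1, profile2)
    return categorize(r, p, config)


def categorize(r: float, p: float, config: AnalysisConfig) -> str:
    if not np.isfinite(r):
        return "noncoding"
    if r > config.r_schema and p < config.alpha_corr:
        return "schema"
    if r >= config.r_noncoding:
        return "nonschema"
    return "noncoding"


def threshold_sweep(profile_pairs: list[tuple[np.ndarray, np.ndarray]],
                    thresholds: np.ndarray,
                    config: AnalysisConfig | None = None,
                    apply_p: bool = True) -> np.ndarray:
    """Fraction of units classified schema at each r threshold.

    Nonincreasing in the threshold; with ``apply_p=False`` only the r
    cut applies (threshold 0 then counts every positively correlated
    unit).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("thresholds must be non-empty")
    config = config or AnalysisConfig()
    rs, ps = [], []
    for p1, p2 in profile_pairs:
        r, p = cross_maze_r(p1, p2)
        rs.append(r); ps.append(p)
    rs = np.asarray(rs); ps = np.asarray(ps)
    ok = np.isfinite(rs)
    if apply_p:
        ok = ok & (ps < config.alpha_corr)
    return np.array([(ok & (rs > th)).mean() for th in thresholds])


# ---------------------------------------------------------------------------
# Structured shuffles (single-matrix API + batched engine)
# ---------------------------------------------------------------------------

def _permute_along(values: np.ndarray, axis: int, rng: np.random.Generator) -> np.ndarray:
    """Independently permute ``values`` along ``axis`` for every other index."""
    keys = rng.random(values.shape)
    order = np.argsort(keys, axis=axis)
    return np.take_along_axis(values, order, axis=axis)


def shuffle_epoch(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each trial row's 9 epoch values independently.

    Destroys any rate-epoch relationship while keeping each trial's value
    multiset — hence reward and position structure — intact.  Supports a
    leading batch dimension.
    """
    values = np.asarray(values, dtype=float)
    return _permute_along(values, axis=-1, rng=rng)


def _group_rows(labels: pd.DataFrame, by: str) -> list[np.ndarray]:
    col = labels[by].to_numpy()
    return [np.flatnonzero(col == v) for v in pd.unique(col)]


def _shuffle_grouped(values: np.ndarray, groups: list[np.ndarray],
                     rng: np.random.Generator) -> np.ndarray:
    """Permute rows-within-group independently per epoch column (and batch)."""
    out = np.array(values, dtype=float, copy=True)
    for rows in groups:
        sub = out[..., rows, :]
        out[..., rows, :] = _permute_along(sub, axis=-2, rng=rng)
    return out


#: Serial rank of a position within its reward category (P1,P3 are the
#: first position of the nonrewarded/rewarded pair; P2,P4 the second).
_POSITION_RANK = {"P1": 0, "P2": 1, "P3": 0, "P4": 1}


def shuffle_reward(values: np.ndarray, labels: pd.DataFrame,
                   rng: np.random.Generator) -> np.ndarray:
    """Exchange rates between reward categories within (epoch, subsequence).

    Cells are permuted uniformly at random within strata that match the
    position's serial rank inside its reward category ({P1, P3} and
    {P2, P4} per subsequence), so reward structure is destroyed while
    epoch and position-within-subsequence relationships stay intact.
    Stratum multisets are preserved exactly.  Raises when a stratum lacks
    both reward categories.
    """
    rank = labels["position"].map(_POSITION_RANK)
    key = labels["subsequence"].astype(str) + ":" + rank.astype(str)
    groups = [np.flatnonzero((key == v).to_numpy()) for v in pd.unique(key)]
    for rows in groups:
        if labels["rewarded"].iloc[rows].nunique() < 2:
            raise ValueError("a reward-shuffle stratum has a single reward category")
    return _shuffle_grouped(values, groups, rng)


def shuffle_position(values: np.ndarray, labels: pd.DataFrame,
                     rng: np.random.Generator) -> np.ndarray:
    """Exchange rates between positions within (epoch, reward category).

    Strata respect reward, so reward-only tuning is unaffected in
    expectation while position structure is destroyed.
    """
    return _shuffle_grouped(values, _group_rows(labels, "rewarded"), rng)


def _shuffled_profiles(matrix: EpochRateMatrix, factor: str, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """(n, 72) profiles of ``n`` independent shuffles of one matrix."""
    batch = np.broadcast_to(matrix.values, (n, *matrix.values.shape))
    if factor == "epoch":
        shuffled = shuffle_epoch(batch, rng)
    elif factor == "reward":
        shuffled = shuffle_reward(batch, matrix.labels, rng)
    elif factor == "position":
        shuffled = shuffle_position(batch, matrix.labels, rng)
    else:
        raise ValueError(f"unknown factor {factor!r}")
    return profile_from_values(shuffled, matrix.labels)


def _batch_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = (xc * yc).sum(axis=-1)
    den = np.sqrt((xc ** 2).sum(axis=-1) * (yc ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def attribute_factors(matrix1: EpochRateMatrix, matrix2: EpochRateMatrix,
                      config: AnalysisConfig | None = None,
                      seed: int | np.random.Generator | None = None
                      ) -> tuple[dict[str, bool | None], dict[str, float]]:
    """Which factors (epoch, reward, position) carry the cross-maze match.

    For each factor, both mazes' trial matrices are shuffled
    ``config.n_shuffles`` times within that factor's strata, profiles and
    cross-maze correlations recomputed, and the factor flagged when the
    observed r strictly exceeds the empirical ``shuffle_percentile``-th
    order statistic of the shuffled r distribution.  Degenerate profiles
    yield flags of ``None``.
    Returns ``(flags, summaries)`` where summaries hold the per-factor
    cutoff (the shuffled-r order statistic).
    """
    config = config or AnalysisConfig()
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    r_actual, _ = cross_maze_r(build_profile(matrix1), build_profile(matrix2))
    flags: dict[str, bool | None] = {}
    summaries: dict[str, float] = {}
    if not np.isfinite(r_actual):
        return {f: None for f in FACTORS}, summaries

    k = int(np.ceil(config.n_shuffles * config.shuffle_percentile / 100.0)) - 1
    for factor in FACTORS:
        p1 = _shuffled_profiles(matrix1, factor, config.n_shuffles, rng)
        p2 = _shuffled_profiles(matrix2, factor, config.n_shuffles, rng)
        r_sh = _batch_pearson(p1, p2)
        r_sh = np.where(np.isfinite(r_sh), r_sh, 0.0)
        cutoff = float(np.sort(r_sh)[k])
        flags[factor] = bool(r_actual > cutoff)
        summaries[factor] = cutoff
    return flags, summaries


def classify_and_attribute(matrix1: EpochRateMatrix, matrix2: EpochRateMatrix,
                           config: AnalysisConfig | None = None,
                           seed=None, attribute: bool = True) -> UnitClassification:
    """Full per-unit classification: r, category, and shuffle attribution."""
    config = config or AnalysisConfig()
    r, p = cross_maze_r(build_profile(matrix1), build_profile(matrix2))
    category = categorize(r, p, config)
    attribution: dict[str, bool | None] = {}
    summaries: dict[str, float] = {}
    if attribute and np.isfinite(r):
        attribution, summaries = attribute_factors(matrix1, matrix2, config, seed)
    elif attribute:
        attribution = {f: None for f in FACTORS}
    return UnitClassification(matrix1.unit_id, r, p, category, attribution, summaries)


# ---------------------------------------------------------------------------
# Three-way selectivity ANOVA and partial eta-squared
# ---------------------------------------------------------------------------

def _dummies(levels: np.ndarray) -> np.ndarray:
    """Full-rank treatment coding (drop first level)."""
    uniq = pd.unique(levels)
    return np.column_stack([(levels == u).astype(float) for u in uniq[1:]]) \
        if len(uniq) > 1 else np.empty((len(levels), 0))


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and model rank of OLS y ~ [1, X]."""
    Xf = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, _, rank, _ = np.linalg.lstsq(Xf, y, rcond=None)
    resid = y - Xf @ beta
    return float(resid @ resid), int(rank)


def selectivity_anova(matrix: EpochRateMatrix,
                      alpha: float = 0.01) -> SelectivityResult:
    """Three-way main-effects ANOVA (epoch, reward, position) on one maze.

    Observations are the matrix cells (one rate per trial x epoch).  In
    this task reward is a deterministic function of position (P1, P2
    nonrewarded; P3, P4 rewarded), so the three-factor design is
    rank-deficient; sums of squares are computed by nested model
    comparison in the Type-II spirit, with the aliasing resolved
    hierarchically: SS_epoch = R(epoch | reward, position),
    SS_reward = R(reward | epoch), and SS_position = R(position | epoch,
    reward) — the estimable within-reward-category position contrasts.
    Partial eta-squared per factor is SS_factor / (SS_factor + SS_error).
    The preferred level of each significant factor is the level with the
    maximal mean rate (ties broken toward the lowest-index level, logged).
    """
    n_trials, n_epochs = matrix.values.shape
    y = matrix.values.ravel()
    epoch = np.tile(np.asarray(matrix.epochs, dtype=object), n_trials)
    reward = np.repeat(matrix.labels["rewarded"].to_numpy(), n_epochs)
    position = np.repeat(matrix.labels["position"].to_numpy(object), n_epochs)

    D_e, D_r, D_p = _dummies(epoch), _dummies(reward), _dummies(position)
    full = np.column_stack([D_e, D_r, D_p])
    rss_full, rank_full = _rss(y, full)
    df_err = len(y) - rank_full
    if df_err <= 0:
        raise ValueError("rank-deficient design: no error degrees of freedom")

    comparisons = {
        "epoch": (np.column_stack([D_r, D_p]), full),
        "reward": (D_e, np.column_stack([D_e, D_r])),
        "position": (np.column_stack([D_e, D_r]), full),
    }
    p_values, eta2 = {}, {}
    tol = 1e-12 * max(float(y @ y), 1.0)  # numerically-zero SS threshold
    for factor, (X_red, X_big) in comparisons.items():
        rss_red, rank_red = _rss(y, X_red)
        rss_big, rank_big = _rss(y, X_big)
        ss_f = max(rss_red - rss_big, 0.0)
        df_f = rank_big - rank_red
        if df_f == 0 or ss_f <= tol:
            p_values[factor] = 1.0
            eta2[factor] = 0.0
            continue
        ms_err = rss_full / df_err
        if ms_err > 0:
            F = (ss_f / df_f) / ms_err
            p_values[factor] = float(stats.f.sf(F, df_f, df_err))
        else:  # deterministic factor effect with no residual variance
            p_values[factor] = 0.0
        eta2[factor] = float(ss_f / (ss_f + rss_full))

    level_arrays = {"epoch": epoch, "reward": reward, "position": position}
    preferred = {}
    for factor, levels in level_arrays.items():
        if p_values[factor] >= alpha:
            continue
        uniq = list(pd.unique(levels))
        means = np.array([y[levels == u].mean() for u in uniq])
        best = int(np.argmax(means))
        if np.sum(means == means[best]) > 1:
            logger.info("unit %s: tie on %s preferred level; taking lowest index",
                        matrix.unit_id, factor)
        preferred[factor] = str(uniq[best])

    return SelectivityResult(matrix.unit_id, p_values, eta2, preferred)


# ---------------------------------------------------------------------------
# Results table (external interface)
# ---------------------------------------------------------------------------

def results_table(classifications: list[UnitClassification],
                  selectivities: list[SelectivityResult] | None = None
                  ) -> pd.DataFrame:
    sel = {s.unit_id: s for s in selectivities or []}
    rows = []
    for c in classifications:
        row = {
            "unit_id": c.unit_id, "r": c.r, "p_r": c.p_r, "category": c.category,
            "epoch_flag": c.attribution.get("epoch"),
            "reward_flag": c.attribution.get("reward"),
            "position_flag": c.attribution.get("position"),
        }
        s = sel.get(c.unit_id)
        for f in FACTORS:
            row[f"eta2_{f}"] = s.partial_eta2[f] if s else np.nan
            row[f"p_{f}"] = s.p_values[f] if s else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
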
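"""Within- and across-maze trial-type decoding from single cells and ensembles.

Single-cell decoding: from a unit's 160 x 9 (trials x epochs) matrix per
maze, one random trial per trial type is held out (an 8 x 9 test set), a
regularized linear multiclass classifier is trained on the remaining
152 x 9 rows from maze 1, and tested within maze on the held-out rows and
across maze on the maze-2 rows with the identical within-type indices.
Accuracies are averaged over 1,000 repeats; chance is 1/8.

Ensemble decoding builds a pseudo-ensemble (units aligned by within-type
trial index), randomly selects 15 trials per trial type per repeat
(a 120 x 9 matrix per maze per unit), leaves one trial per type out, and
decodes each epoch separately from the population rate vector, averaging
over 200 repeats.  The classifier is one-vs-rest linear (binary machines
aggregated by argmax to 8 classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .response import EpochRateMatrix

CHANCE_LEVEL = 1.0 / 8.0


@dataclass
class DecodeResult:
    id: str
    accuracy_within: float
    accuracy_across: float
    per_epoch_within: np.ndarray | None = None
    per_epoch_across: np.ndarray | None = None
    n_repeats: int = 0
    seed: int | None = None


def _make_classifier():
    # L2-regularized linear machine, fixed C=1, features standardized on
    # the training fold only.
    return make_pipeline(
        StandardScaler(),
        LinearSVC(C=1.0, max_iter=5000, tol=1e-4),
    )


def _stacked(matrix: EpochRateMatrix) -> np.ndarray:
    """(8, n_per_type, 9) view; requires equal per-type counts."""
    counts = matrix.trials_per_type()
    n_set = set(counts.values())
    if len(counts) != 8 or len(n_set) != 1:
        raise ValueError("matrix must have 8 trial types with equal trial counts")
    n = n_set.pop()
    return matrix.values.reshape(8, n, matrix.values.shape[1])


def single_cell_decode(matrix1: EpochRateMatrix, matrix2: EpochRateMatrix,
                       n_repeats: int = 1000,
                       seed: int | np.random.Generator = 0) -> DecodeResult:
    """Leave-one-trial-per-type-out linear decoding for one unit.

    Per repeat, one random within-type index per type is held out of the
    maze-1 matrix; the classifier trains on the rest and is tested within
    maze (held-out maze-1 rows) and across maze (index-matched maze-2
    rows).  Returns mean accuracies over ``n_repeats``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x1, x2 = _stacked(matrix1), _stacked(matrix2)
    if x1.shape != x2.shape:
        raise ValueError("per-type trial counts differ between mazes")
    n_types, n_per_type, _ = x1.shape
    labels = np.repeat(np.arange(n_types), n_per_type - 1)
    test_labels = np.arange(n_types)

    acc_w = np.empty(n_repeats)
    acc_a = np.empty(n_repeats)
    for rep in range(n_repeats):
        held = rng.integers(0, n_per_type, size=n_types)
        keep = np.ones((n_types, n_per_type), dtype=bool)
        keep[np.arange(n_types), held] = False
        train = x1[keep].reshape(-1, x1.shape[2])
        test_w = x1[np.arange(n_types), held]
        test_a = x2[np.arange(n_types), held]
        clf = _make_classifier()
        clf.fit(train, labels)
        acc_w[rep] = np.mean(clf.predict(test_w) == test_labels)
        acc_a[rep] = np.mean(clf.predict(test_a) == test_labels)
    return DecodeResult(
        id=matrix1.unit_id,
        accuracy_within=float(acc_w.mean()),
        accuracy_across=float(acc_a.mean()),
        n_repeats=n_repeats,
    )


def ensemble_decode(matrices1: list[EpochRateMatrix],
                    matrices2: list[EpochRateMatrix],
                    n_units: int | None = None,
                    trials_per_type: int = 15,
                    n_repeats: int = 200,
                    seed: int | np.random.Generator = 0) -> DecodeResult:
    """Per-epoch pseudo-ensemble decoding of the 8 trial types.

    Units (possibly from different sessions) are aligned by within-type
    trial index.  Per repeat: ``trials_per_type`` indices per type are
    drawn (the 120 x 9 per-maze matrix at the default 15), one trial per
    type is left out, and for each epoch a one-vs-rest linear classifier
    decodes trial type from the population rate vector, tested within and
    across maze.  Accuracies are averaged over repeats.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(matrices1) != len(matrices2):
        raise ValueError("need both-maze matrices for every unit")
    if n_units is not None:
        if n_units > len(matrices1):
            raise ValueError(f"requested {n_units} units, only {len(matrices1)} available")
        pick = rng.choice(len(matrices1), size=n_units, replace=False)
        matrices1 = [matrices1[i] for i in pick]
        matrices2 = [matrices2[i] for i in pick]

    x1 = np.stack([_stacked(m) for m in matrices1], axis=-1)  # (8, n, 9, units)
    x2 = np.stack([_stacked(m) for m in matrices2], axis=-1)
    if x1.shape != x2.shape:
        raise ValueError("per-type trial counts differ between mazes")
    n_types, n_avail, n_epochs, _ = x1.shape
    if n_avail < trials_per_type:
        raise ValueError(f"need {trials_per_type} trials per type, have {n_avail}")

    labels = np.repeat(np.arange(n_types), trials_per_type - 1)
    test_labels = np.arange(n_types)
    acc_w = np.zeros((n_repeats, n_epochs))
    acc_a = np.zeros((n_repeats, n_epochs))
    for rep in range(n_repeats):
        sel = np.stack([
            rng.choice(n_avail, size=trials_per_type, replace=False)
            for _ in range(n_types)
        ])  # per-type sampled within-type indices, shared across units
        held_col = rng.integers(0, trials_per_type, size=n_types)
        sub1 = x1[np.arange(n_types)[:, None], sel]  # (8, 15, 9, units)
        sub2 = x2[np.arange(n_types)[:, None], sel]
        keep = np.ones((n_types, trials_per_type), dtype=bool)
        keep[np.arange(n_types), held_col] = False
        for e in range(n_epochs):
            train = sub1[..., e, :][keep]
            test_w = sub1[np.arange(n_types), held_col, e, :]
            test_a = sub2[np.arange(n_types), held_col, e, :]
            clf = _make_classifier()
            clf.fit(train, labels)
            acc_w[rep, e] = np.mean(clf.predict(test_w) == test_labels)
            acc_a[rep, e] = np.mean(clf.predict(test_a) == test_labels)
    return DecodeResult(
        id=f"ensemble_{len(matrices1)}u",
        accuracy_within=float(acc_w.mean()),
        accuracy_across=float(acc_a.mean()),
        per_epoch_within=acc_w.mean(axis=0),
        per_epoch_across=acc_a.mean(axis=0),
        n_repeats=n_repeats,
    )


def _shuffle_types(matrix: EpochRateMatrix, rng: np.random.Generator) -> EpochRateMatrix:
    """Random reassignment of rows to trial types (labels kept, rows permuted)."""
    perm = rng.permutation(len(matrix.values))
    return EpochRateMatrix(
        unit_id=matrix.unit_id,
        maze_id=matrix.maze_id,
        values=matrix.values[perm],
        labels=matrix.labels.reset_index(drop=True),
        epochs=matrix.epochs,
    )


def label_shuffle_null(decode_fn, matrix1, matrix2, n_null: int = 100,
                       seed: int | np.random.Generator = 0, **decode_kwargs
                       ) -> np.ndarray:
    """Null accuracy distribution with trial-type labels permuted.

    Runs the given decoder (``single_cell_decode`` or a compatible
    callable) ``n_null`` times on matrices whose rows are randomly
    reassigned to trial types in each maze; the resulting within-maze
    accuracies form a distribution centered at chance (1/8).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accs = np.empty(n_null)
    for i in range(n_null):
        m1 = _shuffle_types(matrix1, rng)
        m2 = _shuffle_types(matrix2, rng)
        res = decode_fn(m1, m2, seed=rng, **decode_kwargs)
        accs[i] = res.accuracy_within
    return accs
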
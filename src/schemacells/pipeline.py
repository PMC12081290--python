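"""Pipeline orchestration: simulate -> rates -> classify -> decode -> geometry.

Stages communicate through plain files in a run directory, so any stage
can be re-run in isolation; a JSON manifest records the configuration
snapshot, global seed, input digests and per-stage outputs.  A single
global seed fans out to independent per-stage streams, and re-running a
manifest reproduces byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoding import ensemble_decode, single_cell_decode
from .geometry import (
    PopulationTensor,
    embed_population,
    lda_cluster_silhouette,
    procrustes_dissimilarity,
    tca_decompose,
)
from .response import EPOCH_NAMES, EpochRateMatrix, build_epoch_matrix, build_profile
from .schema_class import (
    FACTORS,
    AnalysisConfig,
    classify_and_attribute,
    results_table,
    selectivity_anova,
    threshold_sweep,
)
from .synthetic import BehaviorSpec, generate_population
from .task_model import make_default_design, read_session, write_session

logger = logging.getLogger(__name__)

STAGES = ("simulate", "rates", "classify", "decode", "geometry", "report")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "runs/schemacells",
    "session": {
        "trials_per_type": 20,
        "n_units": 200,
        "category_mix": [0.4, 0.3, 0.3],
        "p_correct": 0.9,
    },
    "classify": {
        "r_schema": 0.8,
        "r_noncoding": 0.4,
        "alpha_corr": 0.01,
        "n_shuffles": 1000,
        "shuffle_percentile": 99,
        "alpha_anova": 0.01,
        "attribute": True,
        "epoch_subset": None,
        "threshold_sweep": None,
    },
    "decode": {
        "n_single_units": 10,
        "single_repeats": 1000,
        "ensemble_units": 50,
        "ensemble_repeats": 200,
        "ensemble_trials_per_type": 15,
    },
    "geometry": {
        "tca_rank": 6,
        "tca_restarts": 5,
        "tca_iters": 200,
        "n_neighbors": 19,
    },
    "report": {"plots": True},
}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    """Parse a YAML config, filling defaults and failing fast on unknown keys."""
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    def merge(default, given, prefix=""):
        out = dict(default)
        for key, value in given.items():
            if key not in default:
                raise ConfigError(f"unknown config key {prefix + key!r}")
            if isinstance(default[key], dict) and isinstance(value, dict):
                out[key] = merge(default[key], value, prefix=f"{prefix}{key}.")
            else:
                out[key] = value
        return out

    return merge(DEFAULT_CONFIG, user)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    idx = STAGES.index(stage)
    return np.random.default_rng(np.random.SeedSequence([seed, idx]))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, list[str]] = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: dict, out: Path, seed: int) -> list[str]:
    sess = config["session"]
    design = make_default_design(sess["trials_per_type"])
    behavior = BehaviorSpec(p_correct={p: sess["p_correct"]
                                       for p in ("P1", "P2", "P3", "P4")})
    rng = _stage_rng(seed, "simulate")
    trials, spikes, specs = generate_population(
        design, sess["n_units"], tuple(sess["category_mix"]), rng, behavior)
    write_session(out / "trials.csv", out / "spikes.csv", trials, spikes)
    truth = [dict(s.to_dict(), intended_category=getattr(s, "intended_category", None))
             for s in specs]
    (out / "tuning_truth.json").write_text(json.dumps(truth))
    logger.info("simulate: %d trials, %d units", len(trials), len(spikes))
    return ["trials.csv", "spikes.csv", "tuning_truth.json"]


def stage_rates(config: dict, out: Path, seed: int) -> list[str]:
    design = make_default_design(config["session"]["trials_per_type"])
    trials, spikes = read_session(out / "trials.csv", out / "spikes.csv", design)
    frames = []
    for st in spikes:
        for maze_id in design.maze_ids:
            m = build_epoch_matrix(st, trials, design, maze_id)
            frame = m.labels.copy()
            frame.insert(0, "maze_id", maze_id)
            frame.insert(0, "unit_id", st.unit_id)
            for j, ep in enumerate(m.epochs):
                frame[ep] = m.values[:, j]
            frames.append(frame)
    rates = pd.concat(frames, ignore_index=True)
    rates.to_csv(out / "rates.csv", index=False, float_format="%.6f")
    logger.info("rates: %d units x %d rows", len(spikes), len(rates))
    return ["rates.csv"]


def load_matrices(out: Path) -> dict[str, dict[str, EpochRateMatrix]]:
    """{unit_id: {maze_id: EpochRateMatrix}} from the rates stage output."""
    rates = pd.read_csv(out / "rates.csv")
    label_cols = ["type_key", "subsequence", "position", "rewarded", "within_type_index"]
    result: dict[str, dict[str, EpochRateMatrix]] = {}
    for (unit_id, maze_id), grp in rates.groupby(["unit_id", "maze_id"], sort=False):
        result.setdefault(str(unit_id), {})[str(maze_id)] = EpochRateMatrix(
            unit_id=str(unit_id),
            maze_id=str(maze_id),
            values=grp[list(EPOCH_NAMES)].to_numpy(float),
            labels=grp[label_cols].reset_index(drop=True),
        )
    return result


def _slice_epochs(matrix: EpochRateMatrix, epochs: list[str]) -> EpochRateMatrix:
    idx = [matrix.epochs.index(e) for e in epochs]
    return EpochRateMatrix(matrix.unit_id, matrix.maze_id,
                           matrix.values[:, idx], matrix.labels, tuple(epochs))


def stage_classify(config: dict, out: Path, seed: int) -> list[str]:
    cc = config["classify"]
    acfg = AnalysisConfig(
        r_schema=cc["r_schema"], r_noncoding=cc["r_noncoding"],
        alpha_corr=cc["alpha_corr"], n_shuffles=cc["n_shuffles"],
        shuffle_percentile=cc["shuffle_percentile"], alpha_anova=cc["alpha_anova"],
        seed=seed,
    )
    rng = _stage_rng(seed, "classify")
    matrices = load_matrices(out)
    maze_ids = sorted(next(iter(matrices.values())))
    subset = cc["epoch_subset"]

    classifications, selectivities = [], []
    for unit_id, per_maze in matrices.items():
        m1, m2 = per_maze[maze_ids[0]], per_maze[maze_ids[1]]
        if subset:
            m1, m2 = _slice_epochs(m1, subset), _slice_epochs(m2, subset)
        classifications.append(
            classify_and_attribute(m1, m2, acfg, seed=rng, attribute=cc["attribute"]))
        selectivities.append(selectivity_anova(per_maze[maze_ids[0]],
                                               alpha=cc["alpha_anova"]))
    table = results_table(classifications, selectivities)
    table.to_csv(out / "classification.csv", index=False, float_format="%.6g")
    outputs = ["classification.csv"]

    if cc["threshold_sweep"]:
        pairs = []
        for per_maze in matrices.values():
            m1, m2 = per_maze[maze_ids[0]], per_maze[maze_ids[1]]
            pairs.append((build_profile(m1).values, build_profile(m2).values))
        thresholds = np.asarray(cc["threshold_sweep"], dtype=float)
        frac = threshold_sweep(pairs, thresholds, acfg)
        pd.DataFrame({"threshold": thresholds, "schema_fraction": frac}).to_csv(
            out / "threshold_sweep.csv", index=False)
        outputs.append("threshold_sweep.csv")
    counts = table["category"].value_counts()
    logger.info("classify: %s", counts.to_dict())
    return outputs


def stage_decode(config: dict, out: Path, seed: int) -> list[str]:
    dc = config["decode"]
    rng = _stage_rng(seed, "decode")
    matrices = load_matrices(out)
    maze_ids = sorted(next(iter(matrices.values())))
    cls = pd.read_csv(out / "classification.csv")

    rows = []
    unit_ids = list(matrices)
    pick = unit_ids if len(unit_ids) <= dc["n_single_units"] else [
        unit_ids[i] for i in rng.choice(len(unit_ids), dc["n_single_units"],
                                        replace=False)
    ]
    for unit_id in pick:
        m1 = matrices[unit_id][maze_ids[0]]
        m2 = matrices[unit_id][maze_ids[1]]
        res = single_cell_decode(m1, m2, n_repeats=dc["single_repeats"], seed=rng)
        rows.append({"id": unit_id, "mode": "single", "epoch": "all",
                     "within_acc": res.accuracy_within,
                     "across_acc": res.accuracy_across,
                     "n_repeats": res.n_repeats, "seed": seed})

    schema_units = cls.loc[cls["category"] == "schema", "unit_id"].astype(str)
    schema_units = [u for u in schema_units if u in matrices]
    n_ens = min(dc["ensemble_units"], len(schema_units))
    if n_ens >= 2:
        m1s = [matrices[u][maze_ids[0]] for u in schema_units]
        m2s = [matrices[u][maze_ids[1]] for u in schema_units]
        res = ensemble_decode(m1s, m2s, n_units=n_ens,
                              trials_per_type=dc["ensemble_trials_per_type"],
                              n_repeats=dc["ensemble_repeats"], seed=rng)
        for e, name in enumerate(EPOCH_NAMES):
            rows.append({"id": res.id, "mode": "ensemble", "epoch": name,
                         "within_acc": res.per_epoch_within[e],
                         "across_acc": res.per_epoch_across[e],
                         "n_repeats": res.n_repeats, "seed": seed})
        rows.append({"id": res.id, "mode": "ensemble", "epoch": "all",
                     "within_acc": res.accuracy_within,
                     "across_acc": res.accuracy_across,
                     "n_repeats": res.n_repeats, "seed": seed})
    else:
        logger.warning("decode: too few schema cells (%d) for ensemble decoding",
                       len(schema_units))
    pd.DataFrame(rows).to_csv(out / "decoding.csv", index=False, float_format="%.6f")
    return ["decoding.csv"]


def stage_geometry(config: dict, out: Path, seed: int) -> list[str]:
    gc = config["geometry"]
    rng = _stage_rng(seed, "geometry")
    matrices = load_matrices(out)
    maze_ids = sorted(next(iter(matrices.values())))
    unit_ids = list(matrices)

    # Condition-by-epoch mean responses: units x (maze * 8 types * 9 epochs)
    profiles = {m: np.vstack([build_profile(matrices[u][m]).values for u in unit_ids])
                for m in maze_ids}
    responses = np.hstack([profiles[m] for m in maze_ids])
    maze_labels = np.repeat(maze_ids, profiles[maze_ids[0]].shape[1])

    result: dict = {"procrustes": {}}
    for method in ("linear", "nonlinear"):
        pts = embed_population(responses, maze_labels, method=method,
                               n_neighbors=gc["n_neighbors"])
        result["procrustes"][method] = procrustes_dissimilarity(
            pts[maze_ids[0]], pts[maze_ids[1]])

    # Trials x (units * epochs) matrix for clustering + the trial tensor
    per_trial = {m: np.stack([matrices[u][m].values for u in unit_ids], axis=0)
                 for m in maze_ids}  # (N, K_m, 9)
    tensor_vals = np.concatenate([per_trial[m] for m in maze_ids], axis=1)  # (N, K, 9)
    labels = pd.concat(
        [matrices[unit_ids[0]][m].labels.assign(maze_id=m) for m in maze_ids],
        ignore_index=True)
    tensor = PopulationTensor(np.transpose(tensor_vals, (0, 2, 1)),
                              labels[["maze_id", "type_key"]])
    tensor.save_h5(out / "tensor.h5")

    K = tensor_vals.shape[1]
    trial_matrix = tensor_vals.transpose(1, 0, 2).reshape(K, -1)
    type_labels = (labels["maze_id"] + ":" + labels["type_key"]).to_numpy()
    silhouettes, _ = lda_cluster_silhouette(trial_matrix, type_labels)
    result["silhouette_by_type"] = silhouettes
    result["silhouette_mean"] = float(np.mean(list(silhouettes.values())))

    factors, err = tca_decompose(tensor, rank=gc["tca_rank"],
                                 n_restarts=gc["tca_restarts"], seed=rng,
                                 n_iter=gc["tca_iters"])
    result["tca"] = {"rank": gc["tca_rank"], "relative_error": err}
    for name, f in zip(("unit", "epoch", "trial"), factors):
        pd.DataFrame(f, columns=[f"c{i}" for i in range(f.shape[1])]).to_csv(
            out / f"tca_{name}_factors.csv", index=False, float_format="%.6f")
    (out / "geometry.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    return ["geometry.json", "tensor.h5", "tca_unit_factors.csv",
            "tca_epoch_factors.csv", "tca_trial_factors.csv"]


def summarize(out: Path, plots: bool = True) -> dict:
    """Machine-readable summary of a completed (or partial) run."""
    summary: dict = {"missing": []}
    cls_path = out / "classification.csv"
    if cls_path.exists():
        cls = pd.read_csv(cls_path)
        summary["n_units"] = int(len(cls))
        summary["category_counts"] = {
            c: int((cls["category"] == c).sum())
            for c in ("schema", "nonschema", "noncoding")
        }
        flags = cls[["epoch_flag", "reward_flag", "position_flag"]].map(
            lambda v: v is True or str(v) == "True")
        venn: dict[str, int] = {}
        for _, row in flags.iterrows():
            key = "+".join(f for f, v in zip(FACTORS, row) if v) or "none"
            venn[key] = venn.get(key, 0) + 1
        summary["attribution_venn"] = venn
    else:
        summary["missing"].append("classification.csv")

    dec_path = out / "decoding.csv"
    if dec_path.exists():
        dec = pd.read_csv(dec_path)
        single = dec[dec["mode"] == "single"]
        if len(single):
            summary["single_cell_decoding"] = {
                "mean_within": float(single["within_acc"].mean()),
                "mean_across": float(single["across_acc"].mean()),
            }
        ens = dec[(dec["mode"] == "ensemble") & (dec["epoch"] == "all")]
        if len(ens):
            summary["ensemble_decoding"] = {
                "within": float(ens["within_acc"].iloc[0]),
                "across": float(ens["across_acc"].iloc[0]),
            }
    else:
        summary["missing"].append("decoding.csv")

    geo_path = out / "geometry.json"
    if geo_path.exists():
        summary["geometry"] = json.loads(geo_path.read_text())
    else:
        summary["missing"].append("geometry.json")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    if plots and "category_counts" in summary:
        _plot_summary(summary, out)
    return summary


def _plot_summary(summary: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    counts = summary["category_counts"]
    axes[0].bar(list(counts), list(counts.values()), color="tab:blue")
    axes[0].set_ylabel("units")
    axes[0].set_title("cross-maze categories")
    if "single_cell_decoding" in summary:
        d = summary["single_cell_decoding"]
        axes[1].bar(["within", "across"], [d["mean_within"], d["mean_across"]],
                    color="tab:orange")
        axes[1].axhline(1 / 8, ls="--", c="k", lw=1, label="chance (12.5%)")
        axes[1].set_ylabel("decoding accuracy")
        axes[1].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "summary.png", dpi=120)
    plt.close(fig)


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "rates": stage_rates,
    "classify": stage_classify,
    "decode": stage_decode,
    "geometry": stage_geometry,
}


def run_pipeline(config_path=None, config: dict | None = None,
                 out_dir=None, seed: int | None = None,
                 stages: list[str] | None = None) -> RunManifest:
    """Run the full pipeline (or selected stages) from a config.

    Returns the saved :class:`RunManifest`; re-running with the same
    config and seed reproduces identical tables.
    """
    if config is None:
        config = load_config(config_path) if config_path else merge_config({})
    else:
        config = merge_config(config)
    if seed is not None:
        config["seed"] = seed
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, seed=config["seed"])

    for stage in stages or STAGES:
        if stage == "report":
            summarize(out, plots=config["report"]["plots"])
            manifest.outputs["report"] = ["summary.json"]
            continue
        outputs = STAGE_FUNCS[stage](config, out, config["seed"])
        manifest.outputs[stage] = outputs
        for name in outputs:
            p = out / name
            if p.suffix == ".csv":
                manifest.input_digests[name] = _digest(p)
    manifest.save(out / "manifest.json")
    return manifest
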
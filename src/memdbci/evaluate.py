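"""Pipeline orchestration and evaluation metrics.

``run_pipeline`` wires the whole classification chain together:
stratified train/test split -> per-channel min-max normalization ->
decomposition + feature extraction -> network training -> prediction ->
confusion matrix / accuracy / error rate. All randomness flows from one
root seed split into named per-stage streams, so a report regenerates
byte-identically from its embedded config.

Feature columns are rescaled onto [-1, +1] using the *training* split's
extremes before they reach the network (raw energies span orders of
magnitude and would saturate a sigmoidal layer); the same affine map is
applied to the test split, so no test information leaks into training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import ffbpnn
from .exceptions import InvalidSpecError
from .features import FeatureConfig, extract_features, feature_names
from .preprocess import normalize_trial
from .synth import TrialSet

__all__ = [
    "ConfusionMatrix",
    "PipelineConfig",
    "confusion",
    "stratified_split",
    "extract_feature_matrix",
    "run_pipeline",
    "save_trials",
    "load_trials",
    "save_model",
    "load_model",
]


@dataclass
class ConfusionMatrix:
    """K x K count matrix, rows = true class, cols = predicted class."""

    counts: np.ndarray
    class_names: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    @property
    def error_rate(self) -> float:
        return 1.0 - self.accuracy

    def to_text(self) -> str:
        width = max(6, max(len(n) for n in self.class_names) + 1)
        head = " " * width + "".join(f"{n:>{width}}" for n in self.class_names)
        rows = [
            f"{n:>{width}}" + "".join(f"{c:>{width}d}" for c in row)
            for n, row in zip(self.class_names, self.counts)
        ]
        return "\n".join(
            [head, *rows, f"accuracy {self.accuracy:.4f}  error {self.error_rate:.4f}"]
        )


def confusion(true_labels, pred_labels, n_classes: int) -> ConfusionMatrix:
    """Count matrix of true vs predicted labels in ``0..n_classes-1``."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_labels, dtype=int)
    if t.shape != p.shape:
        raise InvalidSpecError("label arrays must have equal length")
    if t.size and (min(t.min(), p.min()) < 0 or max(t.max(), p.max()) >= n_classes):
        raise InvalidSpecError(f"labels out of range 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts, class_names=[str(k) for k in range(n_classes)])


def stratified_split(
    labels, train_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split preserving class proportions within one trial."""
    if not 0 < train_frac < 1:
        raise InvalidSpecError("train fraction must be in (0, 1)")
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end pipeline, JSON-serializable."""

    normalization: str = "trial"  # "trial" | "recording" | "off"
    features: FeatureConfig = field(default_factory=FeatureConfig)
    hidden: tuple[int, ...] = (10,)
    tf: str = "tansig"
    alpha: float = 1e-3
    error_goal: float = 1e-2
    max_epochs: int = 2000
    train_frac: float = 0.7
    seed: int = 0
    scale_features: bool = True


def _normalize(trials: list[np.ndarray], mode: str) -> list[np.ndarray]:
    if mode == "off":
        return trials
    if mode == "trial":
        return [normalize_trial(t) for t in trials]
    if mode == "recording":
        # one affine map per channel over the whole recording
        lo = np.min([t.min(axis=1) for t in trials], axis=0)
        hi = np.max([t.max(axis=1) for t in trials], axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        return [
            2.0 * (t - lo[:, None]) / span[:, None] - 1.0 for t in trials
        ]
    raise InvalidSpecError(f"unknown normalization mode {mode!r}")


def extract_feature_matrix(
    trials: list[np.ndarray], fs: float, cfg: FeatureConfig
) -> np.ndarray:
    return np.array([extract_features(t, fs, cfg).values for t in trials])


def run_pipeline(cfg: PipelineConfig, data: TrialSet) -> dict:
    """Run normalize -> decompose -> featurize -> train -> evaluate.

    Returns a JSON-serializable report with the confusion matrix,
    accuracy, error rate, MSE history and full provenance (config and
    derived per-stage seeds).
    """
    labels = np.asarray(data.labels, dtype=int)
    n_classes = int(labels.max()) + 1
    if n_classes < 2:
        raise InvalidSpecError("need at least 2 classes")
    counts = np.bincount(labels, minlength=n_classes)
    if counts.min() < 4:
        raise InvalidSpecError("need at least 4 trials per class")

    root = np.random.SeedSequence(cfg.seed)
    split_seed, net_seed = (int(s.generate_state(1)[0] % 2**31) for s in root.spawn(2))

    trials = _normalize(data.trials, cfg.normalization)
    train_idx, test_idx = stratified_split(labels, cfg.train_frac, split_seed)

    F = extract_feature_matrix(trials, data.fs, cfg.features)
    F_train, F_test = F[train_idx], F[test_idx]
    y_train, y_test = labels[train_idx], labels[test_idx]

    if cfg.scale_features:
        lo = F_train.min(axis=0)
        hi = F_train.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        scale = lambda A: np.where(  # noqa: E731
            (hi > lo)[None, :], 2.0 * (A - lo[None, :]) / span[None, :] - 1.0, 0.0
        )
        F_train, F_test = scale(F_train), scale(F_test)

    T_train = ffbpnn.one_hot(y_train, n_classes)
    tcfg = ffbpnn.TrainConfig(
        alpha=cfg.alpha,
        error_goal=cfg.error_goal,
        max_epochs=cfg.max_epochs,
        seed=net_seed,
    )
    sizes = [F_train.shape[1], *cfg.hidden, n_classes]
    result = ffbpnn.train(F_train, T_train, sizes, tcfg, tf=cfg.tf)

    y_pred = ffbpnn.classify(result.params, F_test)
    cm = confusion(y_test, y_pred, n_classes)

    cfg_dict = asdict(cfg)
    cfg_dict["features"]["stop"] = asdict(cfg.features.stop)
    return {
        "config": cfg_dict,
        "seeds": {"root": cfg.seed, "split": split_seed, "network": net_seed},
        "n_trials": len(data.trials),
        "n_train": int(train_idx.size),
        "n_test": int(test_idx.size),
        "confusion": cm.counts.tolist(),
        "accuracy": cm.accuracy,
        "error_rate": cm.error_rate,
        "mse_history": result.mse_history,
        "stopped_by": result.stopped_by,
        "epochs_run": result.epochs_run,
        "feature_names": feature_names(data.trials[0].shape[0], cfg.features),
    }


# ---------------------------------------------------------------------------
# on-disk trial sets: one delimited text file per trial (rows = channels),
# labels.csv (trial_id,label) and manifest.json (fs + generator params)


def save_trials(data: TrialSet, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, trial in enumerate(data.trials):
        np.savetxt(out / f"trial_{i:04d}.csv", trial, delimiter=",")
    with open(out / "labels.csv", "w") as fh:
        fh.write("trial_id,label\n")
        for i, lab in enumerate(data.labels):
            fh.write(f"{i},{int(lab)}\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"fs": data.fs, "n_trials": len(data.trials), "meta": data.meta}, fh, indent=1)


def load_trials(in_dir: str | Path) -> TrialSet:
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    rows = (src / "labels.csv").read_text().strip().splitlines()[1:]
    labels = np.array([int(r.split(",")[1]) for r in rows])
    trials = [
        np.atleast_2d(np.loadtxt(src / f"trial_{i:04d}.csv", delimiter=","))
        for i in range(len(labels))
    ]
    return TrialSet(trials=trials, labels=labels, fs=float(manifest["fs"]), meta=manifest.get("meta", {}))


def save_model(params: ffbpnn.NetParams, path: str | Path) -> None:
    obj = {
        "layer_sizes": list(params.layer_sizes),
        "tf": list(params.tf),
        "W": [w.tolist() for w in params.W],
        "b": [b.tolist() for b in params.b],
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def load_model(path: str | Path) -> ffbpnn.NetParams:
    obj = json.loads(Path(path).read_text())
    return ffbpnn.NetParams(
        layer_sizes=obj["layer_sizes"],
        W=[np.array(w) for w in obj["W"]],
        b=[np.array(b) for b in obj["b"]],
        tf=obj["tf"],
    )
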
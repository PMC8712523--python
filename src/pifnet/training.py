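"""Training and validation protocol for the model-family comparison.

The protocol mirrors standard practice for CNN benchmarking on registered
neuroimaging volumes: repeated random train/validation/test splits (grouped
by subject where subjects contribute several images), random hyperparameter
search over a small discrete grid, Adam optimization of the cross-entropy,
early stopping on the validation metric, and test-set metrics reported as
percentages (AUC ROC, balanced accuracy, sensitivity, specificity).  The
convergence-speed comparison between model families counts the validation
evaluations until early stopping on matched splits and seeds.

Conventions the protocol leaves open and how they are fixed here: one
"iteration" for the patience counter is one validation evaluation (one
epoch at this data scale); "improvement" means a higher validation balanced
accuracy, ties broken by a lower validation loss; the optimizer is Adam at
the sampled learning rate; a hard cap (default 200 epochs) terminates runs
stuck in their initial optimization basin.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .architectures import ModelHandle

__all__ = [
    "HYPERPARAMETER_GRID", "SplitPlan", "TrialRecord",
    "normalize", "augment", "sample_hyperparameters", "make_splits",
    "train", "evaluate", "convergence_report",
]

#: The discrete random-search grid for the protocol.
HYPERPARAMETER_GRID = {
    "architecture": ("A", "B"),
    "learning_rate": (1e-4, 5e-5),
    "batch_size": (4, 6, 12),
    "patience": (12, 16),
}


def normalize(volume: np.ndarray) -> np.ndarray:
    """Max-intensity normalization: divide by the volume's maximum value."""
    volume = np.asarray(volume)
    peak = volume.max()
    if not peak > 0:
        raise ValueError("cannot max-normalize a volume with non-positive maximum")
    return volume / peak


def _translate(volume: np.ndarray, offsets: tuple[int, ...]) -> np.ndarray:
    out = np.zeros_like(volume)
    src, dst = [], []
    for off, s in zip(offsets, volume.shape):
        if off >= 0:
            src.append(slice(0, s - off))
            dst.append(slice(off, s))
        else:
            src.append(slice(-off, s))
            dst.append(slice(0, s + off))
    out[tuple(dst)] = volume[tuple(src)]
    return out


def augment(volume: np.ndarray, model_family: str,
            rng: np.random.Generator, *, max_translation: int = 2,
            ) -> np.ndarray:
    """Random translation, plus sagittal flip for non-PIF families.

    PIF models receive translation only: a flip would swap the content of
    left and right latent patches, violating the requirement that each
    patch sees the same content on every iteration.  The sagittal axis is
    the first spatial axis.  Translation is zero-filled and bounded by
    ``max_translation`` voxels per axis.
    """
    offsets = tuple(int(rng.integers(-max_translation, max_translation + 1))
                    for _ in range(volume.ndim))
    out = _translate(volume, offsets)
    if model_family != "pif" and rng.random() < 0.5:
        out = out[::-1].copy()
    return out


def sample_hyperparameters(rng: np.random.Generator, n_draws: int = 5
                           ) -> list[dict]:
    """Draw ``n_draws`` settings from the grid, each architecture >= 2 times.

    The architecture constraint makes the comparison between capacity
    variants meaningful within one split; it requires ``n_draws >= 4``.
    Draws are redrawn wholesale until the constraint holds, so the sequence
    is a deterministic function of the generator state.
    """
    if n_draws < 4:
        raise ValueError(
            "the architecture-balance constraint needs at least 4 draws")
    while True:
        archs = [str(rng.choice(HYPERPARAMETER_GRID["architecture"]))
                 for _ in range(n_draws)]
        if min(archs.count(a) for a in HYPERPARAMETER_GRID["architecture"]) >= 2:
            break
    draws = []
    for arch in archs:
        draws.append({
            "architecture": arch,
            "learning_rate": float(rng.choice(HYPERPARAMETER_GRID["learning_rate"])),
            "batch_size": int(rng.choice(HYPERPARAMETER_GRID["batch_size"])),
            "patience": int(rng.choice(HYPERPARAMETER_GRID["patience"])),
        })
    return draws


@dataclass(frozen=True)
class SplitPlan:
    """Train/validation/test fractions and repetition count.

    ``group_by_subject`` keeps all images of one subject inside one
    partition (mandatory when subjects contribute several time points).
    """

    fractions: tuple[float, float, float] = (0.64, 0.16, 0.20)
    n_repetitions: int = 10
    group_by_subject: bool = True

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {self.fractions}")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("all three fractions must be positive")


def make_splits(subject_ids: list[str], plan: SplitPlan,
                rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Repeated random (train, val, test) index splits, grouped by subject.

    Groups are shuffled and assigned whole to partitions until each
    partition reaches its image-count target, so realized fractions match
    the plan to within one subject group.  Partitions are always disjoint.
    """
    n = len(subject_ids)
    groups: dict[str, list[int]] = {}
    if plan.group_by_subject:
        for i, sid in enumerate(subject_ids):
            groups.setdefault(sid, []).append(i)
    else:
        groups = {str(i): [i] for i in range(n)}
    keys = sorted(groups)
    largest = max(len(v) for v in groups.values())
    targets = [f * n for f in plan.fractions]
    if largest > min(targets):
        raise ValueError(
            f"a subject group of {largest} images exceeds the smallest "
            f"partition target {min(targets):.1f}")

    splits = []
    for _ in range(plan.n_repetitions):
        order = list(rng.permutation(keys))
        parts: list[list[int]] = [[], [], []]
        t_train, t_val = targets[0], targets[0] + targets[1]
        count = 0
        for key in order:
            idx = groups[key]
            if count < t_train:
                parts[0].extend(idx)
            elif count < t_val:
                parts[1].extend(idx)
            else:
                parts[2].extend(idx)
            count += len(idx)
        splits.append(tuple(np.array(sorted(p), dtype=int) for p in parts))
    return splits


@dataclass
class TrialRecord:
    """Provenance and outcome of one training run."""

    split_id: int
    seed: int
    hyperparams: dict
    val_series: list[float] = field(default_factory=list)
    stop_iteration: int = 0
    wallclock_s: float = 0.0
    test_metrics: dict = field(default_factory=dict)
    diverged: bool = False

    def to_dict(self) -> dict:
        return {
            "split_id": self.split_id, "seed": self.seed,
            "hyperparams": self.hyperparams, "val_series": self.val_series,
            "stop_iteration": self.stop_iteration,
            "wallclock_s": self.wallclock_s,
            "test_metrics": self.test_metrics, "diverged": self.diverged,
        }


def _metrics_from_scores(scores: np.ndarray, preds: np.ndarray,
                         labels: np.ndarray) -> dict:
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels)
    pos, neg = labels == 1, labels == 0
    sens = float((preds[pos] == 1).mean()) if pos.any() else float("nan")
    spec = float((preds[neg] == 0).mean()) if neg.any() else float("nan")
    out = {
        "sensitivity": 100.0 * sens,
        "specificity": 100.0 * spec,
        "balanced_accuracy": 100.0 * (sens + spec) / 2.0,
    }
    if pos.any() and neg.any():
        out["auc_roc"] = 100.0 * float(roc_auc_score(labels, scores))
    else:
        out["auc_roc"] = None  # AUC undefined on a single-class set
    return out


def evaluate(model: ModelHandle, volumes: np.ndarray, labels: np.ndarray,
             *, batch_size: int = 16) -> dict:
    """Test metrics as percentages.

    Balanced accuracy is the mean of sensitivity and specificity; the AUC
    is the rank statistic of the class-1 softmax score and is ``None`` when
    the set contains a single class (the other metrics are still computed).
    """
    if len(volumes) == 0:
        raise ValueError("empty evaluation set")
    from .nn import softmax

    scores, preds = [], []
    for start in range(0, len(volumes), batch_size):
        x = np.asarray(volumes[start:start + batch_size])[:, None]
        logits = model.predict_logits(x)
        scores.append(softmax(logits)[:, 1])
        preds.append(logits.argmax(axis=1))
    return _metrics_from_scores(np.concatenate(scores), np.concatenate(preds),
                                labels)


def train(handle: ModelHandle, volumes: np.ndarray, labels: np.ndarray,
          split: tuple[np.ndarray, np.ndarray, np.ndarray],
          hyperparams: dict, rng: np.random.Generator, *,
          split_id: int = 0, seed: int = 0, max_epochs: int = 200,
          use_augmentation: bool = True, max_translation: int = 2
          ) -> TrialRecord:
    """Optimize ``handle`` on one split with early stopping.

    The validation balanced accuracy is evaluated once per epoch; training
    stops when it has not improved for ``hyperparams['patience']``
    evaluations (or at ``max_epochs``).  The best-validation weights are
    restored before the test-set evaluation.
    """
    train_idx, val_idx, test_idx = (np.asarray(s) for s in split)
    patience = int(hyperparams["patience"])
    if patience < 1:
        raise ValueError("patience must be >= 1")
    batch_size = int(hyperparams["batch_size"])
    opt = handle.make_optimizer(float(hyperparams["learning_rate"]))

    record = TrialRecord(split_id=split_id, seed=seed,
                         hyperparams=dict(hyperparams))
    best_metric, best_loss = -np.inf, np.inf
    best_params = {k: v.copy() for k, v in handle.network.named_params().items()}
    since_improvement = 0
    t0 = time.perf_counter()

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(train_idx))
        diverged = False
        for start in range(0, len(order), batch_size):
            idx = train_idx[order[start:start + batch_size]]
            batch = volumes[idx]
            if use_augmentation:
                batch = np.stack([
                    augment(v, handle.family, rng,
                            max_translation=max_translation) for v in batch])
            loss, grads = handle.model.loss_and_grads(
                np.asarray(batch)[:, None], labels[idx])
            if not np.isfinite(loss):
                diverged = True
                break
            opt.step(grads)
        if diverged:
            record.diverged = True
            break

        val, val_loss = _evaluate_with_loss(handle, volumes[val_idx],
                                            labels[val_idx])
        record.val_series.append(val["balanced_accuracy"])
        record.stop_iteration = epoch
        # patience counts evaluations since the metric last strictly
        # improved; the loss tie-break only selects which equal-metric
        # checkpoint is kept
        if (val["balanced_accuracy"] > best_metric
                or (val["balanced_accuracy"] == best_metric
                    and val_loss < best_loss - 1e-12)):
            best_loss = val_loss
            best_params = {k: v.copy()
                           for k, v in handle.network.named_params().items()}
        if val["balanced_accuracy"] > best_metric:
            best_metric = val["balanced_accuracy"]
            since_improvement = 0
        else:
            since_improvement += 1
        if since_improvement >= patience:
            break

    record.wallclock_s = time.perf_counter() - t0
    handle.network.set_params(best_params)
    if len(test_idx):
        record.test_metrics = evaluate(handle, volumes[test_idx],
                                       labels[test_idx])
    return record


def _evaluate_with_loss(handle: ModelHandle, volumes: np.ndarray,
                        labels: np.ndarray, batch_size: int = 16
                        ) -> tuple[dict, float]:
    """Metrics plus mean cross-entropy from a single forward pass."""
    from .nn import cross_entropy, softmax

    scores, preds, total = [], [], 0.0
    for start in range(0, len(volumes), batch_size):
        x = np.asarray(volumes[start:start + batch_size])[:, None]
        y = labels[start:start + batch_size]
        logits = handle.predict_logits(x)
        loss, _ = cross_entropy(logits, y)
        total += loss * len(y)
        scores.append(softmax(logits)[:, 1])
        preds.append(logits.argmax(axis=1))
    metrics = _metrics_from_scores(np.concatenate(scores),
                                   np.concatenate(preds), labels)
    return metrics, total / len(volumes)


def convergence_report(records: dict[str, list[TrialRecord]]):
    """Per-family convergence summary plus the paired PIF-vs-baseline check.

    Returns a DataFrame with one row per model family (mean and standard
    error of the stop iteration, mean recorded wall-clock — reported, never
    asserted, since it is hardware-dependent).  When both a ``pif`` and a
    ``baseline`` family are present, the frame's ``attrs`` carry the paired
    per-split iteration differences (pif - baseline) on matched split ids.
    """
    import pandas as pd

    if len(records) < 2:
        raise ValueError("need at least two model families to compare")
    for fam, recs in records.items():
        if len(recs) < 3:
            raise ValueError(f"family '{fam}' has fewer than 3 records")
    split_sets = {fam: sorted(r.split_id for r in recs)
                  for fam, recs in records.items()}
    ref = next(iter(split_sets.values()))
    if any(s != ref for s in split_sets.values()):
        raise ValueError(f"split ids differ across families: {split_sets}")

    rows = []
    for fam, recs in records.items():
        stops = np.array([r.stop_iteration for r in recs], dtype=float)
        walls = np.array([r.wallclock_s for r in recs], dtype=float)
        rows.append({
            "family": fam,
            "n_runs": len(recs),
            "stop_iteration_mean": stops.mean(),
            "stop_iteration_se": stops.std(ddof=1) / np.sqrt(len(stops)),
            "stop_iteration_median": float(np.median(stops)),
            "wallclock_s_mean": walls.mean(),
        })
    df = pd.DataFrame(rows)
    if {"pif", "baseline"} <= set(records):
        by_split = {fam: {r.split_id: r.stop_iteration for r in recs}
                    for fam, recs in records.items()}
        diffs = [by_split["pif"][s] - by_split["baseline"][s] for s in ref]
        df.attrs["paired_iteration_diff_pif_minus_baseline"] = diffs
    return df
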
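"""Cross-validation protocols and scores.

Classification tasks are scored with the Matthews correlation
coefficient (the Phi score)

    Phi = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

evaluated per held-out batch of a repeated (optionally stratified)
leave-5-out cross-validation and reported on the [0, 1] scale through the
affine transform (Phi + 1) / 2.  Continuous tasks are scored as the R^2
pooled over all repeated test-set predictions; the temperature sensor is
additionally scored as the average per-test-set s.d. of the
predicted-minus-true residual (with an RMSE variant that includes bias).
All preprocessing (zero-variance pruning, standardization, SNR
filtering) is fitted on each training fold only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .readout import train_readout
from .table import FeatureTable
from .tasks import TaskSpec


# ---------------------------------------------------------------------------
# split plans

@dataclass
class SplitPlan:
    splits: list[tuple[np.ndarray, np.ndarray]]  # (train ids, test ids)
    repeats: int
    stratified: bool
    seed: int

    def __iter__(self):
        return iter(self.splits)

    def __len__(self):
        return len(self.splits)


def make_splits(
    n: int,
    labels: np.ndarray | None = None,
    batch_size: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Repeated leave-``batch_size``-out split plan.

    Within each repeat the test batches partition the dataset; the final
    batch is smaller when n is not a multiple of the batch size.  With
    ``labels``, batches are stratified by dealing each class round-robin
    into capacity-limited batches (after shuffling), so every batch holds
    representative inputs from both classes whenever the class sizes
    allow it.
    """
    if n < 2 * batch_size:
        raise ValueError("need at least two batches of samples")
    rng = np.random.default_rng(seed)
    n_batches = math.ceil(n / batch_size)
    sizes = [batch_size] * (n_batches - 1) + [n - batch_size * (n_batches - 1)]
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    all_ids = np.arange(n)
    for _ in range(repeats):
        batches: list[list[int]] = [[] for _ in range(n_batches)]
        if labels is None:
            order = rng.permutation(n)
            pos = 0
            for b, size in enumerate(sizes):
                batches[b] = list(order[pos:pos + size])
                pos += size
        else:
            y = np.asarray(labels)
            classes = [c for c in np.unique(y)]
            small = [c for c in classes if np.sum(y == c) < n_batches]
            if small:
                warnings.warn(
                    f"class(es) {small} have fewer members than batches; "
                    "stratification is best-effort", stacklevel=2,
                )
            cursor = int(rng.integers(n_batches))
            for c in classes:
                members = rng.permutation(all_ids[y == c])
                for m in members:
                    placed = False
                    for step in range(n_batches):
                        b = (cursor + step) % n_batches
                        if len(batches[b]) < sizes[b]:
                            batches[b].append(int(m))
                            cursor = (b + 1) % n_batches
                            placed = True
                            break
                    assert placed
        for b in range(n_batches):
            test = np.sort(np.array(batches[b], dtype=int))
            train = np.setdiff1d(all_ids, test)
            splits.append((train, test))
    return SplitPlan(splits=splits, repeats=repeats,
                     stratified=labels is not None, seed=seed)


# ---------------------------------------------------------------------------
# scores

def phi_score(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    if tp + tn + fp + fn == 0:
        raise ValueError("undefined score: empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def transform_phi(phi: float) -> float:
    """Affine map of Phi from [-1, 1] to the reported [0, 1] accuracy scale."""
    return (phi + 1.0) / 2.0


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def r2_pooled(predictions: np.ndarray, truths: np.ndarray) -> float:
    """1 - SS_res/SS_tot over the pooled test predictions of all repeats."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    ss_res = np.sum((t - p) ** 2)
    ss_tot = np.sum((t - t.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("targets are constant; R^2 undefined")
    return float(1.0 - ss_res / ss_tot)


def sensor_error(split_predictions: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Average over test sets of the s.d. of (predicted - true).

    The pure-s.d. convention ignores a constant bias; see
    :func:`sensor_rmse` for the bias-inclusive variant.  Test sets with a
    single sample (a trailing partial batch) carry no spread information
    and are skipped.
    """
    sds = [float(np.std(np.asarray(p, float) - np.asarray(t, float), ddof=1))
           for p, t in split_predictions if len(p) >= 2]
    if not sds:
        raise ValueError("no test set with >= 2 samples")
    return float(np.mean(sds))


def sensor_rmse(split_predictions: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Average per-test-set RMSE of (predicted - true); includes bias."""
    vals = [float(np.sqrt(np.mean((np.asarray(p, float) - np.asarray(t, float)) ** 2)))
            for p, t in split_predictions]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# end-to-end evaluation

@dataclass
class EvaluationReport:
    task: str
    kind: str
    scores: np.ndarray  # per-split transformed Phi (binary) or empty
    mean: float
    sd: float
    per_input: np.ndarray | None = None  # per-sample mean test correctness
    pooled_r2: float | None = None
    sensor_sd: float | None = None
    sensor_rmse: float | None = None
    predictions: pd.DataFrame | None = None  # pooled test predictions
    baseline: "EvaluationReport | None" = None
    n_splits: int = 0

    def summary(self) -> str:
        lines = [f"task={self.task} kind={self.kind} splits={self.n_splits}"]
        if self.kind == "binary":
            lines.append(f"mean transformed Phi = {self.mean:.3f} +/- {self.sd:.3f}")
        else:
            lines.append(f"pooled R^2 = {self.pooled_r2:.3f}")
            if self.sensor_sd is not None:
                lines.append(
                    f"sensor error (avg test-set s.d.) = {self.sensor_sd:.3f}"
                    f" | RMSE variant = {self.sensor_rmse:.3f}"
                )
        if self.baseline is not None:
            b = self.baseline
            val = b.mean if self.kind == "binary" else b.pooled_r2
            lines.append(f"no-reservoir baseline: {val:.3f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class Protocol:
    """Cross-validation protocol parameters."""

    repeats: int = 10
    batch_size: int = 5
    stratified: bool = True
    seed: int = 0


def _raw_input_features(task: TaskSpec, metadata: pd.DataFrame) -> pd.DataFrame:
    """The task's own (normalized) inputs as a feature matrix — the
    training-algorithm-without-reservoir comparator."""
    from .tasks import normalize_input

    cols = {}
    for key, rng in task.input_dims:
        col = f"meta_{key}" if f"meta_{key}" in metadata.columns else key
        vals = metadata[col].to_numpy(dtype=float)
        cols[key] = normalize_input(vals, *rng) if rng is not None else vals
    return pd.DataFrame(cols, index=metadata.index)


def _run_protocol(
    X: pd.DataFrame,
    y: np.ndarray,
    kind: str,
    protocol: Protocol,
    alpha: float,
    C: float,
    snr_groups=None,
    task_name: str = "",
) -> EvaluationReport:
    n = len(X)
    labels = y if (kind == "binary" and protocol.stratified) else None
    plan = make_splits(n, labels=labels, batch_size=protocol.batch_size,
                       repeats=protocol.repeats, seed=protocol.seed)
    mode = "classifier" if kind == "binary" else "regressor"
    scores = []
    hits = np.zeros(n)
    counts = np.zeros(n)
    pooled_pred, pooled_true, pooled_idx = [], [], []
    per_split_pairs = []
    for train, test in plan:
        groups = None if snr_groups is None else np.asarray(snr_groups)[train]
        model = train_readout(X.iloc[train], y[train], mode=mode,
                              alpha=alpha, C=C, snr_groups=groups)
        pred = model.predict(X.iloc[test])
        truth = y[test]
        if kind == "binary":
            scores.append(transform_phi(phi_score(*confusion(truth, pred))))
            hits[test] += (pred == truth).astype(float)
            counts[test] += 1
        else:
            per_split_pairs.append((pred, truth))
        pooled_pred.append(pred)
        pooled_true.append(truth)
        pooled_idx.append(test)
    predictions = pd.DataFrame(
        {
            "sample": np.concatenate(pooled_idx),
            "truth": np.concatenate(pooled_true),
            "prediction": np.concatenate(pooled_pred),
        }
    )
    if kind == "binary":
        arr = np.asarray(scores)
        per_input = np.divide(hits, counts, out=np.full(n, np.nan), where=counts > 0)
        return EvaluationReport(
            task=task_name, kind=kind, scores=arr, mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)), per_input=per_input,
            predictions=predictions, n_splits=len(plan),
        )
    r2 = r2_pooled(predictions["prediction"], predictions["truth"])
    return EvaluationReport(
        task=task_name, kind=kind, scores=np.array([]), mean=r2, sd=float("nan"),
        pooled_r2=r2,
        sensor_sd=sensor_error(per_split_pairs),
        sensor_rmse=sensor_rmse(per_split_pairs),
        predictions=predictions, n_splits=len(plan),
    )


def evaluate_task(
    table: FeatureTable,
    task: TaskSpec,
    protocol: Protocol = Protocol(),
    alpha: float = 1.0,
    C: float = 1.0,
    snr_group_key: str | None = None,
    baseline: bool = False,
    feature_subset: list[str] | None = None,
) -> EvaluationReport:
    """Score one task on one dataset with repeated L5O-CV.

    Per split: preprocess on the training fold only, fit the readout,
    predict the held-out batch, score.  ``baseline=True`` additionally
    runs the same trainer on the raw normalized task inputs (the
    no-reservoir comparator).  ``snr_group_key`` names a metadata column
    whose levels define the replicate groups of the SNR filter.
    """
    y = task.targets(table.metadata)
    kind = "binary" if task.kind == "binary" else "continuous"
    if kind == "binary" and len(np.unique(y)) < 2:
        raise ValueError(
            f"task {task.name!r} yields a single class on this dataset"
        )
    X = table.features if feature_subset is None else table.features[feature_subset]
    groups = None
    if snr_group_key is not None:
        col = f"meta_{snr_group_key}"
        if col not in table.data.columns:
            raise KeyError(f"metadata column {col!r} not in table")
        groups = table.data[col].to_numpy()
    report = _run_protocol(X, y, kind, protocol, alpha, C, groups, task.name)
    if baseline:
        Xb = _raw_input_features(task, table.metadata)
        report.baseline = _run_protocol(Xb, y, kind, protocol, alpha, C, None,
                                        task.name + "+baseline")
    return report


def feature_count_ablation(
    table: FeatureTable,
    task: TaskSpec,
    counts: list[int],
    protocol: Protocol = Protocol(),
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Evaluate on nested random feature subsets of increasing size."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(table.feature_names)
    rows = []
    for k in counts:
        if not 1 <= k <= len(order):
            raise ValueError(f"subset size {k} out of range")
        rep = evaluate_task(table, task, protocol=protocol,
                            feature_subset=list(order[:k]), **kwargs)
        score = rep.mean if rep.kind == "binary" else rep.pooled_r2
        rows.append({"n_features": k, "score": score, "sd": rep.sd})
    return pd.DataFrame(rows)
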
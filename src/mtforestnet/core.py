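"""Progressive multitask stacked random forests.

The model couples T binary classification tasks that may share few or no
chemicals. Layer 1 is one random forest per task trained on the raw
fingerprint matrix (m bits) — exactly the conventional single-task
baseline. Every subsequent layer trains one forest per task on the original
m bits concatenated with all T tasks' class-1 probability scores from the
immediately previous layer (width m + T), so information flows between
tasks through a shared, low-dimensional "biological" score block even when
their chemical spaces are disjoint. Layers are added while the mean
validation AUC strictly improves; the selected layer is the argmax of mean
validation AUC.

Usage follows the model/results convention::

    model = MTForestNet(tasks, params=ForestParams())
    res = model.fit(max_layers=10)
    res.summary()
    scores = res.predict(X_new)          # ScoreMatrix at the best layer
    report = res.evaluate(split="test")
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .exceptions import (
    SplitError,
    UndefinedAUCError,
    ValidationError,
)

logger = logging.getLogger("mtforestnet")

SPLIT_TAGS = ("train", "validation", "test")
FORMAT_VERSION = 1


@dataclass(frozen=True)
class ForestParams:
    """Random-forest configuration shared by every classifier in the cascade.

    Defaults are the reference configuration: 500 trees, max_features =
    floor(log2(feature number)) of the *current* training matrix width, and
    random seed 8.
    """

    n_estimators: int = 500
    max_features_rule: str = "log2"
    random_state: int = 8

    def max_features(self, width: int) -> int:
        if self.max_features_rule != "log2":
            raise ValidationError(f"unknown max_features rule {self.max_features_rule!r}")
        return max(1, int(math.log2(width)))

    def make_classifier(self, width: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features(width),
            random_state=self.random_state,
            n_jobs=1,
        )


@dataclass
class TaskDataset:
    """One learning task: fingerprints, binary labels, optional split tags."""

    task_name: str
    chem_ids: np.ndarray  # (n,) str
    X: np.ndarray  # (n, m) uint8
    y: np.ndarray  # (n,) {0,1}
    split: np.ndarray | None = None  # (n,) in SPLIT_TAGS

    def __post_init__(self) -> None:
        self.chem_ids = np.asarray(self.chem_ids, dtype=object)
        self.X = np.asarray(self.X, dtype=np.uint8)
        self.y = np.asarray(self.y, dtype=np.int8)
        n = len(self.chem_ids)
        if self.X.ndim != 2 or self.X.shape[0] != n or self.y.shape[0] != n:
            raise ValidationError(f"task {self.task_name!r}: inconsistent shapes")
        if len(set(self.chem_ids)) != n:
            raise ValidationError(f"task {self.task_name!r}: duplicate chemical ids")
        if not np.isin(self.y, (0, 1)).all():
            raise ValidationError(f"task {self.task_name!r}: labels must be 0/1")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if self.split.shape[0] != n:
                raise ValidationError(f"task {self.task_name!r}: split length mismatch")
            bad = set(self.split) - set(SPLIT_TAGS)
            if bad:
                raise ValidationError(f"task {self.task_name!r}: bad split tags {bad}")

    @property
    def n_features(self) -> int:
        return int(self.X.shape[1])

    def indices(self, tag: str) -> np.ndarray:
        if self.split is None:
            raise ValidationError(f"task {self.task_name!r} has no split tags")
        return np.flatnonzero(self.split == tag)


@dataclass
class ScoreMatrix:
    """chemicals × tasks matrix of class-1 probability scores from one layer."""

    chem_ids: np.ndarray
    scores: np.ndarray
    task_order: list[str]
    layer_index: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValidationError("scores outside [0, 1]")
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.task_order):
            raise ValidationError("score matrix shape does not match task order")


@dataclass
class Layer:
    """One trained cascade layer: one classifier per task, plus wiring info."""

    classifiers: list
    task_order: list[str]
    uses_scores: bool
    include_own_score: bool
    base_width: int

    def input_width(self, task_index: int) -> int:
        t = len(self.task_order)
        if not self.uses_scores:
            return self.base_width
        return self.base_width + (t if self.include_own_score else t - 1)

    def score_columns(self, task_index: int) -> np.ndarray:
        """Which previous-layer score columns feed this task's classifier."""
        t = len(self.task_order)
        cols = np.arange(t)
        if not self.include_own_score:
            cols = cols[cols != task_index]
        return cols


def stratified_split(
    task: TaskDataset,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> TaskDataset:
    """Tag every chemical train/validation/test, stratified by label.

    Within each class the chemicals are shuffled with the given seed and
    allocated to the three sets by largest-remainder rounding of the target
    fractions, so realized fractions match the configured ones to within one
    chemical per stratum. Deterministic for a fixed seed.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValidationError(f"fractions {fractions} do not sum to 1")
    y = task.y
    for c in (0, 1):
        if (y == c).sum() < 2:
            raise SplitError(
                f"task {task.task_name!r}: class {c} has fewer than 2 chemicals"
            )
    rng = np.random.default_rng(seed)
    tags = np.empty(len(y), dtype=object)
    for c in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == c))
        n = len(idx)
        exact = np.array(fractions) * n
        base = np.floor(exact).astype(int)
        order = np.argsort(-(exact - base), kind="stable")
        for j in order[: n - base.sum()]:
            base[j] += 1
        stop = np.cumsum(base)
        tags[idx[: stop[0]]] = "train"
        tags[idx[stop[0]: stop[1]]] = "validation"
        tags[idx[stop[1]:]] = "test"
    return TaskDataset(task.task_name, task.chem_ids, task.X, y, tags)


def split_tasks(
    tasks: list[TaskDataset],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> list[TaskDataset]:
    """Split each task independently; per-task seeds derive from ``seed``
    and a CRC32 of the task name, so adding a task never perturbs others."""
    out = []
    for t in tasks:
        task_seed = (zlib.crc32(t.task_name.encode()) ^ seed) & 0x7FFFFFFF
        out.append(stratified_split(t, fractions, task_seed))
    return out


def auc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) AUC with midrank tie handling.

    Equals the probability that a random positive outscores a random
    negative, with half credit for ties.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("auc requires two equal-length vectors")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("both classes must be present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


class _UnionTable:
    """Deduplicated table of all chemicals over all tasks (id -> one row)."""

    def __init__(self, tasks: list[TaskDataset]):
        widths = {t.n_features for t in tasks}
        if len(widths) != 1:
            raise ValidationError(f"tasks have inconsistent feature widths {widths}")
        self.row_of: dict[str, int] = {}
        blocks, start = [], 0
        task_rows = []
        for t in tasks:
            new = [i for i, cid in enumerate(t.chem_ids) if cid not in self.row_of]
            for i in new:
                self.row_of[t.chem_ids[i]] = start
                start += 1
            if new:
                blocks.append(t.X[new])
            task_rows.append(np.array([self.row_of[c] for c in t.chem_ids]))
        self.X = np.vstack(blocks) if blocks else np.zeros((0, tasks[0].n_features), np.uint8)
        self.task_rows = task_rows
        self.chem_ids = np.empty(len(self.row_of), dtype=object)
        for cid, r in self.row_of.items():
            self.chem_ids[r] = cid


def _positive_proba(clf, X) -> np.ndarray:
    if X.shape[0] == 0:
        return np.zeros(0)
    proba = clf.predict_proba(X)
    cols = np.flatnonzero(clf.classes_ == 1)
    if cols.size == 0:  # trained without positives (precluded by the split contract)
        return np.zeros(X.shape[0])
    return proba[:, cols[0]]


def train_layer(
    tasks: list[TaskDataset],
    prev_scores: ScoreMatrix | None,
    params: ForestParams,
    include_own_score: bool = True,
) -> Layer:
    """Train one cascade layer: one forest per task on its own train split.

    Layer 1 (``prev_scores is None``) consumes the raw m-bit fingerprints;
    deeper layers consume the fingerprints concatenated with the previous
    layer's T score columns (own task's score included by default).
    """
    task_order = [t.task_name for t in tasks]
    base_width = tasks[0].n_features
    layer = Layer([], task_order, prev_scores is not None, include_own_score, base_width)
    if prev_scores is not None:
        row_of = {cid: i for i, cid in enumerate(prev_scores.chem_ids)}
    classifiers = []
    for ti, task in enumerate(tasks):
        tr = task.indices("train")
        X_tr = task.X[tr]
        if prev_scores is not None:
            try:
                rows = np.array([row_of[c] for c in task.chem_ids[tr]])
            except KeyError as exc:
                raise ValidationError(
                    f"no previous-layer score for chemical {exc.args[0]!r} "
                    f"of task {task.task_name!r}"
                ) from exc
            S = prev_scores.scores[rows][:, layer.score_columns(ti)]
            X_tr = np.hstack([X_tr, S])
        clf = params.make_classifier(X_tr.shape[1])
        clf.fit(X_tr, task.y[tr])
        classifiers.append(clf)
    layer.classifiers = classifiers
    return layer


def score_all(
    layer: Layer,
    X: np.ndarray,
    prev_scores: np.ndarray | None = None,
    chem_ids: np.ndarray | None = None,
) -> ScoreMatrix:
    """Score every row of ``X`` with every task's classifier of one layer."""
    X = np.asarray(X)
    n = X.shape[0]
    t = len(layer.task_order)
    if layer.uses_scores:
        if prev_scores is None:
            raise ValidationError("layer consumes previous-layer scores; none given")
        if prev_scores.shape != (n, t):
            raise ValidationError("previous-layer score matrix has wrong shape")
    if X.shape[1] != layer.base_width:
        raise ValidationError(
            f"feature width {X.shape[1]} != expected {layer.base_width}"
        )
    S = np.zeros((n, t))
    for ti, clf in enumerate(layer.classifiers):
        Xin = X
        if layer.uses_scores:
            Xin = np.hstack([X, prev_scores[:, layer.score_columns(ti)]])
        S[:, ti] = _positive_proba(clf, Xin)
    if chem_ids is None:
        chem_ids = np.array([f"row{i}" for i in range(n)], dtype=object)
    return ScoreMatrix(chem_ids, S, list(layer.task_order), layer_index=0)


@dataclass
class EvaluationReport:
    """Per-task AUCs on one split at one layer, with summary statistics."""

    split: str
    layer: int
    per_task_auc: dict[str, float]  # NaN when undefined on that split
    mean_auc: float
    n_defined: int
    n_above_threshold: int
    auc_threshold: float = 0.8


class MTForestNet:
    """Model object binding the task datasets to the cascade configuration.

    Parameters
    ----------
    tasks
        One :class:`TaskDataset` per learning task. Tasks may share all,
        some, or none of their chemicals; a chemical id appearing in several
        tasks must denote the same fingerprint row.
    params
        Forest configuration applied to every classifier (default 500 trees,
        log2 max-features rule, seed 8).
    include_own_score
        Whether a task's own previous-layer score is part of its
        concatenated input (default True; switch off for ablation).
    """

    def __init__(
        self,
        tasks: list[TaskDataset],
        params: ForestParams | None = None,
        include_own_score: bool = True,
    ):
        if not tasks:
            raise ValidationError("no tasks given")
        names = [t.task_name for t in tasks]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate task names")
        self.tasks = tasks
        self.params = params or ForestParams()
        self.include_own_score = include_own_score

    def fit(
        self,
        max_layers: int = 10,
        split_seed: int | None = None,
        fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    ) -> "MTForestNetResults":
        """Train layers until mean validation AUC stops strictly improving.

        Tasks lacking split tags are stratified-split first (``split_seed``
        required then). Each layer's per-task validation AUC and their mean
        are recorded; growth stops when a new layer's mean is not strictly
        greater than the best mean seen, or at ``max_layers``. The
        non-improving layer is retained for inspection but never selected:
        the best layer is the argmax of mean validation AUC.
        """
        if max_layers < 1:
            raise ValidationError("max_layers must be >= 1")
        tasks = self.tasks
        if any(t.split is None for t in tasks):
            if split_seed is None:
                raise ValidationError("tasks are unsplit and no split_seed given")
            tasks = split_tasks(tasks, fractions, split_seed)
            self.tasks = tasks
        union = _UnionTable(tasks)
        layers: list[Layer] = []
        layer_scores: list[np.ndarray] = []
        per_layer_auc: list[np.ndarray] = []
        mean_auc: list[float] = []
        best_mean = -np.inf
        prev = None
        for k in range(1, max_layers + 1):
            prev_sm = None
            if prev is not None:
                prev_sm = ScoreMatrix(union.chem_ids, prev, [t.task_name for t in tasks], k - 1)
            layer = train_layer(tasks, prev_sm, self.params, self.include_own_score)
            sm = score_all(layer, union.X, prev, union.chem_ids)
            aucs = self._validation_aucs(tasks, union, sm.scores)
            mean = float(np.nanmean(aucs))
            layers.append(layer)
            layer_scores.append(sm.scores)
            per_layer_auc.append(aucs)
            mean_auc.append(mean)
            logger.info("[mtfn] layer %d mean validation AUC %.4f", k, mean)
            if k >= 2 and mean <= best_mean:
                logger.info("[mtfn] no improvement at layer %d; stopping", k)
                break
            best_mean = max(best_mean, mean)
            prev = sm.scores
        best_layer = int(np.argmax(mean_auc)) + 1
        logger.info("[mtfn] selected layer %d", best_layer)
        return MTForestNetResults(
            task_order=[t.task_name for t in tasks],
            layers=layers,
            per_layer_validation_auc=per_layer_auc,
            mean_validation_auc=mean_auc,
            best_layer=best_layer,
            params=self.params,
            include_own_score=self.include_own_score,
            feature_length=tasks[0].n_features,
            tasks=tasks,
            _union=union,
            _layer_scores=layer_scores,
        )

    @staticmethod
    def _validation_aucs(tasks, union, scores) -> np.ndarray:
        out = np.full(len(tasks), np.nan)
        for ti, task in enumerate(tasks):
            va = task.indices("validation")
            rows = union.task_rows[ti][va]
            y = task.y[va]
            try:
                out[ti] = auc(scores[rows, ti], y)
            except UndefinedAUCError:
                logger.warning(
                    "[mtfn] task %r: single-class validation split, AUC undefined",
                    task.task_name,
                )
        return out


@dataclass
class MTForestNetResults:
    """Fitted cascade: trained layers, layer-selection trace, and scoring API."""

    task_order: list[str]
    layers: list[Layer]
    per_layer_validation_auc: list[np.ndarray]
    mean_validation_auc: list[float]
    best_layer: int
    params: ForestParams
    include_own_score: bool
    feature_length: int
    tasks: list[TaskDataset] | None = None
    _union: _UnionTable | None = field(default=None, repr=False)
    _layer_scores: list[np.ndarray] | None = field(default=None, repr=False)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_tasks(self) -> int:
        return len(self.task_order)

    # ------------------------------------------------------------------ scoring
    def predict(
        self,
        X_new: np.ndarray,
        layer: int | None = None,
        chem_ids: np.ndarray | None = None,
        return_calls: bool = False,
        call_threshold: float = 0.5,
    ):
        """Propagate new fingerprints through the cascade up to ``layer``
        (default: the selected best layer) and return the ScoreMatrix.

        Layer k >= 2 consumes ``X_new`` concatenated with layer k-1's
        scores, mirroring training. With ``return_calls`` a (ScoreMatrix,
        binary-call matrix) pair is returned; calls are score >= threshold.
        """
        X_new = np.asarray(X_new, dtype=np.uint8)
        if X_new.ndim != 2 or X_new.shape[1] != self.feature_length:
            raise ValidationError(
                f"expected width {self.feature_length}, got {X_new.shape}"
            )
        target = self.best_layer if layer is None else layer
        if not 1 <= target <= self.n_layers:
            raise ValidationError(f"layer {target} not in [1, {self.n_layers}]")
        prev = None
        for k in range(1, target + 1):
            sm = score_all(self.layers[k - 1], X_new, prev, chem_ids)
            sm.layer_index = k
            prev = sm.scores
        if return_calls:
            return sm, (sm.scores >= call_threshold).astype(np.uint8)
        return sm

    def _ensure_scores(self, tasks=None):
        if self._layer_scores is not None:
            return
        tasks = tasks or self.tasks
        if tasks is None:
            raise ValidationError(
                "no cached scores and no tasks given; pass tasks= to evaluate"
            )
        self.tasks = tasks
        union = _UnionTable(tasks)
        prev = None
        layer_scores = []
        for k in range(1, self.n_layers + 1):
            sm = score_all(self.layers[k - 1], union.X, prev, union.chem_ids)
            layer_scores.append(sm.scores)
            prev = sm.scores
        self._union = union
        self._layer_scores = layer_scores

    def evaluate(
        self,
        split: str = "test",
        layer: int | None = None,
        tasks: list[TaskDataset] | None = None,
        auc_threshold: float = 0.8,
    ) -> EvaluationReport:
        """Per-task AUC on one split, at the selected (or given) layer.

        Tasks whose split holds a single class get AUC NaN, are excluded
        from the mean, and trigger a warning. Also reports how many tasks
        clear ``auc_threshold``.
        """
        if split not in ("validation", "test"):
            raise ValidationError("split must be 'validation' or 'test'")
        self._ensure_scores(tasks)
        target = self.best_layer if layer is None else layer
        scores = self._layer_scores[target - 1]
        per_task: dict[str, float] = {}
        for ti, task in enumerate(self.tasks):
            idx = task.indices(split)
            rows = self._union.task_rows[ti][idx]
            try:
                per_task[task.task_name] = auc(scores[rows, ti], task.y[idx])
            except UndefinedAUCError:
                logger.warning(
                    "[mtfn] task %r: single-class %s split, AUC undefined",
                    task.task_name, split,
                )
                per_task[task.task_name] = float("nan")
        vals = np.array(list(per_task.values()))
        defined = vals[~np.isnan(vals)]
        return EvaluationReport(
            split=split,
            layer=target,
            per_task_auc=per_task,
            mean_auc=float(defined.mean()) if defined.size else float("nan"),
            n_defined=int(defined.size),
            n_above_threshold=int((defined > auc_threshold).sum()),
            auc_threshold=auc_threshold,
        )

    def summary(self) -> str:
        """Human-readable fit summary: layer trace and best-layer AUCs."""
        lines = [
            "MTForestNet results",
            "===================",
            f"tasks: {self.n_tasks}   feature length: {self.feature_length}   "
            f"forest: {self.params.n_estimators} trees, "
            f"max_features rule {self.params.max_features_rule}, "
            f"seed {self.params.random_state}",
            f"own-task score included: {self.include_own_score}",
            "",
            "layer   mean validation AUC",
        ]
        for k, m in enumerate(self.mean_validation_auc, start=1):
            marker = "  <- selected" if k == self.best_layer else ""
            lines.append(f"{k:>5}   {m:.4f}{marker}")
        best = self.per_layer_validation_auc[self.best_layer - 1]
        lines += ["", "per-task validation AUC at selected layer:"]
        for name, a in zip(self.task_order, best):
            lines.append(f"  {name:<24} {a:.4f}" if np.isfinite(a) else f"  {name:<24} undefined")
        return "\n".join(lines)

    # -------------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        """Persist to a directory: JSON manifest + one joblib per classifier."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": FORMAT_VERSION,
            "task_order": self.task_order,
            "params": asdict(self.params),
            "include_own_score": self.include_own_score,
            "feature_length": self.feature_length,
            "n_layers": self.n_layers,
            "best_layer": self.best_layer,
            "per_layer_validation_auc": [
                [None if not np.isfinite(a) else float(a) for a in v]
                for v in self.per_layer_validation_auc
            ],
            "mean_validation_auc": [float(m) for m in self.mean_validation_auc],
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for k, layer in enumerate(self.layers, start=1):
            d = path / f"layer_{k:02d}"
            d.mkdir(exist_ok=True)
            for ti, clf in enumerate(layer.classifiers):
                joblib.dump(clf, d / f"task_{ti:03d}.joblib")

    @classmethod
    def load(cls, path: str | Path) -> "MTForestNetResults":
        """Load a persisted model; predictions reproduce bit-identically."""
        path = Path(path)
        try:
            manifest = json.loads((path / "manifest.json").read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ValidationError(f"cannot read model manifest in {path}: {exc}") from exc
        for key in ("format_version", "task_order", "params", "n_layers", "best_layer"):
            if key not in manifest:
                raise ValidationError(f"model manifest in {path} lacks {key!r}")
        if manifest["format_version"] != FORMAT_VERSION:
            raise ValidationError(
                f"unsupported model format version {manifest['format_version']}"
            )
        task_order = manifest["task_order"]
        params = ForestParams(**manifest["params"])
        layers = []
        for k in range(1, manifest["n_layers"] + 1):
            d = path / f"layer_{k:02d}"
            classifiers = [
                joblib.load(d / f"task_{ti:03d}.joblib") for ti in range(len(task_order))
            ]
            layers.append(
                Layer(
                    classifiers,
                    list(task_order),
                    uses_scores=k > 1,
                    include_own_score=manifest["include_own_score"],
                    base_width=manifest["feature_length"],
                )
            )
        per_layer = [
            np.array([np.nan if a is None else a for a in v])
            for v in manifest["per_layer_validation_auc"]
        ]
        return cls(
            task_order=list(task_order),
            layers=layers,
            per_layer_validation_auc=per_layer,
            mean_validation_auc=list(manifest["mean_validation_auc"]),
            best_layer=manifest["best_layer"],
            params=params,
            include_own_score=manifest["include_own_score"],
            feature_length=manifest["feature_length"],
        )


@dataclass
class AblationReport:
    """Result of refitting the cascade with one dataset group excluded."""

    excluded_group: str
    task_names: list[str]
    mean_test_auc: float
    frac_above_threshold: float
    per_task_auc: dict[str, float]
    results: MTForestNetResults


def ablate_dataset(
    tasks: list[TaskDataset],
    group_assignment: dict[str, str],
    excluded_group: str,
    params: ForestParams | None = None,
    known_groups: list[str] | None = None,
    max_layers: int = 10,
    split_seed: int | None = None,
    include_own_score: bool = True,
    auc_threshold: float = 0.8,
) -> AblationReport:
    """Refit the full pipeline with every task of one dataset group removed.

    ``group_assignment`` maps every task name to its dataset group. A group
    name must be known — i.e. appear among the assignment's values or in
    ``known_groups`` (which lets an explicitly declared empty group act as a
    no-op exclusion).
    """
    missing = [t.task_name for t in tasks if t.task_name not in group_assignment]
    if missing:
        raise ValidationError(f"tasks without a group: {missing}")
    known = set(group_assignment.values()) | set(known_groups or [])
    if excluded_group not in known:
        raise ValidationError(f"unknown dataset group {excluded_group!r}")
    remaining = [t for t in tasks if group_assignment[t.task_name] != excluded_group]
    if not remaining:
        raise ValidationError(f"excluding {excluded_group!r} leaves no tasks")
    res = MTForestNet(remaining, params, include_own_score).fit(
        max_layers=max_layers, split_seed=split_seed
    )
    rep = res.evaluate("test", auc_threshold=auc_threshold)
    return AblationReport(
        excluded_group=excluded_group,
        task_names=[t.task_name for t in remaining],
        mean_test_auc=rep.mean_auc,
        frac_above_threshold=rep.n_above_threshold / max(rep.n_defined, 1),
        per_task_auc=rep.per_task_auc,
        results=res,
    )
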
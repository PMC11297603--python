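"""Downstream augmentation: cascade predictions as auxiliary features.

A trained cascade's T binary task predictions ("ZF features") can be
appended to a chemical's raw fingerprint to form an augmented feature
vector (1024 + 48 = 1072 bits in the reference configuration) for an
*external* binary classification task. Because the T columns may be
redundant, a sequential backward floating selection with conditional
inclusion can prune them on the training split; robustness is assessed by
repeated random 80/20 splits.

Everything here is leakage-safe by construction: per run, feature selection
and model fitting see only the training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .core import ForestParams, MTForestNetResults, auc
from .exceptions import SplitError, ValidationError


@dataclass
class AugmentedDataset:
    """Raw fingerprints side-by-side with binary cascade predictions."""

    chem_ids: np.ndarray
    X_base: np.ndarray   # (n, m) uint8
    X_zf: np.ndarray     # (n, T) uint8 binary calls
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X_base = np.asarray(self.X_base, dtype=np.uint8)
        self.X_zf = np.asarray(self.X_zf, dtype=np.uint8)
        if self.X_zf.size and not np.isin(self.X_zf, (0, 1)).all():
            raise ValidationError("ZF features must be binary")
        if self.X_base.shape[0] != self.X_zf.shape[0]:
            raise ValidationError("base and ZF blocks have different row counts")

    @property
    def X_combined(self) -> np.ndarray:
        return np.hstack([self.X_base, self.X_zf])

    @property
    def width(self) -> int:
        return self.X_base.shape[1] + self.X_zf.shape[1]


def augment(
    results: MTForestNetResults,
    X_base: np.ndarray,
    chem_ids: np.ndarray | None = None,
    call_threshold: float = 0.5,
) -> AugmentedDataset:
    """Append the cascade's best-layer binary calls to raw fingerprints.

    Column order of the ZF block follows the model's task order. The
    operation is deterministic given a persisted model.
    """
    X_base = np.asarray(X_base, dtype=np.uint8)
    sm, calls = results.predict(
        X_base, return_calls=True, call_threshold=call_threshold, chem_ids=chem_ids
    )
    return AugmentedDataset(sm.chem_ids, X_base, calls)


@dataclass
class SelectionResult:
    """Outcome of the floating backward search."""

    selected: tuple[int, ...]
    cv_auc: float
    n_evaluations: int
    trace: list[tuple[tuple[int, ...], float]] = field(repr=False, default_factory=list)


def _cv_auc(X, y, cols, k_folds, seed, params) -> float:
    Xs = X[:, cols] if len(cols) else np.zeros((len(y), 1))
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(Xs, y):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise SplitError("degenerate single-class fold")
        clf = params.make_classifier(Xs.shape[1])
        clf.fit(Xs[tr], y[tr])
        proba = clf.predict_proba(Xs[te])
        p1 = proba[:, np.flatnonzero(clf.classes_ == 1)[0]]
        aucs.append(auc(p1, y[te]))
    return float(np.mean(aucs))


def sbfs_conditional(
    X: np.ndarray,
    y: np.ndarray,
    candidate_columns: list[int],
    fixed_columns: list[int] | tuple = (),
    k_folds: int = 10,
    seed: int = 0,
    params: ForestParams | None = None,
) -> SelectionResult:
    """Sequential backward floating selection with conditional inclusion.

    Starting from the full candidate set, repeatedly remove the candidate
    whose removal maximizes stratified k-fold CV AUC; after each removal,
    conditionally re-admit a previously removed candidate if doing so
    strictly improves on the best CV AUC recorded at the resulting set size
    (the floating step). ``fixed_columns`` always stay in the feature matrix
    and are never candidates for removal. The returned set is the best CV
    AUC encountered anywhere in the search; ties prefer the smaller set,
    then the lexicographically first. Consequently the selected set's CV AUC
    is never below the full candidate set's.
    """
    if not candidate_columns:
        raise ValidationError("candidate_columns must be non-empty")
    params = params or ForestParams()
    X = np.asarray(X)
    y = np.asarray(y)
    fixed = tuple(fixed_columns)
    cache: dict[tuple[int, ...], float] = {}
    n_eval = 0

    def evaluate(cols: tuple[int, ...]) -> float:
        nonlocal n_eval
        if cols not in cache:
            cache[cols] = _cv_auc(X, y, list(fixed) + list(cols), k_folds, seed, params)
            n_eval += 1
        return cache[cols]

    def key(cols: tuple[int, ...]):
        # maximize AUC; tie -> smaller set -> lexicographically first
        return (-evaluate(cols), len(cols), cols)

    current = tuple(sorted(candidate_columns))
    all_candidates = set(current)
    trace = [(current, evaluate(current))]
    best = current
    best_by_size: dict[int, float] = {len(current): evaluate(current)}

    while len(current) > 1:
        # backward step: best single removal
        options = [tuple(c for c in current if c != r) for r in current]
        current = min(options, key=key)
        trace.append((current, evaluate(current)))
        best_by_size[len(current)] = max(
            best_by_size.get(len(current), -np.inf), evaluate(current)
        )
        if key(current) < key(best):
            best = current
        # conditional inclusion: float back up while it strictly improves the
        # best set recorded at that size
        while len(current) < len(all_candidates):
            excluded = sorted(all_candidates - set(current))
            adds = [tuple(sorted(current + (c,))) for c in excluded]
            cand = min(adds, key=key)
            size_up = len(current) + 1
            if evaluate(cand) > best_by_size.get(size_up, -np.inf) and \
                    evaluate(cand) > evaluate(current):
                current = cand
                trace.append((current, evaluate(current)))
                best_by_size[size_up] = evaluate(current)
                if key(current) < key(best):
                    best = current
            else:
                break
    return SelectionResult(best, evaluate(best), n_eval, trace)


def _run_seed(master_seed: int, run_index: int) -> int:
    """Per-run seed derived from the master seed via a counter scheme."""
    ss = np.random.SeedSequence([int(master_seed), int(run_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RepeatedEvaluation:
    """Summary over repeated random train/test splits."""

    mean_auc: float
    variance: float
    per_run_auc: np.ndarray
    selection_counts: dict[int, int]  # ZF column -> times selected
    runs: int
    use_zf: bool
    use_selection: bool


def repeated_evaluation(
    X_base: np.ndarray,
    y: np.ndarray,
    results: MTForestNetResults | None = None,
    runs: int = 100,
    test_fraction: float = 0.2,
    use_zf: bool = True,
    use_selection: bool = False,
    seed: int = 0,
    params: ForestParams | None = None,
    selection_params: ForestParams | None = None,
    k_folds: int = 10,
    call_threshold: float = 0.5,
    zf_features: np.ndarray | None = None,
) -> RepeatedEvaluation:
    """Repeated stratified 80/20 evaluation of a forest on (augmented) features.

    Per run: stratified split with a per-run seed derived from the master
    seed; optional ZF augmentation; optional floating selection over the ZF
    columns computed on the training split only; a forest with the given
    parameters trained on the training split; AUC measured on the held-out
    test split. Returns the mean and sample variance of the per-run AUCs
    plus ZF-column selection frequencies.

    ``zf_features`` allows supplying precomputed binary ZF columns directly
    (otherwise they come from :func:`augment` applied to ``results``).
    """
    X_base = np.asarray(X_base)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("labels must contain both classes")
    params = params or ForestParams()
    selection_params = selection_params or params
    if use_zf:
        if zf_features is not None:
            X_zf = np.asarray(zf_features, dtype=np.uint8)
        elif results is not None:
            X_zf = augment(results, X_base, call_threshold=call_threshold).X_zf
        else:
            raise ValidationError("use_zf requires a fitted model or zf_features")
        X_full = np.hstack([X_base, X_zf])
        zf_cols = list(range(X_base.shape[1], X_full.shape[1]))
    else:
        X_full = X_base
        zf_cols = []

    per_run = np.zeros(runs)
    counts: dict[int, int] = {c: 0 for c in zf_cols}
    base_cols = list(range(X_base.shape[1]))
    for r in range(runs):
        rs = _run_seed(seed, r)
        idx = np.arange(len(y))
        tr, te = train_test_split(idx, test_size=test_fraction, stratify=y, random_state=rs)
        cols = base_cols + zf_cols
        if use_zf and use_selection and zf_cols:
            sel = sbfs_conditional(
                X_full[tr], y[tr], zf_cols, fixed_columns=base_cols,
                k_folds=k_folds, seed=rs, params=selection_params,
            )
            cols = base_cols + list(sel.selected)
            for c in sel.selected:
                counts[c] += 1
        clf = params.make_classifier(len(cols))
        clf.fit(X_full[np.ix_(tr, cols)], y[tr])
        proba = clf.predict_proba(X_full[np.ix_(te, cols)])
        p1 = proba[:, np.flatnonzero(clf.classes_ == 1)[0]]
        per_run[r] = auc(p1, y[te])
    return RepeatedEvaluation(
        mean_auc=float(per_run.mean()),
        variance=float(per_run.var(ddof=1)) if runs > 1 else 0.0,
        per_run_auc=per_run,
        selection_counts=counts,
        runs=runs,
        use_zf=use_zf,
        use_selection=use_selection,
    )
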
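"""Chemical-space relatedness diagnostics.

Two datasets collected by different labs rarely test the same chemicals.
Before attempting any cross-task learning it is worth quantifying *how*
different their chemical spaces are. This module provides the three
diagnostics used for that characterization:

* the highest percentage of common chemicals across all subset pairs of two
  dataset groups (identity overlap),
* the average Tanimoto similarity across subset pairs (structural overlap),
* a binned summary of absolute Pearson correlations between task labels on
  shared chemicals (label relatedness),

plus a mean-centered PCA projection for visualizing fingerprint spaces.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .exceptions import UndefinedCorrelationError, ValidationError
from .io_featurize import Fingerprint

#: |r| bin edges and names: low < 0.3 <= medium < 0.5 <= high < 0.7 <= very_high
CORRELATION_BINS = (
    ("low", 0.0, 0.3),
    ("medium", 0.3, 0.5),
    ("high", 0.5, 0.7),
    ("very_high", 0.7, np.inf),
)


@dataclass
class Subset:
    """A named set of chemicals with (optional) fingerprints, row-aligned."""

    name: str
    ids: list[str]
    fingerprints: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise ValidationError(f"subset {self.name!r} is empty")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError(f"subset {self.name!r} has duplicate chemical ids")
        if self.fingerprints is not None:
            self.fingerprints = np.asarray(self.fingerprints, dtype=np.uint8)
            if self.fingerprints.shape[0] != len(self.ids):
                raise ValidationError(
                    f"subset {self.name!r}: {len(self.ids)} ids but "
                    f"{self.fingerprints.shape[0]} fingerprint rows"
                )


@dataclass
class DatasetGroup:
    """One dataset: an ordered list of endpoint subsets of chemicals."""

    name: str
    subsets: list[Subset] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subsets:
            raise ValidationError(f"dataset group {self.name!r} has no subsets")


@dataclass
class TaskCorrelationSummary:
    """Counts of task pairs per |r| bin, plus pairs that could not be binned."""

    counts: dict[str, int]
    uncategorized_pairs: int
    min_shared: int
    n_tasks: int

    @property
    def total_pairs(self) -> int:
        return sum(self.counts.values()) + self.uncategorized_pairs


def _bits(fp) -> np.ndarray:
    return fp.bits if isinstance(fp, Fingerprint) else np.asarray(fp, dtype=np.uint8)


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto (Jaccard) similarity of two equal-length binary vectors.

    Defined as |A∩B| / |A∪B| over set bits; 0 by convention when both
    vectors are all-zero.
    """
    a, b = _bits(fp_a), _bits(fp_b)
    if a.shape != b.shape:
        raise ValidationError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    if isinstance(fp_a, Fingerprint) and isinstance(fp_b, Fingerprint) \
            and fp_a.scheme != fp_b.scheme:
        raise ValidationError(f"scheme mismatch: {fp_a.scheme} vs {fp_b.scheme}")
    inter = int(np.sum((a != 0) & (b != 0)))
    union = int(np.sum((a != 0) | (b != 0)))
    return inter / union if union else 0.0


def common_chemical_percentage(a: DatasetGroup, b: DatasetGroup) -> float:
    """Highest subset-wise percentage of common chemicals between two groups.

    For every pair of one subset from each group, the percentage is
    100 · |common ids| / |union of ids| (the union — the unique chemicals in
    both subsets — is the denominator); the maximum over all n × m subset
    pairs is returned.
    """
    best = 0.0
    for sa in a.subsets:
        ids_a = set(sa.ids)
        for sb in b.subsets:
            ids_b = set(sb.ids)
            union = ids_a | ids_b
            pct = 100.0 * len(ids_a & ids_b) / len(union)
            best = max(best, pct)
    return best


def _cross_mean_tanimoto(sa: Subset, sb: Subset) -> float:
    if sa.fingerprints is None or sb.fingerprints is None:
        missing = sa.name if sa.fingerprints is None else sb.name
        raise ValidationError(f"subset {missing!r} has no fingerprints")
    A = (sa.fingerprints != 0).astype(np.float64)
    B = (sb.fingerprints != 0).astype(np.float64)
    if A.shape[1] != B.shape[1]:
        raise ValidationError(
            f"fingerprint length mismatch between subsets "
            f"{sa.name!r} ({A.shape[1]}) and {sb.name!r} ({B.shape[1]})"
        )
    inter = A @ B.T
    union = A.sum(1)[:, None] + B.sum(1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)
    return float(sim.mean())


def average_similarity(a: DatasetGroup, b: DatasetGroup) -> float:
    """Average Tanimoto similarity between two groups, as a percentage.

    Each of the n × m subset pairs contributes the mean Tanimoto over all its
    cross-pairs of chemicals (a chemical present in both subsets contributes
    its self-similarity of 1); the unweighted mean of those subset-pair means,
    times 100, is returned.
    """
    means = [
        _cross_mean_tanimoto(sa, sb)
        for sa in a.subsets
        for sb in b.subsets
    ]
    return 100.0 * float(np.mean(means))


def task_correlation_summary(
    task_labels: dict[str, dict[str, int]],
    min_shared: int = 3,
) -> TaskCorrelationSummary:
    """Bin absolute Pearson correlations of shared-chemical labels.

    For every unordered task pair, Pearson r is computed over the chemicals
    labeled in both tasks. Pairs with fewer than ``min_shared`` shared
    chemicals, or with zero label variance in either task over the shared
    chemicals, are counted as uncategorized (two shared points always give
    |r| = 1, hence the default minimum of 3).
    """
    if min_shared < 3:
        raise ValidationError("min_shared must be >= 3")
    counts = {name: 0 for name, _, _ in CORRELATION_BINS}
    uncategorized = 0
    names = list(task_labels)
    for ta, tb in itertools.combinations(names, 2):
        la, lb = task_labels[ta], task_labels[tb]
        shared = sorted(set(la) & set(lb))
        if len(shared) < min_shared:
            uncategorized += 1
            continue
        x = np.array([la[c] for c in shared], dtype=float)
        y = np.array([lb[c] for c in shared], dtype=float)
        if x.std() == 0 or y.std() == 0:
            uncategorized += 1
            continue
        r = abs(float(stats.pearsonr(x, y).statistic))
        for name, lo, hi in CORRELATION_BINS:
            if lo <= r < hi:
                counts[name] += 1
                break
    return TaskCorrelationSummary(counts, uncategorized, min_shared, len(names))


def pca_projection(
    fingerprints: np.ndarray,
    n_components: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA of a fingerprint matrix (bits treated as reals).

    Returns the projected coordinates and the explained-variance fractions
    of the requested components (non-increasing, each in [0, 1]). No
    scaling is applied beyond mean-centering.
    """
    X = np.asarray(fingerprints, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < n_components + 1:
        raise ValidationError(
            f"need at least {n_components + 1} fingerprints for "
            f"{n_components} components, got {X.shape[0] if X.ndim == 2 else 'non-matrix'}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_


def pairwise_group_report(groups: list[DatasetGroup]) -> "pd.DataFrame":
    """Both relatedness metrics for every pair of groups, as a tidy table."""
    import pandas as pd

    rows = []
    for ga, gb in itertools.combinations_with_replacement(groups, 2):
        rows.append(
            {
                "group_a": ga.name,
                "group_b": gb.name,
                "common_chemical_pct": common_chemical_percentage(ga, gb),
                "average_similarity_pct": average_similarity(ga, gb),
            }
        )
    return pd.DataFrame(rows)


def pearson(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors (length >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson requires two equal-length vectors")
    if x.size < 3:
        raise ValidationError("pearson requires length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("zero variance in at least one vector")
    return float(stats.pearsonr(x, y).statistic)
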
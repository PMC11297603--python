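"""Embryonic zebrafish (EZ) Metric: weighted-sum overall-toxicity scoring.

The EZ Metric summarizes morbidity and mortality of embryonic zebrafish as
a weighted sum of binary endpoint calls — 4 endpoints scored at 24 hours
post fertilization (mortality, delayed development, absent spontaneous
movement, notochord malformation) and 17 at 120 hpf (mortality, organ
malformation and dysfunction). Weight values are deliberately *not*
hard-coded: they are supplied as configuration (a YAML mapping endpoint ->
weight with a 24hpf/120hpf group tag), because the published weighting
scheme lives in supplementary material and may be revised. A uniform-weight
example configuration ships with the package as a clearly labeled
placeholder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .chemspace import pearson
from .exceptions import ValidationError

VALID_GROUPS = ("24hpf", "120hpf")


@dataclass
class EZWeights:
    """Endpoint-name -> nonnegative weight, with a timepoint group per endpoint."""

    weights: dict[str, float]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if w < 0:
                raise ValidationError(f"negative weight for endpoint {name!r}")
        for name, g in self.groups.items():
            if name not in self.weights:
                raise ValidationError(f"group tag for unknown endpoint {name!r}")
            if g not in VALID_GROUPS:
                raise ValidationError(f"unknown group {g!r} for endpoint {name!r}")

    @property
    def total(self) -> float:
        return float(sum(self.weights.values()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EZWeights":
        """Load ``{endpoint: {weight: w, group: 24hpf|120hpf}}`` (or plain
        ``{endpoint: weight}``) from YAML."""
        raw = yaml.safe_load(Path(path).read_text())
        weights, groups = {}, {}
        for name, spec in raw.items():
            if isinstance(spec, dict):
                weights[name] = float(spec["weight"])
                if "group" in spec:
                    groups[name] = str(spec["group"])
            else:
                weights[name] = float(spec)
        return cls(weights, groups)


def ez_score(
    calls: dict[str, int | None],
    weights: EZWeights,
    missing_policy: str = "skip",
) -> float:
    """Weighted sum of binary endpoint calls.

    ``missing_policy="skip"`` (default) drops endpoints with a missing call
    from the sum — the standard treatment when some endpoints were never
    measured; ``"error"`` raises instead.
    """
    if missing_policy not in ("skip", "error"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    total = 0.0
    for name, call in calls.items():
        if name not in weights.weights:
            raise ValidationError(f"unknown endpoint {name!r}")
        if call is None:
            if missing_policy == "error":
                raise ValidationError(f"missing call for endpoint {name!r}")
            continue
        if call not in (0, 1):
            raise ValidationError(f"call for {name!r} must be 0/1/missing, got {call!r}")
        total += weights.weights[name] * call
    return total


@dataclass
class EZComparison:
    """Predicted-vs-experimental EZ scores with agreement statistics."""

    chem_ids: list[str]
    predicted: np.ndarray
    experimental: np.ndarray
    pearson_r: float
    bias: float  # mean(predicted - experimental); sign shows over/under-calling


def compare_ez(
    predicted_calls: dict[str, dict[str, int | None]],
    experimental_calls: dict[str, dict[str, int | None]],
    weights: EZWeights,
    missing_policy: str = "skip",
) -> EZComparison:
    """Score both call sets chemical-by-chemical and compare.

    Both sides must cover the same chemicals; the Pearson correlation of
    the paired scores and the mean signed difference (predicted minus
    experimental, the over/under-calling tendency) are reported.
    """
    pred_ids, exp_ids = set(predicted_calls), set(experimental_calls)
    if pred_ids != exp_ids:
        diff = sorted(pred_ids.symmetric_difference(exp_ids))
        raise ValidationError(f"chemical sets differ: {diff}")
    chem_ids = sorted(pred_ids)
    pred = np.array([ez_score(predicted_calls[c], weights, missing_policy) for c in chem_ids])
    exp = np.array([ez_score(experimental_calls[c], weights, missing_policy) for c in chem_ids])
    return EZComparison(
        chem_ids=chem_ids,
        predicted=pred,
        experimental=exp,
        pearson_r=pearson(pred, exp),
        bias=float(np.mean(pred - exp)),
    )
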
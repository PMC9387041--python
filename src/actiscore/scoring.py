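"""Five-epoch linear discriminant scoring of 2-min activity epochs.

Each 2-min epoch is scored from a symmetric 10-min window of activity
counts (the epoch itself plus two epochs either side):

    z = a_-2 x_-2 + a_-1 x_-1 + a x + a_+1 x_+1 + a_+2 x_+2

with ``z >= threshold`` classified wake (W_ACT) and ``z < threshold``
sleep (S_ACT).  The shipped :data:`CHILD_FS760` model carries the published
school-aged-children coefficients for the waist-worn FS-760 actigraph,
whose decision boundary sits at z = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .epochs import ActivitySeries
from .errors import ValidationError

#: Number of epochs in the scoring window (x_-2 .. x_+2).
WINDOW = 5

#: Supported treatments of epochs lacking full +/-2-epoch context.
EDGE_POLICIES = ("zero", "extend")


@dataclass(frozen=True)
class DiscriminantModel:
    """Coefficient vector (a_-2, a_-1, a, a_+1, a_+2) and wake threshold."""

    coefficients: tuple[float, ...]
    threshold: float = 1.0
    label: str = "custom"

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.coefficients)
        if len(coeffs) != WINDOW:
            raise ValidationError(
                f"discriminant model needs exactly {WINDOW} coefficients, got {len(coeffs)}"
            )
        if not all(math.isfinite(c) for c in coeffs):
            raise ValidationError("coefficients must be finite")
        if not math.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")
        object.__setattr__(self, "coefficients", coeffs)
        object.__setattr__(self, "threshold", float(self.threshold))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "coefficients": list(self.coefficients),
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminantModel":
        try:
            return cls(
                coefficients=tuple(d["coefficients"]),
                threshold=float(d.get("threshold", 1.0)),
                label=str(d.get("label", "custom")),
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed model specification: {exc}") from exc


#: Published FS-760 discriminant for school-aged children (boundary z = 1).
CHILD_FS760 = DiscriminantModel(
    coefficients=(0.108294, 0.147294, 0.230126, 0.099353, 0.059580),
    threshold=1.0,
    label="child_fs760",
)

#: Named built-in models addressable from the CLI as ``builtin:<name>``.
BUILTIN_MODELS: dict[str, DiscriminantModel] = {"child_fs760": CHILD_FS760}


@dataclass(frozen=True)
class SWSeries:
    """Per-epoch discriminant scores and sleep/wake labels.

    ``labels[i]`` is ``"W"`` (W_ACT) exactly when ``scores[i] >= threshold``.
    """

    labels: tuple[str, ...]
    scores: tuple[float, ...]
    model_label: str = "custom"
    edge_policy: str = "zero"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.scores):
            raise ValidationError("labels and scores must have equal length")

    def __len__(self) -> int:
        return len(self.labels)


def discriminant_score(window: Sequence[float], model: DiscriminantModel) -> float:
    """Exact dot product of a 5-epoch activity window with the model.

    The window is ordered (x_-2, x_-1, x, x_+1, x_+2); there is no intercept.
    """
    if len(window) != WINDOW:
        raise ValidationError(
            f"scoring window must hold exactly {WINDOW} counts, got {len(window)}"
        )
    values = [float(v) for v in window]
    if not all(math.isfinite(v) for v in values):
        raise ValidationError("scoring window contains non-finite values")
    return float(sum(a * x for a, x in zip(model.coefficients, values)))


def classify(z: float, model: DiscriminantModel) -> str:
    """``"W"`` if z >= threshold else ``"S"`` (exact comparison, no epsilon)."""
    if not math.isfinite(z):
        raise ValidationError(f"discriminant score must be finite, got {z!r}")
    return "W" if z >= model.threshold else "S"


def score_series(
    a: Union[ActivitySeries, Sequence[float]],
    model: DiscriminantModel = CHILD_FS760,
    edge_policy: str = "zero",
) -> SWSeries:
    """Score every 2-min epoch of an activity series.

    Epochs within two positions of either end lack full window context;
    ``edge_policy="zero"`` treats the missing neighbours as zero activity
    (deterministic, biases edges toward sleep), ``"extend"`` replicates the
    nearest observed count.
    """
    counts = np.asarray(a.counts if isinstance(a, ActivitySeries) else a, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValidationError("activity series must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(counts)):
        raise ValidationError("activity series contains non-finite values")
    if edge_policy not in EDGE_POLICIES:
        raise ValidationError(
            f"unknown edge policy {edge_policy!r}; expected one of {EDGE_POLICIES}"
        )
    pad_mode = "constant" if edge_policy == "zero" else "edge"
    padded = np.pad(counts, 2, mode=pad_mode)
    windows = np.lib.stride_tricks.sliding_window_view(padded, WINDOW)
    scores = windows @ np.asarray(model.coefficients)
    labels = np.where(scores >= model.threshold, "W", "S")
    return SWSeries(
        labels=tuple(labels.tolist()),
        scores=tuple(float(z) for z in scores),
        model_label=model.label,
        edge_policy=edge_policy,
    )
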
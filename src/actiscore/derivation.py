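"""Derivation of a five-coefficient discriminant from paired activity and
PSG data, rescaled so the decision boundary sits at z = 1.

Training rows are 5-epoch activity windows labelled by the collapsed PSG
class of the centre epoch (S_PSG = 0, W_PSG = 1), pooled over all subjects
and epochs.  The classifier is Fisher's linear discriminant: direction
w proportional to Sigma_pooled^{-1} (mu_W - mu_S), equal-cost boundary at
the class-mean midpoint, i.e. raw cut c0 = w . (mu_S + mu_W) / 2.  Dividing
w by c0 moves the boundary to w' . x = 1 without changing any decision,
which is how an all-positive coefficient vector with a fixed threshold of 1
arises.  A prior-weighted cut (log-prior offset) is available; it makes the
rule affine, and the intercept is folded into the reported threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .epochs import ActivitySeries, CollapsedHypnogram
from .errors import DegenerateDataError, ValidationError
from .scoring import WINDOW, DiscriminantModel, EDGE_POLICIES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingSet:
    """Pooled epoch-level design matrix for discriminant fitting.

    ``X`` holds one 5-window of activity per scored epoch, ``y`` the
    collapsed PSG class of its centre epoch (0 = sleep, 1 = wake), and
    ``subject_ids`` the owning subject of each row.
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=np.int8)
        ids = np.asarray(self.subject_ids)
        if X.ndim != 2 or X.shape[1] != WINDOW:
            raise ValidationError(f"training features must be (n, {WINDOW})")
        if y.shape != (X.shape[0],) or ids.shape != (X.shape[0],):
            raise ValidationError("features, labels and subject ids must align")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValidationError("labels must be 0 (sleep) or 1 (wake)")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "subject_ids", ids)

    def __len__(self) -> int:
        return self.X.shape[0]


def assemble_training_set(
    cohort: Iterable[tuple[str, CollapsedHypnogram, ActivitySeries]],
    edge_policy: str = "zero",
) -> TrainingSet:
    """Build the pooled training set from aligned per-subject nights.

    One row is produced per 2-min epoch of every subject (epoch pooling, no
    per-subject weighting); boundary epochs are completed per
    ``edge_policy`` exactly as in scoring.
    """
    if edge_policy not in EDGE_POLICIES:
        raise ValidationError(f"unknown edge policy {edge_policy!r}")
    pad_mode = "constant" if edge_policy == "zero" else "edge"
    xs, ys, ids = [], [], []
    for subject_id, collapsed, activity in cohort:
        n = min(len(collapsed), len(activity))
        if n == 0:
            continue
        counts = np.asarray(activity.counts[:n], dtype=float)
        padded = np.pad(counts, 2, mode=pad_mode)
        xs.append(np.lib.stride_tricks.sliding_window_view(padded, WINDOW))
        ys.append(np.array([0 if e.sw == "S" else 1 for e in collapsed.epochs[:n]]))
        ids.append(np.repeat(subject_id, n))
    if not xs:
        raise ValidationError("empty cohort")
    ts = TrainingSet(
        X=np.concatenate(xs), y=np.concatenate(ys), subject_ids=np.concatenate(ids)
    )
    if len(np.unique(ts.y)) < 2:
        raise DegenerateDataError(
            "training set contains a single class; both sleep and wake epochs "
            "are required to fit a discriminant"
        )
    return ts


def fit_discriminant(
    ts: TrainingSet,
    label: str = "derived",
    priors: tuple[float, float] | None = None,
) -> DiscriminantModel:
    """Fit the Fisher discriminant and rescale its boundary to z = 1.

    Parameters
    ----------
    priors
        Optional (sleep, wake) class priors; when given, the equal-cost
        midpoint cut is shifted by the log prior ratio along w before
        rescaling (folding the offset into the threshold).  Default: equal
        costs, midpoint cut.

    Raises
    ------
    DegenerateDataError
        If one class is absent, the class means coincide, or the raw cut
        c0 is not positive (the boundary then cannot be rescaled to +1).
    """
    X, y = ts.X, ts.y
    mask_w = y == 1
    n_s, n_w = int((~mask_w).sum()), int(mask_w.sum())
    if n_s < 2 or n_w < 2:
        raise DegenerateDataError(
            f"need >= 2 epochs per class to estimate covariance (S={n_s}, W={n_w})"
        )
    Xs, Xw = X[~mask_w], X[mask_w]
    mu_s, mu_w = Xs.mean(axis=0), Xw.mean(axis=0)
    diff = mu_w - mu_s
    if np.allclose(diff, 0.0):
        raise DegenerateDataError("class means coincide; discriminant is undefined")
    pooled = (
        (n_s - 1) * np.cov(Xs, rowvar=False) + (n_w - 1) * np.cov(Xw, rowvar=False)
    ) / (n_s + n_w - 2)
    try:
        w = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError:
        w = None
    if w is None or not np.all(np.isfinite(w)):
        # integer counts can collapse the within-class covariance
        lam = 1e-6 * np.trace(pooled) / WINDOW
        if lam <= 0:
            lam = 1e-6
        warnings.warn(
            f"singular pooled covariance; refitting with ridge lambda={lam:.3g}",
            stacklevel=2,
        )
        w = np.linalg.solve(pooled + lam * np.eye(WINDOW), diff)
    midpoint = (mu_s + mu_w) / 2.0
    c0 = float(w @ midpoint)
    if priors is not None:
        pi_s, pi_w = priors
        if pi_s <= 0 or pi_w <= 0:
            raise ValidationError("priors must be positive")
        c0 = c0 - float(np.log(pi_w / pi_s))
    if c0 <= 0:
        raise DegenerateDataError(
            f"raw decision cut c0={c0:.4g} is not positive; the boundary cannot "
            "be rescaled to z = 1 (wake scores would not exceed sleep scores)"
        )
    coeffs = w / c0
    logger.info(
        "fitted discriminant %s: coefficients=%s (n_S=%d, n_W=%d)",
        label, np.round(coeffs, 6).tolist(), n_s, n_w,
    )
    return DiscriminantModel(
        coefficients=tuple(float(c) for c in coeffs), threshold=1.0, label=label
    )


def split_cohort(
    subject_ids: Sequence[str], seed: int
) -> tuple[list[str], list[str]]:
    """Seeded random subject-level split into two near-equal groups.

    Group A receives the extra subject when the cohort size is odd; the
    split is deterministic given the seed.
    """
    ids = list(subject_ids)
    if len(ids) < 2:
        raise ValidationError("split needs >= 2 subjects")
    if len(set(ids)) != len(ids):
        raise ValidationError("subject ids must be unique")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_a = (len(ids) + 1) // 2
    group_a = [ids[i] for i in sorted(perm[:n_a])]
    group_b = [ids[i] for i in sorted(perm[n_a:])]
    return group_a, group_b
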
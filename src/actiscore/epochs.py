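"""Epoch-grid data model: 30-s hypnograms, 2-min activity series, and the
collapse of PSG staging onto the 2-min sleep/wake grid.

PSG is staged visually in 30-s epochs (stages W, N1, N2, N3, R); the
waist-worn actigraph stores one activity count per 2-min epoch.  To compare
the two, each block of four consecutive 30-s stages is re-classified as a
single 2-min epoch:

* two or more Stage W in the block -> wake (``W_PSG``);
* otherwise sleep (``S_PSG``), sub-classified as the most frequent non-W
  stage in the block, frequency ties broken by the priority
  R > N1 > N2 > N3.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import pandas as pd

from .errors import AlignmentError, ValidationError

#: Canonical stage vocabulary (AASM).
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")
SLEEP_STAGES: tuple[str, ...] = ("N1", "N2", "N3", "R")

#: Priority used to break frequency ties among non-W stages (highest first).
TIE_PRIORITY: tuple[str, ...] = ("R", "N1", "N2", "N3")

#: Legacy stage tokens accepted on input (R&K-era table labels).
LEGACY_STAGE_MAP: dict[str, str] = {
    "W": "W", "N1": "N1", "N2": "N2", "N3": "N3", "R": "R",
    "Stage W": "W", "Stage 1": "N1", "Stage 2": "N2",
    "Stage 3+4": "N3", "Stage REM": "R",
    "1": "N1", "2": "N2", "3+4": "N3", "REM": "R",
}

EPOCH_30S = timedelta(seconds=30)
EPOCH_2MIN = timedelta(minutes=2)
#: 30-s stages per 2-min epoch.
STAGES_PER_EPOCH = 4

#: Maximum stored activity level (32 discrete levels, 0..31).
MAX_COUNT = 31

#: Default analysis cap on time in bed, minutes (first 7 h analysed).
DEFAULT_TIB_CAP_MIN = 420.0


def normalize_stage(token: str) -> str:
    """Map a stage token (canonical or legacy) to one of W/N1/N2/N3/R."""
    stage = LEGACY_STAGE_MAP.get(str(token).strip())
    if stage is None:
        raise ValidationError(f"unknown sleep stage token: {token!r}")
    return stage


@dataclass(frozen=True)
class Hypnogram30:
    """A night of 30-s sleep staging anchored at lights-off.

    Parameters
    ----------
    stages
        Ordered stage labels, one per 30-s epoch, starting at lights-off.
    lights_off, lights_on
        Timestamps bounding time in bed; their span must equal
        ``30 s * len(stages)``.
    """

    stages: tuple[str, ...]
    lights_off: datetime
    lights_on: datetime

    def __post_init__(self) -> None:
        stages = tuple(normalize_stage(s) for s in self.stages)
        object.__setattr__(self, "stages", stages)
        if len(stages) < STAGES_PER_EPOCH:
            raise ValidationError(
                f"hypnogram needs >= {STAGES_PER_EPOCH} stages, got {len(stages)}"
            )
        span = self.lights_on - self.lights_off
        if span != EPOCH_30S * len(stages):
            raise ValidationError(
                f"lights span {span} does not equal 30 s x {len(stages)} stages"
            )

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def tib_min(self) -> float:
        """Time in bed, minutes."""
        return len(self.stages) * 0.5

    def truncated(self, cap_min: float) -> "Hypnogram30":
        """Return the first ``cap_min`` minutes; shorter nights unchanged."""
        n = int(cap_min * 2)
        if n >= len(self.stages):
            return self
        return Hypnogram30(
            stages=self.stages[:n],
            lights_off=self.lights_off,
            lights_on=self.lights_off + EPOCH_30S * n,
        )


@dataclass(frozen=True)
class ActivitySeries:
    """Integer activity counts in [0, 31], one per 2-min epoch."""

    counts: tuple[int, ...]
    start: datetime

    def __post_init__(self) -> None:
        counts = []
        for i, c in enumerate(self.counts):
            if isinstance(c, bool) or int(c) != c:
                raise ValidationError(f"activity count at epoch {i} is not an integer: {c!r}")
            c = int(c)
            if not 0 <= c <= MAX_COUNT:
                raise ValidationError(
                    f"activity count at epoch {i} out of range [0, {MAX_COUNT}]: {c}"
                )
            counts.append(c)
        object.__setattr__(self, "counts", tuple(counts))

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class CollapsedEpoch:
    """One 2-min PSG epoch: sleep/wake class plus sleep substage.

    ``substage`` is ``None`` exactly when ``sw == "W"``.
    """

    sw: str  # "S" (S_PSG) or "W" (W_PSG)
    substage: str | None

    def __post_init__(self) -> None:
        if self.sw not in ("S", "W"):
            raise ValidationError(f"sw must be 'S' or 'W', got {self.sw!r}")
        if (self.substage is None) != (self.sw == "W"):
            raise ValidationError("substage must be None iff the epoch is wake")
        if self.substage is not None and self.substage not in SLEEP_STAGES:
            raise ValidationError(f"invalid substage {self.substage!r}")


@dataclass(frozen=True)
class CollapsedHypnogram:
    """2-min sleep/wake epochs collapsed from 30-s staging."""

    epochs: tuple[CollapsedEpoch, ...]
    lights_off: datetime
    lights_on: datetime

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def sw_labels(self) -> tuple[str, ...]:
        return tuple(e.sw for e in self.epochs)

    @property
    def tib_min(self) -> float:
        return len(self.epochs) * 2.0


def collapse_window(stages: Sequence[str]) -> CollapsedEpoch:
    """Collapse exactly four 30-s stages into one 2-min S/W epoch.

    Two or more W -> wake; otherwise sleep with substage = most frequent
    non-W stage, frequency ties broken by R > N1 > N2 > N3.
    """
    window = [normalize_stage(s) for s in stages]
    if len(window) != STAGES_PER_EPOCH:
        raise ValidationError(
            f"collapse window must hold exactly {STAGES_PER_EPOCH} stages, got {len(window)}"
        )
    counts = Counter(window)
    if counts["W"] >= 2:
        return CollapsedEpoch(sw="W", substage=None)
    non_w = {s: c for s, c in counts.items() if s != "W"}
    top = max(non_w.values())
    # ties among equally frequent stages fall to the priority order
    substage = next(s for s in TIE_PRIORITY if non_w.get(s, 0) == top)
    return CollapsedEpoch(sw="S", substage=substage)


def collapse_hypnogram(
    h: Hypnogram30,
    trailing: str = "drop_trailing",
    tib_cap_min: float | None = DEFAULT_TIB_CAP_MIN,
) -> CollapsedHypnogram:
    """Collapse a 30-s hypnogram onto the 2-min grid.

    Non-overlapping 4-stage windows are consumed from lights-off onward.
    Nights longer than ``tib_cap_min`` are truncated to that cap first
    (analysis uses the first 7 h by default); shorter nights are used whole.

    Parameters
    ----------
    trailing
        ``"drop_trailing"`` drops stages that do not fill a final window;
        ``"error"`` raises instead.
    """
    if trailing not in ("drop_trailing", "error"):
        raise ValidationError(f"unknown trailing policy {trailing!r}")
    if tib_cap_min is not None:
        h = h.truncated(tib_cap_min)
    n_epochs, remainder = divmod(len(h.stages), STAGES_PER_EPOCH)
    if remainder and trailing == "error":
        raise ValidationError(
            f"{remainder} trailing 30-s stages do not fill a 2-min epoch"
        )
    epochs = tuple(
        collapse_window(h.stages[i * STAGES_PER_EPOCH: (i + 1) * STAGES_PER_EPOCH])
        for i in range(n_epochs)
    )
    return CollapsedHypnogram(
        epochs=epochs,
        lights_off=h.lights_off,
        lights_on=h.lights_off + EPOCH_2MIN * n_epochs,
    )


def align_series(
    c: CollapsedHypnogram,
    a: ActivitySeries,
    tolerance: int = 2,
) -> pd.DataFrame:
    """Pair collapsed PSG epochs with activity counts on the shared grid.

    Both series must be anchored at the same lights-off instant.  The pair
    table is truncated to the shorter series; a length mismatch above
    ``tolerance`` epochs raises a warning (the data still align, but a large
    mismatch usually means a clock problem).

    Returns
    -------
    pandas.DataFrame
        Columns ``epoch_index``, ``psg_sw``, ``psg_substage``, ``count``.
    """
    if c.lights_off != a.start:
        raise AlignmentError(
            f"hypnogram lights-off {c.lights_off.isoformat()} != "
            f"activity start {a.start.isoformat()}"
        )
    diff = abs(len(c) - len(a))
    if diff > tolerance:
        warnings.warn(
            f"PSG and activity lengths differ by {diff} epochs "
            f"({len(c)} vs {len(a)}); pairing the first {min(len(c), len(a))}",
            stacklevel=2,
        )
    n = min(len(c), len(a))
    return pd.DataFrame(
        {
            "epoch_index": range(n),
            "psg_sw": [e.sw for e in c.epochs[:n]],
            "psg_substage": [e.substage for e in c.epochs[:n]],
            "count": list(a.counts[:n]),
        }
    )
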
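"""Seeded simulator of paired overnight hypnograms and activity series.

The generator stands in for laboratory recordings: a first-order Markov
chain over the five AASM stages at 30-s resolution produces the hypnogram,
and each 2-min epoch receives an integer activity count drawn from an
overdispersed (negative-binomial) law whose mean depends on the epoch's
dominant stage, clipped to the device's 32 stored levels [0, 31].  A
fraction of wake bouts is "quiet wakefulness" — the subject lies still and
the bout's count mean drops to near-sleep level — which is the mechanism
that caps actigraphic specificity in practice.

Defaults emulate the study conditions the scoring method assumes:
7-h time in bed, sleep efficiency near 90%, sleep latency around 10 min,
and per-stage activity ordered W > R > N1 > N2 > N3, with children moving
more than adults in every stage.  The chain kernel and count laws are a
statistical stand-in — no apnea events, no circadian drift, and activity is
generated from the window-dominant stage rather than 30-s mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Sequence, Union

import numpy as np

from .epochs import (
    EPOCH_30S,
    MAX_COUNT,
    STAGES,
    STAGES_PER_EPOCH,
    ActivitySeries,
    Hypnogram30,
    collapse_window,
)
from .errors import ValidationError

#: Default lights-off instant stamped on simulated nights (arbitrary).
DEFAULT_LIGHTS_OFF = datetime(2000, 1, 1, 21, 30)

#: 30-s stage transition kernel (rows/cols ordered W, N1, N2, N3, R).
#: Tuned to the ~90% sleep-efficiency, ~10-min-latency overnight regime.
DEFAULT_TRANSITIONS = np.array(
    [
        # W      N1     N2     N3     R
        [0.940, 0.060, 0.000, 0.000, 0.000],  # W
        [0.020, 0.760, 0.220, 0.000, 0.000],  # N1
        [0.005, 0.020, 0.907, 0.050, 0.018],  # N2
        [0.002, 0.000, 0.060, 0.933, 0.005],  # N3
        [0.008, 0.030, 0.062, 0.000, 0.900],  # R
    ]
)

#: Per-stage 2-min count means; children move more in every stage.
CHILD_ACTIVITY_MEANS = {"W": 8.0, "R": 1.6, "N1": 0.8, "N2": 0.4, "N3": 0.2}
ADULT_ACTIVITY_MEANS = {"W": 6.0, "R": 0.8, "N1": 0.4, "N2": 0.2, "N3": 0.1}

#: Probability that a whole wake bout is "quiet wakefulness" (lying still),
#: and the count mean of quiet-wake epochs.  Quiet wake is what caps
#: actigraphic specificity: a subject lying motionless awake produces a
#: movement trace indistinguishable from sleep.
DEFAULT_QUIET_WAKE_PROB = 0.30
DEFAULT_QUIET_WAKE_MEAN = 0.8

#: Negative-binomial dispersion (shape k); smaller = more overdispersed.
DEFAULT_DISPERSION = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    Parameters
    ----------
    transition_matrix
        Row-stochastic 5x5 kernel over (W, N1, N2, N3, R) at 30-s steps.
    initial_stage_probs
        Distribution of the stage at lights-off (default: awake).
    tib_min
        Time in bed, minutes; must be divisible by 2.
    activity_means
        Per-stage mean of the 2-min count law.
    dispersion
        Negative-binomial shape parameter k (variance = m + m^2/k).
    population
        "child" or "adult"; selects the activity scale and labels output.
    """

    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy()
    )
    initial_stage_probs: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0)
    tib_min: float = 420.0
    activity_means: dict[str, float] = field(
        default_factory=lambda: dict(CHILD_ACTIVITY_MEANS)
    )
    dispersion: float = DEFAULT_DISPERSION
    quiet_wake_prob: float = DEFAULT_QUIET_WAKE_PROB
    quiet_wake_mean: float = DEFAULT_QUIET_WAKE_MEAN
    population: str = "child"
    lights_off: datetime = DEFAULT_LIGHTS_OFF

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (5, 5) or np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0):
            raise ValidationError("transition matrix must be 5x5 row-stochastic")
        object.__setattr__(self, "transition_matrix", tm)
        p0 = np.asarray(self.initial_stage_probs, dtype=float)
        if p0.shape != (5,) or np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0):
            raise ValidationError("initial stage distribution must be a 5-simplex point")
        if self.tib_min <= 0 or (self.tib_min * 60) % 120 != 0:
            raise ValidationError("tib_min must be positive and divisible by 2 min")
        if set(self.activity_means) != set(STAGES):
            raise ValidationError(f"activity means must cover stages {STAGES}")
        if any(m < 0 for m in self.activity_means.values()):
            raise ValidationError("activity means must be non-negative")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if not 0.0 <= self.quiet_wake_prob <= 1.0:
            raise ValidationError("quiet_wake_prob must lie in [0, 1]")
        if self.quiet_wake_mean < 0:
            raise ValidationError("quiet_wake_mean must be non-negative")
        if self.population not in ("child", "adult"):
            raise ValidationError("population must be 'child' or 'adult'")

    @classmethod
    def child(cls, **overrides) -> "SimConfig":
        return cls(population="child",
                   activity_means=dict(CHILD_ACTIVITY_MEANS), **overrides)

    @classmethod
    def adult(cls) -> "SimConfig":
        return cls(population="adult", activity_means=dict(ADULT_ACTIVITY_MEANS))


@dataclass(frozen=True)
class SimulatedSubject:
    """One simulated night: hypnogram, activity, and generating truth.

    ``truth`` records the dominant stage of each 2-min window actually used
    to draw the activity count.
    """

    hypnogram: Hypnogram30
    activity: ActivitySeries
    truth: tuple[str, ...]


SeedLike = Union[int, np.random.SeedSequence]


def _seed_seq(seed: SeedLike) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def _dominant_stage(window: Sequence[str]) -> str:
    epoch = collapse_window(window)
    return "W" if epoch.sw == "W" else epoch.substage  # type: ignore[return-value]


def simulate_subject(cfg: SimConfig, seed: SeedLike) -> SimulatedSubject:
    """Simulate one subject's night, reproducibly.

    Two independent RNG streams are derived from the seed — one for the
    stage chain, one for the counts — so changing the activity model leaves
    the hypnogram trace unchanged and vice versa.
    """
    ss = _seed_seq(seed)
    ss_stages, ss_counts = ss.spawn(2)
    rng_stages = np.random.default_rng(ss_stages)
    rng_counts = np.random.default_rng(ss_counts)

    n_stages = int(cfg.tib_min * 2)
    chain = np.empty(n_stages, dtype=int)
    chain[0] = rng_stages.choice(5, p=np.asarray(cfg.initial_stage_probs))
    tm = cfg.transition_matrix
    for i in range(1, n_stages):
        chain[i] = rng_stages.choice(5, p=tm[chain[i - 1]])
    stages = tuple(STAGES[i] for i in chain)

    lights_off = cfg.lights_off
    hypnogram = Hypnogram30(
        stages=stages,
        lights_off=lights_off,
        lights_on=lights_off + EPOCH_30S * n_stages,
    )

    n_epochs = n_stages // STAGES_PER_EPOCH
    truth = []
    counts = []
    k = cfg.dispersion
    in_wake_bout = False
    bout_is_quiet = False
    for e in range(n_epochs):
        window = stages[e * STAGES_PER_EPOCH: (e + 1) * STAGES_PER_EPOCH]
        stage = _dominant_stage(window)
        truth.append(stage)
        mean = cfg.activity_means[stage]
        if stage == "W":
            if not in_wake_bout:
                # quiet/active is a property of the whole wake bout
                bout_is_quiet = rng_counts.random() < cfg.quiet_wake_prob
                in_wake_bout = True
            if bout_is_quiet:
                mean = cfg.quiet_wake_mean
        else:
            in_wake_bout = False
        if mean == 0:
            raw = 0
        else:
            raw = int(rng_counts.negative_binomial(k, k / (k + mean)))
        counts.append(min(raw, MAX_COUNT))
    activity = ActivitySeries(counts=tuple(counts), start=lights_off)
    return SimulatedSubject(hypnogram=hypnogram, activity=activity, truth=tuple(truth))


def simulate_cohort(
    cfg: SimConfig, n_subjects: int, seed: SeedLike
) -> list[SimulatedSubject]:
    """Simulate ``n_subjects`` independent nights from per-subject seeds
    spawned from the master seed; reproducible and order-stable."""
    if n_subjects < 1:
        raise ValidationError(f"cohort size must be >= 1, got {n_subjects}")
    child_seeds = _seed_seq(seed).spawn(n_subjects)
    return [simulate_subject(cfg, s) for s in child_seeds]
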
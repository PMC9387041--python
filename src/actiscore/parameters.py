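"""Sleep parameters (SL, WASO, TST, SE) on the 2-min epoch grid, and the
run-length rule optimization.

PSG definitions: sleep latency SL is lights-off to the first sleep epoch;
TST is the total sleep time from onset to lights-on; WASO is
TIB - (SL + TST); SE is 100 * TST / TIB.

Activity definitions use run-length rules: sleep onset is the first run of
at least ``n_sl`` consecutive S_ACT epochs; WASO counts only W_ACT runs of
at least ``n_waso`` consecutive epochs after onset (shorter wake bursts are
treated as sleep for the parameter arithmetic only — epoch labels are never
rewritten).  TST_ACT = TIB - SL_ACT - WASO_ACT, so SL + WASO + TST = TIB
holds exactly by construction for both methods.

``optimize_run_rule`` reproduces the calibration search: for n = 1..10 it
compares cohort means of the activity parameter against PSG, keeps the n
whose paired difference is non-significant with ICC >= 0.6, and among those
picks the n minimizing |mean difference| (smallest n on ties).  The
published optima, n_sl = 4 and n_waso = 5, are the shipped defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .epochs import CollapsedHypnogram
from .errors import DegenerateDataError, ValidationError
from .scoring import SWSeries
from .validation import icc as _icc, paired_ttest

#: Epoch duration on the analysis grid, minutes.
EPOCH_MIN = 2.0

#: Search range of the run-length rule.
N_RANGE = tuple(range(1, 11))

#: Published defaults for the run-length rules.
DEFAULT_N_SL = 4
DEFAULT_N_WASO = 5


@dataclass(frozen=True)
class RunRuleParams:
    """Run lengths (in 2-min epochs) defining activity sleep onset and WASO."""

    n_sl: int = DEFAULT_N_SL
    n_waso: int = DEFAULT_N_WASO

    def __post_init__(self) -> None:
        for name, n in (("n_sl", self.n_sl), ("n_waso", self.n_waso)):
            if not isinstance(n, (int, np.integer)) or not 1 <= int(n) <= 10:
                raise ValidationError(f"{name} must be an integer in [1, 10], got {n!r}")


@dataclass(frozen=True)
class SleepParameters:
    """SL, WASO, TST (minutes), TIB (minutes) and SE (%).

    ``onset_defined`` is False for nights with no qualifying sleep onset; in
    that case SL/WASO/TST are ``nan`` and SE is 0.
    """

    sl_min: float
    waso_min: float
    tst_min: float
    tib_min: float
    se_pct: float
    onset_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "sl_min": self.sl_min,
            "waso_min": self.waso_min,
            "tst_min": self.tst_min,
            "tib_min": self.tib_min,
            "se_pct": self.se_pct,
            "onset_defined": self.onset_defined,
        }


def _labels(s) -> list[str]:
    seq = list(s.labels) if isinstance(s, SWSeries) else list(s)
    if not seq:
        raise ValidationError("empty sleep/wake label sequence")
    for lab in seq:
        if lab not in ("S", "W"):
            raise ValidationError(f"label must be 'S' or 'W', got {lab!r}")
    return seq


def find_runs(labels: Sequence[str], symbol: str) -> list[tuple[int, int]]:
    """Maximal runs of ``symbol`` as (start_index, length) pairs."""
    runs = []
    start = None
    for i, lab in enumerate(labels):
        if lab == symbol and start is None:
            start = i
        elif lab != symbol and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(labels) - start))
    return runs


def psg_parameters(c: CollapsedHypnogram) -> SleepParameters:
    """Sleep parameters from collapsed PSG epochs.

    A night with no sleep epoch at all has no onset: SL/WASO/TST are nan,
    SE = 0, ``onset_defined`` False.
    """
    labels = [e.sw for e in c.epochs]
    tib = len(labels) * EPOCH_MIN
    if "S" not in labels:
        return SleepParameters(
            sl_min=math.nan, waso_min=math.nan, tst_min=math.nan,
            tib_min=tib, se_pct=0.0, onset_defined=False,
        )
    onset = labels.index("S")
    sl = onset * EPOCH_MIN
    tst = labels[onset:].count("S") * EPOCH_MIN
    waso = tib - (sl + tst)
    return SleepParameters(
        sl_min=sl, waso_min=waso, tst_min=tst, tib_min=tib,
        se_pct=100.0 * tst / tib,
    )


def act_sleep_onset(
    s, n_sl: int, strict_gt: bool = False
) -> int | None:
    """Index of the first epoch of the first qualifying S_ACT run.

    A run qualifies when its length is >= n_sl (or > n_sl with
    ``strict_gt``).  Returns ``None`` when no run qualifies.
    """
    if not 1 <= int(n_sl) <= 10:
        raise ValidationError(f"n_sl must be in [1, 10], got {n_sl}")
    labels = _labels(s)
    need = int(n_sl) + (1 if strict_gt else 0)
    for start, length in find_runs(labels, "S"):
        if length >= need:
            return start
    return None


def act_waso(
    s, onset: int, n_waso: int, strict_gt: bool = False
) -> float:
    """WASO_ACT in minutes: qualifying W_ACT runs strictly after onset.

    Only maximal W_ACT runs of length >= n_waso (or > with ``strict_gt``)
    count; shorter wake bursts contribute nothing.
    """
    labels = _labels(s)
    if onset is None:
        raise DegenerateDataError("WASO is undefined without a sleep onset")
    if not 0 <= int(onset) < len(labels):
        raise ValidationError(f"onset index {onset} outside the night")
    if not 1 <= int(n_waso) <= 10:
        raise ValidationError(f"n_waso must be in [1, 10], got {n_waso}")
    need = int(n_waso) + (1 if strict_gt else 0)
    total_epochs = sum(
        length
        for start, length in find_runs(labels, "W")
        if start > onset and length >= need
    )
    return total_epochs * EPOCH_MIN


def act_parameters(
    s,
    rules: RunRuleParams = RunRuleParams(),
    strict_gt: bool = False,
) -> SleepParameters:
    """Activity sleep parameters under the given run-length rules.

    TST = TIB - SL - WASO, so the conservation identity is exact.  A night
    with no qualifying onset yields nan parameters, SE = 0.
    """
    labels = _labels(s)
    tib = len(labels) * EPOCH_MIN
    onset = act_sleep_onset(labels, rules.n_sl, strict_gt=strict_gt)
    if onset is None:
        return SleepParameters(
            sl_min=math.nan, waso_min=math.nan, tst_min=math.nan,
            tib_min=tib, se_pct=0.0, onset_defined=False,
        )
    sl = onset * EPOCH_MIN
    waso = act_waso(labels, onset, rules.n_waso, strict_gt=strict_gt)
    tst = tib - sl - waso
    return SleepParameters(
        sl_min=sl, waso_min=waso, tst_min=tst, tib_min=tib,
        se_pct=100.0 * tst / tib,
    )


@dataclass(frozen=True)
class OptimizationResult:
    """Per-n comparison table and the chosen run length.

    ``table`` columns: n, mean_act, mean_psg, delta, t, p, icc, icc_p,
    n_subjects, feasible.  ``chosen_n`` is None when no n is feasible.
    """

    param: str
    table: pd.DataFrame
    chosen_n: int | None

    @property
    def feasible_ns(self) -> list[int]:
        return [int(n) for n in self.table.loc[self.table["feasible"], "n"]]


def optimize_run_rule(
    psg_values: Sequence[float],
    act_values_by_n: Mapping[int, Sequence[float]],
    param: str = "SL",
    alpha: float = 0.05,
    icc_min: float = 0.6,
) -> OptimizationResult:
    """Choose the run length n whose cohort mean best matches PSG.

    For each n the paired difference act - psg is tested (two-sided paired
    t); n is feasible when p >= alpha (no significant difference) and
    ICC >= icc_min.  Among feasible n the one minimizing |mean difference|
    wins, smallest n on ties.  Subjects with an undefined (nan) activity
    value at a given n are dropped pairwise for that n.
    """
    psg = np.asarray(psg_values, dtype=float)
    if psg.ndim != 1 or psg.size < 3:
        raise ValidationError("optimization needs >= 3 subjects")
    if not act_values_by_n:
        raise ValidationError("empty n range")
    rows = []
    for n in sorted(int(k) for k in act_values_by_n):
        act = np.asarray(act_values_by_n[n], dtype=float)
        if act.shape != psg.shape:
            raise ValidationError(
                f"activity values for n={n} do not align with PSG values"
            )
        mask = np.isfinite(act) & np.isfinite(psg)
        a, p_vals = act[mask], psg[mask]
        if mask.sum() < 3:
            rows.append(
                dict(n=n, mean_act=math.nan, mean_psg=math.nan, delta=math.nan,
                     t=math.nan, p=math.nan, icc=math.nan, icc_p=math.nan,
                     n_subjects=int(mask.sum()), feasible=False)
            )
            continue
        delta = float(a.mean() - p_vals.mean())
        t, pval = paired_ttest(a, p_vals)
        icc_val, icc_p = _icc(p_vals, a)
        feasible = (
            math.isfinite(pval) and pval >= alpha
            and math.isfinite(icc_val) and icc_val >= icc_min
        )
        rows.append(
            dict(n=n, mean_act=float(a.mean()), mean_psg=float(p_vals.mean()),
                 delta=delta, t=t, p=pval, icc=icc_val, icc_p=icc_p,
                 n_subjects=int(mask.sum()), feasible=feasible)
        )
    table = pd.DataFrame(rows)
    feasible = table[table["feasible"]]
    chosen_n = None
    if not feasible.empty:
        # stable sort keeps the smallest n among |delta| ties
        chosen_n = int(
            feasible.assign(absdelta=feasible["delta"].abs())
            .sort_values(["absdelta", "n"], kind="stable")
            .iloc[0]["n"]
        )
    return OptimizationResult(param=param, table=table, chosen_n=chosen_n)


def optimize_cohort(
    pairs: Iterable[tuple[CollapsedHypnogram, Union[SWSeries, Sequence[str]]]],
    param: str = "SL",
    n_range: Sequence[int] = N_RANGE,
    n_sl_for_waso: int = DEFAULT_N_SL,
    alpha: float = 0.05,
    icc_min: float = 0.6,
    strict_gt: bool = False,
) -> OptimizationResult:
    """Run the optimization search over a cohort of paired nights.

    ``param`` is "SL" or "WASO".  For WASO the onset is fixed by
    ``n_sl_for_waso`` (the optimized sleep-onset rule) while the WASO run
    length is searched.  Nights without a qualifying onset contribute nan
    and are dropped pairwise per n.
    """
    if param not in ("SL", "WASO"):
        raise ValidationError(f"param must be 'SL' or 'WASO', got {param!r}")
    pairs = list(pairs)
    psg_vals = []
    act_by_n: dict[int, list[float]] = {int(n): [] for n in n_range}
    for collapsed, sw in pairs:
        psg = psg_parameters(collapsed)
        psg_vals.append(psg.sl_min if param == "SL" else psg.waso_min)
        labels = _labels(sw)
        for n in n_range:
            if param == "SL":
                onset = act_sleep_onset(labels, n, strict_gt=strict_gt)
                val = math.nan if onset is None else onset * EPOCH_MIN
            else:
                onset = act_sleep_onset(labels, n_sl_for_waso, strict_gt=strict_gt)
                val = (
                    math.nan
                    if onset is None
                    else act_waso(labels, onset, n, strict_gt=strict_gt)
                )
            act_by_n[int(n)].append(val)
    return optimize_run_rule(
        psg_vals, act_by_n, param=param, alpha=alpha, icc_min=icc_min
    )
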
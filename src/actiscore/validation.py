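"""Epoch-by-epoch validation of actigraphic scoring against PSG.

Conventions follow the actigraphy-validation literature: sensitivity is the
true-sleep detection rate (fraction of PSG sleep epochs scored S_ACT),
specificity the true-wake detection rate, and the per-stage agreement of a
sleep stage is the fraction of its epochs scored S_ACT (for W, scored
W_ACT).  Method agreement across subjects is summarised by the intraclass
correlation coefficient; ICC(2,1) (two-way random effects, absolute
agreement, single measures) is the default form for method-comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .epochs import CollapsedHypnogram, SLEEP_STAGES, STAGES
from .errors import ValidationError
from .scoring import SWSeries

#: Stage order used in report tables.
REPORT_STAGES = ("N1", "N2", "N3", "R", "W")


@dataclass
class ValidationReport:
    """2x2 confusion tallies and the derived agreement percentages.

    Percentages with an empty denominator (e.g. specificity on a night with
    no PSG wake) are ``None`` and excluded from cohort means.
    """

    n_epochs: int
    n_ss: int  # PSG sleep scored S_ACT
    n_sw: int  # PSG sleep scored W_ACT
    n_ws: int  # PSG wake scored S_ACT
    n_ww: int  # PSG wake scored W_ACT
    agreement_overall_pct: float
    sensitivity_pct: float | None
    specificity_pct: float | None
    agreement_by_stage: dict[str, float | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_epochs": self.n_epochs,
            "n_ss": self.n_ss,
            "n_sw": self.n_sw,
            "n_ws": self.n_ws,
            "n_ww": self.n_ww,
            "agreement_overall_pct": self.agreement_overall_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "agreement_by_stage": dict(self.agreement_by_stage),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        return cls(
            n_epochs=int(d["n_epochs"]),
            n_ss=int(d["n_ss"]),
            n_sw=int(d["n_sw"]),
            n_ws=int(d["n_ws"]),
            n_ww=int(d["n_ww"]),
            agreement_overall_pct=float(d["agreement_overall_pct"]),
            sensitivity_pct=_opt_float(d.get("sensitivity_pct")),
            specificity_pct=_opt_float(d.get("specificity_pct")),
            agreement_by_stage={
                k: _opt_float(v) for k, v in d.get("agreement_by_stage", {}).items()
            },
        )


def _opt_float(v) -> float | None:
    return None if v is None else float(v)


def _as_sw(labels) -> list[str]:
    seq = list(labels.labels) if isinstance(labels, SWSeries) else list(labels)
    for lab in seq:
        if lab not in ("S", "W"):
            raise ValidationError(f"sleep/wake label must be 'S' or 'W', got {lab!r}")
    return seq


def confusion_metrics(psg: Sequence[str], act) -> ValidationReport:
    """Overall agreement, sensitivity and specificity of ACT vs PSG labels.

    Both sequences are per-2-min-epoch "S"/"W" labels of equal length.
    """
    psg_labels = _as_sw(psg)
    act_labels = _as_sw(act)
    if len(psg_labels) != len(act_labels):
        raise ValidationError(
            f"PSG and ACT label sequences differ in length "
            f"({len(psg_labels)} vs {len(act_labels)})"
        )
    if not psg_labels:
        raise ValidationError("cannot validate an empty epoch sequence")
    n_ss = n_sw = n_ws = n_ww = 0
    for p, a in zip(psg_labels, act_labels):
        if p == "S":
            if a == "S":
                n_ss += 1
            else:
                n_sw += 1
        else:
            if a == "S":
                n_ws += 1
            else:
                n_ww += 1
    total = len(psg_labels)
    n_sleep = n_ss + n_sw
    n_wake = n_ws + n_ww
    return ValidationReport(
        n_epochs=total,
        n_ss=n_ss,
        n_sw=n_sw,
        n_ws=n_ws,
        n_ww=n_ww,
        agreement_overall_pct=100.0 * (n_ss + n_ww) / total,
        sensitivity_pct=100.0 * n_ss / n_sleep if n_sleep else None,
        specificity_pct=100.0 * n_ww / n_wake if n_wake else None,
    )


def stagewise_agreement(c: CollapsedHypnogram, act) -> dict[str, float | None]:
    """Per-PSG-stage agreement with the activity scoring.

    For each sleep substage the match target is S_ACT; for W it is W_ACT.
    Stages absent from the night map to ``None``.
    """
    act_labels = _as_sw(act)
    if len(c) != len(act_labels):
        raise ValidationError(
            f"collapsed hypnogram and ACT labels differ in length "
            f"({len(c)} vs {len(act_labels)})"
        )
    out: dict[str, float | None] = {}
    for stage in REPORT_STAGES:
        if stage == "W":
            idx = [i for i, e in enumerate(c.epochs) if e.sw == "W"]
            target = "W"
        else:
            idx = [i for i, e in enumerate(c.epochs) if e.substage == stage]
            target = "S"
        if not idx:
            out[stage] = None
        else:
            hits = sum(1 for i in idx if act_labels[i] == target)
            out[stage] = 100.0 * hits / len(idx)
    return out


def validate_subject(c: CollapsedHypnogram, act) -> ValidationReport:
    """Full per-subject report: confusion metrics plus per-stage agreement."""
    report = confusion_metrics(c.sw_labels, act)
    report.agreement_by_stage = stagewise_agreement(c, act)
    return report


def icc(
    psg_values: Sequence[float],
    act_values: Sequence[float],
    form: str = "icc2",
) -> tuple[float, float]:
    """Intraclass correlation between paired per-subject measurements.

    Parameters
    ----------
    form
        ``"icc2"`` -> ICC(2,1), two-way random effects, absolute agreement,
        single measures (default; penalises systematic offsets).
        ``"icc3"`` -> ICC(3,1), two-way mixed, consistency.

    Returns
    -------
    (icc, p)
        The coefficient and the p-value of its F test.  When the residual
        mean square is exactly zero (identical raters) the F statistic is
        unbounded; the result is (1.0, 0.0) if subjects differ, and
        (nan, nan) — undefined — if there is no variance at all.
    """
    x = np.asarray(psg_values, dtype=float)
    y = np.asarray(act_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("ICC needs two equal-length 1-D value sequences")
    if x.size < 3:
        raise ValidationError(f"ICC needs >= 3 paired subjects, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("ICC inputs must be finite")
    if form not in ("icc2", "icc3"):
        raise ValidationError(f"unknown ICC form {form!r}")

    if np.ptp(np.concatenate([x, y])) == 0.0:
        return (math.nan, math.nan)
    if np.array_equal(x, y):
        return (1.0, 0.0)

    n = x.size
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "rater": np.tile(["psg", "act"], n),
            "value": np.column_stack([x, y]).ravel(),
        }
    )
    with warnings.catch_warnings():
        # degenerate mean squares (e.g. zero residual) raise benign divide
        # warnings inside pingouin; the resulting inf F / p=0 are correct
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            long, targets="subject", raters="rater", ratings="value"
        ).set_index("Type")
    # absolute agreement, single measures = ICC(2,1); consistency = ICC(3,1)
    row = table.loc["ICC(A,1)" if form == "icc2" else "ICC(C,1)"]
    return (float(row["ICC"]), float(row["pval"]))


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Student's t-test (df = n - 1).

    Identically-zero differences are the degenerate perfect-agreement case:
    defined here as t = 0, p = 1.  Zero-variance non-zero differences give
    t = +/-inf, p = 0.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("paired t-test needs two equal-length sequences, n >= 2")
    d = x - y
    if np.all(d == d[0]):
        if d[0] == 0.0:
            return (0.0, 1.0)
        return (math.copysign(math.inf, d[0]), 0.0)
    t, p = stats.ttest_rel(x, y)
    return (float(t), float(p))


def unpaired_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided unpaired Student's t-test (equal variances, df = nA+nB-2)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size < 2 or y.size < 2:
        raise ValidationError("unpaired t-test needs >= 2 observations per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x.mean() == y.mean():
            return (0.0, 1.0)
        return (math.copysign(math.inf, x.mean() - y.mean()), 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return (float(t), float(p))


def group_ttests(
    group_a: pd.DataFrame, group_b: pd.DataFrame, paired: bool = False
) -> pd.DataFrame:
    """Per-metric two-sided t-tests between two groups of subject metrics.

    Both inputs are subject-by-metric tables sharing column names; missing
    (flagged) values are dropped pairwise.  Returns a table with columns
    ``t`` and ``p`` indexed by metric.
    """
    metrics = [m for m in group_a.columns if m in group_b.columns]
    if not metrics:
        raise ValidationError("groups share no metric columns")
    rows = {}
    for m in metrics:
        a = group_a[m].dropna().to_numpy(dtype=float)
        b = group_b[m].dropna().to_numpy(dtype=float)
        if paired:
            mask = group_a[m].notna().to_numpy() & group_b[m].notna().to_numpy()
            a = group_a[m].to_numpy(dtype=float)[mask]
            b = group_b[m].to_numpy(dtype=float)[mask]
            rows[m] = paired_ttest(a, b)
        else:
            rows[m] = unpaired_ttest(a, b)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["t", "p"])


def report_frame(reports: Iterable[ValidationReport]) -> pd.DataFrame:
    """Subject-by-metric table (overall, per-stage, sensitivity, specificity)."""
    rows = []
    for r in reports:
        row = {"agreement_overall_pct": r.agreement_overall_pct}
        for stage in REPORT_STAGES:
            row[f"agreement_{stage}_pct"] = r.agreement_by_stage.get(stage)
        row["sensitivity_pct"] = r.sensitivity_pct
        row["specificity_pct"] = r.specificity_pct
        rows.append(row)
    return pd.DataFrame(rows).astype(float)


def cohort_summary(reports: Iterable[ValidationReport]) -> pd.DataFrame:
    """Cohort mean +/- SD of each metric, flagged missing values excluded.

    Metrics are computed per subject and then averaged across subjects
    (matching the mean +/- SD presentation of validation tables), not pooled
    over epochs.
    """
    frame = report_frame(reports)
    return pd.DataFrame(
        {
            "mean": frame.mean(skipna=True),
            "sd": frame.std(skipna=True, ddof=1),
            "n_subjects": frame.notna().sum(),
        }
    )


def feature_table(
    subjects: Iterable[tuple[str, CollapsedHypnogram, Sequence[int], float | None]],
) -> pd.DataFrame:
    """Per-subject features for external regression analyses.

    Each element is ``(subject_id, collapsed, counts, age_or_None)``.
    Emits sleep efficiency (PSG) and mean activity during PSG wake, NREM
    and REM epochs.
    """
    from .parameters import psg_parameters  # local import avoids a cycle

    rows = []
    for subject_id, collapsed, counts, age in subjects:
        counts_arr = np.asarray(list(counts)[: len(collapsed)], dtype=float)
        wake = [i for i, e in enumerate(collapsed.epochs) if e.sw == "W"]
        nrem = [
            i for i, e in enumerate(collapsed.epochs) if e.substage in ("N1", "N2", "N3")
        ]
        rem = [i for i, e in enumerate(collapsed.epochs) if e.substage == "R"]
        params = psg_parameters(collapsed)
        rows.append(
            {
                "subject_id": subject_id,
                "age": age,
                "se_psg_pct": params.se_pct,
                "mean_count_wake": counts_arr[wake].mean() if wake else np.nan,
                "mean_count_nrem": counts_arr[nrem].mean() if nrem else np.nan,
                "mean_count_rem": counts_arr[rem].mean() if rem else np.nan,
            }
        )
    return pd.DataFrame(rows)
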
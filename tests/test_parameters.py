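"""Run-length sleep parameters (SL, WASO, TST, SE) and the n-optimization."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from actiscore import (
    DegenerateDataError,
    RunRuleParams,
    ValidationError,
    act_parameters,
    act_sleep_onset,
    act_waso,
    collapse_hypnogram,
    optimize_cohort,
    optimize_run_rule,
    psg_parameters,
)
from actiscore.parameters import find_runs

from conftest import make_hypnogram

sw_labels = st.lists(st.sampled_from(["S", "W"]), min_size=1, max_size=80)


# ---------------------------------------------------------------- oracles

def oracle_runs(labels, symbol):
    """Brute force: for every index, test whether it starts a maximal run."""
    runs = []
    for i in range(len(labels)):
        if labels[i] == symbol and (i == 0 or labels[i - 1] != symbol):
            j = i
            while j < len(labels) and labels[j] == symbol:
                j += 1
            runs.append((i, j - i))
    return runs


def oracle_onset(labels, n):
    for start, length in oracle_runs(labels, "S"):
        if length >= n:
            return start
    return None


def oracle_waso(labels, onset, n):
    return 2.0 * sum(
        length for start, length in oracle_runs(labels, "W")
        if start > onset and length >= n
    )


# ------------------------------------------------------------ PSG parameters

def test_psg_parameters_hand_trace():
    """210 epochs, first two wake, rest sleep: SL=4, TST=416, WASO=0."""
    stages = ["W"] * 8 + ["N2"] * 832
    p = psg_parameters(collapse_hypnogram(make_hypnogram(stages)))
    assert p.sl_min == 4.0
    assert p.tst_min == 416.0
    assert p.waso_min == 0.0
    assert p.se_pct == pytest.approx(100 * 416 / 420, abs=5e-3)


def test_psg_all_sleep():
    p = psg_parameters(collapse_hypnogram(make_hypnogram(["N2"] * 40)))
    assert (p.sl_min, p.waso_min, p.se_pct) == (0.0, 0.0, 100.0)


def test_psg_all_wake_has_no_onset():
    p = psg_parameters(collapse_hypnogram(make_hypnogram(["W"] * 40)))
    assert not p.onset_defined
    assert math.isnan(p.sl_min) and p.se_pct == 0.0


def test_psg_interior_wake_counts_as_waso():
    # 2 epochs W, 3 epochs S, 2 epochs W, 3 epochs S
    stages = ["W"] * 8 + ["N2"] * 12 + ["W"] * 8 + ["N2"] * 12
    p = psg_parameters(collapse_hypnogram(make_hypnogram(stages)))
    assert p.sl_min == 4.0 and p.waso_min == 4.0 and p.tst_min == 12.0
    assert p.sl_min + p.waso_min + p.tst_min == p.tib_min


# --------------------------------------------------------- activity onset/WASO

def test_onset_examples():
    labels = ["W", "W", "S", "S", "S", "W", "S", "S", "S", "S"]
    assert act_sleep_onset(labels, 4) == 6
    assert act_sleep_onset(labels, 1) == 2
    assert act_sleep_onset(["S"] * 12, 10) == 0
    assert act_sleep_onset(["W"] * 5 + ["S", "S"], 3) is None


def test_strict_gt_reading_requires_one_more_epoch():
    labels = ["W", "S", "S", "S", "W"]
    assert act_sleep_onset(labels, 3) == 1
    assert act_sleep_onset(labels, 3, strict_gt=True) is None


def test_waso_counts_only_long_runs():
    # W-runs after onset of lengths 3, 5, 7
    labels = (
        ["S"] * 4 + ["W"] * 3 + ["S"] * 2 + ["W"] * 5 + ["S"] * 2 + ["W"] * 7 + ["S"]
    )
    onset = act_sleep_onset(labels, 2)
    assert onset == 0
    assert act_waso(labels, onset, 5) == (5 + 7) * 2.0
    assert act_waso(labels, onset, 1) == (3 + 5 + 7) * 2.0
    assert act_waso(["S"] * 10, 0, 3) == 0.0


def test_waso_requires_defined_onset():
    with pytest.raises(DegenerateDataError):
        act_waso(["S", "W"], None, 2)


@given(sw_labels, st.integers(1, 10))
def test_onset_matches_brute_force(labels, n):
    assert act_sleep_onset(labels, n) == oracle_onset(labels, n)


@given(sw_labels, st.integers(1, 10), st.integers(1, 10))
def test_waso_matches_brute_force(labels, n_sl, n_waso):
    onset = oracle_onset(labels, n_sl)
    if onset is not None:
        assert act_waso(labels, onset, n_waso) == oracle_waso(labels, onset, n_waso)


@given(sw_labels)
def test_find_runs_matches_oracle(labels):
    for symbol in ("S", "W"):
        assert find_runs(labels, symbol) == oracle_runs(labels, symbol)


# ----------------------------------------------------------- act parameters

def test_act_parameters_arithmetic():
    """SL=12, WASO=24, TIB=420 -> TST=384, SE=91.43%."""
    labels = (
        ["W"] * 6 + ["S"] * 50 + ["W"] * 5 + ["S"] * 50 + ["W"] * 7 + ["S"] * 92
    )
    assert len(labels) == 210
    p = act_parameters(labels, RunRuleParams(n_sl=4, n_waso=5))
    assert p.sl_min == 12.0 and p.waso_min == 24.0
    assert p.tst_min == 384.0
    assert p.se_pct == pytest.approx(100 * 384 / 420, abs=5e-3)


def test_act_parameters_all_sleep():
    p = act_parameters(["S"] * 30)
    assert (p.sl_min, p.waso_min, p.tst_min, p.se_pct) == (0.0, 0.0, 60.0, 100.0)


def test_act_parameters_no_onset_flagged():
    p = act_parameters(["W"] * 30)
    assert not p.onset_defined and p.se_pct == 0.0


@given(sw_labels, st.integers(1, 10), st.integers(1, 10))
def test_conservation_sl_waso_tst_tib(labels, n_sl, n_waso):
    p = act_parameters(labels, RunRuleParams(n_sl=n_sl, n_waso=n_waso))
    if p.onset_defined:
        assert p.sl_min + p.waso_min + p.tst_min == p.tib_min


@given(sw_labels, st.integers(1, 10))
def test_sl_at_n1_lower_bounds_sl_at_any_n(labels, n):
    onset1 = act_sleep_onset(labels, 1)
    onset_n = act_sleep_onset(labels, n)
    if onset_n is not None:
        assert onset1 is not None and onset1 <= onset_n


@given(sw_labels, st.integers(1, 9))
def test_waso_non_increasing_in_n(labels, n):
    onset = act_sleep_onset(labels, 1)
    if onset is not None:
        assert act_waso(labels, onset, n) >= act_waso(labels, onset, n + 1)


# ------------------------------------------------------------- optimization

def test_run_rule_params_validated():
    with pytest.raises(ValidationError):
        RunRuleParams(n_sl=0)
    with pytest.raises(ValidationError):
        RunRuleParams(n_waso=11)
    defaults = RunRuleParams()
    assert (defaults.n_sl, defaults.n_waso) == (4, 5)


def _concordant_cohort(rng, n_subjects=12):
    """Cohort whose ACT labels equal the PSG S/W labels exactly."""
    pairs = []
    for _ in range(n_subjects):
        sl_epochs = int(rng.integers(1, 12))
        stages = (
            ["W"] * (4 * sl_epochs)
            + ["N2"] * (4 * int(rng.integers(60, 90)))
            + ["W"] * 8
            + ["N2"] * 40
        )
        collapsed = collapse_hypnogram(make_hypnogram(stages))
        pairs.append((collapsed, list(collapsed.sw_labels)))
    return pairs


def test_perfect_concordance_chooses_n_equal_1():
    rng = np.random.default_rng(3)
    pairs = _concordant_cohort(rng)
    result = optimize_cohort(pairs, param="SL")
    assert result.chosen_n == 1
    row = result.table.set_index("n").loc[1]
    assert row["delta"] == 0.0
    assert row["icc"] == pytest.approx(1.0, abs=1e-12)
    assert row["p"] == 1.0


def test_optimizer_matches_exhaustive_search_with_false_wake_runs():
    """Inject brief false-wake runs of length 4 into the ACT labels; an
    independent exhaustive search over n must pick the same n."""
    rng = np.random.default_rng(5)
    pairs = []
    for _ in range(15):
        sl_epochs = int(rng.integers(2, 10))
        true_wake = int(rng.integers(6, 10))  # a real mid-night awakening
        psg_labels = (
            ["W"] * sl_epochs + ["S"] * 60 + ["W"] * true_wake + ["S"] * 80
        )
        collapsed = collapse_hypnogram(
            make_hypnogram(
                [s if s == "W" else "N2" for s in psg_labels for _ in range(4)]
            ),
            tib_cap_min=None,
        )
        act = list(psg_labels)
        # false wake bursts of exactly 4 epochs, well away from the true bout
        for start in (sl_epochs + 10, sl_epochs + 25, len(act) - 30):
            act[start: start + 4] = ["W"] * 4
        pairs.append((collapsed, act))

    result = optimize_cohort(pairs, param="WASO", n_sl_for_waso=1)

    # independent exhaustive search over the same definition
    from actiscore.validation import icc as icc_fn, paired_ttest

    best = None
    for n in range(1, 11):
        psg_vals, act_vals = [], []
        for collapsed, act in pairs:
            psg_vals.append(psg_parameters(collapsed).waso_min)
            onset = oracle_onset(act, 1)
            act_vals.append(oracle_waso(act, onset, n))
        delta = np.mean(act_vals) - np.mean(psg_vals)
        _, p = paired_ttest(act_vals, psg_vals)
        icc_val, _ = icc_fn(psg_vals, act_vals)
        if p >= 0.05 and icc_val >= 0.6:
            if best is None or abs(delta) < best[1]:
                best = (n, abs(delta))
    assert best is not None
    assert result.chosen_n == best[0]


def test_optimizer_reports_infeasible_search():
    psg = [10.0, 20.0, 30.0]
    act_by_n = {n: [100.0, 200.0, 300.0] for n in range(1, 4)}
    result = optimize_run_rule(psg, act_by_n)
    assert result.chosen_n is None
    assert not result.table["feasible"].any()


def test_optimizer_requires_three_subjects():
    with pytest.raises(ValidationError):
        optimize_run_rule([1.0, 2.0], {1: [1.0, 2.0]})
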
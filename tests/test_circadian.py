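"""Melatonin-onset estimation, phase arithmetic, Grubbs screening and PRC
correction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sstats

from flashsleep.circadian import (
    DLMOError,
    InsufficientBaselineError,
    MelatoninSeries,
    NoOnsetError,
    PhaseResponseCurve,
    PRCDomainError,
    RiseNotCapturedError,
    compute_threshold,
    estimate_dlmo,
    grubbs_test,
    net_shift,
    phase_angle,
    phase_shift,
    prc_correct,
)


def _series(times, conc, n_day=3):
    times = np.asarray(times, dtype=float)
    flags = np.zeros(len(times), dtype=bool)
    flags[:n_day] = True
    return MelatoninSeries(times=times, concentrations=conc, daytime_flags=flags)


# ---------------------------------------------------------------- threshold

@pytest.mark.parametrize("daytime, expected", [
    ([1.0, 2.0, 3.0], 4.0),
    ([1.0, 1.5, 0.5], 2.0),
])
def test_threshold_is_twice_daytime_mean(daytime, expected):
    s = _series([-9, -8.5, -8, -2, -1], daytime + [10.0, 20.0])
    assert compute_threshold(s) == pytest.approx(expected)


def test_zero_daytime_gives_unusable_threshold():
    s = _series([-9, -8.5, -8, -2, -1], [0, 0, 0, 10, 20])
    thr = compute_threshold(s)
    assert thr == 0.0
    with pytest.raises(DLMOError):
        estimate_dlmo(s, thr)


def test_threshold_requires_enough_daytime_samples():
    s = _series([-9, -8.5, -8, -2], [1, 1, 1, 10], n_day=2)
    with pytest.raises(InsufficientBaselineError):
        compute_threshold(s, n_daytime=3)


# ----------------------------------------------------------------- onset

def test_onset_interpolates_between_bracketing_samples():
    # threshold 2.0 crossed between 20:30 (1.8) and 21:00 (3.0):
    # fraction (2.0-1.8)/(3.0-1.8) of 30 min -> 20:35
    s = _series([17, 17.5, 18, 20.0, 20.5, 21.0],
                [0.5, 0.5, 0.5, 1.0, 1.8, 3.0])
    est = estimate_dlmo(s, 2.0)
    assert est.onset_time == pytest.approx(20 + 35 / 60, abs=1e-9)
    assert est.crossing_indices == (4, 5)


def test_sample_exactly_at_threshold_is_the_onset():
    s = _series([17, 17.5, 18, 19, 20], [0.5, 0.5, 0.5, 2.0, 5.0])
    assert estimate_dlmo(s, 2.0).onset_time == pytest.approx(19.0)


def test_flat_series_has_no_onset():
    s = _series([17, 17.5, 18, 19], [0.5, 0.6, 0.5, 0.6])
    with pytest.raises(NoOnsetError):
        estimate_dlmo(s, 2.0)


def test_series_starting_above_threshold_is_rejected():
    s = _series([17, 18, 19], [5.0, 6.0, 7.0])
    with pytest.raises(RiseNotCapturedError):
        estimate_dlmo(s, 2.0)


def test_sustained_rule_skips_single_sample_spike():
    s = _series([17, 17.5, 18, 18.5, 19, 19.5],
                [0.5, 0.5, 0.5, 5.0, 0.5, 0.5])
    with pytest.raises(NoOnsetError):
        estimate_dlmo(s, 2.0)
    # the plain first-crossing rule accepts the spike
    est = estimate_dlmo(s, 2.0, require_sustained=False)
    assert est.crossing_indices == (2, 3)


def _oracle_onset(times, conc, thr, sustained=True):
    """Brute-force scan over all adjacent sample pairs."""
    n = len(conc)
    for i in range(n):
        if conc[i] < thr:
            continue
        if sustained and i + 1 < n and conc[i + 1] < thr:
            continue
        if i == 0:
            return "rise-not-captured"
        frac = (thr - conc[i - 1]) / (conc[i] - conc[i - 1])
        return times[i - 1] + frac * (times[i] - times[i - 1])
    return "no-onset"


def test_onset_matches_bruteforce_scan_on_random_series(rng):
    """Oracle equivalence over 1000 random melatonin-like series."""
    for _ in range(1000):
        n = rng.integers(5, 25)
        times = np.cumsum(rng.uniform(0.2, 1.0, n)) - 9.0
        base = rng.uniform(0.2, 3.0)
        amp = rng.uniform(0.0, 40.0)
        mid = rng.uniform(times[0], times[-1] + 2)
        conc = base + amp / (1 + np.exp(-(times - mid) / 0.5))
        conc *= rng.lognormal(0, 0.3, n)
        thr = 2 * conc[:3].mean()
        s = _series(times, conc)
        expected = _oracle_onset(times, conc, thr)
        if expected == "no-onset":
            with pytest.raises(NoOnsetError):
                estimate_dlmo(s, thr)
        elif expected == "rise-not-captured":
            with pytest.raises(RiseNotCapturedError):
                estimate_dlmo(s, thr)
        else:
            got = estimate_dlmo(s, thr).onset_time
            assert got == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------- phase arithmetic

@pytest.mark.parametrize("base, post, expected", [
    (21.0, 22.5, -1.5),   # delay
    (21.0, 21.0, 0.0),
    (22.0, 21.5, 0.5),    # advance
])
def test_phase_shift_sign_convention(base, post, expected):
    assert phase_shift(base, post) == pytest.approx(expected)


@given(st.floats(-12, 12), st.floats(-12, 12))
def test_phase_shift_antisymmetric(a, b):
    assert phase_shift(a, b) == pytest.approx(-phase_shift(b, a))


@pytest.mark.parametrize("flash, placebo, expected", [
    (-1.3, -0.2, -1.1),
    (-0.7, -0.7, 0.0),
    (-6.4, 0.0, -6.4),    # magnitude of the largest observed responder
])
def test_net_shift_subtracts_control(flash, placebo, expected):
    assert net_shift(flash, placebo) == pytest.approx(expected)


@pytest.mark.parametrize("dlmo, stim, expected", [
    (21.0, 24.0, 3.0),
    (22.0, 22.0, 0.0),
    (23.0, 22.0, -1.0),   # stimulus before DLMO: allowed, negative
])
def test_phase_angle(dlmo, stim, expected):
    assert phase_angle(dlmo, stim) == pytest.approx(expected)


# ----------------------------------------------------------------- Grubbs

def test_grubbs_flags_known_outlier():
    r = grubbs_test([2, 3, 3, 4, 10], alpha=0.05)
    assert r.statistic == pytest.approx(1.7449, abs=1e-4)
    assert r.critical_value == pytest.approx(1.7150, abs=1e-4)
    assert r.outlier_index == 4 and r.is_outlier


def test_grubbs_small_symmetric_sample_has_no_outlier():
    r = grubbs_test([1.0, 2.0, 3.0], alpha=0.05)
    assert not r.is_outlier


@pytest.mark.parametrize("bad", [[5.0, 5.0, 5.0], [1.0, 2.0]])
def test_grubbs_rejects_degenerate_input(bad):
    with pytest.raises(ValueError):
        grubbs_test(bad)


def _grubbs_oracle(x, alpha):
    x = np.asarray(x, float)
    n = len(x)
    g = max(abs(v - x.mean()) for v in x) / x.std(ddof=1)
    t = sstats.t.ppf(1 - alpha / (2 * n), n - 2)
    crit = (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))
    return g, crit, g > crit


@pytest.mark.parametrize("alpha", [0.01, 0.05])
def test_grubbs_matches_bruteforce_formula(alpha, rng):
    for n in range(3, 31):
        x = rng.normal(0, 1, n)
        if rng.random() < 0.5:
            x[rng.integers(n)] += rng.uniform(2, 6)
        r = grubbs_test(x, alpha=alpha)
        g, crit, flagged = _grubbs_oracle(x, alpha)
        assert r.statistic == pytest.approx(g, rel=1e-12)
        assert r.critical_value == pytest.approx(crit, rel=1e-12)
        assert r.is_outlier == flagged


# ------------------------------------------------------------------ PRC

def _linear_prc():
    # toy linear PRC P(psi) = -0.5 - 0.2 (psi - 2) on [1, 5]
    psi = np.array([1.0, 5.0])
    return PhaseResponseCurve(phases=psi, shifts=-0.5 - 0.2 * (psi - 2))


def test_prc_correction_identity_at_mean_phase():
    prc = _linear_prc()
    assert prc_correct(-1.0, 3.0, 3.0, prc) == pytest.approx(-1.0)


def test_prc_correction_rescales_by_prc_ratio():
    prc = _linear_prc()
    # P(2) = -0.5, P(3) = -0.7 -> corrected = -1.0 * (-0.7 / -0.5) = -1.4
    assert prc_correct(-1.0, 2.0, 3.0, prc) == pytest.approx(-1.4)


@given(st.floats(-5, 5), st.floats(1.2, 4.8), st.floats(1.2, 4.8),
       st.floats(0.1, 10))
def test_prc_correction_scale_equivariant(shift, psi_i, psi_mean, c):
    prc = _linear_prc()
    one = prc_correct(shift, psi_i, psi_mean, prc)
    scaled = prc_correct(c * shift, psi_i, psi_mean, prc)
    assert scaled == pytest.approx(c * one, rel=1e-9, abs=1e-9)
    assert prc_correct(0.0, psi_i, psi_mean, prc) == 0.0


def test_prc_refuses_out_of_domain_queries():
    prc = _linear_prc()
    with pytest.raises(PRCDomainError):
        prc_correct(-1.0, 0.5, 3.0, prc)
    with pytest.raises(PRCDomainError):
        prc(6.0)


def test_prc_zero_prediction_is_an_error():
    psi = np.array([0.0, 4.0])
    prc = PhaseResponseCurve(phases=psi, shifts=np.array([0.0, -2.0]))
    with pytest.raises(ZeroDivisionError):
        prc_correct(-1.0, 0.0, 2.0, prc)


def test_series_validation():
    with pytest.raises(ValueError):
        MelatoninSeries(times=[1.0, 1.0], concentrations=[1, 2],
                        daytime_flags=[True, True])
    with pytest.raises(ValueError):
        MelatoninSeries(times=[1.0, 2.0], concentrations=[1, -2],
                        daytime_flags=[True, True])
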
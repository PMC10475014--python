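"""Ground-truth fidelity and seeded determinism of the study generator."""

import numpy as np
import pytest

from flashsleep.architecture import STAGES
from flashsleep.circadian import (NoOnsetError, compute_threshold,
                                  estimate_dlmo)
from flashsleep.synthetic import (
    SimConfig,
    gen_cohort,
    gen_eeg,
    gen_hypnogram,
    gen_melatonin_profile,
    gen_stage_probabilities,
    toy_prc,
)


# -------------------------------------------------------------- melatonin

def test_noise_free_profile_recovers_analytic_crossing():
    cfg = SimConfig(noise_cv=0.0, baseline_daytime_level=1.0,
                    onset_amplitude=10.0, true_dlmo=-2.0)
    series, truth = gen_melatonin_profile(cfg)
    est = estimate_dlmo(series, compute_threshold(series))
    assert truth["warning"] is None
    assert abs(est.onset_time - truth["true_onset_h"]) * 60 <= 5.0


def test_same_seed_bitwise_identical_series():
    cfg = SimConfig(seed=42)
    a, _ = gen_melatonin_profile(cfg, participant=3, visit=1)
    b, _ = gen_melatonin_profile(cfg, participant=3, visit=1)
    assert np.array_equal(a.concentrations, b.concentrations)
    c, _ = gen_melatonin_profile(cfg, participant=3, visit=2)
    assert not np.array_equal(a.concentrations, c.concentrations)


def test_flat_profile_never_crosses_threshold():
    cfg = SimConfig(noise_cv=0.0, onset_amplitude=0.0)
    series, truth = gen_melatonin_profile(cfg)
    assert truth["warning"] is not None
    with pytest.raises(NoOnsetError):
        estimate_dlmo(series, compute_threshold(series))


def test_melatonin_stays_in_assay_range():
    series, _ = gen_melatonin_profile(SimConfig(seed=5))
    assert np.all(series.concentrations > 0)
    assert series.concentrations.max() < 60  # near the 50 pg/mL assay ceiling


# ----------------------------------------------------------------- cohort

def test_default_cohort_matches_study_design():
    cfg = SimConfig(seed=0)
    coh = gen_cohort(cfg, include_sleep=False)
    assert len(coh.participants) == 10          # cohort size under study
    for part in coh.participants:
        conds = sorted(v.condition for v in part.visits.values())
        assert conds == ["flash", "placebo"]
        dt = np.diff(part.visits[1].mel_baseline.times)
        assert np.allclose(dt, 0.5)             # 30-min saliva sampling


def test_true_shift_sample_mean_near_population_mean():
    cfg = SimConfig(seed=0, n_participants=200)
    coh = gen_cohort(cfg, include_sleep=False)
    shifts = [p["true_net_shift_h"]
              for p in coh.ground_truth["participants"].values()]
    assert abs(np.mean(shifts) - (-1.13)) <= 0.25   # CLT bound at n=200


def test_degenerate_cohort_is_deterministic():
    cfg = SimConfig(seed=0, n_participants=4, true_shift_sd=0.0,
                    drift_sd=0.0, noise_cv=0.0)
    coh = gen_cohort(cfg, include_sleep=False)
    gt = coh.ground_truth["participants"]
    flash_shifts = {
        v["true_delta_phi_h"]
        for p in gt.values() for v in p["visits"].values()
        if v["condition"] == "flash"
    }
    assert len(flash_shifts) == 1  # all participants share one true shift


def test_cohort_needs_two_participants():
    with pytest.raises(ValueError):
        gen_cohort(SimConfig(n_participants=1))


# -------------------------------------------------------------- hypnogram

def test_hour_hypnogram_has_240_epochs():
    h = gen_hypnogram(SimConfig(), 1.0, seed=(0, 1))
    assert h.n_epochs == 240


def test_identity_matrix_freezes_the_chain():
    cfg = SimConfig(hypnogram_transition_matrix=np.eye(5))
    h = gen_hypnogram(cfg, 0.5, seed=(0, 1), start_stage="N2")
    assert set(h.stages) == {"N2"}


def test_empirical_transition_rates_within_binomial_bounds():
    cfg = SimConfig(seed=3)
    h = gen_hypnogram(cfg, 10_000 * 15 / 3600.0, seed=(3, 0))
    m = cfg.hypnogram_transition_matrix
    a, b = h.stages[:-1], h.stages[1:]
    for i, si in enumerate(STAGES):
        n_i = np.count_nonzero(a == si)
        if n_i < 50:
            continue
        for j, sj in enumerate(STAGES):
            k = np.count_nonzero((a == si) & (b == sj))
            p = m[i, j]
            assert abs(k - n_i * p) <= 3 * np.sqrt(n_i * p * (1 - p)) + 1e-9


def test_bad_transition_matrix_rejected():
    m = np.eye(5)
    m[0, 0] = 0.5
    with pytest.raises(ValueError):
        SimConfig(hypnogram_transition_matrix=m)


# ------------------------------------------------------------ probabilities

def test_identity_confusion_gives_one_hot():
    h = gen_hypnogram(SimConfig(), 0.5, seed=(0, 1))
    p = gen_stage_probabilities(h, np.eye(5), seed=(0, 2))
    idx = np.array([STAGES.index(s) for s in h.stages])
    assert np.allclose(p.probs[np.arange(len(idx)), idx], 1.0)


def test_probability_vectors_sum_to_one():
    cfg = SimConfig()
    h = gen_hypnogram(cfg, 2.0, seed=(1, 1))
    p = gen_stage_probabilities(h, cfg.scorer_confusion, seed=(1, 2))
    assert np.allclose(p.probs.sum(axis=1), 1.0, atol=1e-9)


def test_mean_scored_stage_probability_tracks_confusion_diagonal():
    from flashsleep.architecture import Hypnogram

    cfg = SimConfig()
    # scorer spread 0.89/0.04/0.02/0.00/0.05 on wake: the mean scored-stage
    # probability over many W epochs approaches the diagonal value
    h = Hypnogram(stages=np.array(["W"] * 2000))
    p = gen_stage_probabilities(h, cfg.scorer_confusion, seed=(2, 2))
    assert np.mean(p.probs[:, 0]) == pytest.approx(0.89, abs=0.02)
    assert np.all(p.probs[:, 3] == 0.0)  # zero confusion mass stays zero


def test_negative_confusion_rejected():
    h = gen_hypnogram(SimConfig(), 0.25, seed=(0, 1))
    c = np.eye(5)
    c[0, 0], c[0, 1] = 1.5, -0.5
    with pytest.raises(ValueError):
        gen_stage_probabilities(h, c, seed=(0, 2))


# -------------------------------------------------------------------- EEG

def test_eeg_seeded_determinism():
    cfg = SimConfig()
    h = gen_hypnogram(cfg, 0.5, seed=(0, 1))
    a = gen_eeg(h, cfg, seed=(9, 9))
    b = gen_eeg(h, cfg, seed=(9, 9))
    assert np.array_equal(a[0].samples, b[0].samples)
    assert not np.array_equal(a[0].samples, a[1].samples)  # channels differ


def test_zero_weights_give_zero_signal():
    cfg = SimConfig(stage_band_weights={
        s: {b: 0.0 for b in ("delta", "theta", "alpha", "sigma", "beta")}
        for s in STAGES})
    h = gen_hypnogram(cfg, 0.25, seed=(0, 1))
    sigs = gen_eeg(h, cfg, seed=(0, 2))
    assert np.all(sigs[0].samples == 0.0)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(sampling_interval=0)
    with pytest.raises(ValueError):
        SimConfig(noise_cv=-0.1)
    with pytest.raises(ValueError):
        SimConfig(eeg_fs=50.0)


def test_toy_prc_is_delay_only_and_bounded():
    prc = toy_prc()
    assert prc.phases[0] == 0.0 and prc.phases[-1] == 12.0
    values = [prc(x) for x in np.linspace(0, 12, 49)]
    assert all(v < 0 for v in values)
    assert min(values) == pytest.approx(-1.5, abs=1e-6)
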
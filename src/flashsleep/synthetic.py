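"""Synthetic paired-visit study generator.

Emulates the data a two-visit, within-subject flash-therapy study produces —
salivary melatonin profiles around each night, scored hypnograms with
per-epoch stage probabilities, and stage-dependent band-limited EEG — with
full ground truth, so every downstream analysis stage can be tested without
any recorded data.

The model, briefly:

* melatonin follows a near square-wave: a flat daytime baseline plus a
  logistic-sigmoid evening rise, multiplied by lognormal assay noise with a
  configured coefficient of variation;
* each participant's flash visit carries a true flash-induced shift drawn
  from Normal(true_shift_mean, true_shift_sd); both visits additionally carry
  a small protocol drift (circadian period != 24 h), which is what the
  control-subtraction in the analysis removes;
* hypnograms are first-order Markov chains over {W, N1, N2, N3, REM} at 15-s
  epochs, with defaults that keep early-night sleep dominated by N2/N3;
* stage probabilities are Dirichlet draws centred on a scorer confusion row
  for the epoch's true stage (one-hot under an identity confusion);
* EEG is the sum over the five sleep bands of band-pass-filtered Gaussian
  noise, scaled per epoch by stage-specific band weights (no physiological
  waveform modelling — no spindles or K-complexes).

Everything is deterministic given (config, seed): all randomness flows from
`numpy` SeedSequences derived from the config seed and the participant /
visit / quantity being generated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .architecture import Hypnogram, STAGES, StageProbabilities
from .circadian import MelatoninSeries, PhaseResponseCurve
from .spectral import PsgSignal

# stream tags for per-quantity random generators
_S_MEL, _S_HYP, _S_PROB, _S_EEG, _S_COHORT = range(5)


def _default_transition_matrix() -> np.ndarray:
    """Per-15-s-epoch stage transition probabilities (rows: from-stage in
    STAGES order).  High self-transition keeps bouts realistically long;
    N2/N3 dominate, as in the early night when the stimulus is delivered."""
    return np.array([
        # W      N1     N2     N3     REM
        [0.950, 0.040, 0.010, 0.000, 0.000],  # W
        [0.020, 0.900, 0.080, 0.000, 0.000],  # N1
        [0.005, 0.010, 0.955, 0.025, 0.005],  # N2
        [0.002, 0.003, 0.030, 0.960, 0.005],  # N3
        [0.010, 0.020, 0.020, 0.000, 0.950],  # REM
    ])


def _default_stage_band_weights() -> dict[str, dict[str, float]]:
    """Per-stage RMS amplitude (uV) of each band-limited noise component.
    Chosen so N3 is strongly delta-dominant, N2 carries sigma (spindle-band)
    power, and wake carries relatively more alpha/beta."""
    return {
        "W":   {"delta": 1.0, "theta": 1.0, "alpha": 3.0, "sigma": 0.5, "beta": 2.0},
        "N1":  {"delta": 2.0, "theta": 3.0, "alpha": 1.5, "sigma": 0.5, "beta": 1.0},
        "N2":  {"delta": 4.0, "theta": 2.0, "alpha": 1.0, "sigma": 2.0, "beta": 0.5},
        "N3":  {"delta": 10.0, "theta": 2.0, "alpha": 0.5, "sigma": 1.0, "beta": 0.3},
        "REM": {"delta": 2.0, "theta": 3.0, "alpha": 1.0, "sigma": 0.5, "beta": 1.0},
    }


def _default_scorer_confusion() -> np.ndarray:
    """Automatic-scorer confusion: row = true stage, columns = probability
    mass the scorer places on each stage.  The W row follows the canonical
    worked example of probability scoring (0.89/0.04/0.02/0.00/0.05)."""
    return np.array([
        [0.89, 0.04, 0.02, 0.00, 0.05],  # W
        [0.05, 0.80, 0.10, 0.00, 0.05],  # N1
        [0.01, 0.05, 0.85, 0.07, 0.02],  # N2
        [0.00, 0.01, 0.10, 0.89, 0.00],  # N3
        [0.03, 0.05, 0.04, 0.00, 0.88],  # REM
    ])


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the design under study: 10 participants, two visits,
    saliva every 30 min, assay-level noise (intra-assay CV 5.4%), a true
    flash-induced delay of 1.13 h with between-participant SD 1.27 h, a small
    placebo drift (12 +/- 20 min delay), stimulus from 0.5 h to 1.5 h after
    habitual sleep onset (HSOn), 8 h of sleep at 15-s epochs, and two central
    EEG channels at 100 Hz.

    Melatonin levels sit inside the assay's reportable range (0.78-50 pg/mL):
    daytime baseline 2 pg/mL, nocturnal amplitude 40 pg/mL.  ``true_dlmo`` is
    the sigmoid *midpoint* in hours relative to HSOn; with the default rise
    duration the noise-free threshold crossing lands ~1.5 h earlier, i.e.
    ~2.5 h before HSOn, so the phase angle of a stimulus at +0.5 h is ~3 h.
    """

    seed: int = 0
    n_participants: int = 10
    baseline_daytime_level: float = 2.0     # pg/mL
    onset_amplitude: float = 40.0           # pg/mL
    true_dlmo: float = -1.0                 # h relative to HSOn (sigmoid midpoint)
    dlmo_sd: float = 1.0                    # between-participant SD, h
    rise_duration: float = 0.5              # sigmoid time constant, h
    sampling_interval: float = 30.0         # minutes
    noise_cv: float = 0.054                 # assay coefficient of variation
    true_shift_mean: float = -1.13          # h; negative = delay
    true_shift_sd: float = 1.27             # h
    drift_mean: float = -0.2                # h; placebo-visit drift (delay)
    drift_sd: float = 20.0 / 60.0           # h
    hypnogram_transition_matrix: np.ndarray = field(
        default_factory=_default_transition_matrix)
    stage_band_weights: dict[str, dict[str, float]] = field(
        default_factory=_default_stage_band_weights)
    scorer_confusion: np.ndarray = field(default_factory=_default_scorer_confusion)
    prob_concentration: float = 50.0        # Dirichlet concentration
    eeg_fs: float = 100.0                   # Hz
    eeg_channels: tuple[str, ...] = ("C3", "C4")
    sleep_duration: float = 8.0             # h (HSOff - HSOn)
    epoch_length: float = 15.0              # s
    baseline_window: tuple[float, float] = (-9.0, 0.0)   # saliva sampling, h
    post_window: tuple[float, float] = (-9.0, 4.0)       # h, second night axis
    daytime_cutoff: float = -6.5            # samples at/before this are "daytime"

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        m = np.asarray(self.hypnogram_transition_matrix, dtype=float)
        if m.shape != (len(STAGES), len(STAGES)):
            raise ValueError("transition matrix must be 5x5 over W,N1,N2,N3,REM")
        if np.any(m < 0):
            raise ValueError("transition probabilities must be nonnegative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each transition-matrix row must sum to 1")
        self.hypnogram_transition_matrix = m
        c = np.asarray(self.scorer_confusion, dtype=float)
        if np.any(c < 0):
            raise ValueError("confusion entries must be nonnegative")
        if not np.allclose(c.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each confusion row must sum to 1")
        self.scorer_confusion = c
        for stage, w in self.stage_band_weights.items():
            if any(v < 0 for v in w.values()):
                raise ValueError(f"negative band weight for stage {stage}")
        if self.eeg_fs < 100.0:
            raise ValueError("eeg_fs must be >= 100 Hz")


def _rng(config_seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config_seed), *map(int, keys)]))


def melatonin_times(config: SimConfig, day: str) -> np.ndarray:
    """Saliva sampling schedule (hours relative to that night's HSOn)."""
    lo, hi = config.baseline_window if day == "baseline" else config.post_window
    step = config.sampling_interval / 60.0
    return np.arange(lo, hi + 1e-9, step)


def melatonin_model(
    t: np.ndarray, config: SimConfig, true_dlmo: Optional[float] = None
) -> np.ndarray:
    """Noise-free melatonin profile: baseline + amplitude * sigmoid."""
    t0 = config.true_dlmo if true_dlmo is None else true_dlmo
    z = (np.asarray(t, dtype=float) - t0) / config.rise_duration
    return config.baseline_daytime_level + config.onset_amplitude / (1.0 + np.exp(-z))


def analytic_threshold_crossing(
    config: SimConfig, true_dlmo: float, threshold: float
) -> Optional[float]:
    """Exact time the noise-free profile crosses ``threshold``, or None if
    the sigmoid never reaches it."""
    q = (threshold - config.baseline_daytime_level) / config.onset_amplitude \
        if config.onset_amplitude > 0 else -1.0
    if not 0.0 < q < 1.0:
        return None
    return float(true_dlmo + config.rise_duration * np.log(q / (1.0 - q)))


def gen_melatonin_profile(
    config: SimConfig,
    participant: int = 0,
    visit: int = 0,
    day: str = "baseline",
    true_dlmo: Optional[float] = None,
) -> tuple[MelatoninSeries, dict]:
    """One participant-day melatonin series plus its ground truth.

    The ground truth carries the sigmoid midpoint, the noise-free threshold
    (twice the mean of the first three daytime samples of the noiseless
    profile) and its analytic crossing time, plus a ``warning`` string when
    the sampling window does not bracket that crossing.
    """
    if day not in ("baseline", "post"):
        raise ValueError("day must be 'baseline' or 'post'")
    t0 = config.true_dlmo if true_dlmo is None else float(true_dlmo)
    t = melatonin_times(config, day)
    clean = melatonin_model(t, config, t0)
    daytime = t <= config.daytime_cutoff + 1e-9
    if daytime.sum() < 3:
        raise ValueError("sampling schedule has fewer than 3 daytime points")
    rng = _rng(config.seed, _S_MEL, participant, visit, 0 if day == "baseline" else 1)
    if config.noise_cv > 0:
        sigma2 = np.log(1.0 + config.noise_cv ** 2)
        noise = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=len(t)))
        conc = clean * noise
    else:
        conc = clean.copy()
    series = MelatoninSeries(
        times=t, concentrations=conc, daytime_flags=daytime,
        participant=f"p{participant:02d}", label=f"v{visit}-{day}",
    )
    thr_true = 2.0 * float(np.mean(clean[daytime][:3]))
    crossing = analytic_threshold_crossing(config, t0, thr_true)
    warning = None
    if crossing is None:
        warning = "profile never reaches the doubled-baseline threshold"
    elif not t[0] < crossing < t[-1]:
        warning = "sampling window does not cover the true onset"
    truth = {
        "sigmoid_midpoint_h": t0,
        "true_threshold_pg_ml": thr_true,
        "true_onset_h": crossing,
        "warning": warning,
    }
    return series, truth


@dataclass
class VisitData:
    """Everything generated for one participant-visit (one lab stay)."""

    condition: str                      # "placebo" | "flash"
    mel_baseline: MelatoninSeries
    mel_post: MelatoninSeries
    hypnogram: Optional[Hypnogram] = None
    probabilities: Optional[StageProbabilities] = None
    signals: Optional[list[PsgSignal]] = None


@dataclass
class ParticipantData:
    pid: str
    visits: dict[int, VisitData]


@dataclass
class Cohort:
    config: SimConfig
    participants: list[ParticipantData]
    ground_truth: dict


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n_sd: float = 2.5) -> float:
    """Normal draw rejected outside mean +/- n_sd * sd (keeps simulated
    onsets inside the saliva sampling windows)."""
    if sd == 0:
        return mean
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= n_sd * sd:
            return float(x)


def gen_cohort(
    config: SimConfig,
    include_sleep: bool = True,
    include_eeg: bool = True,
) -> Cohort:
    """Generate the full paired-visit cohort with ground truth.

    Each participant receives one placebo and one flash visit in randomized
    order.  The flash visit's true phase change is flash effect + drift; the
    placebo visit's is drift alone; the true *net* shift (what the
    control-subtracted analysis estimates) is the flash effect.
    """
    if config.n_participants < 2:
        raise ValueError("a paired cohort needs n_participants >= 2")
    participants: list[ParticipantData] = []
    truth: dict = {"participants": {}}
    for p in range(config.n_participants):
        pid = f"p{p:02d}"
        rng = _rng(config.seed, _S_COHORT, p)
        t0 = _truncated_normal(rng, config.true_dlmo, config.dlmo_sd)
        flash_effect = rng.normal(config.true_shift_mean, config.true_shift_sd)
        order = ["placebo", "flash"] if rng.random() < 0.5 else ["flash", "placebo"]
        visits: dict[int, VisitData] = {}
        ptruth: dict = {
            "sigmoid_midpoint_h": t0,
            "true_net_shift_h": flash_effect,
            "visits": {},
        }
        for v, condition in enumerate(order, start=1):
            drift = rng.normal(config.drift_mean, config.drift_sd)
            delta_phi = flash_effect + drift if condition == "flash" else drift
            mel_base, tb = gen_melatonin_profile(config, p, v, "baseline", t0)
            mel_post, tp = gen_melatonin_profile(config, p, v, "post",
                                                 t0 - delta_phi)
            hyp = probs = sigs = None
            if include_sleep:
                hyp = gen_hypnogram(config, config.sleep_duration,
                                    seed=(config.seed, _S_HYP, p, v))
                probs = gen_stage_probabilities(
                    hyp, config.scorer_confusion,
                    seed=(config.seed, _S_PROB, p, v),
                    concentration=config.prob_concentration)
                if include_eeg:
                    sigs = gen_eeg(hyp, config, seed=(config.seed, _S_EEG, p, v))
            visits[v] = VisitData(condition=condition, mel_baseline=mel_base,
                                  mel_post=mel_post, hypnogram=hyp,
                                  probabilities=probs, signals=sigs)
            ptruth["visits"][v] = {
                "condition": condition,
                "true_delta_phi_h": delta_phi,
                "true_dlmo_baseline_h": tb["true_onset_h"],
                "true_dlmo_post_h": tp["true_onset_h"],
                "warnings": [w for w in (tb["warning"], tp["warning"]) if w],
            }
        participants.append(ParticipantData(pid=pid, visits=visits))
        truth["participants"][pid] = ptruth
    return Cohort(config=config, participants=participants, ground_truth=truth)


def gen_hypnogram(
    config: SimConfig,
    duration: float,
    seed,
    start_stage: str = "N1",
) -> Hypnogram:
    """First-order Markov hypnogram of ``duration`` hours at 15-s epochs.

    Epoch count is floor(duration * 3600 / epoch_length); the chain starts
    from ``start_stage`` (N1 by default — the recording begins at sleep
    onset).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(*np.atleast_1d(seed))
    m = config.hypnogram_transition_matrix
    cum = np.cumsum(m, axis=1)
    n = int(duration * 3600.0 / config.epoch_length)
    if n < 1:
        raise ValueError("duration shorter than one epoch")
    state = STAGES.index(start_stage)
    draws = rng.random(n - 1)
    out = np.empty(n, dtype=np.int64)
    out[0] = state
    for i in range(1, n):
        state = int(np.searchsorted(cum[state], draws[i - 1], side="right"))
        state = min(state, len(STAGES) - 1)  # guard float roundoff at 1.0
        out[i] = state
    return Hypnogram(stages=np.array(STAGES)[out], start_time=0.0,
                     epoch_length=config.epoch_length)


def gen_stage_probabilities(
    hypnogram: Hypnogram,
    confusion: np.ndarray,
    seed,
    concentration: float = 50.0,
) -> StageProbabilities:
    """Per-epoch scorer probability vectors.

    Each epoch's vector is a Dirichlet draw with parameters
    ``concentration * confusion[scored stage]``: its mean is exactly the
    confusion row, rows always sum to 1, entries with zero confusion mass
    stay exactly zero, and an identity confusion yields one-hot vectors.
    """
    c = np.asarray(confusion, dtype=float)
    if np.any(c < 0):
        raise ValueError("confusion entries must be nonnegative")
    if not np.allclose(c.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("confusion rows must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(*np.atleast_1d(seed))
    stage_idx = np.array([STAGES.index(s) for s in hypnogram.stages])
    alpha = concentration * c[stage_idx]
    # gamma(0) == 0, so zero-confusion entries remain exactly zero
    g = rng.gamma(np.maximum(alpha, 0.0))
    probs = g / g.sum(axis=1, keepdims=True)
    return StageProbabilities(probs=probs)


def gen_eeg(
    hypnogram: Hypnogram,
    config: SimConfig,
    seed,
    channels: Optional[tuple[str, ...]] = None,
) -> list[PsgSignal]:
    """Stage-weighted band-limited noise EEG, one signal per channel.

    For each band, unit-RMS band-pass-filtered Gaussian noise spans the whole
    recording and is scaled per epoch by the stage's band weight (in uV), so
    each epoch's per-band RMS amplitude is the configured weight.  Channels
    receive independent noise.
    """
    from .spectral import BANDS  # local import; canonical band edges

    channels = channels or config.eeg_channels
    fs = config.eeg_fs
    spe = int(round(hypnogram.epoch_length * fs))
    n = hypnogram.n_epochs * spe
    rng = seed if isinstance(seed, np.random.Generator) else _rng(*np.atleast_1d(seed))
    weights = config.stage_band_weights
    out: list[PsgSignal] = []
    for ch in channels:
        acc = np.zeros(n)
        for band, (lo, hi) in BANDS.items():
            w_epoch = np.array([weights.get(s, {}).get(band, 0.0)
                                for s in hypnogram.stages])
            noise = rng.standard_normal(n)
            if np.all(w_epoch == 0):
                continue
            sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
            filt = sps.sosfiltfilt(sos, noise)
            filt = filt / filt.std()
            acc += filt * np.repeat(w_epoch, spe)
        out.append(PsgSignal(channel=ch, fs=fs, samples=acc,
                             start_time=hypnogram.start_time))
    return out


def toy_prc(n_points: int = 25) -> PhaseResponseCurve:
    """SYNTHETIC phase response curve for simulation and tests only.

    A smooth delay-only curve over phase angles 0-12 h after DLMO, peaking
    (most negative, -1.5 h) 6 h after onset:  P(psi) = -0.6 - 0.9 sin(pi
    psi / 12).  It is *not* a published human PRC and carries no
    physiological authority; real analyses must supply their own table.
    """
    psi = np.linspace(0.0, 12.0, n_points)
    shift = -0.6 - 0.9 * np.sin(np.pi * psi / 12.0)
    return PhaseResponseCurve(phases=psi, shifts=shift)
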
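"""Circadian phase estimation from salivary melatonin.

The circadian phase marker used throughout is the dim-light melatonin onset
(DLMO): the time at which salivary melatonin rises above a participant-specific
threshold, here twice the mean of the first daytime samples.  Phase shifts are
differences between DLMOs estimated on consecutive evenings; the sign
convention is that a *delay* (melatonin onset moving later) gives a negative
shift.  The phase angle of stimulation (psi) is the interval from DLMO to the
onset of the light stimulus, and is used to rescale observed shifts through a
user-supplied phase response curve (PRC).

All times are continuous hours on a common axis (hours relative to habitual
sleep onset, HSOn); no midnight-wrap arithmetic happens in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


class DLMOError(ValueError):
    """Base class for melatonin-onset estimation failures."""


class InsufficientBaselineError(DLMOError):
    """Fewer daytime samples than required for the threshold."""


class NoOnsetError(DLMOError):
    """The series never exceeds the threshold."""


class RiseNotCapturedError(DLMOError):
    """The series starts at or above the threshold: the rise was missed."""


@dataclass
class MelatoninSeries:
    """Timestamped salivary melatonin concentrations for one participant-day.

    Parameters
    ----------
    times : array of float
        Sample times in hours relative to the night's habitual sleep onset;
        strictly increasing.
    concentrations : array of float
        Salivary melatonin in pg/mL; nonnegative.
    daytime_flags : array of bool
        True for samples taken during the day, well before the melatonin
        rise; the first three flagged samples define the DLMO threshold.
    """

    times: np.ndarray
    concentrations: np.ndarray
    daytime_flags: np.ndarray
    participant: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.daytime_flags = np.asarray(self.daytime_flags, dtype=bool)
        if self.times.ndim != 1 or len(self.times) != len(self.concentrations):
            raise ValueError("times and concentrations must be 1-D and equal length")
        if len(self.daytime_flags) != len(self.times):
            raise ValueError("daytime_flags length mismatch")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class DLMOEstimate:
    """A melatonin-onset estimate with its threshold and bracketing samples."""

    threshold: float
    onset_time: float
    crossing_indices: tuple[int, int]


def compute_threshold(
    series: MelatoninSeries, n_daytime: int = 3, multiplier: float = 2.0
) -> float:
    """Participant-specific DLMO threshold: ``multiplier`` (conventionally 2)
    times the mean of the first ``n_daytime`` daytime concentrations.

    Raises
    ------
    InsufficientBaselineError
        If fewer than ``n_daytime`` samples are flagged as daytime.
    """
    idx = np.flatnonzero(series.daytime_flags)
    if len(idx) < n_daytime:
        raise InsufficientBaselineError(
            f"insufficient daytime baseline: need {n_daytime} daytime samples, "
            f"have {len(idx)}"
        )
    return multiplier * float(np.mean(series.concentrations[idx[:n_daytime]]))


def estimate_dlmo(
    series: MelatoninSeries,
    threshold: float,
    require_sustained: bool = True,
) -> DLMOEstimate:
    """Estimate DLMO as the linearly interpolated crossing of ``threshold``.

    The onset is placed between the last sample below the threshold and the
    first sample of the first exceedance.  With ``require_sustained`` (the
    default) an exceedance only counts if the following sample, when present,
    is also at or above the threshold — guarding against single-sample assay
    spikes; set it False for a plain first-crossing rule.

    Raises
    ------
    NoOnsetError / RiseNotCapturedError / DLMOError
    """
    if not threshold > 0:
        raise DLMOError("threshold must be positive")
    c = series.concentrations
    t = series.times
    n = len(c)
    if n < 2:
        raise DLMOError("need at least two samples")
    for i in range(n):
        if c[i] >= threshold:
            if require_sustained and i + 1 < n and c[i + 1] < threshold:
                continue
            if i == 0:
                raise RiseNotCapturedError(
                    "rise not captured: first sample already at/above threshold"
                )
            frac = (threshold - c[i - 1]) / (c[i] - c[i - 1])
            onset = t[i - 1] + frac * (t[i] - t[i - 1])
            return DLMOEstimate(
                threshold=threshold,
                onset_time=float(onset),
                crossing_indices=(i - 1, i),
            )
    raise NoOnsetError("no onset detected: series never exceeds threshold")


def phase_shift(dlmo_baseline: float, dlmo_post: float) -> float:
    """Circadian phase shift: baseline DLMO minus post-stimulus DLMO.

    A delay (onset moving later) yields a negative value.
    """
    return float(dlmo_baseline) - float(dlmo_post)


def net_shift(delta_phi_flash: float, delta_phi_placebo: float) -> float:
    """Control-subtracted shift: the placebo-visit change (protocol drift)
    removed from the flash-visit change, both from the same participant."""
    return float(delta_phi_flash) - float(delta_phi_placebo)


def phase_angle(dlmo_baseline: float, stimulus_onset: float) -> float:
    """Phase angle of stimulation: stimulus onset minus baseline DLMO.

    Positive when the stimulus follows melatonin onset (the usual case);
    negative values are allowed but indicate the stimulus preceded DLMO.
    """
    return float(stimulus_onset) - float(dlmo_baseline)


@dataclass
class GrubbsResult:
    statistic: float
    critical_value: float
    outlier_index: Optional[int]
    alpha: float
    n: int

    @property
    def is_outlier(self) -> bool:
        return self.outlier_index is not None


def grubbs_test(values: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test.

    The statistic is G = max|x_i - mean| / s (sample SD, n-1 denominator);
    the critical value is ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the
    upper alpha/(2n) quantile of Student's t on n-2 degrees of freedom.  The
    most deviant point is flagged iff G exceeds the critical value.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("Grubbs test undefined for zero-variance sample")
    dev = np.abs(x - x.mean())
    i_max = int(np.argmax(dev))
    g = float(dev[i_max] / s)
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    g_crit = float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))
    return GrubbsResult(
        statistic=g,
        critical_value=g_crit,
        outlier_index=i_max if g > g_crit else None,
        alpha=alpha,
        n=n,
    )


class PRCDomainError(ValueError):
    """Query outside the tabulated phase-response-curve domain."""


@dataclass
class PhaseResponseCurve:
    """Tabulated phase response curve, interpolated piecewise-linearly.

    ``phases`` are hours after DLMO (strictly increasing); ``shifts`` the
    predicted phase shift in hours for a stimulus at that phase.  Queries
    outside the tabulated domain raise; the curve never extrapolates.
    """

    phases: np.ndarray
    shifts: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.phases.ndim != 1 or len(self.phases) != len(self.shifts):
            raise ValueError("phases and shifts must be 1-D and equal length")
        if len(self.phases) < 2:
            raise ValueError("PRC needs at least two points")
        if not np.all(np.diff(self.phases) > 0):
            raise ValueError("PRC phases must be strictly increasing")

    def __call__(self, psi: float) -> float:
        psi = float(psi)
        if psi < self.phases[0] or psi > self.phases[-1]:
            raise PRCDomainError(
                f"phase angle {psi:g} h outside PRC domain "
                f"[{self.phases[0]:g}, {self.phases[-1]:g}] h"
            )
        return float(np.interp(psi, self.phases, self.shifts))


def prc_correct(
    observed_shift: float,
    psi_i: float,
    psi_mean: float,
    prc: PhaseResponseCurve,
) -> float:
    """Rescale an observed shift to the expected magnitude at the cohort-mean
    phase angle: corrected = observed * PRC(psi_mean) / PRC(psi_i).

    Individual deviations of stimulus timing from the cohort-mean phase angle
    change the shift the PRC predicts; dividing out the individual prediction
    and multiplying by the prediction at the mean places all participants on a
    common stimulus phase.  Identity when psi_i equals psi_mean.
    """
    p_i = prc(psi_i)
    if p_i == 0:
        raise ZeroDivisionError(
            f"PRC predicts zero shift at phase angle {psi_i:g} h; "
            "correction undefined"
        )
    return float(observed_shift) * prc(psi_mean) / p_i
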
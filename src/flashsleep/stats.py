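"""Paired-design statistics for the two-visit study report.

Implements the bespoke computations the analysis needs directly: paired
Cohen's d, Bonferroni-corrected significance thresholds, and forward and
reverse power analyses for the two-sided paired t-test via the noncentral t
distribution.  Group inference by mixed-effects models or Bayes factors is
deliberately out of scope; :func:`summarize_cohort` emits tidy per-outcome
summaries ready for such fits in external software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class PairedSample:
    """Per-participant (flash, placebo) outcome pairs."""

    flash: np.ndarray
    placebo: np.ndarray

    def __post_init__(self) -> None:
        self.flash = np.asarray(self.flash, dtype=float)
        self.placebo = np.asarray(self.placebo, dtype=float)
        if self.flash.shape != self.placebo.shape or self.flash.ndim != 1:
            raise ValueError("flash and placebo must be 1-D and paired")

    @property
    def differences(self) -> np.ndarray:
        return self.flash - self.placebo

    def __len__(self) -> int:
        return len(self.flash)


@dataclass
class PowerSpec:
    """Inputs to a paired-t power computation.

    alpha is the two-sided significance level; power the target power;
    sd_diff the standard deviation of paired differences in the outcome's
    units (for minimal-detectable-difference questions); effect_size_d the
    standardized effect (for sample-size questions); n the number of pairs.
    """

    alpha: float = 0.05
    power: float = 0.80
    sd_diff: Optional[float] = None
    effect_size_d: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.sd_diff is not None and self.sd_diff < 0:
            raise ValueError("sd_diff must be nonnegative")


def interpret_d(d: float) -> str:
    """Conventional effect-size bands: small/medium/large at 0.2/0.5/0.8."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def cohens_d_paired(sample: PairedSample) -> float:
    """Paired Cohen's d: mean of the flash-placebo differences divided by
    the sample standard deviation (n-1 denominator) of those differences."""
    if len(sample) < 2:
        raise ValueError("need at least 2 pairs")
    diff = sample.differences
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero difference SD; Cohen's d undefined")
    return float(diff.mean() / sd)


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison threshold family_alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return family_alpha / m


def power_paired_t(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided paired t-test.

    P(|T'| > t_crit) with T' noncentral t on n-1 degrees of freedom and
    noncentrality d*sqrt(n); t_crit is the two-sided alpha critical value.
    scipy's noncentral-t CDF loses accuracy at extreme noncentrality, where
    the true power is 1 to machine precision; that case is clamped.
    """
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    df = n - 1
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    ncp = d * math.sqrt(n)
    dist = stats.nct(df, ncp)
    p = float(dist.sf(t_crit) + dist.cdf(-t_crit))
    if math.isnan(p):
        p = 1.0
    return min(max(p, 0.0), 1.0)


def mdd_paired_t(spec: PowerSpec) -> float:
    """Minimal detectable mean difference (reverse power analysis).

    The smallest |delta|, in the outcome's units, for which a two-sided
    paired t-test with n pairs and difference SD ``sd_diff`` reaches the
    target power at the given alpha — found by root-finding on the
    noncentral-t power function.
    """
    if spec.sd_diff is None or spec.n is None:
        raise ValueError("mdd_paired_t needs sd_diff and n")
    if spec.n < 2:
        raise ValueError("need n >= 2 pairs")
    if spec.sd_diff == 0:
        return 0.0

    def gap(delta: float) -> float:
        return power_paired_t(spec.n, delta / spec.sd_diff, spec.alpha) - spec.power

    hi = spec.sd_diff
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6 * spec.sd_diff:
            raise ValueError("infeasible power specification")
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-10))


def n_required_paired_t(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest number of pairs reaching the target power for a standardized
    effect ``effect_size_d`` (forward power analysis)."""
    if spec.effect_size_d is None or spec.effect_size_d <= 0:
        raise ValueError("n_required_paired_t needs effect_size_d > 0")
    n = 2
    while n <= n_max:
        if power_paired_t(n, spec.effect_size_d, spec.alpha) >= spec.power:
            return n
        n += 1
    raise ValueError("no n below n_max reaches the target power")


def _mean_sd(values: np.ndarray) -> tuple[Optional[float], Optional[float]]:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return None, None
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size >= 2 else None
    return mean, sd


def _paired_block(pivot: pd.DataFrame) -> dict:
    """Condition summaries + paired d for one outcome's flash/placebo table."""
    out: dict = {}
    for cond in ("placebo", "flash"):
        if cond in pivot:
            m, s = _mean_sd(pivot[cond].to_numpy())
            out[cond] = {"mean": m, "sd": s}
    complete = pivot.dropna() if {"flash", "placebo"} <= set(pivot.columns) else None
    if complete is not None and len(complete) >= 2:
        try:
            d = cohens_d_paired(PairedSample(complete["flash"].to_numpy(),
                                             complete["placebo"].to_numpy()))
            out["cohens_d"] = {"d": d, "interpretation": interpret_d(d)}
        except ValueError:
            out["cohens_d"] = None
    else:
        out["cohens_d"] = None
    return out


def summarize_cohort(
    phase_records: pd.DataFrame,
    architecture: Optional[pd.DataFrame] = None,
    band_powers: Optional[pd.DataFrame] = None,
    grubbs_alpha: float = 0.05,
    n_staging_comparisons: int = 7,
    n_spectral_comparisons: int = 5,
) -> dict:
    """Assemble the study report: mean +/- SD per condition, paired Cohen's d
    per outcome, a Grubbs screen of the flash-visit phase angles, and the
    Bonferroni-corrected thresholds for the two outcome families (5 stage
    durations + 2 transition kinds = 7 staging comparisons; 5 bands).

    ``phase_records`` needs columns participant, condition, delta_phi_h and,
    for flash rows, psi_h / corrected_shift_h / net_shift_h.  Architecture and
    band-power tables are tidy (participant, condition, window, metric/stage/
    band, value).  Participants missing one of the two conditions are dropped
    from paired statistics with a warning entry in the report.
    """
    from .circadian import grubbs_test  # local import to avoid cycle

    report: dict = {"warnings": []}

    # --- circadian phase ---------------------------------------------------
    phase: dict = {}
    counts = phase_records.groupby("participant")["condition"].nunique()
    incomplete = sorted(counts.index[counts < 2])
    if incomplete:
        report["warnings"].append(
            f"participants dropped from paired statistics (one visit only): "
            f"{incomplete}"
        )
    pivot = phase_records.pivot_table(index="participant", columns="condition",
                                      values="delta_phi_h", aggfunc="first")
    phase["delta_phi_h"] = _paired_block(pivot)
    flash = phase_records[phase_records["condition"] == "flash"]
    for col in ("psi_h", "corrected_shift_h", "net_shift_h"):
        if col in flash.columns:
            m, s = _mean_sd(flash[col].to_numpy())
            phase[col] = {"mean": m, "sd": s}
    psi = flash["psi_h"].dropna().to_numpy() if "psi_h" in flash.columns else np.array([])
    if psi.size >= 3 and psi.std(ddof=1) > 0:
        g = grubbs_test(psi, alpha=grubbs_alpha)
        phase["psi_grubbs"] = {
            "statistic": g.statistic,
            "critical_value": g.critical_value,
            "outlier_index": g.outlier_index,
            "is_outlier": g.is_outlier,
            "alpha": grubbs_alpha,
            "n": g.n,
        }
    else:
        phase["psi_grubbs"] = None
    report["phase"] = phase

    # --- sleep architecture ------------------------------------------------
    if architecture is not None and len(architecture):
        arch: dict = {}
        for (window, metric), grp in architecture.groupby(["window", "metric"]):
            pv = grp.pivot_table(index="participant", columns="condition",
                                 values="value", aggfunc="first")
            arch.setdefault(str(window), {})[str(metric)] = _paired_block(pv)
        report["architecture"] = arch

    # --- spectral power ----------------------------------------------------
    if band_powers is not None and len(band_powers):
        spec: dict = {}
        # average power across the stages present for each participant-visit,
        # giving one value per (participant, condition, window, band)
        coll = (band_powers
                .groupby(["participant", "condition", "window", "band"],
                         as_index=False)["power_uv2"].mean())
        for (window, band), grp in coll.groupby(["window", "band"]):
            pv = grp.pivot_table(index="participant", columns="condition",
                                 values="power_uv2", aggfunc="first")
            spec.setdefault(str(window), {})[str(band)] = _paired_block(pv)
        report["spectral"] = spec

    report["thresholds"] = {
        "family_alpha": 0.05,
        "sleep_staging": bonferroni_alpha(0.05, n_staging_comparisons),
        "spectral": bonferroni_alpha(0.05, n_spectral_comparisons),
    }
    return report
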
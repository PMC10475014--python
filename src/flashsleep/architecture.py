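"""Hypnogram architecture metrics: stage durations, stage transitions and
probability-scoring summaries within protocol analysis windows.

Hypnograms are sequences of 15-s epochs scored as W, N1, N2, N3 or REM
(plus ARTIFACT, which is excluded from every metric and breaks adjacency
for transition counting).  The two protocol windows are the stimulus hour
(0.5-1.5 h after habitual sleep onset) and the 6.5 h that follow it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
ARTIFACT = "ARTIFACT"
VALID_STAGES = frozenset(STAGES) | {ARTIFACT}
SLEEP_STAGES = frozenset({"N1", "N2", "N3", "REM"})

EPOCH_SECONDS = 15.0


@dataclass
class Hypnogram:
    """Scored sleep-stage sequence in fixed-length epochs.

    ``start_time`` is the start of the first epoch in hours relative to
    habitual sleep onset (HSOn); ``epoch_length`` is in seconds.
    """

    stages: np.ndarray
    start_time: float = 0.0
    epoch_length: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="<U8")
        if self.stages.ndim != 1 or len(self.stages) == 0:
            raise ValueError("hypnogram must be a nonempty 1-D stage sequence")
        bad = set(np.unique(self.stages)) - VALID_STAGES
        if bad:
            raise ValueError(f"unknown stage label(s): {sorted(bad)}")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def epoch_starts(self) -> np.ndarray:
        """Epoch start times in hours relative to HSOn."""
        return self.start_time + np.arange(self.n_epochs) * self.epoch_length / 3600.0

    @property
    def duration_hours(self) -> float:
        return self.n_epochs * self.epoch_length / 3600.0


@dataclass
class StageProbabilities:
    """Per-epoch probability distribution over the five sleep stages.

    Columns follow :data:`STAGES` order; each row sums to 1.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(STAGES):
            raise ValueError(f"probs must be (n_epochs, {len(STAGES)})")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each epoch's probabilities must sum to 1")

    def __len__(self) -> int:
        return len(self.probs)

    def column(self, stage: str) -> np.ndarray:
        return self.probs[:, STAGES.index(stage)]


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open analysis window [start, end) in hours relative to HSOn."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("window end must exceed start")

    @property
    def span_hours(self) -> float:
        return self.end - self.start


#: The hour of flash (or sham) exposure: 30 min after HSOn, lasting 1 h.
INTERVENTION_WINDOW = AnalysisWindow("intervention", 0.5, 1.5)
#: The 6.5 h following the stimulus hour.
POST_WINDOW = AnalysisWindow("post", 1.5, 8.0)


def window_mask(hypnogram: Hypnogram, window: AnalysisWindow) -> np.ndarray:
    """Boolean mask of epochs whose *start* lies in [window.start, window.end)."""
    starts = hypnogram.epoch_starts
    return (starts >= window.start - 1e-9) & (starts < window.end - 1e-9)


def slice_window(hypnogram: Hypnogram, window: AnalysisWindow) -> Hypnogram:
    """Restrict a hypnogram to an analysis window.

    Boundary epochs are assigned by their start time (half-open convention),
    which makes windowing deterministic and additive over disjoint windows.
    """
    mask = window_mask(hypnogram, window)
    if not mask.any():
        raise ValueError(
            f"window [{window.start:g}, {window.end:g}) h does not overlap "
            f"the hypnogram span"
        )
    first = int(np.argmax(mask))
    return Hypnogram(
        stages=hypnogram.stages[mask],
        start_time=float(hypnogram.epoch_starts[first]),
        epoch_length=hypnogram.epoch_length,
    )


def stage_durations(hypnogram: Hypnogram) -> dict[str, float]:
    """Minutes spent in each of the five stages; ARTIFACT epochs excluded.

    Durations over non-artifact epochs always sum to
    (non-artifact epoch count) x epoch_length.
    """
    non_artifact = hypnogram.stages != ARTIFACT
    if not non_artifact.any():
        raise ValueError("all epochs are artifact; no durations defined")
    minutes_per_epoch = hypnogram.epoch_length / 60.0
    return {
        s: float(np.count_nonzero(hypnogram.stages == s)) * minutes_per_epoch
        for s in STAGES
    }


def count_transitions(
    hypnogram: Hypnogram,
    kind: str,
    taxonomy: str = "n3_to_light",
) -> int:
    """Count adjacent-epoch stage transitions of a given kind.

    kind
        ``"deep_to_light"`` — deep-to-light transitions; under the default
        ``taxonomy="n3_to_light"`` these are N3 followed by N2 or N1; under
        ``taxonomy="n2n3_to_n1"`` they are N2 or N3 followed by N1 (the
        variant phrasing used in parts of the sleep literature).
    kind
        ``"sleep_to_wake"`` — any sleep stage (N1, N2, N3, REM) followed by W.

    ARTIFACT epochs break adjacency: no transition is counted into, out of,
    or across an artifact epoch.
    """
    if kind not in ("deep_to_light", "sleep_to_wake"):
        raise ValueError(f"unknown transition kind {kind!r}")
    if taxonomy not in ("n3_to_light", "n2n3_to_n1"):
        raise ValueError(f"unknown transition taxonomy {taxonomy!r}")
    s = hypnogram.stages
    if len(s) < 2:
        return 0
    a, b = s[:-1], s[1:]
    ok = (a != ARTIFACT) & (b != ARTIFACT)
    if kind == "sleep_to_wake":
        hit = np.isin(a, list(SLEEP_STAGES)) & (b == "W")
    elif taxonomy == "n3_to_light":
        hit = (a == "N3") & np.isin(b, ["N2", "N1"])
    else:
        hit = np.isin(a, ["N2", "N3"]) & (b == "N1")
    return int(np.count_nonzero(hit & ok))


def probability_score(
    probs: StageProbabilities,
    hypnogram: Hypnogram,
    stage: str,
    window: Optional[AnalysisWindow] = None,
) -> float:
    """Mean probability of ``stage`` over epochs scored as that stage.

    Follows the scorer-confidence summary convention: the average of p(stage)
    restricted to epochs whose discrete score *is* that stage (ARTIFACT epochs
    excluded), optionally within an analysis window.  Returns NaN — a missing
    value, not zero — when no such epoch exists, mirroring the reduced degrees
    of freedom rare stages produce in short windows.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    if len(probs) != hypnogram.n_epochs:
        raise ValueError(
            f"probability rows ({len(probs)}) do not match hypnogram epochs "
            f"({hypnogram.n_epochs})"
        )
    mask = hypnogram.stages == stage
    if window is not None:
        mask &= window_mask(hypnogram, window)
    if not mask.any():
        return float("nan")
    return float(np.mean(probs.column(stage)[mask]))
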
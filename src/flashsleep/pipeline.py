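"""Study configuration, file ingest, and end-to-end orchestration.

A study is described by a single JSON config naming the participants (with
habitual sleep onset/offset clock times and the visit-to-condition map) and
the input files: a melatonin CSV, hypnogram and stage-probability CSVs, a
directory of per-visit EDF recordings, and a phase-response-curve CSV.  All
clock times are normalized once at ingest to continuous hours relative to
each night's habitual sleep onset (HSOn); every analysis constant (windows,
bands, epoch length, threshold multiplier, daytime sample count) is
overridable in the config but defaults to the protocol values.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .architecture import (AnalysisWindow, Hypnogram, STAGES,
                           StageProbabilities, VALID_STAGES, count_transitions,
                           probability_score, slice_window, stage_durations)
from .circadian import (DLMOError, MelatoninSeries, PhaseResponseCurve,
                        compute_threshold, estimate_dlmo, net_shift,
                        phase_angle, phase_shift, prc_correct)
from .io import clock_to_hours, read_edf, wrap_relative, write_edf
from .spectral import BANDS, band_power_by_stage, preprocess
from .stats import summarize_cohort
from .synthetic import Cohort, SimConfig, gen_cohort, toy_prc

DEFAULT_WINDOWS = {"intervention": (0.5, 1.5), "post": (1.5, 8.0)}


@dataclass
class ParticipantConfig:
    pid: str
    hson: float          # clock hours
    hsoff: float         # clock hours
    visits: dict[int, str]  # visit number -> "placebo" | "flash"

    @property
    def sleep_duration(self) -> float:
        return (self.hsoff - self.hson) % 24.0


@dataclass
class StudyConfig:
    participants: list[ParticipantConfig]
    base_dir: Path
    paths: dict[str, str]
    seed: int = 0
    stimulus_offset_h: float = 0.5
    threshold_multiplier: float = 2.0
    n_daytime: int = 3
    epoch_length_s: float = 15.0
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS))
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BANDS))
    transition_taxonomy: str = "n3_to_light"
    prc_mode: str = "multiplicative"
    eeg_channels: tuple[str, ...] = ("C3", "C4")

    def __post_init__(self) -> None:
        if not self.participants:
            raise ValueError("config lists no participants")
        for p in self.participants:
            if p.sleep_duration <= 0:
                raise ValueError(f"{p.pid}: HSOff must follow HSOn")
            conds = sorted(p.visits.values())
            if conds != ["flash", "placebo"]:
                raise ValueError(
                    f"{p.pid}: need exactly one placebo and one flash visit, "
                    f"got {conds}"
                )
        if self.prc_mode != "multiplicative":
            raise ValueError("only the multiplicative PRC correction is implemented")

    def path(self, key: str) -> Path:
        return self.base_dir / self.paths[key]

    @classmethod
    def from_json(cls, config_path) -> "StudyConfig":
        config_path = Path(config_path)
        with open(config_path) as fh:
            raw = json.load(fh)
        participants = [
            ParticipantConfig(
                pid=str(p["id"]),
                hson=clock_to_hours(p["hson"]),
                hsoff=clock_to_hours(p["hsoff"]),
                visits={int(k): str(v) for k, v in p["visits"].items()},
            )
            for p in raw["participants"]
        ]
        kwargs = {}
        for key in ("seed", "stimulus_offset_h", "threshold_multiplier",
                    "n_daytime", "epoch_length_s", "transition_taxonomy",
                    "prc_mode"):
            if key in raw:
                kwargs[key] = raw[key]
        if "windows" in raw:
            kwargs["windows"] = {k: tuple(v) for k, v in raw["windows"].items()}
        if "bands" in raw:
            kwargs["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        if "eeg_channels" in raw:
            kwargs["eeg_channels"] = tuple(raw["eeg_channels"])
        return cls(participants=participants, base_dir=config_path.parent,
                   paths=dict(raw["paths"]), **kwargs)


@dataclass
class VisitInputs:
    condition: str
    mel_baseline: MelatoninSeries
    mel_post: MelatoninSeries
    hypnogram: Optional[Hypnogram]
    probabilities: Optional[StageProbabilities]
    edf_path: Optional[Path]


@dataclass
class Study:
    config: StudyConfig
    prc: Optional[PhaseResponseCurve]
    visits: dict[tuple[str, int], VisitInputs]  # (pid, visit) -> inputs


def _melatonin_series(df: pd.DataFrame, pconf: ParticipantConfig, visit: int,
                      day: str, path: Path) -> MelatoninSeries:
    sel = df[(df["participant"] == pconf.pid) & (df["visit"] == visit)
             & (df["day"] == day)]
    if sel.empty:
        raise ValueError(f"{path}: no melatonin rows for {pconf.pid} "
                         f"visit {visit} day {day}")
    rel = np.array([wrap_relative(t, pconf.hson) for t in sel["time_h"]])
    order = np.argsort(rel)
    rel_sorted = rel[order]
    if np.any(np.diff(rel_sorted) <= 0):
        rows = sel.index[order].to_numpy()
        raise ValueError(
            f"{path}: non-monotone melatonin times for {pconf.pid} visit "
            f"{visit} day {day} (rows {rows.tolist()})"
        )
    return MelatoninSeries(
        times=rel_sorted,
        concentrations=sel["concentration_pg_ml"].to_numpy()[order],
        daytime_flags=sel["is_daytime"].astype(bool).to_numpy()[order],
        participant=pconf.pid,
        label=f"v{visit}-{day}",
    )


def read_inputs(config: StudyConfig) -> Study:
    """Parse and validate every input file into an in-memory study dataset.

    Melatonin and hypnogram tables are loaded fully; EDF files are validated
    (existence plus channel presence) but their samples are read lazily by
    the spectral stage, one visit at a time.
    """
    mel_path = config.path("melatonin")
    hyp_path = config.path("hypnograms")
    prob_path = config.path("probabilities")
    for key in ("melatonin", "hypnograms", "probabilities", "prc"):
        p = config.path(key)
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")

    mel = pd.read_csv(mel_path)
    need = {"participant", "visit", "day", "time_h", "concentration_pg_ml",
            "is_daytime"}
    if not need <= set(mel.columns):
        raise ValueError(f"{mel_path}: missing column(s) {sorted(need - set(mel.columns))}")

    hyp = pd.read_csv(hyp_path)
    bad = hyp[~hyp["stage"].isin(VALID_STAGES)]
    if len(bad):
        r = bad.index[0]
        raise ValueError(
            f"{hyp_path}: unknown stage label {bad['stage'].iloc[0]!r} at row "
            f"{r + 2} (participant {bad['participant'].iloc[0]}, "
            f"epoch {bad['epoch_index'].iloc[0]})"
        )
    probs = pd.read_csv(prob_path)

    prc_df = pd.read_csv(config.path("prc"))
    prc = PhaseResponseCurve(phases=prc_df["phase_h_after_dlmo"].to_numpy(),
                             shifts=prc_df["shift_h"].to_numpy())

    edf_dir = config.base_dir / config.paths.get("edf_dir", "edf")
    visits: dict[tuple[str, int], VisitInputs] = {}
    for pconf in config.participants:
        for visit, condition in sorted(pconf.visits.items()):
            mb = _melatonin_series(mel, pconf, visit, "baseline", mel_path)
            mp = _melatonin_series(mel, pconf, visit, "post", mel_path)
            h = hyp[(hyp["participant"] == pconf.pid) & (hyp["visit"] == visit)]
            hypno = probmat = None
            if len(h):
                h = h.sort_values("epoch_index")
                if not np.array_equal(h["epoch_index"].to_numpy(),
                                      np.arange(len(h))):
                    raise ValueError(
                        f"{hyp_path}: epoch indices for {pconf.pid} visit "
                        f"{visit} are not contiguous from 0"
                    )
                hypno = Hypnogram(stages=h["stage"].to_numpy(), start_time=0.0,
                                  epoch_length=config.epoch_length_s)
                pr = probs[(probs["participant"] == pconf.pid)
                           & (probs["visit"] == visit)].sort_values("epoch_index")
                if len(pr):
                    if len(pr) != hypno.n_epochs:
                        raise ValueError(
                            f"{prob_path}: {pconf.pid} visit {visit} has "
                            f"{len(pr)} probability rows for "
                            f"{hypno.n_epochs} epochs"
                        )
                    probmat = StageProbabilities(
                        probs=pr[[f"p_{s}" for s in STAGES]].to_numpy())
            edf_path = edf_dir / f"{pconf.pid}_v{visit}.edf"
            if edf_path.exists():
                read_edf(edf_path, channels=config.eeg_channels)  # validates
            else:
                edf_path = None
            visits[(pconf.pid, visit)] = VisitInputs(
                condition=condition, mel_baseline=mb, mel_post=mp,
                hypnogram=hypno, probabilities=probmat, edf_path=edf_path)
    return Study(config=config, prc=prc, visits=visits)


# --------------------------------------------------------------------------
# analysis stages
# --------------------------------------------------------------------------

def phase_records(
    visit_tuples,
    prc: Optional[PhaseResponseCurve] = None,
    stimulus_offset_h: float = 0.5,
    n_daytime: int = 3,
    threshold_multiplier: float = 2.0,
) -> pd.DataFrame:
    """DLMO, phase shift, phase angle, PRC-corrected and net shifts.

    ``visit_tuples`` yields (participant, visit, condition, baseline series,
    post series).  One output row per participant-condition.  Visits whose
    melatonin series do not yield an onset (no crossing inside the sampled
    window) get NaN estimates and a warning; their participant drops out of
    paired quantities.
    """
    rows = []
    for pid, visit, condition, mel_baseline, mel_post in visit_tuples:
        rec = {"participant": pid, "visit": visit, "condition": condition,
               "dlmo_baseline_h": np.nan, "dlmo_post_h": np.nan,
               "delta_phi_h": np.nan, "psi_h": np.nan,
               "corrected_shift_h": np.nan, "net_shift_h": np.nan}
        try:
            thr_b = compute_threshold(mel_baseline, n_daytime,
                                      threshold_multiplier)
            db = estimate_dlmo(mel_baseline, thr_b).onset_time
            thr_p = compute_threshold(mel_post, n_daytime,
                                      threshold_multiplier)
            dp = estimate_dlmo(mel_post, thr_p).onset_time
        except DLMOError as err:
            warnings.warn(f"{pid} visit {visit}: {err}")
            rows.append(rec)
            continue
        rec.update(dlmo_baseline_h=db, dlmo_post_h=dp,
                   delta_phi_h=phase_shift(db, dp))
        if condition == "flash":
            rec["psi_h"] = phase_angle(db, stimulus_offset_h)
        rows.append(rec)
    df = pd.DataFrame(rows)

    flash = df["condition"] == "flash"
    psi_mean = df.loc[flash, "psi_h"].mean()
    if prc is not None and np.isfinite(psi_mean):
        for i in df.index[flash]:
            psi_i, dphi = df.at[i, "psi_h"], df.at[i, "delta_phi_h"]
            if np.isfinite(psi_i) and np.isfinite(dphi):
                df.at[i, "corrected_shift_h"] = prc_correct(
                    dphi, psi_i, psi_mean, prc)
    placebo = df[df["condition"] == "placebo"].set_index("participant")
    for i in df.index[flash]:
        pid = df.at[i, "participant"]
        if pid in placebo.index:
            dp_f, dp_p = df.at[i, "delta_phi_h"], placebo.at[pid, "delta_phi_h"]
            if np.isfinite(dp_f) and np.isfinite(dp_p):
                df.at[i, "net_shift_h"] = net_shift(dp_f, dp_p)
    return df


def analyze_phase(study: Study) -> pd.DataFrame:
    """Phase-shift records for a file-backed study (see :func:`phase_records`)."""
    cfg = study.config
    tuples = [(pid, visit, vi.condition, vi.mel_baseline, vi.mel_post)
              for (pid, visit), vi in sorted(study.visits.items())]
    return phase_records(tuples, prc=study.prc,
                         stimulus_offset_h=cfg.stimulus_offset_h,
                         n_daytime=cfg.n_daytime,
                         threshold_multiplier=cfg.threshold_multiplier)


def cohort_phase_records(
    cohort: Cohort,
    prc: Optional[PhaseResponseCurve] = None,
    stimulus_offset_h: float = 0.5,
) -> pd.DataFrame:
    """Phase-shift records computed directly on an in-memory synthetic cohort."""
    tuples = [(part.pid, visit, vd.condition, vd.mel_baseline, vd.mel_post)
              for part in cohort.participants
              for visit, vd in sorted(part.visits.items())]
    return phase_records(tuples, prc=prc, stimulus_offset_h=stimulus_offset_h)


def analyze_architecture(study: Study) -> pd.DataFrame:
    """Stage durations, transition counts and probability scores per window.

    Tidy output: participant, condition, window, metric, value.  Metrics are
    ``duration_<stage>_min``, ``transitions_deep_to_light``,
    ``transitions_sleep_to_wake`` and ``p_<stage>`` (NaN when the stage is
    absent from the window).
    """
    cfg = study.config
    rows = []
    for (pid, visit), vi in sorted(study.visits.items()):
        if vi.hypnogram is None:
            continue
        for wname, (lo, hi) in cfg.windows.items():
            window = AnalysisWindow(wname, lo, hi)
            sliced = slice_window(vi.hypnogram, window)
            metrics: dict[str, float] = {}
            for stage, minutes in stage_durations(sliced).items():
                metrics[f"duration_{stage}_min"] = minutes
            metrics["transitions_deep_to_light"] = count_transitions(
                sliced, "deep_to_light", taxonomy=cfg.transition_taxonomy)
            metrics["transitions_sleep_to_wake"] = count_transitions(
                sliced, "sleep_to_wake")
            if vi.probabilities is not None:
                for stage in STAGES:
                    metrics[f"p_{stage}"] = probability_score(
                        vi.probabilities, vi.hypnogram, stage, window)
            for metric, value in metrics.items():
                rows.append({"participant": pid, "condition": vi.condition,
                             "window": wname, "metric": metric,
                             "value": value})
    return pd.DataFrame(rows, columns=["participant", "condition", "window",
                                       "metric", "value"])


def analyze_spectral(study: Study) -> pd.DataFrame:
    """Per-stage band powers per window over the central derivations.

    EDF signals are loaded one visit at a time, preprocessed (100 Hz,
    0.2-49 Hz zero-phase band-pass), pooled per scored stage within each
    window and integrated per band.
    """
    cfg = study.config
    frames = []
    for (pid, visit), vi in sorted(study.visits.items()):
        if vi.edf_path is None or vi.hypnogram is None:
            continue
        signals = [preprocess(s)
                   for s in read_edf(vi.edf_path, channels=cfg.eeg_channels)]
        for wname, (lo, hi) in cfg.windows.items():
            window = AnalysisWindow(wname, lo, hi)
            table = band_power_by_stage(signals, vi.hypnogram, window,
                                        bands=cfg.bands,
                                        channels=cfg.eeg_channels)
            table.insert(0, "participant", pid)
            table.insert(1, "condition", vi.condition)
            frames.append(table)
    if not frames:
        return pd.DataFrame(columns=["participant", "condition", "window",
                                     "channel", "stage", "band", "power_uv2"])
    return pd.concat(frames, ignore_index=True)


def _config_digest(config: StudyConfig) -> str:
    blob = json.dumps({
        "participants": [(p.pid, p.hson, p.hsoff, sorted(p.visits.items()))
                         for p in config.participants],
        "stimulus_offset_h": config.stimulus_offset_h,
        "threshold_multiplier": config.threshold_multiplier,
        "n_daytime": config.n_daytime,
        "epoch_length_s": config.epoch_length_s,
        "windows": sorted(config.windows.items()),
        "bands": sorted(config.bands.items()),
        "transition_taxonomy": config.transition_taxonomy,
        "prc_mode": config.prc_mode,
        "seed": config.seed,
    }, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_full_analysis(config: StudyConfig, out_dir) -> dict:
    """Execute the full pipeline and write the report bundle.

    Writes phase_shifts.csv, sleep_architecture.csv, band_power.csv,
    report.json and provenance.json into ``out_dir``.  Any stage failure
    removes the partially written output directory before re-raising.
    """
    out_dir = Path(out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        study = read_inputs(config)
        phase = analyze_phase(study)
        arch = analyze_architecture(study)
        spectral = analyze_spectral(study)
        report = summarize_cohort(phase, arch, spectral)
        report["provenance"] = {
            "package": "flashsleep",
            "version": __version__,
            "config_sha256": _config_digest(config),
            "seed": config.seed,
            "prc_mode": config.prc_mode,
            "transition_taxonomy": config.transition_taxonomy,
        }
        phase.to_csv(out_dir / "phase_shifts.csv", index=False)
        arch.to_csv(out_dir / "sleep_architecture.csv", index=False)
        spectral.to_csv(out_dir / "band_power.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(_jsonable(report["provenance"]), fh, indent=2,
                      sort_keys=True)
        return report
    except Exception:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        else:
            for name in ("phase_shifts.csv", "sleep_architecture.csv",
                         "band_power.csv", "report.json", "provenance.json"):
                (out_dir / name).unlink(missing_ok=True)
        raise


# --------------------------------------------------------------------------
# simulation to disk
# --------------------------------------------------------------------------

def simulate_study(
    sim_config: SimConfig,
    out_dir,
    hson: str = "00:00",
    include_eeg: bool = True,
) -> StudyConfig:
    """Write a complete synthetic study (inputs + ground truth) to disk.

    Produces the exact input layout :func:`read_inputs` consumes — melatonin,
    hypnogram and probability CSVs with clock times, per-visit EDF files, a
    synthetic PRC table — plus ground_truth.json and the study config, and
    returns the parsed :class:`StudyConfig`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = gen_cohort(sim_config, include_sleep=True, include_eeg=include_eeg)
    hson_h = clock_to_hours(hson)
    hsoff_h = (hson_h + sim_config.sleep_duration) % 24.0

    mel_rows, hyp_rows, prob_rows = [], [], []
    for part in cohort.participants:
        for visit, vd in sorted(part.visits.items()):
            for day, series in (("baseline", vd.mel_baseline),
                                ("post", vd.mel_post)):
                for t, c, d in zip(series.times, series.concentrations,
                                   series.daytime_flags):
                    mel_rows.append({
                        "participant": part.pid, "visit": visit, "day": day,
                        "time_h": round((t + hson_h) % 24.0, 6),
                        "concentration_pg_ml": round(float(c), 6),
                        "is_daytime": bool(d),
                    })
            for i, stage in enumerate(vd.hypnogram.stages):
                hyp_rows.append({"participant": part.pid, "visit": visit,
                                 "epoch_index": i, "stage": stage})
            for i, vec in enumerate(vd.probabilities.probs):
                row = {"participant": part.pid, "visit": visit,
                       "epoch_index": i}
                row.update({f"p_{s}": round(float(v), 9)
                            for s, v in zip(STAGES, vec)})
                prob_rows.append(row)
            if vd.signals is not None:
                write_edf(out_dir / "edf" / f"{part.pid}_v{visit}.edf",
                          vd.signals)
    pd.DataFrame(mel_rows).to_csv(out_dir / "melatonin.csv", index=False)
    pd.DataFrame(hyp_rows).to_csv(out_dir / "hypnograms.csv", index=False)
    pd.DataFrame(prob_rows).to_csv(out_dir / "probabilities.csv", index=False)

    prc = toy_prc()
    pd.DataFrame({"phase_h_after_dlmo": prc.phases,
                  "shift_h": prc.shifts}).to_csv(out_dir / "prc.csv",
                                                 index=False)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(_jsonable(cohort.ground_truth), fh, indent=2, sort_keys=True)

    hsoff = f"{int(hsoff_h):02d}:{int(round((hsoff_h % 1) * 60)):02d}"
    study_cfg = {
        "seed": sim_config.seed,
        "participants": [
            {"id": part.pid, "hson": hson, "hsoff": hsoff,
             "visits": {str(v): vd.condition
                        for v, vd in sorted(part.visits.items())}}
            for part in cohort.participants
        ],
        "paths": {"melatonin": "melatonin.csv",
                  "hypnograms": "hypnograms.csv",
                  "probabilities": "probabilities.csv",
                  "edf_dir": "edf",
                  "prc": "prc.csv"},
        "windows": {k: list(v) for k, v in DEFAULT_WINDOWS.items()},
    }
    with open(out_dir / "study_config.json", "w") as fh:
        json.dump(study_cfg, fh, indent=2, sort_keys=True)
    return StudyConfig.from_json(out_dir / "study_config.json")
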
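"""End-to-end analysis: conditioning → features → topography → metrics.

``analyze_subject`` turns one (recording, torque) pair into the full
per-segment variable table, the maxima record and the endurance time;
``cohort_report`` stacks subjects into the repeated-measures battery and
the endurance regression.  ``run_pipeline`` is the file-based wrapper the
CLI uses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import io as eio
from .core_types import (
    AnalysisRegion,
    EMGRecording,
    METRIC_FIELDS,
    Position,
    RoATrajectory,
    SegmentMetrics,
    TorqueTrace,
    validate_recording,
)
from .features import aif, rms_envelope
from .preprocess import (
    EnduranceResult,
    FilterSpec,
    detect_bad_channels,
    endurance_time,
    filter_emg,
    filter_torque,
    segment_contraction,
)
from .spatial_metrics import MetricConfig, displacement, segment_metrics
from .stats import (
    RegressionRow,
    RepeatedMeasuresTable,
    VariableReport,
    analyze_variable,
    endurance_regression,
)
from .topography import maps_from_envelope, roa_trajectory

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Every tunable of the analysis chain, schema-validated.

    Unknown keys are rejected so configuration typos fail loudly.
    """

    model_config = ConfigDict(extra="forbid")

    filter_order: int = 3
    band_low_hz: float = 20.0
    band_high_hz: float = 450.0
    notch_hz: float = 50.0
    notch_q: float = 30.0
    torque_lowpass_hz: float = 10.0

    auto_bad_channels: bool = True
    snr_floor_db: float = 3.0

    quasi_zero_s: float = 4.0
    segment_length_s: float = 10.0
    drop_fraction: float = 0.5
    sustain_s: float = 3.0

    envelope_window_s: float = 0.5
    frame_rate_hz: float = 10.0
    aif_frame_s: float = 0.5
    roa_threshold_fraction: float = 0.7

    reference_policy: str = "baseline"
    baseline_s: float = 1.0
    ellipse_confidence: float = 0.95
    circle_z: float = 1.645
    max_gap_s: float = 1.0

    alpha: float = 0.05
    alpha_strict: float = 0.01
    seed: int = 0

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(
            order=self.filter_order,
            band=(self.band_low_hz, self.band_high_hz),
            notch_hz=self.notch_hz,
            notch_q=self.notch_q,
            torque_lowpass_hz=self.torque_lowpass_hz,
        )

    def metric_config(self) -> MetricConfig:
        return MetricConfig(
            reference_policy=self.reference_policy,
            baseline_s=self.baseline_s,
            ellipse_confidence=self.ellipse_confidence,
            circle_z=self.circle_z,
            max_gap_s=self.max_gap_s,
        )

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SubjectResult:
    """Everything one subject contributes downstream."""

    region: AnalysisRegion
    endurance: EnduranceResult
    trajectory: RoATrajectory
    metrics: list[SegmentMetrics]
    maxima: dict[str, float]
    displacement_mm: float
    bad_channels: set[Position]
    findings: list[str]
    config_hash: str


def analyze_subject(
    rec: EMGRecording,
    tq: TorqueTrace,
    config: PipelineConfig | None = None,
) -> SubjectResult:
    """Run the full single-subject chain on in-memory data."""
    config = config or PipelineConfig()
    findings = validate_recording(rec)
    for f in findings:
        logger.warning("recording: %s", f)
    spec = config.filter_spec()

    tq_f = filter_torque(tq, spec)
    region = segment_contraction(
        tq_f,
        quasi_zero_s=config.quasi_zero_s,
        segment_length_s=config.segment_length_s,
        mark_fraction=config.drop_fraction,
        sustain_s=config.sustain_s,
    )
    endurance = endurance_time(tq_f, config.drop_fraction, config.sustain_s)

    rec_f = filter_emg(rec, spec)

    bad: set[Position] = set(rec.layout.bad)
    if config.auto_bad_channels:
        # quasi-zero reference: the pre-contraction stretch where torque is
        # still below 10 % MVT (falls back to the robust rule when absent)
        idx = np.nonzero(tq_f.torque >= 0.1 * tq_f.mvt)[0]
        t_active = idx[0] / tq_f.fs if idx.size else 0.0
        ref = (0.0, min(t_active, rec.duration_s)) if t_active >= 0.25 else None
        bad = detect_bad_channels(
            rec_f,
            snr_floor_db=config.snr_floor_db,
            hold_window=(region.start_s, region.end_s) if ref else None,
            reference_window=ref,
        )
    good = rec.good_channel_mask(bad)

    env = rms_envelope(rec_f, config.envelope_window_s, config.frame_rate_hz)
    spec_series = aif(rec_f, config.aif_frame_s, (config.band_low_hz, config.band_high_hz))
    maps = maps_from_envelope(env, rec.layout, rec.channel_map, bad)
    traj = roa_trajectory(maps, rec.layout, config.roa_threshold_fraction)

    rows, maxima = segment_metrics(
        traj, env, spec_series, tq_f, region, config.metric_config(), good
    )
    disp = displacement(traj, region)
    return SubjectResult(
        region=region,
        endurance=endurance,
        trajectory=traj,
        metrics=rows,
        maxima=maxima,
        displacement_mm=disp,
        bad_channels=bad,
        findings=findings,
        config_hash=config.hash(),
    )


def run_pipeline(
    emg_path: str | Path,
    sidecar_path: str | Path,
    torque_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    subject: str = "subject",
) -> SubjectResult:
    """File-based single-subject pipeline; writes the artifact directory."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sidecar = eio.read_sidecar(sidecar_path)
    if sidecar.mvt_nm is None:
        raise ValueError("sidecar must declare mvt_nm to normalise torque")
    rec = eio.read_recording(emg_path, sidecar_path)
    tq = eio.read_torque(torque_path, mvt_nm=sidecar.mvt_nm,
                         target_fraction=sidecar.target_fraction)

    result = analyze_subject(rec, tq, config)
    h = result.config_hash
    eio.write_trajectory(out / "trajectory.csv", result.trajectory, config_hash=h)
    eio.write_metrics(out / "metrics.csv", result.metrics, subject=subject, config_hash=h)
    eio.write_maxima(
        out / "maxima.csv", result.maxima, subject=subject,
        endurance_s=result.endurance.endurance_s, config_hash=h,
    )
    log = {
        "subject": subject,
        "config": config.model_dump(),
        "config_hash": h,
        "region": {"start_s": result.region.start_s, "end_s": result.region.end_s},
        "endurance_s": result.endurance.endurance_s,
        "endurance_censored": result.endurance.censored,
        "displacement_mm": result.displacement_mm,
        "bad_channels": sorted(map(list, result.bad_channels)),
        "findings": result.findings,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return result


def cohort_tables(
    results: Sequence[SubjectResult],
) -> dict[str, RepeatedMeasuresTable]:
    """Per-variable subjects x (T1, T2, T3) tables from subject results."""
    tables: dict[str, RepeatedMeasuresTable] = {}
    for name in METRIC_FIELDS:
        data = np.array(
            [[getattr(m, name) for m in r.metrics] for r in results], dtype=float
        )
        try:
            tables[name] = RepeatedMeasuresTable(data, variable=name)
        except ValueError as exc:
            logger.warning("variable %s skipped: %s", name, exc)
    return tables


def cohort_report(
    results: Sequence[SubjectResult],
    gate_alpha: float | None = 0.05,
) -> tuple[dict[str, VariableReport], list[RegressionRow]]:
    """Repeated-measures battery per variable plus endurance regression.

    The regression uses each subject's per-variable maximum over the
    three segments (and the T1→T3 displacement) against endurance time.
    """
    tables = cohort_tables(results)
    reports = {name: analyze_variable(tbl, gate_alpha) for name, tbl in tables.items()}

    endurance = np.array([r.endurance.endurance_s for r in results], dtype=float)
    maxima = {
        name: np.array([r.maxima.get(name, np.nan) for r in results], dtype=float)
        for name in METRIC_FIELDS
    }
    maxima["displacement"] = np.array([r.displacement_mm for r in results], dtype=float)
    regression = endurance_regression(maxima, endurance)
    return reports, regression


def report_to_json(reports: dict[str, VariableReport],
                   regression: list[RegressionRow]) -> dict:
    """Serialisable mirror of the statistics tables."""
    out: dict = {"variables": {}, "regression": []}
    for name, rep in reports.items():
        fr = rep.friedman
        out["variables"][name] = {
            "shapiro_p": rep.shapiro_p,
            "friedman": {
                "chi2": fr.chi2,
                "p": fr.p,
                "p_exact": fr.p_exact,
                "kendall_w": fr.kendall_w,
                "effect": fr.effect,
                "n": fr.n_subjects,
            },
            "pairwise": [dataclasses.asdict(row) for row in rep.pairwise],
        }
    for row in regression:
        out["regression"].append(dataclasses.asdict(row))
    return out


def regression_frame(regression: list[RegressionRow]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in regression])
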
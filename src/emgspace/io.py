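"""Readers and writers for the delimited-text interchange formats.

A recording travels as a channels x samples delimited matrix plus a JSON
sidecar describing the grid and the torque normalisation; torque is a
two-column CSV (time_s, torque_nm).  Result tables (trajectory, metrics,
maxima, regression) are CSVs with 9-significant-digit numeric formatting
so reruns are byte-stable; each carries the pipeline config hash as a
leading ``#`` comment line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .core_types import EMGRecording, GridLayout, RoATrajectory, SegmentMetrics, TorqueTrace

FLOAT_FMT = "%.9g"


class Sidecar(BaseModel):
    """JSON sidecar schema accompanying a recording matrix."""

    model_config = ConfigDict(extra="forbid")

    fs_hz: float = Field(gt=0)
    n_rows: int = 26
    n_cols: int = 5
    ied_fp_mm: float = 8.0
    ied_ft_mm: float = 8.0
    missing: list[tuple[int, int]] = Field(default_factory=lambda: [(0, 4), (13, 4)])
    bad: list[tuple[int, int]] = Field(default_factory=list)
    mvt_nm: float | None = None
    target_fraction: float = 0.60

    def layout(self) -> GridLayout:
        return GridLayout(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            ied_fp=self.ied_fp_mm,
            ied_ft=self.ied_ft_mm,
            missing=frozenset(map(tuple, self.missing)),
            bad=frozenset(map(tuple, self.bad)),
        )


def read_sidecar(path: str | Path) -> Sidecar:
    return Sidecar.model_validate_json(Path(path).read_text())


def write_sidecar(path: str | Path, sidecar: Sidecar) -> None:
    Path(path).write_text(sidecar.model_dump_json(indent=2) + "\n")


def read_recording(matrix_path: str | Path, sidecar_path: str | Path) -> EMGRecording:
    """Load a channels x samples matrix with its sidecar.

    The channel map is built row-major over the non-missing lattice
    positions; a shape mismatch is a load error naming both shapes.
    """
    sidecar = read_sidecar(sidecar_path)
    layout = sidecar.layout()
    matrix = np.loadtxt(matrix_path, delimiter=",", ndmin=2)
    if matrix.shape[0] != layout.n_channels:
        raise ValueError(
            f"matrix has {matrix.shape[0]} rows but the sidecar layout defines "
            f"{layout.n_channels} physical channels "
            f"({layout.n_rows}x{layout.n_cols} minus {len(layout.missing)} missing)"
        )
    return EMGRecording(signals=matrix, fs=sidecar.fs_hz, layout=layout)


def write_recording(
    matrix_path: str | Path,
    sidecar_path: str | Path,
    rec: EMGRecording,
    mvt_nm: float | None = None,
    target_fraction: float = 0.60,
    fmt: str = "%.17g",
) -> None:
    np.savetxt(matrix_path, rec.signals, delimiter=",", fmt=fmt)
    layout = rec.layout
    sidecar = Sidecar(
        fs_hz=rec.fs,
        n_rows=layout.n_rows,
        n_cols=layout.n_cols,
        ied_fp_mm=layout.ied_fp,
        ied_ft_mm=layout.ied_ft,
        missing=sorted(layout.missing),
        bad=sorted(layout.bad),
        mvt_nm=mvt_nm,
        target_fraction=target_fraction,
    )
    write_sidecar(sidecar_path, sidecar)


def read_torque(
    path: str | Path, mvt_nm: float, target_fraction: float = 0.60
) -> TorqueTrace:
    df = pd.read_csv(path, comment="#")
    if not {"time_s", "torque_nm"} <= set(df.columns):
        raise ValueError("torque CSV must have columns time_s, torque_nm")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("torque record too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    return TorqueTrace(
        torque=df["torque_nm"].to_numpy(), fs=fs, mvt=mvt_nm,
        target_fraction=target_fraction,
    )


def write_torque(path: str | Path, tq: TorqueTrace) -> None:
    df = pd.DataFrame({"time_s": tq.t, "torque_nm": tq.torque})
    df.to_csv(path, index=False, float_format="%.17g")


def _write_csv(path: str | Path, df: pd.DataFrame, config_hash: str | None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def write_trajectory(
    path: str | Path, traj: RoATrajectory, config_hash: str | None = None
) -> None:
    df = pd.DataFrame(
        {"t_s": traj.t, "ft_mm": traj.ft, "fp_mm": traj.fp, "kind": traj.kind}
    )
    _write_csv(path, df, config_hash)


def read_trajectory(path: str | Path) -> RoATrajectory:
    df = pd.read_csv(path, comment="#")
    kind = str(df["kind"].iloc[0]) if len(df) else "RoA"
    return RoATrajectory(
        t=df["t_s"].to_numpy(), ft=df["ft_mm"].to_numpy(), fp=df["fp_mm"].to_numpy(),
        kind=kind,
    )


def metrics_frame(rows: Sequence[SegmentMetrics], subject: str | None = None) -> pd.DataFrame:
    records = []
    for r in rows:
        rec = {"segment": r.label, **r.as_dict()}
        if subject is not None:
            rec = {"subject": subject, **rec}
        records.append(rec)
    return pd.DataFrame(records)


def write_metrics(
    path: str | Path,
    rows: Sequence[SegmentMetrics],
    subject: str | None = None,
    config_hash: str | None = None,
) -> None:
    _write_csv(path, metrics_frame(rows, subject), config_hash)


def write_maxima(
    path: str | Path,
    maxima: dict[str, float],
    subject: str | None = None,
    endurance_s: float | None = None,
    config_hash: str | None = None,
) -> None:
    record: dict[str, object] = {}
    if subject is not None:
        record["subject"] = subject
    if endurance_s is not None:
        record["endurance_s"] = endurance_s
    record.update(maxima)
    _write_csv(path, pd.DataFrame([record]), config_hash)


def write_stats_json(path: str | Path, report: dict, config_hash: str | None = None) -> None:
    payload = dict(report)
    if config_hash:
        payload["config_hash"] = config_hash
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
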
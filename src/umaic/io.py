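"""File formats: delimited tables for IPD and digitizer-style artifacts.

All tables are comma-separated UTF-8 text with a header row and '.' decimal
marker; curve and risk-table files mirror the two-column shape a digitizer
export produces.  Schemas are documented in docs/formats.md.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import DataValidationError
from .publication import AggregateSummary, KMCurve, KMPublication, RiskTable
from .reconstruct import ReconstructedIPD
from .simulate import RECORD_COLUMNS

PathLike = Union[str, Path]


def write_ipd(records: pd.DataFrame, path: PathLike) -> None:
    """Write patient records (arm, covariates, treated, time, event)."""
    records[RECORD_COLUMNS].to_csv(path, index=False)


def read_ipd(path: PathLike) -> pd.DataFrame:
    """Read and validate a patient-record table; parse errors name the row."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing columns: {', '.join(missing)}")
    for col in ("age", "time"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise DataValidationError(f"non-numeric {col!r} at row {int(bad[0])}")
        df[col] = pd.to_numeric(df[col])
    if (df["time"] < 0).any():
        row = int(df.index[df["time"] < 0][0])
        raise DataValidationError(f"negative time at row {row}")
    for col in ("postmenopausal", "grade2", "grade3", "treated", "event"):
        bad = df.index[~df[col].isin([0, 1])]
        if len(bad):
            raise DataValidationError(
                f"{col!r} outside {{0, 1}} at row {int(bad[0])}"
            )
        df[col] = df[col].astype(np.int64)
    return df[RECORD_COLUMNS]


def write_curve(curve: KMCurve, path: PathLike) -> None:
    pd.DataFrame({"time_days": curve.times, "survival": curve.survival}).to_csv(
        path, index=False
    )


def read_curve(path: PathLike) -> KMCurve:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_days", "survival"]:
        raise DataValidationError("curve file must have columns time_days, survival")
    return KMCurve(
        times=df["time_days"].to_numpy(float), survival=df["survival"].to_numpy(float)
    )


def write_risk_table(risk: RiskTable, path: PathLike) -> None:
    pd.DataFrame({"time_days": risk.times, "n_at_risk": risk.n_at_risk}).to_csv(
        path, index=False
    )


def read_risk_table(path: PathLike) -> RiskTable:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_days", "n_at_risk"]:
        raise DataValidationError(
            "risk-table file must have columns time_days, n_at_risk"
        )
    return RiskTable(
        times=df["time_days"].to_numpy(float),
        n_at_risk=df["n_at_risk"].to_numpy(np.int64),
    )


def write_aggregates(agg: AggregateSummary, path: PathLike, total_events=None) -> None:
    payload = {
        "mean_age": agg.mean_age,
        "var_age": agg.var_age,
        "p_postmenopausal": agg.p_postmenopausal,
        "p_grade2": agg.p_grade2,
        "p_grade3": agg.p_grade3,
        "n_total": agg.n_total,
    }
    if total_events is not None:
        payload["total_events"] = int(total_events)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_aggregates(path: PathLike):
    """Returns (AggregateSummary, total_events or None)."""
    payload = json.loads(Path(path).read_text())
    total_events = payload.pop("total_events", None)
    return AggregateSummary(**payload), total_events


def write_publication(pub: KMPublication, directory: PathLike, prefix: str = "b_arm") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_curve(pub.curve, directory / f"{prefix}_curve.csv")
    write_risk_table(pub.risk_table, directory / f"{prefix}_risk_table.csv")
    write_aggregates(
        pub.aggregates, directory / f"{prefix}_aggregates.json", pub.total_events
    )


def read_publication(directory: PathLike, prefix: str = "b_arm") -> KMPublication:
    directory = Path(directory)
    curve = read_curve(directory / f"{prefix}_curve.csv")
    risk = read_risk_table(directory / f"{prefix}_risk_table.csv")
    agg, total_events = read_aggregates(directory / f"{prefix}_aggregates.json")
    return KMPublication(
        curve=curve, risk_table=risk, aggregates=agg, total_events=total_events
    )


def write_reconstructed(recon: ReconstructedIPD, path: PathLike) -> None:
    """Two-column IPD file plus a provenance sidecar (<path>.provenance.json)."""
    df = recon.data.rename(columns={"time": "time_days"})
    df.to_csv(path, index=False)
    sidecar = Path(str(path) + ".provenance.json")
    sidecar.write_text(json.dumps({"provenance": recon.provenance, "n": recon.n}))


def read_reconstructed(path: PathLike) -> ReconstructedIPD:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_days", "event"]:
        raise DataValidationError(
            "reconstructed IPD file must have columns time_days, event"
        )
    bad = df.index[~df["event"].isin([0, 1])]
    if len(bad):
        raise DataValidationError(f"'event' outside {{0, 1}} at row {int(bad[0])}")
    sidecar = Path(str(path) + ".provenance.json")
    provenance = "reconstructed"
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text()).get("provenance", provenance)
    return ReconstructedIPD(
        data=df.rename(columns={"time_days": "time"}), provenance=provenance
    )


def write_estimates(estimates: pd.DataFrame, path: PathLike, scenario_id: int) -> None:
    out = estimates.copy()
    out.insert(1, "scenario", scenario_id)
    out.to_csv(path, index=False)


def write_manifest(path: PathLike, config_dict: dict, master_seed: int, version: str) -> None:
    """Reproducibility manifest: config hash, seed, software version."""
    blob = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "master_seed": master_seed,
        "umaic_version": version,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def write_run_log(events: list, path: PathLike) -> None:
    """JSON-lines event log (repetition start/end, exclusions)."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev, default=str) + "\n")
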
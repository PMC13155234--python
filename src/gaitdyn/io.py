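"""File formats: CSV/JSON/YAML readers and writers for every record type.

Interchange is plain text. Acceleration CSVs carry the sampling rate in a
single comment line (`# sample_rate_hz: 128`) followed by columns
t, a_v, a_ap, a_ml; uniform sampling is verified on read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import AXIS_NAMES, AccelSeries, GroundTruth, StrideSeries
from .synthetic import CohortSpec

_MAX_JITTER = 1e-6  # s, allowed timestamp deviation from uniformity


def write_accel_csv(accel: AccelSeries, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample_rate_hz: {accel.sample_rate!r}\n")
        fh.write("t," + ",".join(AXIS_NAMES) + "\n")
        t = accel.time
        for i in range(accel.n_samples):
            row = ",".join(repr(float(v)) for v in accel.samples[i])
            fh.write(f"{float(t[i])!r},{row}\n")


def read_accel_csv(path) -> AccelSeries:
    """Read an acceleration CSV, verifying schema and uniform sampling."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty acceleration file")
    lines = text.splitlines()
    sample_rate = None
    if lines[0].startswith("#"):
        key, _, val = lines[0].lstrip("# ").partition(":")
        if key.strip() == "sample_rate_hz":
            sample_rate = float(val)
        lines = lines[1:]
    df = pd.read_csv(
        pd.io.common.StringIO("\n".join(lines)), float_precision="round_trip"
    )
    missing = [c for c in ("t", *AXIS_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.max(np.abs(dt - dt[0])) > _MAX_JITTER:
        raise ValueError(f"{path}: non-uniform sampling (timestamp jitter)")
    if sample_rate is None:
        sample_rate = 1.0 / dt[0]
    samples = df[list(AXIS_NAMES)].to_numpy(dtype=float)
    return AccelSeries(samples=samples, sample_rate=sample_rate, start_time=float(t[0]))


def write_events_json(events, path, ground_truth: GroundTruth | None = None) -> None:
    payload = {"event_indices": np.asarray(events, dtype=int).tolist()}
    if ground_truth is not None:
        payload["ground_truth"] = {
            "event_indices": ground_truth.event_indices.tolist(),
            "stride_times": ground_truth.stride_times.tolist(),
        }
        if ground_truth.stride_lengths is not None:
            payload["ground_truth"]["stride_lengths"] = (
                ground_truth.stride_lengths.tolist()
            )
    Path(path).write_text(json.dumps(payload, indent=1))


def read_events_json(path) -> np.ndarray:
    payload = json.loads(Path(path).read_text())
    return np.asarray(payload["event_indices"], dtype=int)


def write_stride_table(series_list, path) -> None:
    """Long stride-table CSV: one row per stride per leg."""
    rows = []
    for s in series_list:
        for i in range(s.n_strides):
            rows.append(
                {
                    "participant": s.participant,
                    "group": s.group,
                    "condition": s.condition,
                    "leg": s.leg,
                    "stride_index": i,
                    "stride_time_s": s.stride_times[i],
                    "stride_length_m": (
                        s.stride_lengths[i] if s.stride_lengths is not None else ""
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stride_table(path) -> list[StrideSeries]:
    df = pd.read_csv(path)
    required = {"participant", "group", "condition", "leg", "stride_index",
                "stride_time_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    keys = ["participant", "group", "condition", "leg"]
    for (pid, grp, cond, leg), sub in df.groupby(keys, sort=False):
        sub = sub.sort_values("stride_index")
        lengths = None
        if "stride_length_m" in sub.columns and sub["stride_length_m"].notna().all():
            lengths = sub["stride_length_m"].to_numpy(dtype=float)
        out.append(
            StrideSeries(
                participant=str(pid),
                group=str(grp),
                condition=str(cond),
                leg=str(leg),
                stride_times=sub["stride_time_s"].to_numpy(dtype=float),
                stride_lengths=lengths,
            )
        )
    return out


def write_cohort_spec(spec: CohortSpec, path) -> None:
    d = dataclasses.asdict(spec)
    # tuple-keyed tables flatten to "group/condition" strings for YAML
    d["cv_table"] = {f"{g}/{c}": v for (g, c), v in spec.cv_table.items()}
    d["lde_table"] = {f"{g}/{c}": v for (g, c), v in spec.lde_table.items()}
    d["groups"] = list(spec.groups)
    d["conditions"] = list(spec.conditions)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_cohort_spec(path) -> CohortSpec:
    d = yaml.safe_load(Path(path).read_text())
    d["cv_table"] = {tuple(k.split("/")): v for k, v in d["cv_table"].items()}
    d["lde_table"] = {tuple(k.split("/")): v for k, v in d["lde_table"].items()}
    d["groups"] = tuple(d["groups"])
    d["conditions"] = tuple(d["conditions"])
    return CohortSpec(**d)


def write_report(report, out_dir) -> dict:
    """Write a StudyReport as JSON + CSV tables; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    anova_path = out_dir / "anova_tables.csv"
    report.anova_tables().to_csv(anova_path, index=False)
    paths["anova"] = anova_path
    for name, rep in report.measures.items():
        p1 = out_dir / f"posthoc_{name}.csv"
        rep.posthoc.to_csv(p1, index=False)
        p2 = out_dir / f"simple_effects_{name}.csv"
        rep.simple_effects.to_csv(p2, index=False)
        paths[f"posthoc_{name}"] = p1
        paths[f"simple_effects_{name}"] = p2
    summary_path = out_dir / "cohort_summary.csv"
    report.cohort_summary.to_csv(summary_path, index=False)
    paths["summary"] = summary_path
    report_path = out_dir / "report.json"
    report_path.write_text(
        json.dumps(
            {"pattern": report.pattern, "provenance": report.provenance}, indent=1
        )
    )
    paths["report"] = report_path
    return paths
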
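"""Plain-text I/O for sessions, power traces and athlete profiles.

Sessions and traces are tab-separated tables; athlete profiles are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import Model2Params
from .synthetic import AthleteProfile, BreathSeries, PowerTrace

SESSION_COLUMNS = ["t_s", "vo2", "hr", "rf", "ve", "feo2", "feco2"]
TRACE_COLUMNS = ["t_s", "power_w", "cadence_rpm"]


def write_session(path: str | Path, series: BreathSeries) -> None:
    df = pd.DataFrame({
        "t_s": series.t, "vo2": series.vo2, "hr": series.hr, "rf": series.rf,
        "ve": series.ve, "feo2": series.feo2, "feco2": series.feco2,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_session(path: str | Path) -> BreathSeries:
    df = pd.read_csv(path, sep="\t")
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session file missing columns: {sorted(missing)}")
    return BreathSeries(t=df["t_s"].to_numpy(), vo2=df["vo2"].to_numpy(),
                        hr=df["hr"].to_numpy(), rf=df["rf"].to_numpy(),
                        ve=df["ve"].to_numpy(), feo2=df["feo2"].to_numpy(),
                        feco2=df["feco2"].to_numpy())


def write_trace(path: str | Path, trace: PowerTrace) -> None:
    pd.DataFrame({"t_s": trace.t, "power_w": trace.power,
                  "cadence_rpm": trace.cadence}).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def read_trace(path: str | Path) -> PowerTrace:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file missing columns: {sorted(missing)}")
    return PowerTrace(t=df["t_s"].to_numpy(), power=df["power_w"].to_numpy(),
                      cadence=df["cadence_rpm"].to_numpy())


def write_profile(path: str | Path, profile: AthleteProfile) -> None:
    d = dataclasses.asdict(profile)
    d["true_m2"] = dataclasses.asdict(profile.true_m2)
    Path(path).write_text(json.dumps(d, indent=2))


def read_profile(path: str | Path) -> AthleteProfile:
    d = json.loads(Path(path).read_text())
    d["true_m2"] = Model2Params(**d["true_m2"])
    return AthleteProfile(**d)
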
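"""CSV interchange: long-format BP tables, covariates, outcomes, model reports."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .series import BPSeries

BP_LONG_COLUMNS = ["patient_id", "channel", "time_h", "value_mmhg"]


class ParseError(ValueError):
    pass


def series_from_frame(df: pd.DataFrame, channel=None) -> list:
    """Group a long-format frame into time-sorted BPSeries (one per patient).

    Rejects duplicate (patient, channel, time) rows and non-positive values.
    Patients keep their order of first appearance.
    """
    missing = [c for c in BP_LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s): {missing}")
    sub = df if channel is None else df[df["channel"] == channel]
    out = []
    for (pid, chan), grp in sub.groupby(["patient_id", "channel"], sort=False):
        grp = grp.sort_values("time_h")
        t = grp["time_h"].to_numpy(dtype=float)
        if len(np.unique(t)) != len(t):
            dup = grp.loc[grp["time_h"].duplicated(), :].iloc[0]
            raise ParseError(
                f"duplicate timestamp for patient {pid!r} channel {chan} "
                f"at t={dup['time_h']}"
            )
        try:
            out.append(BPSeries(str(pid), str(chan), t,
                                grp["value_mmhg"].to_numpy(dtype=float)))
        except ValueError as exc:
            raise ParseError(f"patient {pid!r} channel {chan}: {exc}") from exc
    return out


def read_bp_long(path, channel=None) -> list:
    """Read a long-format BP CSV (patient_id,channel,time_h,value_mmhg)."""
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except Exception as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    for col in ("time_h", "value_mmhg"):
        if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ParseError(f"non-numeric {col} at row(s) {list(bad[:5])}")
    return series_from_frame(df, channel=channel)


def frame_from_series(series_list) -> pd.DataFrame:
    """Inverse of :func:`series_from_frame`."""
    parts = []
    for s in series_list:
        parts.append(pd.DataFrame({
            "patient_id": s.patient_id, "channel": s.channel,
            "time_h": s.times, "value_mmhg": s.values,
        }))
    return pd.concat(parts, ignore_index=True)[BP_LONG_COLUMNS]


def write_report_json(path, payload: dict):
    """Serialise a report with fixed float precision for reproducible diffs."""

    def _round(obj):
        if isinstance(obj, float):
            return round(obj, 6)
        if isinstance(obj, dict):
            return {k: _round(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_round(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return round(float(obj), 6)
        if isinstance(obj, np.ndarray):
            return _round(obj.tolist())
        return obj

    with open(path, "w") as fh:
        json.dump(_round(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
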
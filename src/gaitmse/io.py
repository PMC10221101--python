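"""CSV/JSON interchange for signals, entropy profiles and cohort tables.

Signal files are plain CSV with a header ``t,AP,ML,V`` (any subset of the
axis columns), one row per sample.  Entropy results are written in long
format ``subject_id,axis,method,tau,value`` with ``NA`` marking undefined
values; complexity indices appear as ``method=CI_<variant>`` rows with an
empty ``tau``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, Iterable, Mapping

import numpy as np
import pandas as pd

from .entropy import AXES, MultiscaleProfile, SignalTrace, is_undefined

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "profiles_to_long",
    "write_profiles_csv",
    "write_profiles_json",
]


def read_signal_csv(
    path: str | Path, fs: float = 100.0, subject_id: str = ""
) -> Dict[str, SignalTrace]:
    """Read a triaxial (or partial) acceleration CSV into SignalTraces."""
    df = pd.read_csv(path)
    axes = [a for a in AXES if a in df.columns]
    if not axes:
        raise ValueError(f"{path}: no axis column among {AXES} found")
    if not subject_id:
        subject_id = Path(path).stem
    return {
        a: SignalTrace(df[a].to_numpy(dtype=float), fs=fs, axis=a,
                       subject_id=subject_id)
        for a in axes
    }


def write_signal_csv(traces: Mapping[str, SignalTrace], path: str | Path) -> None:
    """Write axis traces (equal length, shared clock) as ``t,AP,ML,V``."""
    axes = [a for a in AXES if a in traces]
    first = traces[axes[0]]
    data = {"t": np.arange(len(first)) / first.fs}
    for a in axes:
        data[a] = traces[a].samples
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.8g")


def profiles_to_long(profiles: Iterable[MultiscaleProfile]) -> pd.DataFrame:
    """Long-format table of per-scale values plus complexity-index rows."""
    rows = []
    for p in profiles:
        for tau in sorted(p.values):
            v = p.values[tau]
            rows.append({
                "subject_id": p.subject_id, "axis": p.axis,
                "method": p.method, "tau": tau,
                "value": math.nan if is_undefined(v) else v,
            })
        rows.append({
            "subject_id": p.subject_id, "axis": p.axis,
            "method": f"CI_{p.method}", "tau": math.nan,
            "value": math.nan if is_undefined(p.ci) else p.ci,
        })
    return pd.DataFrame(rows)


def write_profiles_csv(
    profiles: Iterable[MultiscaleProfile], path: str | Path
) -> None:
    profiles_to_long(profiles).to_csv(
        path, index=False, na_rep="NA", float_format="%.10g"
    )


def write_profiles_json(
    profiles: Iterable[MultiscaleProfile], path: str | Path
) -> None:
    """JSON mirror of the long CSV (undefined values become null)."""
    payload = []
    for p in profiles:
        payload.append({
            "subject_id": p.subject_id,
            "axis": p.axis,
            "method": p.method,
            "values": {
                str(t): (None if is_undefined(v) else v)
                for t, v in sorted(p.values.items())
            },
            "ci": None if is_undefined(p.ci) else p.ci,
        })
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
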
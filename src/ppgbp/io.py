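"""Plain-text waveform and table formats.

A waveform file is a delimited two-column table (``ppg,abp``) preceded by
``#``-prefixed header lines carrying the sampling rate, units and channel
names.  Ground truth and feature/ranking tables are ordinary CSV files via
pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import WaveformRecord
from .synthetic import BeatTruth, GroundTruth

__all__ = ["write_waveform", "read_waveform", "write_ground_truth", "read_ground_truth"]

_MAGIC = "ppgbp-waveform v1"


def write_waveform(path, record: WaveformRecord, units=("adim", "mmHg")) -> None:
    """Write a paired record as headered CSV."""
    path = Path(path)
    n = min(record.ppg.size, record.abp.size)
    with open(path, "w") as fh:
        fh.write(f"# {_MAGIC}\n")
        fh.write(f"# fs={record.fs:g}\n")
        fh.write(f"# units={units[0]},{units[1]}\n")
        fh.write("# channels=ppg,abp\n")
        for k, v in record.meta.items():
            fh.write(f"# meta.{k}={v}\n")
        fh.write("ppg,abp\n")
        for i in range(n):
            fh.write(f"{record.ppg[i]:.10g},{record.abp[i]:.10g}\n")


def read_waveform(path) -> WaveformRecord:
    """Read a headered-CSV paired record."""
    path = Path(path)
    fs = None
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if body.startswith("fs="):
                fs = float(body[3:])
            elif body.startswith("meta."):
                k, _, v = body[5:].partition("=")
                meta[k] = v
            elif body.startswith(("units=", "channels=")) or body == _MAGIC:
                continue
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=' header line")
    df = pd.read_csv(path, skiprows=skip)
    if not {"ppg", "abp"} <= set(df.columns):
        raise ValueError(f"{path}: expected 'ppg' and 'abp' columns")
    return WaveformRecord(ppg=df["ppg"].to_numpy(float),
                          abp=df["abp"].to_numpy(float), fs=fs, meta=meta)


def write_ground_truth(path, truth: GroundTruth) -> None:
    """One row per beat: onset, fiducials, labels; header carries lag/fs."""
    df = truth.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# lag={truth.lag}\n# fs={truth.fs:g}\n")
        df.to_csv(fh, index=False)


def read_ground_truth(path) -> GroundTruth:
    lag, fs = 0, np.nan
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if body.startswith("lag="):
                lag = int(body[4:])
            elif body.startswith("fs="):
                fs = float(body[3:])
    df = pd.read_csv(path, skiprows=skip)

    def _opt(v):
        return None if pd.isna(v) else int(v)

    beats = [
        BeatTruth(onset=int(r.onset), msp=_opt(r.msp), sp=_opt(r.sp), dn=_opt(r.dn),
                  ip=_opt(r.ip), dp=_opt(r.dp), dp_present=bool(r.dp_present),
                  sbp=float(r.sbp), dbp=float(r.dbp))
        for r in df.itertuples()
    ]
    return GroundTruth(beats=beats, lag=lag, fs=fs)
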
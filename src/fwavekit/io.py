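"""Delimited-text record formats.

Records are written as tab-separated columns with a commented header naming
the sampling rate, units, and column schema; simulated records carry their
ground-truth parts.  Beat annotations and the full provenance snapshot go to
a JSON sidecar (``<path>.meta.json``).  Round-trips are lossless to float
formatting precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import AfRecord

__all__ = ["EcgRecord", "read_record", "write_record", "write_components"]

_FLOAT_FMT = "%.10g"


@dataclass
class EcgRecord:
    """A uniformly sampled single-lead trace."""

    x: np.ndarray
    fs: float
    units: str = "uV"
    beat_annotations: list[tuple[int, str]] = field(default_factory=list)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.x)) / self.fs


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_record(record, path, fmt: str = "tsv") -> None:
    """Write an :class:`AfRecord` or :class:`EcgRecord` as delimited text."""
    if fmt != "tsv":
        raise ValueError(f"unsupported format {fmt!r}; only 'tsv' is available")
    path = Path(path)
    x = np.asarray(record.x, dtype=float)
    cols = {"time_s": np.arange(len(x)) / record.fs, "x": x}
    is_af = isinstance(record, AfRecord) or hasattr(record, "fwave_truth")
    if is_af:
        cols["fwave_truth"] = record.fwave_truth
        cols["ventricular"] = record.ventricular
        cols["noise"] = record.noise
    units = getattr(record, "units", "uV")
    header = (
        f"# fwavekit record v1\n"
        f"# fs = {record.fs}\n"
        f"# units = {units}\n"
        f"# columns = {','.join(cols)}\n"
    )
    body = pd.DataFrame(cols).to_csv(
        sep="\t", index=False, float_format=_FLOAT_FMT
    )
    path.write_text(header + body)
    meta = {
        "fs": record.fs,
        "units": units,
        "beat_annotations": [[int(i), t] for i, t in getattr(record, "beat_annotations", [])],
        "provenance": getattr(record, "provenance", {}),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_record(path, fmt: str = "tsv"):
    """Read a record written by :func:`write_record`.

    Returns an :class:`AfRecord` when ground-truth columns are present,
    otherwise an :class:`EcgRecord`.  Raises a parse error naming any
    missing header field.
    """
    if fmt != "tsv":
        raise ValueError(f"unsupported format {fmt!r}; only 'tsv' is available")
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("#").partition("=")
                header[key.strip()] = val.strip()
    if "fs" not in header:
        raise ValueError(f"{path}: missing required header field 'fs'")
    fs = float(header["fs"])
    units = header.get("units", "uV")
    df = pd.read_csv(path, sep="\t", comment="#")

    annotations: list[tuple[int, str]] = []
    provenance: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        annotations = [(int(i), str(t)) for i, t in meta.get("beat_annotations", [])]
        provenance = meta.get("provenance", {})

    if {"fwave_truth", "ventricular", "noise"} <= set(df.columns):
        return AfRecord(
            x=df["x"].to_numpy(),
            fwave_truth=df["fwave_truth"].to_numpy(),
            ventricular=df["ventricular"].to_numpy(),
            noise=df["noise"].to_numpy(),
            fs=fs,
            beat_annotations=annotations,
            provenance=provenance,
        )
    if "x" not in df.columns:
        raise ValueError(f"{path}: missing required column 'x'")
    return EcgRecord(x=df["x"].to_numpy(), fs=fs, units=units, beat_annotations=annotations)


def write_components(result, x, fs, path, config_note: str = "", truth=None) -> None:
    """Export a decomposition as (time, x, x_osc, x_trn, residual) text.

    ``truth`` (the simulated F-wave, when known) is carried through as an
    extra column so the file is self-contained for evaluation.
    """
    path = Path(path)
    x = np.asarray(x, dtype=float)
    cols = {
        "time_s": np.arange(len(x)) / fs,
        "x": x,
        "x_osc": result.x_osc,
        "x_trn": result.x_trn,
        "residual": result.residual,
    }
    if truth is not None:
        cols["fwave_truth"] = np.asarray(truth, dtype=float)
    header = (
        f"# fwavekit components v1\n"
        f"# fs = {fs}\n"
        f"# units = uV\n"
        f"# config = {config_note}\n"
        f"# columns = {','.join(cols)}\n"
    )
    body = pd.DataFrame(cols).to_csv(sep="\t", index=False, float_format=_FLOAT_FMT)
    path.write_text(header + body)
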
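"""Trace files, run configuration and report serialization.

A trace file is plain CSV with a self-describing ``# key = value`` header
block, e.g.::

    # signal_kind = anisotropy
    # rna_id = FRT
    # protein_id = IRP1
    # rna_uM = 0.05
    # protein_uM = 1
    # mn_uM = 0
    # kcl_mM = 100
    # temperature_C = 25
    # n_shots = 5
    # seed = 1
    time_s,signal
    0.001,0.0612843

Numbers are serialized with 9 significant digits, so write-then-read round
trips are lossless at that precision.  ``signal_kind``, ``rna_uM`` and
``protein_uM`` are mandatory; parse errors name the offending line.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .simulate import Condition, KineticTrace

__all__ = ["read_trace", "write_trace", "RunConfig", "TraceParseError",
           "write_report_json", "write_report_tsv"]

_MANDATORY = ("signal_kind", "rna_uM", "protein_uM")
_FLOAT_KEYS = ("rna_uM", "protein_uM", "mn_uM", "kcl_mM", "temperature_C")
_INT_KEYS = ("n_shots", "seed")
_STR_KEYS = ("signal_kind", "rna_id", "protein_id")


class TraceParseError(ValueError):
    """Malformed trace file; message carries the file line number."""


def write_trace(trace: KineticTrace, path) -> Path:
    """Write a trace to the header+CSV dialect (LF endings, 9 sig. digits)."""
    path = Path(path)
    c = trace.condition
    lines = [
        f"# signal_kind = {trace.signal_kind}",
        f"# rna_id = {c.rna_id}",
        f"# protein_id = {c.protein_id}",
        f"# rna_uM = {c.rna_uM:.9g}",
        f"# protein_uM = {c.protein_uM:.9g}",
        f"# mn_uM = {c.mn_uM:.9g}",
        f"# kcl_mM = {c.kcl_mM:.9g}",
        f"# temperature_C = {c.temperature_C:.9g}",
        f"# n_shots = {trace.n_shots_averaged}",
    ]
    if trace.seed is not None:
        lines.append(f"# seed = {trace.seed}")
    lines.append("time_s,signal")
    lines += [f"{t:.9g},{s:.9g}" for t, s in zip(trace.times, trace.signal)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trace(path) -> KineticTrace:
    """Read a trace file; raises :class:`TraceParseError` with line numbers."""
    path = Path(path)
    meta: dict[str, str] = {}
    times: list[float] = []
    signal: list[float] = []
    saw_columns = False
    with open(path, newline=None) as fh:  # universal newlines: CRLF == LF
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise TraceParseError(f"{path}:{lineno}: malformed header line {line!r}")
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
                continue
            if not saw_columns:
                cols = [c.strip() for c in line.split(",")]
                if cols != ["time_s", "signal"]:
                    raise TraceParseError(
                        f"{path}:{lineno}: expected column header 'time_s,signal', got {line!r}")
                saw_columns = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise TraceParseError(f"{path}:{lineno}: expected two comma-separated values")
            try:
                t, s = float(parts[0]), float(parts[1])
            except ValueError:
                raise TraceParseError(f"{path}:{lineno}: non-numeric data") from None
            if np.isnan(t) or np.isnan(s):
                raise TraceParseError(f"{path}:{lineno}: NaN value")
            if times and t <= times[-1]:
                raise TraceParseError(f"{path}:{lineno}: times not strictly increasing")
            times.append(t)
            signal.append(s)

    for key in _MANDATORY:
        if key not in meta:
            raise TraceParseError(f"{path}: missing mandatory metadata {key!r}")
    if len(times) < 2:
        raise TraceParseError(f"{path}: fewer than 2 data points")

    def fget(key, default=0.0):
        return float(meta[key]) if key in meta else default

    cond = Condition(
        rna_id=meta.get("rna_id", ""), protein_id=meta.get("protein_id", ""),
        rna_uM=fget("rna_uM"), protein_uM=fget("protein_uM"),
        mn_uM=fget("mn_uM"), kcl_mM=fget("kcl_mM", 100.0),
        temperature_C=fget("temperature_C", 25.0))
    seed = int(meta["seed"]) if "seed" in meta else None
    n_shots = int(meta.get("n_shots", 1))
    return KineticTrace(np.asarray(times), np.asarray(signal), meta["signal_kind"],
                        cond, n_shots_averaged=n_shots, seed=seed)


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run (YAML or JSON on disk).

    Unknown keys are rejected so a typo cannot silently fall back to a
    default.
    """

    preset: str
    seed: int | None = None
    noise_sd: float | None = None
    n_shots: int | None = None
    alpha: float = 0.05
    kinetics: str = "observed"
    interpolate_mn: bool = False
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.kinetics not in ("observed", "mass_action"):
            raise ValueError(f"unknown kinetics model {self.kinetics!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "preset" not in data:
            raise ValueError("config requires a 'preset' key")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix.lower() == ".json"
                else yaml.safe_load(text))
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)


def write_report_json(report_dict: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report_dict, indent=2, sort_keys=True) + "\n")
    return path


def write_report_tsv(table, path) -> Path:
    """Write a condition table (DataFrame) as TSV."""
    path = Path(path)
    table.to_csv(path, sep="\t", float_format="%.9g")
    return path
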
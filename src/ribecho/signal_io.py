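"""Stable on-disk formats: CSV traces, JSON manifests and model files.

Traces are two-column CSV (``time_s,voltage_V``), one file per trace,
named ``<participant>_<location>_<rep>.csv``. Datasets are tied together
by a JSON manifest holding the device (and, for simulations, cohort)
configuration, the participant records and a trace index. Fitted models
round-trip through JSON at full float precision with sorted keys, so
writers are deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from pathlib import Path

import numpy as np

from .errors import FormatError, ParseError
from .linear import LinearModel, OvoEnsemble
from .sim import (CohortConfig, CohortParams, Dataset, DeviceConfig,
                  Participant, RawTrace, TruncatedNormal)
from .thresholds import FreqThresholdModel, TimeThresholdModel

FORMAT_VERSION = "1.0"
_TRACE_STEM = re.compile(r"^(?P<pid>.+)_(?P<loc>[A-E])_(?P<rep>\d+)$")
#: Relative tolerance for sampling-uniformity of the time column.
_UNIFORM_TOL = 1e-6


# ---------------------------------------------------------------- traces

def trace_filename(trace: RawTrace) -> str:
    return f"{trace.participant_id}_{trace.location}_{trace.rep}.csv"


def write_trace(trace: RawTrace, path: str | Path) -> None:
    path = Path(path)
    n = trace.voltage.size
    t = np.arange(n) / trace.sampling_rate
    data = np.column_stack([t, trace.voltage])
    np.savetxt(path, data, fmt=("%.12e", "%.9e"), delimiter=",",
               header="time_s,voltage_V", comments="")


def read_trace(path: str | Path) -> RawTrace:
    """Parse a two-column trace CSV; sampling rate from the median step.

    Rejects non-monotone time axes and sampling jitter beyond 1 ppm of the
    median step. Participant/location/rep metadata is recovered from the
    ``<participant>_<location>_<rep>`` filename convention when present.
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except Exception as exc:  # noqa: BLE001 - numpy raises assorted types
        line = getattr(exc, "lineno", None)
        where = f" at line {line}" if line else ""
        raise ParseError(f"cannot parse {path}{where}: {exc}") from exc
    if data.size == 0 or data.shape[0] < 2:
        raise ParseError(f"{path}: need at least two samples")
    if data.shape[1] != 2:
        raise ParseError(f"{path}: expected two columns, got {data.shape[1]}")
    t, v = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if (dt <= 0).any():
        raise FormatError(f"{path}: time column must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > _UNIFORM_TOL * med:
        raise FormatError(f"{path}: non-uniform sampling beyond 1 ppm")

    m = _TRACE_STEM.match(path.stem)
    pid = m["pid"] if m else path.stem
    loc = m["loc"] if m else "A"
    rep = int(m["rep"]) if m else 0
    return RawTrace(participant_id=pid, location=loc, rep=rep,
                    sampling_rate=1.0 / med, voltage=v)


# ------------------------------------------------------------- manifests

def _cohort_params_from_dict(d: dict) -> CohortParams:
    kwargs = {}
    for f in dataclasses.fields(CohortParams):
        value = d[f.name]
        kwargs[f.name] = (TruncatedNormal(**value) if isinstance(value, dict)
                          else value)
    return CohortParams(**kwargs)


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    d["low"] = _cohort_params_from_dict(d["low"])
    d["high"] = _cohort_params_from_dict(d["high"])
    d["partial_echo_fraction_range"] = tuple(d["partial_echo_fraction_range"])
    return CohortConfig(**d)


def save_dataset(dataset: Dataset, outdir: str | Path) -> Path:
    """Write every trace CSV plus the manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = []
    for trace in dataset.traces:
        name = trace_filename(trace)
        write_trace(trace, outdir / name)
        index.append({"participant_id": trace.participant_id,
                      "location": trace.location, "rep": trace.rep,
                      "path": name})
    manifest = {
        "format_version": FORMAT_VERSION,
        "device_config": dataclasses.asdict(dataset.device_config),
        "cohort_config": (dataclasses.asdict(dataset.cohort_config)
                          if dataset.cohort_config else None),
        "participants": [dataclasses.asdict(p) for p in dataset.participants],
        "trace_index": index,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def load_dataset(manifest_path: str | Path) -> Dataset:
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{manifest_path}: {exc}") from exc
    if "format_version" not in manifest:
        raise FormatError(f"{manifest_path}: missing format_version")

    device = DeviceConfig(**manifest["device_config"])
    cohort = (cohort_config_from_dict(manifest["cohort_config"])
              if manifest.get("cohort_config") else None)
    participants = [Participant(**p) for p in manifest["participants"]]
    ids = [p.id for p in participants]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{manifest_path}: duplicate participant ids")

    traces = []
    for entry in manifest["trace_index"]:
        path = manifest_path.parent / entry["path"]
        if not path.exists():
            raise FormatError(f"{manifest_path}: missing trace file {path}")
        trace = read_trace(path)
        trace.participant_id = entry["participant_id"]
        trace.location = entry["location"]
        trace.rep = entry["rep"]
        traces.append(trace)
    return Dataset(participants, traces, device, cohort)


# ---------------------------------------------------------------- models

def _linear_to_dict(model: LinearModel) -> dict:
    return {
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "loss": model.loss,
        "reg_strength": model.reg_strength,
        "label_pair": list(model.label_pair),
        "feature_subset": list(model.feature_subset),
        "schema_hash": model.schema_hash,
    }


def _linear_from_dict(d: dict) -> LinearModel:
    return LinearModel(
        weights=np.array(d["weights"], dtype=float), bias=d["bias"],
        loss=d["loss"], reg_strength=d["reg_strength"],
        label_pair=tuple(d["label_pair"]),
        feature_subset=tuple(d["feature_subset"]),
        schema_hash=d["schema_hash"],
    )


def model_to_dict(model, task: int | None = None, cohort: str | None = None,
                  meta: dict | None = None) -> dict:
    """Serializable description of any fitted model."""
    if isinstance(model, TimeThresholdModel):
        kind, task, cohort = "time_threshold", model.task, model.cohort
        params = {"window_start_s": model.window_start_s,
                  "window_end_s": model.window_end_s,
                  "theta1": model.theta1, "theta2": model.theta2}
    elif isinstance(model, FreqThresholdModel):
        kind, task, cohort = "freq_threshold", model.task, model.cohort
        params = {"band_lo_hz": model.band_lo_hz,
                  "band_hi_hz": model.band_hi_hz,
                  "theta1": model.theta1, "theta2": model.theta2}
    elif isinstance(model, OvoEnsemble):
        kind = "ovo_ensemble"
        params = {"classes": list(model.classes),
                  "members": [_linear_to_dict(m) for m in model.members]}
    elif isinstance(model, LinearModel):
        kind = "logistic" if model.loss == "logistic" else "svm"
        params = _linear_to_dict(model)
    else:
        raise FormatError(f"unknown model type {type(model).__name__}")
    return {"format_version": FORMAT_VERSION, "model_kind": kind,
            "task": task, "cohort": cohort, "parameters": params,
            "training_meta": meta or {}}


def model_from_dict(d: dict):
    kind = d.get("model_kind")
    p = d.get("parameters", {})
    if kind == "time_threshold":
        return TimeThresholdModel(d["task"], d["cohort"], p["window_start_s"],
                                  p["window_end_s"], p["theta1"], p["theta2"])
    if kind == "freq_threshold":
        return FreqThresholdModel(d["task"], d["cohort"], p["band_lo_hz"],
                                  p["band_hi_hz"], p["theta1"], p["theta2"])
    if kind in ("logistic", "svm"):
        return _linear_from_dict(p)
    if kind == "ovo_ensemble":
        return OvoEnsemble(tuple(p["classes"]),
                           [_linear_from_dict(m) for m in p["members"]])
    raise FormatError(f"unknown model_kind {kind!r}")


def write_model(model, path: str | Path, task: int | None = None,
                cohort: str | None = None, meta: dict | None = None) -> None:
    Path(path).write_text(
        json.dumps(model_to_dict(model, task, cohort, meta), sort_keys=True,
                   indent=1))


def read_model(path: str | Path):
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return model_from_dict(d)
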
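"""File formats: trace TSV, YAML parameter files, JSON results.

Traces are plain tab-separated tables with a one-line format header
(``# npkinetics trace v1``) and columns ``time_s``, ``extension_nm``,
``force_pN``, ``conc_nM``.  Parameter files are YAML with ``polymer:``,
``lattice:``, ``rates:`` and optional ``protocol:`` blocks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .lattice import (
    ForceClampTrace,
    LatticeConfig,
    Protocol,
    RateParams,
    Segment,
)
from .polymer import ExtensionModel, FJCParams

__all__ = [
    "TRACE_HEADER",
    "ParamSet",
    "read_trace",
    "write_trace",
    "read_params",
    "write_params",
    "write_results",
    "packaged_params_path",
    "load_packaged_params",
]

TRACE_HEADER = "# npkinetics trace v1"
_TRACE_COLUMNS = ["time_s", "extension_nm", "force_pN", "conc_nM"]


class FormatError(ValueError):
    """Malformed input file."""


def write_trace(path: Union[str, Path], trace: ForceClampTrace) -> None:
    path = Path(path)
    df = pd.DataFrame({
        "time_s": trace.time,
        "extension_nm": trace.extension,
        "force_pN": np.full(len(trace.time), trace.force),
        "conc_nM": trace.concentration,
    })
    with open(path, "w") as fh:
        fh.write(TRACE_HEADER + "\n")
        for key, val in sorted(trace.provenance.items()):
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_trace(path: Union[str, Path]) -> ForceClampTrace:
    path = Path(path)
    provenance = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != TRACE_HEADER:
            raise FormatError(
                f"{path}:1: expected header {TRACE_HEADER!r}, got {first!r}"
            )
        skip = 1
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                provenance[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}:{skip + 1}: missing column(s) {', '.join(missing)}"
        )
    force = float(df["force_pN"].iloc[0])
    return ForceClampTrace(
        time=df["time_s"].to_numpy(),
        extension=df["extension_nm"].to_numpy(),
        force=force,
        concentration=df["conc_nM"].to_numpy(),
        provenance=provenance,
    )


@dataclass
class ParamSet:
    """Everything a simulation needs: polymer, lattice, rates, protocol."""

    fjc: FJCParams
    extension_model: ExtensionModel
    lattice: LatticeConfig
    rates: RateParams
    protocol: Optional[Protocol] = None


_GAMMA_KEYS = ("gamma_compact", "gamma_decompact", "gamma_monomer")


def _build(cls, block: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise FormatError(f"{section}: unknown field(s) {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{section}: {exc}") from exc


def read_params(path: Union[str, Path]) -> ParamSet:
    """Load and validate a YAML parameter file.

    Validation errors name the offending block and field.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: top level must be a mapping")

    poly = dict(doc.get("polymer", {}))
    gammas = {k: poly.pop(k, None) for k in _GAMMA_KEYS}
    gammas = {k: ({float(f): float(g) for f, g in v.items()} if v else None)
              for k, v in gammas.items()}
    fjc = _build(FJCParams, poly, "polymer")
    try:
        ext = ExtensionModel(**{k: v for k, v in gammas.items()
                                if v is not None})
    except ValueError as exc:
        raise FormatError(f"polymer gamma tables: {exc}") from exc

    lattice = _build(LatticeConfig, dict(doc.get("lattice", {})), "lattice")

    rates_block = dict(doc.get("rates", {}))
    for name, value in rates_block.items():
        if isinstance(value, (int, float)) and value < 0:
            raise FormatError(f"rates.{name}: must be non-negative, got {value}")
    rates = _build(RateParams, rates_block, "rates")

    protocol = None
    if "protocol" in doc:
        pb = dict(doc["protocol"])
        sched = pb.pop("schedule", None)
        if sched is None:
            raise FormatError("protocol: missing schedule")
        segments = tuple(
            Segment(float(s["duration"]), float(s["concentration"]))
            for s in sched
        )
        protocol = _build(Protocol, {"schedule": segments, **pb}, "protocol")
    return ParamSet(fjc=fjc, extension_model=ext, lattice=lattice, rates=rates,
                    protocol=protocol)


def write_params(path: Union[str, Path], params: ParamSet) -> None:
    doc: dict = {
        "polymer": {
            **dataclasses.asdict(params.fjc),
            "gamma_compact": dict(params.extension_model.gamma_compact),
            "gamma_decompact": dict(params.extension_model.gamma_decompact),
            "gamma_monomer": dict(params.extension_model.gamma_monomer),
        },
        "lattice": dataclasses.asdict(params.lattice),
        "rates": dataclasses.asdict(params.rates),
    }
    if params.protocol is not None:
        doc["protocol"] = {
            "force": params.protocol.force,
            "schedule": [
                {"duration": s.duration, "concentration": s.concentration}
                for s in params.protocol.schedule
            ],
            "sample_interval": params.protocol.sample_interval,
            "noise_sd": params.protocol.noise_sd,
            "seed": params.protocol.seed,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def write_results(path: Union[str, Path], results) -> None:
    """Write fit results / summaries as JSON (numpy-safe)."""
    with open(path, "w") as fh:
        json.dump(_jsonify(results), fh, indent=2)
        fh.write("\n")


def packaged_params_path() -> Path:
    """Path of the packaged calibrated reference parameter file."""
    return Path(__file__).parent / "data" / "params_reference.yaml"


def load_packaged_params() -> ParamSet:
    return read_params(packaged_params_path())
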
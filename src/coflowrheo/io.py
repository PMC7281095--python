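"""YAML configuration loading and run-metadata output.

A run configuration is a single YAML document with ``geometry``,
``fluids``, ``protocol``, ``compliance``, and ``analysis`` blocks whose
keys mirror the corresponding dataclass fields; a synthetic scenario
adds ``aggregation``, ``noise``, ``calibration`` blocks and a mandatory
``seed``.  Defaults filled in for omitted keys are echoed back into the
run metadata so results are reproducible from the metadata alone.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .circuit import ChannelGeometry, CompliancePack, FluidPair, PumpProtocol
from .estimators import VelocityCalibration
from .pipeline import AnalysisConfig
from .synthetic import AggregationModel, NoiseModel, SyntheticScenario

SCHEMA_VERSION = 1


def _build(cls, block: dict | None, **extra):
    block = dict(block or {})
    block.update(extra)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**block)


def load_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    version = doc.get("schema", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {version}")
    return doc


def load_run_config(path) -> dict:
    """Parse a run config into model objects.

    Returns a dict with keys geometry, fluids, protocol, compliance
    (None when absent), analysis (AnalysisConfig), calibration
    (VelocityCalibration or None).
    """
    doc = load_yaml(path)
    protocol = _build(PumpProtocol, doc.get("protocol"))
    fluids = _build(FluidPair, doc.get("fluids"))
    out = {
        "geometry": _build(ChannelGeometry, doc.get("geometry")),
        "fluids": fluids,
        "protocol": protocol,
        "compliance": (
            _build(CompliancePack, doc["compliance"]) if "compliance" in doc else None
        ),
        "analysis": _build(
            AnalysisConfig,
            doc.get("analysis"),
            protocol=protocol,
            mu_R_cP=doc.get("analysis", {}).get("mu_R_cP", fluids.mu_R_cP),
        ),
        "calibration": (
            _build(VelocityCalibration, doc["calibration"])
            if "calibration" in doc
            else None
        ),
    }
    return out


def load_scenario(path) -> SyntheticScenario:
    """Parse a scenario YAML into a SyntheticScenario (seed required)."""
    doc = load_yaml(path)
    if "seed" not in doc:
        raise ValueError("scenario requires an explicit seed")
    return SyntheticScenario(
        seed=int(doc["seed"]),
        protocol=_build(PumpProtocol, doc.get("protocol")),
        compliance=(
            _build(CompliancePack, doc["compliance"])
            if "compliance" in doc
            else SyntheticScenario.__dataclass_fields__["compliance"].default_factory()
        ),
        fluids=_build(FluidPair, doc.get("fluids")),
        aggregation=_build(AggregationModel, doc.get("aggregation")),
        noise=_build(NoiseModel, doc.get("noise")),
        calibration_slope_mm_s_per_mLh=float(
            doc.get("calibration", {}).get("slope_mm_s_per_mLh", 2.0732)
        ),
    )


def dump_metadata(path, objects: dict) -> None:
    """Write every parameter actually used (defaults included) as YAML."""
    payload = {"schema": SCHEMA_VERSION}
    for key, obj in objects.items():
        if obj is None:
            continue
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            payload[key] = _serializable(dataclasses.asdict(obj))
        else:
            payload[key] = _serializable(obj)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _serializable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {k: _serializable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serializable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
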
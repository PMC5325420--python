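"""Configuration loading, result writers, manifests and fixture files.

Configs are YAML or JSON documents validated against the published
schema (``CONFIG_SCHEMA``); unknown keys are rejected so typos never
silently fall back to defaults.  Screen results are written as tidy CSV
and/or JSON next to a manifest that echoes the configuration and hashes
it, making a result directory self-describing and re-runnable.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from importlib import metadata as _im
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .model_core import (
    DrugRegimen,
    KineticParameters,
    MODULE_IDS,
    Species,
    build_module,
    default_parameters,
    stimulus_library,
    validate_topology,
)
from .screens import RESULT_COLUMNS, ScreenConfig, ScreenResult

__all__ = [
    "SCHEMA_VERSION",
    "CONFIG_SCHEMA",
    "load_config",
    "config_from_dict",
    "write_results",
    "read_results",
    "generate_fixtures",
    "package_version",
]

log = logging.getLogger("crosstalksim")

SCHEMA_VERSION = "1.0"

#: Published config schema (JSON-Schema shaped; validated by
#: ``config_from_dict`` with field-level messages).
CONFIG_SCHEMA: dict = {
    "$id": "crosstalksim/screen-config",
    "schema_version": SCHEMA_VERSION,
    "type": "object",
    "additionalProperties": False,
    "properties": {
        "schema_version": {"type": "string"},
        "modules": {
            "type": "array",
            "items": {"type": "integer", "minimum": 0, "maximum": 8},
        },
        "anchor_target": {"enum": ["A", "B", "C", "D", "O"]},
        "partner_targets": {
            "type": "array",
            "items": {"enum": ["A", "B", "C", "D", "O"]},
        },
        "dose": {"type": "number", "exclusiveMinimum": 0},
        "partner_dose": {"type": ["number", "null"], "minimum": 0},
        "stimulus": {"enum": ["S0", "S1", "S2", "S3", "S4", "S5", "S6"]},
        "T": {"type": "number", "exclusiveMinimum": 0},
        "h": {"type": "number", "exclusiveMinimum": 0},
        "scale_grid": {
            "type": "array",
            "items": {"type": "number", "exclusiveMinimum": 0},
        },
        "tol": {"type": "number", "minimum": 0},
        "inhibition": {"enum": ["deactivation", "literal"]},
        "params": {"type": "object"},
    },
}


def package_version() -> str:
    try:
        return _im.version("crosstalksim")
    except _im.PackageNotFoundError:  # running from a source tree
        return "0+unknown"


def _reject(field: str, message: str) -> None:
    raise ValueError(f"config field {field!r}: {message}")


def config_from_dict(data: Mapping[str, Any] | None) -> ScreenConfig:
    """Build a validated ScreenConfig from a plain mapping.

    Missing keys take the standard defaults (T=100, h=0.01, dose=1.0,
    tol=0.05, stimulus=S0); unknown keys are rejected.
    """
    data = dict(data or {})
    data.pop("schema_version", None)
    known = set(CONFIG_SCHEMA["properties"]) - {"schema_version"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; known keys: "
            f"{sorted(known)}"
        )
    kwargs: dict[str, Any] = {}
    if "modules" in data:
        mods = data["modules"]
        if not isinstance(mods, (list, tuple)):
            _reject("modules", "must be a list of integers 0-8")
        for m in mods:
            if not isinstance(m, int) or m not in MODULE_IDS:
                _reject("modules", f"invalid module id {m!r}; expected 0-8")
        kwargs["modules"] = tuple(mods)
    for key in ("dose", "T", "h"):
        if key in data:
            value = data[key]
            if not isinstance(value, (int, float)) or value <= 0:
                _reject(key, f"must be a positive number, got {value!r}")
            kwargs[key] = float(value)
    if "partner_dose" in data:
        pd_ = data["partner_dose"]
        if pd_ is not None and (not isinstance(pd_, (int, float)) or pd_ < 0):
            _reject("partner_dose",
                    f"must be a nonnegative number or null, got {pd_!r}")
        kwargs["partner_dose"] = None if pd_ is None else float(pd_)
    if "tol" in data:
        if not isinstance(data["tol"], (int, float)) or data["tol"] < 0:
            _reject("tol", f"must be a nonnegative number, got {data['tol']!r}")
        kwargs["tol"] = float(data["tol"])
    if "anchor_target" in data:
        try:
            kwargs["anchor_target"] = Species.parse(data["anchor_target"])
        except (ValueError, TypeError) as exc:
            _reject("anchor_target", str(exc))
    if "partner_targets" in data:
        try:
            kwargs["partner_targets"] = tuple(
                Species.parse(t) for t in data["partner_targets"]
            )
        except (ValueError, TypeError) as exc:
            _reject("partner_targets", str(exc))
    if "stimulus" in data:
        if data["stimulus"] not in stimulus_library():
            _reject("stimulus", f"unknown stimulus {data['stimulus']!r}")
        kwargs["stimulus"] = data["stimulus"]
    if "scale_grid" in data:
        grid = data["scale_grid"]
        if (not isinstance(grid, (list, tuple)) or not grid
                or any(not isinstance(s, (int, float)) or s <= 0 for s in grid)):
            _reject("scale_grid", "must be a nonempty list of positive numbers")
        kwargs["scale_grid"] = tuple(float(s) for s in grid)
    if "inhibition" in data:
        if data["inhibition"] not in ("deactivation", "literal"):
            _reject("inhibition", f"must be 'deactivation' or 'literal', "
                    f"got {data['inhibition']!r}")
        kwargs["inhibition"] = data["inhibition"]
    if "params" in data:
        try:
            kwargs["params"] = KineticParameters.from_dict(data["params"])
        except (TypeError, ValueError) as exc:
            _reject("params", str(exc))
    return ScreenConfig(**kwargs)


def load_config(path: str | Path) -> ScreenConfig:
    """Load and validate a YAML or JSON screen configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"could not parse config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError(f"config {path} must be a mapping, got {type(data)}")
    return config_from_dict(data)


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def _manifest(result: ScreenResult, started: str) -> dict:
    config = result.metadata.get("config", {})
    return {
        "schema_version": SCHEMA_VERSION,
        "package_version": package_version(),
        "kind": result.kind,
        "config": config,
        "config_hash": _config_hash(config),
        "n_records": int(len(result.records)),
        "started": started,
        "finished": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "extra_metadata": {
            k: v for k, v in result.metadata.items()
            if k not in ("config", "kind")
        },
    }


def write_results(
    result: ScreenResult,
    out_dir: str | Path,
    fmt: str = "csv",
) -> list[Path]:
    """Write a screen result (records + manifest) into a directory.

    ``fmt`` is "csv", "json" or "both".  Returns the written paths.
    Raises before writing anything if the directory cannot be created.
    """
    if fmt not in ("csv", "json", "both"):
        raise ValueError(f"format must be 'csv', 'json' or 'both', got {fmt!r}")
    out_dir = Path(out_dir)
    started = _dt.datetime.now(_dt.timezone.utc).isoformat()
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write-probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"result directory {out_dir} is not writable: {exc}") from exc

    written: list[Path] = []
    stem = f"{result.kind}_records"
    if fmt in ("csv", "both"):
        csv_path = out_dir / f"{stem}.csv"
        result.records.to_csv(csv_path, index=False)
        written.append(csv_path)
    if fmt in ("json", "both"):
        json_path = out_dir / f"{stem}.json"
        json_path.write_text(json.dumps({
            "kind": result.kind,
            "records": result.records.to_dict(orient="records"),
        }, indent=2, default=_jsonable))
        written.append(json_path)
    manifest_path = out_dir / f"{result.kind}_manifest.json"
    manifest_path.write_text(
        json.dumps(_manifest(result, started), indent=2, default=_jsonable)
    )
    written.append(manifest_path)
    log.info("wrote %d files to %s", len(written), out_dir)
    return written


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_results(out_dir: str | Path, kind: str) -> ScreenResult:
    """Read back a screen result written by ``write_results``.

    Prefers the CSV table; verifies the manifest's config hash matches
    the stored config.
    """
    out_dir = Path(out_dir)
    manifest_path = out_dir / f"{kind}_manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest for kind {kind!r} in {out_dir}")
    manifest = json.loads(manifest_path.read_text())
    if _config_hash(manifest["config"]) != manifest["config_hash"]:
        raise ValueError(
            f"manifest {manifest_path} config hash mismatch; result "
            "directory is inconsistent"
        )
    csv_path = out_dir / f"{kind}_records.csv"
    json_path = out_dir / f"{kind}_records.json"
    if csv_path.exists():
        records = pd.read_csv(
            csv_path,
            dtype={"partner": "string", "label": "string",
                   "direction": "string", "stimulus": "string",
                   "regimen": "string"},
        )
        for col in ("partner", "label", "direction"):
            records[col] = records[col].fillna("").astype(str)
        records["stimulus"] = records["stimulus"].astype(str)
        records["regimen"] = records["regimen"].astype(str)
    elif json_path.exists():
        payload = json.loads(json_path.read_text())
        records = pd.DataFrame(payload["records"], columns=list(RESULT_COLUMNS))
        records["ci"] = pd.to_numeric(records["ci"], errors="coerce")
    else:
        raise FileNotFoundError(f"no records table for kind {kind!r} in {out_dir}")
    metadata = {"kind": kind, "config": manifest["config"]}
    metadata.update(manifest.get("extra_metadata", {}))
    return ScreenResult(kind=kind, records=records, metadata=metadata)


def generate_fixtures(out_dir: str | Path) -> list[Path]:
    """Materialize the canned scenario files used by tests and demos.

    Writes the nine module topologies, the default parameter set, the
    S0-S6 stimulus pairs, and the standard single-drug and pairwise
    combination regimens, each as a schema-versioned JSON document.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def dump(name: str, payload: dict) -> None:
        payload = {"schema_version": SCHEMA_VERSION, **payload}
        path = out_dir / name
        path.write_text(json.dumps(payload, indent=2))
        written.append(path)

    for m in MODULE_IDS:
        topology = build_module(m)
        violations = validate_topology(topology)
        if violations:  # registry bug; fail loudly rather than ship bad fixtures
            raise AssertionError(
                f"registered module {m} is invalid: {violations}"
            )
        dump(f"module_{m}.json", {"topology": topology.to_dict()})

    dump("parameters.json", {"parameters": default_parameters().to_dict()})

    for name, (g1, g2) in stimulus_library().items():
        dump(f"stimulus_{name}.json",
             {"stimulus": {"G1": g1.to_dict(), "G2": g2.to_dict()}})

    anchor = Species.B
    dump("regimen_single_B.json",
         {"regimen": DrugRegimen.single(anchor).to_dict()})
    for partner in (Species.A, Species.B, Species.C, Species.D):
        dump(
            f"regimen_combo_B_{partner.name}.json",
            {"regimen": DrugRegimen.combo([anchor, partner]).to_dict()},
        )
    dump("regimen_untreated.json",
         {"regimen": DrugRegimen.untreated().to_dict()})
    return written
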
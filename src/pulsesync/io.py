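"""Config loading, schema-checked JSON I/O, and run manifests.

Configuration documents are flat JSON objects whose keys mirror the dataclass
fields (:class:`~pulsesync.circuit.CircuitParams`,
:class:`~pulsesync.stimulus.StimulusProgram`,
:class:`~pulsesync.synth.GeneratorConfig`); loading validates field names and
invariants, so a typo fails loudly rather than silently using a default.
Every CLI run writes a manifest recording tool version, timestamp, seed, and
the fully resolved configuration, which suffices to reproduce the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

from . import __version__ as _version
from .circuit import CircuitParams
from .stimulus import StimulusProgram
from .synth import GeneratorConfig

__all__ = [
    "SchemaError",
    "load_params",
    "load_stimulus",
    "load_generator_config",
    "write_json",
    "write_manifest",
]


class SchemaError(ValueError):
    """A config document does not match its schema."""


def _load_flat(path, cls, alias: dict | None = None):
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a JSON object")
    alias = alias or {}
    doc = {alias.get(k, k): v for k, v in doc.items()}
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - fields
    if unknown:
        raise SchemaError(f"{path}: unknown field(s) {sorted(unknown)}; expected from {sorted(fields)}")
    try:
        return cls(**doc)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def load_params(path) -> CircuitParams:
    """Read a CircuitParams JSON document."""
    return _load_flat(path, CircuitParams)


def load_stimulus(path) -> StimulusProgram:
    """Read a StimulusProgram JSON document.

    A ``pulses`` list is given as ``[[start, end, channel], ...]``.
    """
    prog = _load_flat(path, StimulusProgram)
    if prog.pulses:
        prog = dataclasses.replace(
            prog, pulses=tuple((float(s), float(e), str(c)) for s, e, c in prog.pulses)
        )
    return prog


def load_generator_config(path) -> GeneratorConfig:
    """Read a GeneratorConfig JSON document."""
    return _load_flat(path, GeneratorConfig)


def write_json(obj, path) -> None:
    """Serialise a dataclass or plain dict to pretty JSON."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    try:
        import numpy as np

        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, np.generic):
            return x.item()
    except ImportError:  # pragma: no cover
        pass
    return str(x)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir, subcommand: str, config: dict, seed: int | None,
                   outputs: list[str]) -> Path:
    """Write the run manifest next to the outputs; returns its path."""
    out_dir = Path(out_dir)
    manifest = {
        "tool": "pulsesync",
        "version": _version,
        "subcommand": subcommand,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "outputs": outputs,
    }
    path = out_dir / f"{subcommand}_manifest.json"
    write_json(manifest, path)
    return path
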
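"""Metrics record mirroring the competition's ranking criteria: accuracy
against the plaintext oracle, configured security level, per-phase timings,
serialized storage footprint, and per-direction communication cost.

Timings are reported but never asserted (hardware-dependent); storage and
communication are serialized-byte counts, which are deterministic for fixed
inputs and seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

__all__ = ["MetricsReport", "REPORT_SCHEMA", "validate_report", "config_hash"]


def config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class MetricsReport:
    task: str
    accuracy: dict  # {"exact_match": bool|None, "max_abs_deviation": float|None, "compared": int}
    security_bits: int | None
    time_s: dict = field(default_factory=dict)
    storage_bytes: int = 0
    comm_bytes: dict = field(default_factory=dict)  # per direction
    seed: int | None = None
    config: str = ""

    def __post_init__(self) -> None:
        if "exact_match" not in self.accuracy or "compared" not in self.accuracy:
            raise ValueError(
                "a metrics report requires an oracle-accuracy comparison "
                "(keys 'exact_match' and 'compared')"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, default=str) + "\n")
        return path


#: shipped report schema (JSON-Schema subset); see :func:`validate_report`
REPORT_SCHEMA: dict = {
    "type": "object",
    "required": ["task", "accuracy", "security_bits", "time_s",
                 "storage_bytes", "comm_bytes"],
    "properties": {
        "task": {"type": "string"},
        "accuracy": {
            "type": "object",
            "required": ["exact_match", "compared"],
        },
        "security_bits": {"type": ["integer", "null"]},
        "time_s": {"type": "object"},
        "storage_bytes": {"type": "integer", "minimum": 0},
        "comm_bytes": {"type": "object"},
        "seed": {"type": ["integer", "null"]},
        "config": {"type": "string"},
    },
}


def validate_report(report: Mapping[str, Any]) -> None:
    """Check a serialized report against :data:`REPORT_SCHEMA` (minimal
    validator; raises ValueError on the first violation)."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report missing required field {key!r}")
    if not isinstance(report["task"], str):
        raise ValueError("task must be a string")
    acc = report["accuracy"]
    if not isinstance(acc, Mapping) or "exact_match" not in acc or "compared" not in acc:
        raise ValueError("accuracy must contain an oracle comparison")
    if not isinstance(report["storage_bytes"], int) or report["storage_bytes"] < 0:
        raise ValueError("storage_bytes must be a non-negative integer")
    if not isinstance(report["time_s"], Mapping) or not isinstance(
        report["comm_bytes"], Mapping
    ):
        raise ValueError("time_s and comm_bytes must be objects")
    sec = report["security_bits"]
    if sec is not None and not isinstance(sec, int):
        raise ValueError("security_bits must be an integer or null")
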
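"""Append-only structured run log, flushed per event.

Events are written as one JSON object per line (JSON Lines), so the log
remains parseable even after abnormal termination. Schema version 1:
every record has ``schema``, ``stage``, ``event`` and free-form ``data``.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any

SCHEMA_VERSION = 1


def _coerce(obj: Any) -> Any:
    """Fall-back JSON encoder for numpy scalars and arrays."""
    if hasattr(obj, "item"):
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return str(obj)


class RunLog:
    """Collects stage events; optionally mirrors each event to a file."""

    def __init__(self, path: str | Path | None = None) -> None:
        self.events: list[dict[str, Any]] = []
        self._path = Path(path) if path is not None else None
        if self._path is not None:
            self._path.parent.mkdir(parents=True, exist_ok=True)
            self._path.write_text("")

    def record(self, stage: str, event: str, **data: Any) -> dict[str, Any]:
        rec = {
            "schema": SCHEMA_VERSION,
            "time": time.time(),
            "stage": stage,
            "event": event,
            "data": data,
        }
        self.events.append(rec)
        if self._path is not None:
            with self._path.open("a") as fh:
                fh.write(json.dumps(rec, default=_coerce) + "\n")
                fh.flush()
        return rec

    def warning(self, stage: str, message: str, **data: Any) -> dict[str, Any]:
        return self.record(stage, "warning", message=message, **data)

    def warnings(self) -> list[dict[str, Any]]:
        return [e for e in self.events if e["event"] == "warning"]


def load_runlog(path: str | Path) -> list[dict[str, Any]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            out.append(json.loads(line))
    return out
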
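"""Report writers and run manifests.

Every CSV/JSON report is accompanied by a ``manifest.json`` recording
the tool version, the scenario and models run, a hash of the parameter
set, the applied cost-rule ledger and any warnings emitted, so a report
can always be traced back to its inputs. CSV output uses RFC-4180 with
a dot decimal separator regardless of locale; timestamps live only in
the manifest, so payload files are byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .costs import CostRules
from .parameters import ScenarioParameters

logger = logging.getLogger("brcascreen")


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def config_hash(params: ScenarioParameters) -> str:
    payload = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def build_manifest(
    params: ScenarioParameters,
    model_ids: list[int],
    cost_rules: CostRules | None = None,
    warnings: list[str] | None = None,
    extra: dict[str, Any] | None = None,
) -> dict[str, Any]:
    manifest: dict[str, Any] = {
        "tool": "brcascreen",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "scenario": params.scenario_label,
        "models": model_ids,
        "config_hash": config_hash(params),
        "cost_rules": dataclasses.asdict(cost_rules or CostRules()),
        "warnings": warnings or [],
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_report(
    frame: pd.DataFrame,
    out_dir: str | Path,
    stem: str,
    manifest: dict[str, Any],
) -> list[Path]:
    """Write ``<stem>.csv``, ``<stem>.json`` and ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{stem}.csv"
    json_path = out / f"{stem}.json"
    frame.to_csv(csv_path, float_format="%.6g")
    json_path.write_text(
        json.dumps(
            {"manifest_ref": "manifest.json", "data": _frame_payload(frame)},
            indent=2,
        )
        + "\n"
    )
    manifest_path = out / "manifest.json"
    manifest = dict(manifest)
    manifest["files"] = [csv_path.name, json_path.name]
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return [csv_path, json_path, manifest_path]


def _frame_payload(frame: pd.DataFrame) -> dict[str, Any]:
    clean = frame.copy()
    clean.index = [str(i) for i in clean.index]
    return json.loads(clean.to_json(orient="index"))
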
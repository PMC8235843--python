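"""Deterministic human- and machine-readable reports for pipeline results.

Every rendered file embeds the tool version, a hash of the run configuration
and the RNG seed, so a result can always be traced back to its inputs.
Undefined diagnostic metrics render as an en dash in text formats and as
``null`` in JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Optional

from . import __version__
from .diagnostics import RESPONSE_GROUPS, format_metric
from .variants import ValidationError

FORMATS = ("tsv", "json", "markdown")
SCHEMA_VERSION = 1


def config_hash(config: Any) -> str:
    if is_dataclass(config) and not isinstance(config, type):
        config = asdict(config)
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_lines(seed: Optional[int], digest: str, comment: str) -> list[str]:
    return [
        f"{comment} ctdna-kinetics v{__version__}",
        f"{comment} config_hash={digest} seed={seed if seed is not None else 'none'}",
        f"{comment} schema_version={SCHEMA_VERSION}",
    ]


def _diagnostics_rows(blocks: dict) -> list[dict]:
    rows = []
    for name, block in blocks.items():
        table, metrics = block["table"], block["metrics"]
        for direction in ("increase", "decrease"):
            row = {"predictor": name, "direction": direction}
            row.update(table.row(direction))
            rows.append(row)
        rows.append(
            {
                "predictor": name,
                "direction": "metrics",
                "specificity": format_metric(metrics.specificity),
                "sensitivity": format_metric(metrics.sensitivity),
                "ppv": format_metric(metrics.ppv),
                "npv": format_metric(metrics.npv),
                "excluded": ",".join(table.excluded_patients),
            }
        )
    return rows


def _jsonable(value):
    if is_dataclass(value) and not isinstance(value, type):
        return _jsonable(asdict(value))
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple, set)):
        return [_jsonable(v) for v in value]
    if hasattr(value, "item"):  # numpy scalars
        return value.item()
    if hasattr(value, "tolist"):
        return value.tolist()
    if isinstance(value, float) and value != value:
        return None
    return value


def render_report(
    bundle: dict[str, Any],
    out_dir: str | Path,
    fmt: str = "json",
    seed: Optional[int] = None,
    run_config: Any = None,
) -> list[Path]:
    """Write a results bundle (stage name -> result object) to files.

    Stable field ordering and deterministic bytes: rendering the same bundle
    twice yields identical files. Returns the written paths.
    """
    if not bundle:
        raise ValidationError("render_report requires at least one stage result")
    if fmt not in FORMATS:
        raise ValidationError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = config_hash(run_config or {})
    written: list[Path] = []
    if fmt == "json":
        payload = {
            "tool": "ctdna-kinetics",
            "version": __version__,
            "schema_version": SCHEMA_VERSION,
            "seed": seed,
            "config_hash": digest,
            "results": {
                name: _jsonable(_expand(value)) for name, value in bundle.items()
            },
        }
        path = out_dir / "report.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(path)
        return written
    comment = "#" if fmt == "tsv" else ">"
    lines = _header_lines(seed, digest, comment)
    if fmt == "markdown":
        lines.append("")
    for name, value in bundle.items():
        lines.extend(_render_stage(name, value, fmt))
    suffix = "tsv" if fmt == "tsv" else "md"
    path = out_dir / f"report.{suffix}"
    path.write_text("\n".join(lines) + "\n")
    written.append(path)
    return written


def _expand(value):
    import pandas as pd

    if isinstance(value, pd.DataFrame):
        return value.to_dict("records")
    if isinstance(value, dict) and value and all(
        isinstance(v, dict) and "table" in v for v in value.values()
    ):
        return {
            name: {
                "counts": {
                    f"{direction}|{group}": count
                    for (direction, group), count in block["table"].counts.items()
                },
                "excluded_patients": block["table"].excluded_patients,
                "metrics": block["metrics"],
            }
            for name, block in value.items()
        }
    return value


def _render_stage(name: str, value, fmt: str) -> list[str]:
    import pandas as pd

    lines = []
    title = f"## {name}" if fmt == "markdown" else f"# stage: {name}"
    lines.append(title)
    if isinstance(value, pd.DataFrame):
        frame = value
    elif isinstance(value, dict) and value and all(
        isinstance(v, dict) and "table" in v for v in value.values()
    ):
        frame = pd.DataFrame(_diagnostics_rows(value))
    else:
        frame = pd.DataFrame([_jsonable(_expand(value))]) if not isinstance(
            value, list
        ) else pd.DataFrame(_jsonable(value))
    frame = frame.fillna("")
    if fmt == "tsv":
        lines.append(frame.to_csv(sep="\t", index=False).rstrip("\n"))
    else:
        lines.append(_markdown_table(frame))
        lines.append("")
    return lines


def _markdown_table(frame) -> str:
    headers = [str(c) for c in frame.columns]
    rows = ["| " + " | ".join(headers) + " |",
            "| " + " | ".join("---" for _ in headers) + " |"]
    for record in frame.itertuples(index=False):
        rows.append("| " + " | ".join(str(v) for v in record) + " |")
    return "\n".join(rows)
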
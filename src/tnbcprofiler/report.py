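"""Minimal JSON + Markdown run reports.

Analysis entry points collect their key numbers into plain dictionaries;
this module renders them to a machine-readable JSON file and a short
human-readable Markdown summary next to it.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_report"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def _md_value(value) -> str:
    if isinstance(value, float):
        return f"{value:.4g}"
    return str(value)


def write_report(prefix, sections: dict) -> tuple[Path, Path]:
    """Write ``<prefix>.json`` and ``<prefix>.md`` from nested sections.

    ``sections`` maps section title -> dict of named results (numbers,
    Series, DataFrames).  Returns the two paths written.
    """
    prefix = Path(prefix)
    json_path = prefix.with_suffix(".json")
    md_path = prefix.with_suffix(".md")
    payload = _jsonable(sections)
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    lines = ["# Analysis report", ""]
    for title, content in sections.items():
        lines.append(f"## {title}")
        lines.append("")
        if isinstance(content, pd.DataFrame):
            lines.append(content.to_markdown())
        elif isinstance(content, dict):
            for key, value in content.items():
                if isinstance(value, pd.DataFrame):
                    lines.append(f"**{key}**")
                    lines.append("")
                    lines.append(value.to_markdown())
                else:
                    lines.append(f"- {key}: {_md_value(_jsonable(value))}")
        else:
            lines.append(_md_value(_jsonable(content)))
        lines.append("")
    md_path.write_text("\n".join(lines))
    return json_path, md_path
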
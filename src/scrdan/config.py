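"""Flat TOML configs mirroring the dataclass field names.

Sections: [simulate], [preprocess], [model], [loss], [train]. CLI flags
override file values, which override the dataclass defaults. Every run
writes its resolved configuration back out as TOML so it can be re-fed via
--config to reproduce the run.
"""

from __future__ import annotations

import tomllib
from dataclasses import fields, is_dataclass
from pathlib import Path

SECTIONS = ("simulate", "preprocess", "model", "loss", "train")


def load_config(path) -> dict[str, dict]:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    unknown = set(cfg) - set(SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple, frozenset, set)):
        items = sorted(v) if isinstance(v, (set, frozenset)) else v
        return "[" + ", ".join(_toml_value(x) for x in items) + "]"
    raise TypeError(f"cannot serialise {type(v).__name__} to TOML")


def dump_config(sections: dict[str, object], path) -> None:
    """Write dataclasses (or plain dicts) as a flat TOML file."""
    lines: list[str] = []
    for name, obj in sections.items():
        if obj is None:
            continue
        lines.append(f"[{name}]")
        if is_dataclass(obj):
            items = [(f.name, getattr(obj, f.name)) for f in fields(obj)]
        else:
            items = list(obj.items())
        for key, value in items:
            if value is None:
                continue
            lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def build(dataclass_type, file_section: dict | None, overrides: dict | None):
    """Dataclass instance from defaults < config file < CLI overrides."""
    kwargs = dict(file_section or {})
    for key, value in (overrides or {}).items():
        if value is not None:
            kwargs[key] = value
    valid = {f.name for f in fields(dataclass_type)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ValueError(
            f"unknown {dataclass_type.__name__} fields: {sorted(unknown)}"
        )
    return dataclass_type(**kwargs)
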
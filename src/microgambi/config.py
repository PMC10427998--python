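"""Flat ``key = value`` configuration files for the CLI.

One key per line, ``#`` comments; keys mirror the fields of
:class:`~microgambi.index.IndexConfig` and
:class:`~microgambi.simulate.CommunitySpec`.  Vector values
(``class_boundaries``, ``egiii_read_fraction_per_station``) are
comma-separated.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Union

from .index import IndexConfig
from .simulate import CommunitySpec

__all__ = ["parse_flat_config", "index_config_from_mapping",
           "community_spec_from_mapping"]


def parse_flat_config(source: Union[str, Path]) -> dict[str, str]:
    text = Path(source).read_text(encoding="utf-8") if "\n" not in str(source) else str(source)
    out: dict[str, str] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {ln}: expected 'key = value', got {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _coerce(raw: str, typ):
    if typ is int:
        return int(raw)
    if typ is float:
        return float(raw)
    return raw


def index_config_from_mapping(mapping: dict[str, str], **overrides) -> IndexConfig:
    kwargs: dict = {}
    for f in fields(IndexConfig):
        if f.name not in mapping:
            continue
        raw = mapping[f.name]
        if f.name == "class_boundaries":
            kwargs[f.name] = tuple(float(x) for x in raw.split(","))
        elif f.name == "denominator_policy":
            kwargs[f.name] = raw
        else:
            kwargs[f.name] = float(raw)
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return IndexConfig(**kwargs)


def community_spec_from_mapping(mapping: dict[str, str], **overrides) -> CommunitySpec:
    kwargs: dict = {}
    for f in fields(CommunitySpec):
        if f.name not in mapping:
            continue
        raw = mapping[f.name]
        if f.name == "egiii_read_fraction_per_station":
            kwargs[f.name] = tuple(float(x) for x in raw.split(","))
        elif f.name in ("not_assigned_read_share", "not_in_list_read_share",
                        "dispersion"):
            kwargs[f.name] = float(raw)
        else:
            kwargs[f.name] = int(raw)
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return CommunitySpec(**kwargs)
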
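"""JSON (de)serialization for result dataclasses.

Result records are flat dataclasses of floats, strings, enums, tuples and
float-keyed dicts.  ``record_to_dict`` / ``record_from_dict`` convert between
the dataclass and a JSON-compatible dict, using the declared field types to
restore enums, tuples and numeric dict keys on the way back in.
"""

from __future__ import annotations

import dataclasses
import enum
import typing
from typing import Any


def record_to_dict(record: Any) -> dict:
    """Convert a result dataclass to a JSON-compatible dict."""
    return {f.name: _encode(getattr(record, f.name)) for f in dataclasses.fields(record)}


def _encode(value: Any) -> Any:
    if isinstance(value, enum.Enum):
        return value.value
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return record_to_dict(value)
    if isinstance(value, dict):
        return {str(k): _encode(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_encode(v) for v in value]
    if hasattr(value, "item"):  # numpy scalar
        return value.item()
    return value


def record_from_dict(cls: type, data: dict) -> Any:
    """Rebuild a dataclass instance of ``cls`` from ``record_to_dict`` output.

    Fields with ``init=False`` (derived quantities) are skipped; the
    dataclass recomputes them in ``__post_init__``.
    """
    hints = typing.get_type_hints(cls)
    kwargs = {}
    for f in dataclasses.fields(cls):
        if not f.init or f.name not in data:
            continue
        kwargs[f.name] = _decode(hints[f.name], data[f.name])
    return cls(**kwargs)


def _decode(hint: Any, value: Any) -> Any:
    origin = typing.get_origin(hint)
    args = typing.get_args(hint)
    if origin is typing.Union:  # Optional[...]
        non_none = [a for a in args if a is not type(None)]
        if value is None:
            return None
        return _decode(non_none[0], value)
    if isinstance(hint, type) and issubclass(hint, enum.Enum):
        return hint(value)
    if isinstance(hint, type) and dataclasses.is_dataclass(hint):
        return record_from_dict(hint, value)
    if origin is tuple:
        elem = args[0] if args else float
        if len(args) == 2 and args[1] is Ellipsis:
            return tuple(_decode(elem, v) for v in value)
        return tuple(_decode(a, v) for a, v in zip(args, value))
    if origin is dict:
        kt, vt = args if args else (str, float)
        return {kt(k): _decode(vt, v) for k, v in value.items()}
    if hint is float:
        return float(value)
    if hint is int:
        return int(value)
    return value
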
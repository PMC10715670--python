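"""JSON (de)serialization for model parameter objects.

Files carry a ``"type"`` tag so mixed tooling can round-trip any of the
parameter containers; matrices are stored row-major as nested lists.
"""

from __future__ import annotations

import json

from .core import GeneralJointParams, PairParams
from .mg import MGParams
from .tuning import ContrastTuning

__all__ = ["read_params", "write_params"]

_TYPES = {
    "PairParams": PairParams,
    "ContrastTuning": ContrastTuning,
    "GeneralJointParams": GeneralJointParams,
    "MGParams": MGParams,
}


def write_params(obj, path) -> None:
    name = type(obj).__name__
    if name not in _TYPES:
        raise TypeError(f"cannot serialize {name}; expected one of {sorted(_TYPES)}")
    payload = {"type": name, **obj.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_params(path):
    with open(path) as fh:
        payload = json.load(fh)
    name = payload.pop("type", None)
    if name not in _TYPES:
        raise ValueError(f"{path}: missing or unknown 'type' tag {name!r}")
    return _TYPES[name].from_dict(payload)
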
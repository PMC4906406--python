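"""Small shared helpers: seed fan-out, hashing, validation errors."""

from __future__ import annotations

import hashlib
import json
from typing import Any


class ValidationError(ValueError):
    """Input violates a domain invariant (bad geometry, counts, labels...)."""


class FormatError(ValueError):
    """A file is structurally malformed (missing column, bad field)."""


class NotEvaluableError(ValueError):
    """A sample/patient does not meet the preconditions of an analysis."""


def derive_seed(seed: int, *tokens: Any) -> int:
    """Derive a stage-local seed from a global seed and a name.

    Stable across runs and platforms; inserting a new stage must not
    reshuffle the randomness of unrelated stages, so each stage draws
    from its own derived stream. Result is < 2**31.
    """
    payload = json.dumps([int(seed), *[str(t) for t in tokens]]).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def config_hash(config: dict) -> str:
    """Order-independent hash of a JSON-serialisable config mapping."""
    canonical = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canonical).hexdigest()[:16]
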
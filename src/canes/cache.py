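"""Content-addressed result caching.

Repeated invocations with identical inputs and seed return byte-identical
reports without recomputation.  Keys hash the command, the resolved
configuration, and the full content of every input file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path


def cache_key(command: str, config: dict, input_paths=()) -> str:
    h = hashlib.sha256()
    h.update(command.encode())
    h.update(json.dumps(config, sort_keys=True, default=str).encode())
    for p in input_paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()[:24]


def cached_run(cache_dir, key: str, compute, suffix: str = ".out"):
    """Return ``compute()`` bytes, memoized on disk under ``key``.

    Returns ``(payload_bytes, hit)``.
    """
    if cache_dir is None:
        return compute(), False
    path = Path(cache_dir) / f"{key}{suffix}"
    if path.exists():
        return path.read_bytes(), True
    payload = compute()
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(payload)
    return payload, False
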
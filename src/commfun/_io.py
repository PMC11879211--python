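"""CSV round-tripping with provenance headers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, seed=None, cfg_hash: str | None = None) -> None:
    """Write a table with a comment header carrying seed and config hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# commfun seed={seed} config={cfg_hash}\n"
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
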
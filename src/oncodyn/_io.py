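"""CSV/JSON output helpers with provenance headers.

Every output file starts with '#'-prefixed comment lines carrying the
package version, the master seed and a short hash of the resolved
configuration, so a fixture or result can be traced back to its recipe.
Dialect: comma-separated, '.' decimal.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["config_hash", "write_csv", "read_csv", "write_json"]


def config_hash(config: dict | str) -> str:
    """Short deterministic hash of a resolved configuration."""
    text = config if isinstance(config, str) else json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _header_lines(meta: dict) -> str:
    lines = [f"# oncodyn {__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def write_csv(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta or {}))
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(path, obj: dict, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_provenance": {"oncodyn": __version__, **(meta or {})}, **obj}
    path.write_text(json.dumps(payload, indent=2, default=str))
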
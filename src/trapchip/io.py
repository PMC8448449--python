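"""Configuration and table/image I/O with provenance.

Configs are YAML or JSON (equivalent structure).  CSV tables carry a
``# config_hash=...`` first line naming the configuration that generated
them; TIFF images store the hash in their description tag; JSON summaries
carry it as a field.  All formats round-trip losslessly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd
import tifffile
import yaml

__all__ = [
    "load_config",
    "save_config",
    "config_hash",
    "write_table",
    "read_table",
    "write_image",
    "read_image",
    "write_json",
    "read_json",
]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path, expected_columns: list[str] | None = None
               ) -> pd.DataFrame:
    """Read a provenance-stamped CSV.

    Missing expected columns are an error listing them; unknown extra
    columns are tolerated with a warning (forward compatibility).
    """
    df = pd.read_csv(path, comment="#")
    if expected_columns is not None:
        missing = [c for c in expected_columns if c not in df.columns]
        if missing:
            raise ValueError(f"table {path} lacks columns {missing}")
        extra = [c for c in df.columns if c not in expected_columns]
        if extra:
            warnings.warn(f"table {path} has unknown columns {extra}", stacklevel=2)
    return df


def table_hash(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("# config_hash="):
        return first.split("=", 1)[1]
    return ""


def write_image(img, path: str | Path, config_hash: str = "") -> None:
    tifffile.imwrite(str(path), img, description=f"config_hash={config_hash}")


def read_image(path: str | Path):
    return tifffile.imread(str(path))


def write_json(obj: dict, path: str | Path, config_hash: str = "") -> None:
    payload = dict(obj)
    payload["config_hash"] = config_hash
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
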
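"""File I/O: long-format CSV, YAML/JSON configuration, run manifests."""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .data import LATENT_COLUMN, SCHEMA, LongTableDataset
from .exceptions import InvalidArgumentError


def write_long_csv(data: LongTableDataset, path: str | Path) -> Path:
    path = Path(path)
    cols = list(SCHEMA) + ([LATENT_COLUMN] if data.has_latent else [])
    data.df[cols].to_csv(path, index=False, float_format="%.17g")
    return path


def read_long_csv(path: str | Path) -> LongTableDataset:
    """Strict reader for the documented schema.

    Extra columns are tolerated with a warning; missing values are an error
    listing offending rows; status must parse as exactly {0, 1}.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in SCHEMA if c not in df.columns]
    if missing_cols:
        raise InvalidArgumentError(f"{path}: missing required columns {missing_cols}")
    extra = [c for c in df.columns if c not in SCHEMA and c != LATENT_COLUMN]
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {extra}", stacklevel=2)
        df = df.drop(columns=extra)
    core = df[list(SCHEMA)]
    if core.isna().any().any():
        bad = (core.isna().any(axis=1)).to_numpy().nonzero()[0] + 2  # 1-based + header
        raise InvalidArgumentError(
            f"{path}: missing values in file lines {bad.tolist()} (data must be balanced)"
        )
    status = df["status_y2"].to_numpy()
    if not np.isin(status, [0, 1]).all():
        bad_vals = sorted(set(status) - {0, 1})
        raise InvalidArgumentError(f"{path}: status_y2 values outside {{0,1}}: {bad_vals}")
    df["status_y2"] = df["status_y2"].astype(int)
    return LongTableDataset(df, {"source": str(path)})


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict[str, Any]:
    """Single YAML/JSON config with sections {data, model, priors, sampler, run}."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise InvalidArgumentError(f"{path}: config must be a mapping")
    return cfg


class RunManifest:
    """One manifest per CLI run: config hash, seeds, inputs, outputs."""

    def __init__(self, stage: str, config: dict[str, Any] | None = None):
        self.payload: dict[str, Any] = {
            "stage": stage,
            "package_version": _version(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "config": config or {},
            "config_hash": hashlib.sha256(
                json.dumps(config or {}, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "inputs": {},
            "outputs": {},
            "seeds": {},
        }

    def add_input(self, name: str, path: str | Path) -> None:
        self.payload["inputs"][name] = {"path": str(path), "sha256": file_digest(path)}

    def add_output(self, name: str, path: str | Path) -> None:
        p = Path(path)
        entry: dict[str, Any] = {"path": str(p)}
        if p.is_file():
            entry["sha256"] = file_digest(p)
        self.payload["outputs"][name] = entry

    def add_seed(self, name: str, seed: int) -> None:
        self.payload["seeds"][name] = int(seed)

    def write(self, path: str | Path) -> Path:
        p = Path(path)
        p.write_text(json.dumps(self.payload, indent=1))
        return p


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("jointbhm")
    except Exception:  # pragma: no cover
        return "unknown"
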
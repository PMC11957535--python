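"""Readers, writers, configuration, manifests, and logging.

Trial tables round-trip byte-stably through CSV with the canonical header;
times are serialized in ms with fixed 3-digit precision, ages as integer
months, conditions as literal ``sync``/``async`` strings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ibsense.exceptions import ConfigurationError, SchemaError
from ibsense.synth import TRIAL_TABLE_COLUMNS

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "write_summaries",
    "load_config",
    "write_manifest",
    "setup_logging",
]

_NUMERIC_COLS = ("trial_index", "age_group", "looking_time_ms", "trial_duration_ms")
_KNOWN_CONFIG_KEYS = {
    "task",
    "order_mode",
    "seed",
    "synth",
    "paradigm",
    "preprocess",
    "multiverse",
    "output_dir",
    "log_level",
}


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table with the canonical header and 3-decimal times."""
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"table is missing columns: {', '.join(missing)}")
    out = table[TRIAL_TABLE_COLUMNS].copy()
    for col in ("looking_time_ms", "trial_duration_ms"):
        out[col] = out[col].map(lambda v: f"{float(v):.3f}")
    out["technical_error"] = out["technical_error"].map(lambda v: str(bool(v)))
    out.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    """Read a canonical trial-table CSV; malformed rows are reported by line.

    Raises :class:`SchemaError` naming any missing column, and ``ValueError``
    listing the 1-based file line numbers of rows with non-numeric values.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    raw = raw[TRIAL_TABLE_COLUMNS]
    bad_lines = []
    converted = {}
    for col in _NUMERIC_COLS:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & (raw[col] != "")
        bad_lines.extend((raw.index[bad] + 2).tolist())  # +1 header, +1 one-based
        converted[col] = vals
    if bad_lines:
        lines = ", ".join(map(str, sorted(set(bad_lines))))
        raise ValueError(f"non-numeric values on line(s): {lines}")
    out = raw.copy()
    for col in ("trial_index", "age_group"):
        out[col] = converted[col].astype(int)
    for col in ("looking_time_ms", "trial_duration_ms"):
        out[col] = converted[col].astype(float)
    out["technical_error"] = out["technical_error"].str.lower().isin(("true", "1"))
    return out


def write_summaries(summaries: pd.DataFrame, path) -> None:
    out = summaries.copy()
    for col in ("mean_lt_sync_ms", "mean_lt_async_ms"):
        out[col] = out[col].map(lambda v: f"{float(v):.3f}")
    out["discrimination_score"] = out["discrimination_score"].map(
        lambda v: f"{float(v):.6f}"
    )
    out.to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML run configuration, rejecting unknown top-level keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(cfg) - _KNOWN_CONFIG_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return cfg


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(path, config: dict, seed) -> dict:
    """Write a reproducibility manifest (config hash, seed, versions)."""
    import scipy

    from ibsense import __version__

    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "versions": {
            "ibsense": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def setup_logging(level: str = "INFO", logfile=None) -> logging.Logger:
    """Structured logs (timestamp, stage, message) to stderr and optionally a file."""
    logger = logging.getLogger("ibsense")
    logger.setLevel(getattr(logging, level.upper()))
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger
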
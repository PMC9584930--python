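"""File formats and run configuration.

Tables are UTF-8 TSV with a header row; missing responses are written as the
literal token ``NA``.  A session table is long-format with columns
``participant``, ``run``, ``trial``, ``item``, ``response``, ``feedback``;
similarity matrices are square labelled TSV.  Run configurations are
YAML/JSON mappings validated against a documented default schema.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .design import ExperimentDesign, PRESETS
from .population import ReferencePoint, SimilarityMatrix

SESSION_COLUMNS = ("participant", "run", "trial", "item", "response", "feedback")


def write_session(session: pd.DataFrame, path) -> None:
    session.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_session(path, design: ExperimentDesign | None = None) -> pd.DataFrame:
    """Read and validate a session table.

    Raises ``ValueError`` naming the offending line numbers (1-based, header
    is line 1) for out-of-scale values or duplicate (participant, run, trial)
    keys.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing_cols = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    lines = df.index + 2  # header is line 1

    dup = df.duplicated(subset=["participant", "run", "trial"], keep=False)
    if dup.any():
        raise ValueError(f"{path}: duplicate (participant, run, trial) keys on lines {list(lines[dup])}")
    if df["feedback"].isna().any():
        bad = lines[df["feedback"].isna()]
        raise ValueError(f"{path}: feedback missing on lines {list(bad)}")
    if design is not None:
        lo, hi = design.scale_min, design.scale_max
        for col in ("response", "feedback"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & ((vals < lo) | (vals > hi))
            if bad.any():
                raise ValueError(
                    f"{path}: {col} outside scale [{lo}, {hi}] on lines {list(lines[bad])}"
                )
    return df


def write_matrix(sim: SimilarityMatrix | np.ndarray, path, item_ids=None) -> None:
    """Square labelled TSV for similarity matrices."""
    if isinstance(sim, SimilarityMatrix):
        item_ids = item_ids or sim.item_ids
        sim = sim.sim
    labels = list(item_ids) if item_ids else [f"item{k+1:02d}" for k in range(len(sim))]
    pd.DataFrame(sim, index=labels, columns=labels).to_csv(path, sep="\t", index_label="item")


def read_matrix(path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(df.to_numpy(dtype=float), tuple(df.columns))


def write_reference_point(rp: ReferencePoint, path) -> None:
    ids = rp.item_ids or tuple(f"item{k+1:02d}" for k in range(len(rp.rp)))
    pd.DataFrame({"item": ids, "rp": rp.rp, "source": rp.source}).to_csv(
        path, sep="\t", index=False
    )


def read_reference_point(path) -> ReferencePoint:
    df = pd.read_csv(path, sep="\t")
    source = str(df["source"].iloc[0]) if "source" in df else "population"
    return ReferencePoint(df["rp"].to_numpy(float), source, tuple(df["item"]))


# ---------------------------------------------------------------------------
# configuration

#: Full default configuration; every key is documented here and unknown keys
#: are rejected.
CONFIG_DEFAULTS: dict[str, Any] = {
    "preset": "exp1",          # experiment layout (exp1..exp5)
    "seed": 0,                 # master seed for all randomness
    "models": ["M1", "M2", "M3", "M4", "M5"],
    "population": {
        "n_raters": 300,               # raters behind SIM and RP
        "within_factor_loading": 0.6,  # latent loading lambda in (0, 1)
        "valence_fraction": None,      # None = preset default
    },
    "fitting": {
        "xatol": 1e-6,
        "fatol": 1e-6,
        "maxfev": 2000,
        "n_starts": 1,
    },
    "comparison": {
        "alpha0": 1.0,
        "n_mc_samples": 1_000_000,
    },
    "validation": {
        "n_reps": 200,
        "param_low": 0.2,    # confusion draws; recovery uses recovery_low/high
        "param_high": 0.8,
        "recovery_low": 0.0,
        "recovery_high": 1.0,
        "noise_sd": 1.0,
    },
    "simulate": {
        "model": "M5",
        "alpha": 0.3,
        "gamma": 0.3,
        "start": None,        # None = scale midpoint
        "noise_sd": 1.0,
        "n_agents": 10,
        "missing_rate": 0.0,  # fraction of responses blanked to NA
    },
}


def _merge(defaults: Mapping, given: Mapping, path_: str = "") -> dict:
    out = dict(defaults)
    for key, val in given.items():
        where = f"{path_}{key}"
        if key not in defaults:
            raise ValueError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict) and defaults[key]:
            if not isinstance(val, Mapping):
                raise ValueError(f"config key {where} must be a mapping")
            out[key] = _merge(defaults[key], val, where + ".")
        else:
            out[key] = val
    return out


def validate_config(cfg: Mapping) -> dict:
    """Fill defaults and check bounds; raises ``ValueError`` on bad input."""
    full = _merge(CONFIG_DEFAULTS, cfg)
    if full["preset"] not in PRESETS:
        raise ValueError(f"preset must be one of {PRESETS}")
    v = full["validation"]
    for lo_k, hi_k in (("param_low", "param_high"), ("recovery_low", "recovery_high")):
        lo, hi = v[lo_k], v[hi_k]
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"{lo_k}/{hi_k} must satisfy 0 <= low <= high <= 1")
    if v["noise_sd"] < 0 or full["simulate"]["noise_sd"] < 0:
        raise ValueError("noise_sd must be non-negative")
    lam = full["population"]["within_factor_loading"]
    if not (0.0 <= lam < 1.0):
        raise ValueError("within_factor_loading must lie in [0, 1)")
    if full["fitting"]["maxfev"] < 1:
        raise ValueError("maxfev must be positive")
    return full


def load_config(path) -> dict:
    """Load and validate a YAML/JSON run configuration."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return validate_config(data)


def dump_config(cfg: Mapping, path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(cfg), sort_keys=True), encoding="utf-8")


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a configuration (for logging/provenance)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
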
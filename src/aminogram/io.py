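"""Delimited-text I/O, run configuration and provenance metadata.

Input tables are long-format delimited text with one row per plasma
sample: subject_id, group, health_state, mmtt, time_min, fagbh (F, µg/mL
amine-group equivalents before hydrolysis) and fagah (T, after).  Output
tables are plain CSV with a ``#``-prefixed metadata header recording the
software version, seed and a configuration hash, so that identical runs
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .amine_model import ResidueTable
from .auc_pipeline import REQUIRED_COLUMNS
from .estimator import WPolicy

__all__ = [
    "read_assay_table",
    "write_output",
    "read_output",
    "RunConfig",
    "load_config",
    "load_scenario",
]

logger = logging.getLogger("aminogram")

_NUMERIC = ("time_min", "fagbh", "fagah")


def read_assay_table(path, delimiter: str = ",", strict: bool = False) -> pd.DataFrame:
    """Read and validate an assay-record table.

    Header matching is case-insensitive.  Rows with non-numeric readings,
    F <= 0 or T <= 0 are rejected; each rejection is logged with its
    1-based file line number.  With ``strict=True`` any rejected row
    raises instead.

    Raises
    ------
    ValueError
        If required columns are missing (all missing names are listed).
    """
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype=str,
                     skip_blank_lines=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    df = df[list(REQUIRED_COLUMNS)]
    reasons = pd.Series("", index=df.index)
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        reasons[bad & (reasons == "")] = f"non-numeric {col}"
        df[col] = vals
    ok = reasons == ""
    bad_F = ok & (df["fagbh"] <= 0)
    reasons[bad_F] = "fagbh (F) must be > 0"
    bad_T = (reasons == "") & (df["fagah"] <= 0)
    reasons[bad_T] = "fagah (T) must be > 0"
    rejected = df.index[reasons != ""]
    for i in rejected:
        msg = f"{path}: line {i + 2}: row rejected ({reasons[i]})"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    return df.drop(index=rejected).reset_index(drop=True)


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_output(
    table: pd.DataFrame,
    path,
    metadata: dict | None = None,
    float_precision: int = 6,
) -> None:
    """Write a result table as CSV with a provenance comment header.

    Column order and float formatting are fixed, so equal inputs and
    configuration give byte-identical files.
    """
    path = Path(path)
    meta = {"software": f"aminogram {__version__}"}
    if metadata:
        meta.update(metadata)
    try:
        with open(path, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            table.to_csv(fh, index=False, float_format=f"%.{float_precision}g")
    except OSError as e:
        raise OSError(f"failed writing output to {path}: {e}") from e


def read_output(path, delimiter: str = ",") -> pd.DataFrame:
    """Read back a table written by :func:`write_output`."""
    return pd.read_csv(path, sep=delimiter, comment="#")


@dataclass(frozen=True)
class EstimatorConfig:
    method: str = "quadrature"
    resolution: int = 400
    n_samples: int = 1_000_000
    seed: int | None = None
    alpha_max: float = 0.3
    beta_max: float = 0.3

    def kwargs(self) -> dict:
        if self.method == "mc" and self.seed is None:
            raise ValueError("estimator method 'mc' requires an explicit seed")
        return {
            "method": self.method, "resolution": self.resolution,
            "n_samples": self.n_samples, "seed": self.seed,
            "alpha_max": self.alpha_max, "beta_max": self.beta_max,
        }


@dataclass(frozen=True)
class RunConfig:
    """Run-wide settings loaded from a single YAML file."""

    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    w_policy: WPolicy = field(default_factory=WPolicy)
    mode: str = "pointwise"
    residue_table: ResidueTable = field(default_factory=ResidueTable)
    log_level: str = "INFO"

    def hash(self) -> str:
        d = {
            "estimator": asdict(self.estimator),
            "w_policy": asdict(self.w_policy),
            "mode": self.mode,
            "two_amine_residues": sorted(self.residue_table.two_amine_residues),
        }
        return config_hash(d)


def load_config(path=None) -> RunConfig:
    """Load a RunConfig from YAML; missing keys fall back to defaults.

    Recognised keys: ``estimator`` (method, resolution, n_samples, seed,
    alpha_max, beta_max), ``w_policy`` (below_min_action,
    above_max_action), ``mode``, ``two_amine_residues`` (list of
    one-letter codes), ``log_level``.
    """
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    est = EstimatorConfig(**raw.get("estimator", {}))
    pol = WPolicy(**raw.get("w_policy", {}))
    table = ResidueTable()
    if "two_amine_residues" in raw:
        table = ResidueTable(two_amine_residues=frozenset(raw["two_amine_residues"]))
    return RunConfig(
        estimator=est, w_policy=pol,
        mode=raw.get("mode", "pointwise"),
        residue_table=table,
        log_level=raw.get("log_level", "INFO"),
    )


def load_scenario(path):
    """Load a simulation scenario from YAML (keys = SimScenario fields)."""
    from .synthetic import SimScenario

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "schedule" in raw:
        raw["schedule"] = tuple(float(t) for t in raw["schedule"])
    return SimScenario(**raw)
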
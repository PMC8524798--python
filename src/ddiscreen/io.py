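"""CSV schemas, run manifests and file digests.

All pipeline artefacts are plain CSV with JSON sidecars so that a clinical
epidemiology audience can audit every number; each output directory carries
exactly one ``manifest.json`` recording the command, config hash, rule-set
version, seeds and input digests.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .detection import TIMEPOINTS

__all__ = [
    "SchemaError",
    "read_medications",
    "read_covariates",
    "file_sha256",
    "write_manifest",
]

MEDICATION_COLUMNS = ["patient_id", "timepoint", "atc_code"]


class SchemaError(ValueError):
    """Input file does not conform to the expected CSV schema."""


def read_medications(path: str | Path) -> pd.DataFrame:
    """Read a long-format medication CSV (patient_id, timepoint, atc_code).

    Raises :class:`SchemaError` naming the missing column or the offending
    rows for unknown timepoint tokens.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MEDICATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {MEDICATION_COLUMNS}"
        )
    bad = df.loc[~df["timepoint"].isin(TIMEPOINTS)]
    if not bad.empty:
        rows = (bad.index[:5] + 2).tolist()  # +2: header line and 1-basing
        raise SchemaError(
            f"{path}: unknown timepoint token(s) {sorted(bad['timepoint'].unique())} "
            f"at row(s) {rows}; allowed tokens: {list(TIMEPOINTS)}"
        )
    if df[MEDICATION_COLUMNS].isna().any().any():
        raise SchemaError(f"{path}: empty cells in required columns")
    return df[MEDICATION_COLUMNS]


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'patient_id'")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    *,
    seed: int | None = None,
    config: dict | None = None,
    ruleset_version: str | None = None,
    inputs: dict[str, str | Path] | None = None,
    outputs: list[str] | None = None,
) -> Path:
    """Write the run manifest JSON for an output directory."""
    from . import __version__

    manifest = {
        "command": command,
        "tool_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config_hash": (
            hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest()
            if config is not None else None
        ),
        "ruleset_version": ruleset_version,
        "inputs": {
            name: file_sha256(p) for name, p in (inputs or {}).items()
        },
        "outputs": outputs or [],
    }
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return out
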
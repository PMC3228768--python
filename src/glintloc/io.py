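"""Tabular readers/writers and run manifests.

All declared interfaces are UTF-8 CSV with a header row and '.' decimal
separator.  Numeric columns round-trip losslessly (shortest-repr floats).
A run manifest (JSON) written alongside every output directory records the
configuration snapshot, root seed, package version, timestamps and an
inventory of output files with row counts — enough to re-execute the run
bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

__all__ = ["write_results", "read_results", "RunManifest"]


def write_results(table: pd.DataFrame, path: str | Path, schema: list[str] | None = None) -> None:
    """Write a results table as CSV; ``schema`` (if given) must match the columns."""
    if schema is not None:
        missing = [c for c in schema if c not in table.columns]
        if missing:
            raise ValueError(f"table is missing declared columns: {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | Path, schema: list[str] | None = None) -> pd.DataFrame:
    """Read a results CSV; raises ``ValueError`` on a missing header column."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty results file: {path}") from exc
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"results file {path} is missing columns: {missing}")
    return df


@dataclass
class RunManifest:
    """Record of one experiment run, sufficient for bit-identical re-execution."""

    config: dict
    seed: int
    version: str
    started_utc: str = ""
    finished_utc: str = ""
    outputs: dict = field(default_factory=dict)

    def start(self) -> "RunManifest":
        self.started_utc = datetime.now(timezone.utc).isoformat()
        return self

    def finish(self) -> "RunManifest":
        self.finished_utc = datetime.now(timezone.utc).isoformat()
        return self

    def record(self, path: str | Path, table: pd.DataFrame) -> None:
        self.outputs[Path(path).name] = int(len(table))

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = directory / "manifest.json"
        out.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")
        return out

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
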
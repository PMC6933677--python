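"""Output writers and run manifests for reproducible CLI runs."""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import pandas as pd


def _version() -> str:
    try:
        return metadata.version("celldiv")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunManifest:
    """Record of one CLI invocation: parameters, seed, tolerances, outputs.

    Re-running the same command with the manifest's parameters reproduces
    deterministic outputs bit-identically (stochastic outputs identically
    given the seed).
    """

    command: str
    params: dict
    seed: int | None = None
    tolerances: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    started_at: str = field(default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat())
    version: str = field(default_factory=_version)

    def add_output(self, path: Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: Path) -> None:
        path = Path(path)
        self.outputs.append(str(path))
        path.write_text(
            json.dumps(
                {
                    "command": self.command,
                    "params": self.params,
                    "seed": self.seed,
                    "tolerances": self.tolerances,
                    "version": self.version,
                    "outputs": self.outputs,
                    "started_at": self.started_at,
                },
                indent=2,
            )
            + "\n"
        )


def write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
    if manifest is not None:
        manifest.add_output(path)
    return path
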
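"""Delimited-text tables with a JSON metadata header, and run configs.

Every exported table is a plain CSV preceded by '#'-prefixed lines holding a
single JSON object (parameters, tolerances, provenance).  Output is
deterministic: a fixed float format makes identical runs byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .fitness import DiffusionPair
from .rates import BioParams, Environment
from .solver import SolverConfig, TraitGrid

__all__ = ["write_table", "read_table", "load_config"]

FLOAT_FORMAT = "%.17g"


def write_table(path: str | Path, df: pd.DataFrame, metadata: dict) -> None:
    """Write a CSV with a '#'-prefixed JSON metadata header."""
    path = Path(path)
    header = "".join(f"# {line}\n" for line in
                     json.dumps(metadata, indent=1, sort_keys=True).splitlines())
    with open(path, "w", newline="\n") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a table written by :func:`write_table`; returns (frame, meta)."""
    import io as _io

    path = Path(path)
    lines = path.read_text().splitlines(keepends=True)
    meta_lines = [ln[1:].strip() for ln in lines if ln.startswith("#")]
    body = "".join(ln for ln in lines if not ln.startswith("#"))
    df = pd.read_csv(_io.StringIO(body))
    meta = json.loads("\n".join(meta_lines)) if meta_lines else {}
    return df, meta


def load_config(path: str | Path) -> tuple[SolverConfig, BioParams]:
    """Load a structured run config (YAML with sections bio, environment,
    solver); unspecified fields keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    bio_raw = dict(raw.get("bio", {}))
    bio = BioParams(**bio_raw)
    env = Environment(**dict(raw.get("environment", {})))
    sol = dict(raw.get("solver", {}))
    grid_raw = sol.pop("grid", {})
    grid = TraitGrid(**grid_raw) if grid_raw else TraitGrid.default()
    diff_raw = sol.pop("diffusion", {})
    diff = DiffusionPair(**diff_raw) if diff_raw else DiffusionPair()
    config = SolverConfig(grid=grid, diff=diff, env=env, **sol)
    return config, bio
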
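"""Report writers and run manifests.

Every table a simulation campaign publishes should be regenerable
bit-identically: tables are written with a fixed column order and fixed
decimal precision, and each write can be accompanied by a
:class:`RunManifest` recording the config echo, package version, master seed
and run counts that produced it.
"""
from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._rand import derive_rng
from .errors import ConfigurationError
from .population import default_model, generate_population, load_spine_database
from .simulator import DEFAULT_DB_CELLS, DEFAULT_DB_SIZE, SampleSizeTable

__all__ = ["RunManifest", "write_fixture_population", "write_table"]

#: Decimal places used when rendering rates/float columns.
RATE_DECIMALS = 4


@dataclass
class RunManifest:
    """Provenance record tying an emitted table to the run that produced it."""

    config: dict
    master_seed: int
    run_counts: dict = field(default_factory=dict)
    package_version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def read(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def write_fixture_population(path, N: int = DEFAULT_DB_SIZE, seed: int = 0) -> Path:
    """Write a synthetic morphometry CSV from the frozen default model.

    The default N mirrors the size of the measured reference database (2499
    spines over 34 cells).  Values are rendered with 6 decimals so the file
    round-trips losslessly through :func:`load_spine_database` and is
    byte-identical for a fixed seed.
    """
    path = Path(path)
    source = generate_population(
        default_model(), N, derive_rng(seed, 0), n_cells=min(DEFAULT_DB_CELLS, N)
    )
    df = source.to_dataframe()
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
    # sanity: the written table must satisfy the loader's invariants
    load_spine_database(path)
    return path


def _as_dataframe(table) -> pd.DataFrame:
    if isinstance(table, SampleSizeTable):
        return table.rows
    if isinstance(table, pd.DataFrame):
        return table
    raise ConfigurationError(f"cannot write a table of type {type(table).__name__}")


def _formatted(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.{RATE_DECIMALS}f}"
            )
    return out


def write_table(table, path, format: str = "csv") -> Path:
    """Write a result table as csv, tsv or markdown.

    Column order is preserved from the table; floats are rendered with a
    fixed number of decimals so regenerated files diff cleanly.
    """
    df = _formatted(_as_dataframe(table))
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False, lineterminator="\n")
    elif format == "tsv":
        df.to_csv(path, index=False, sep="\t", lineterminator="\n")
    elif format == "markdown":
        cols = [str(c) for c in df.columns]
        lines = [
            "| " + " | ".join(cols) + " |",
            "| " + " | ".join("---" for _ in cols) + " |",
        ]
        for _, row in df.iterrows():
            lines.append("| " + " | ".join(str(v) for v in row) + " |")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ConfigurationError(
            f"unknown table format {format!r}; expected csv, tsv or markdown"
        )
    return path
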
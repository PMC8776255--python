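"""Tabular file formats and validated run configuration.

All data tables are plain CSV with unit-suffixed column names
(``ca_uM``, ``t_ms``, ``peak_rate_per_ms``, ...), '#' comment lines, and
full double precision on write.  Configuration documents are JSON,
validated with pydantic before any computation runs (unknown keys are
rejected).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "TableSchema",
    "SCHEMAS",
    "read_table",
    "write_table",
    "RunConfig",
    "KineticsConfig",
    "PoolsConfig",
    "EnergeticsConfig",
    "ProtocolConfig",
    "TransmissionConfig",
]


@dataclass(frozen=True)
class TableSchema:
    """Column contract for one table kind.

    ``positive`` columns must be strictly > 0, ``non_negative`` >= 0;
    every numeric value must be finite.
    """

    kind: str
    columns: tuple[str, ...]
    positive: tuple[str, ...] = ()
    non_negative: tuple[str, ...] = ()


SCHEMAS: dict[str, TableSchema] = {
    s.kind: s
    for s in [
        TableSchema(
            "dose_response",
            ("ca_uM", "peak_rate_per_ms"),
            positive=("ca_uM", "peak_rate_per_ms"),
        ),
        TableSchema(
            "cumulative_trace",
            ("t_ms", "n_cum", "ca_uM"),
            positive=("ca_uM",),
            non_negative=("t_ms", "n_cum"),
        ),
        TableSchema("ppr_curve", ("tau_int_ms", "ppr"), positive=("tau_int_ms", "ppr")),
        TableSchema("k1_curve", ("ca_uM", "k1_per_ms"), positive=("ca_uM", "k1_per_ms")),
        TableSchema("collapse_points", ("c", "r", "synapse_id")),
    ]
}


def _schema(schema: TableSchema | str) -> TableSchema:
    if isinstance(schema, TableSchema):
        return schema
    try:
        return SCHEMAS[schema]
    except KeyError:
        raise ValueError(
            f"unknown table kind {schema!r}; known kinds: {sorted(SCHEMAS)}"
        ) from None


def _validate(df: pd.DataFrame, sch: TableSchema) -> pd.DataFrame:
    for col in sch.columns:
        if col not in df.columns:
            raise ValueError(f"table of kind {sch.kind!r} is missing column {col!r}")
    df = df[list(sch.columns)]
    numeric = [c for c in sch.columns if c != "synapse_id"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(vals))
        if len(bad):
            raise ValueError(f"non-finite value in column {col!r} at row {bad[0]}")
        if col in sch.positive:
            neg = np.flatnonzero(vals <= 0)
            if len(neg):
                raise ValueError(
                    f"column {col!r} must be strictly positive; offending row {neg[0]} "
                    f"has value {vals[neg[0]]!r}"
                )
        if col in sch.non_negative:
            neg = np.flatnonzero(vals < 0)
            if len(neg):
                raise ValueError(
                    f"column {col!r} must be non-negative; offending row {neg[0]} "
                    f"has value {vals[neg[0]]!r}"
                )
    return df


def read_table(path, schema: TableSchema | str) -> pd.DataFrame:
    """Read and validate a CSV table ('#' comments and blank lines skipped)."""
    sch = _schema(schema)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    return _validate(df, sch)


def write_table(table: pd.DataFrame, path, schema: TableSchema | str) -> None:
    """Write a validated table as CSV at full double precision."""
    sch = _schema(schema)
    df = _validate(pd.DataFrame(table), sch)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# run configuration


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KineticsConfig(_Strict):
    N: int = Field(2, ge=1, le=15)
    k1: float = Field(1.0, gt=0, description="fast conformational rate, 1/ms")
    k2: float = Field(0.01, gt=0, description="slow replenishment rate, 1/ms")


class PoolsConfig(_Strict):
    ntot1: float = Field(100.0, ge=0)
    ntot2: float = Field(200.0, ge=0)


class EnergeticsConfig(_Strict):
    dG: float = Field(20.0, gt=0, description="activation barrier, kBT")
    nCa: float = Field(4.0, gt=0, description="transition-state Ca2+ occupancy")
    k0: float = Field(0.1, gt=0, description="rate at reference concentration, 1/ms")
    ca0: float = Field(1.0, gt=0, description="reference concentration, uM")


class ProtocolConfig(_Strict):
    T: float = Field(1.0, gt=0, description="action-potential duration, ms")
    tau_int: float = Field(50.0, gt=0)
    tau_RRP: float = Field(200.0, gt=0)
    tau_res: float = Field(50.0, gt=0)
    tau_Ca: float = Field(100.0, gt=0)
    sigma: float = Field(1.5, ge=1.0)
    I_Ca: float = Field(0.0, ge=0)
    ca_i: float = Field(10.0, gt=0)
    ca_res: float = Field(0.0, ge=0)


class TransmissionConfig(_Strict):
    # defaults sized to the default energetics (k0=0.1/ms at ca0=1 uM) so
    # that the action-potential fusion probability is high but unsaturated
    M: int = Field(10, ge=0)
    q: float = Field(0.5, gt=0, lt=1)
    ca_rest: float = Field(0.5, gt=0)
    ca_AP: float = Field(2.0, gt=0)
    T: float = Field(1.0, gt=0)
    gamma: float = Field(1.0, gt=0)


class RunConfig(_Strict):
    """Validated top-level configuration for a CLI run."""

    kinetics: KineticsConfig = KineticsConfig()
    pools: PoolsConfig = PoolsConfig()
    energetics: EnergeticsConfig = EnergeticsConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    transmission: TransmissionConfig = TransmissionConfig()
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))
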
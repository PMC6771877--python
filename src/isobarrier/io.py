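"""Delimited-text readers and writers for every table schema.

Dialect: comma-separated, UTF-8, ``.`` decimal, one header row.  Lines
starting with ``#`` are metadata (the CLI records the run seed there) and are
skipped on read.  Unicode minus and en-dash in numeric fields are normalized
to ASCII ``-``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from .core import (
    BroodTable,
    CompoundTable,
    CourtshipTable,
    MatingCountTable,
    MatingTrialRecord,
    OccurrenceTable,
    OvipositionTable,
    PupalFateTable,
    SchemaError,
)

log = logging.getLogger("isobarrier.io")

_DASHES = str.maketrans({"−": "-", "–": "-", "—": "-"})

SCHEMAS: dict[str, tuple[str, ...]] = {
    "mating_counts": ("female_taxon", "male_taxon", "count"),
    "mating_trials": ("trial_id", "female_taxon", "composition", "outcome", "observed"),
    "oviposition": ("taxon", "plant", "eggs"),
    "compounds": ("individual_id", "taxon", "sex", "region", "compound_id", "amount"),
    "courtship": ("trial_id", "female_taxon", "male_taxon", "behavior", "count"),
    "broods": (
        "brood_id",
        "cross_type",
        "eggs_laid",
        "eggs_hatched",
        "eggs_parasitized",
        "protocol_phase",
    ),
    "pupal_fates": ("cross_type", "fate", "count"),
    "occurrences": ("taxon", "lon", "lat"),
}


def _read_csv(path: str | Path, schema_name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in SCHEMAS[schema_name] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing} for schema {schema_name!r}"
        )
    for col in df.columns:
        if df[col].dtype == object:
            cleaned = df[col].str.translate(_DASHES)
            converted = pd.to_numeric(cleaned, errors="coerce")
            lost = cleaned.notna() & converted.isna()
            df[col] = cleaned if lost.any() else converted
    return df


def _build_mating_counts(df: pd.DataFrame) -> MatingCountTable:
    counts = (
        df.pivot_table(
            index="female_taxon", columns="male_taxon", values="count",
            aggfunc="sum", fill_value=0,
        )
    )
    taxa = sorted(set(counts.index) | set(counts.columns))
    counts = counts.reindex(index=taxa, columns=taxa, fill_value=0)
    return MatingCountTable(counts)


def _build_trials(df: pd.DataFrame) -> list[MatingTrialRecord]:
    records = []
    for _, row in df.iterrows():
        outcome = row["outcome"]
        if pd.isna(outcome) or outcome in ("", "none"):
            outcome = None
        records.append(
            MatingTrialRecord(
                trial_id=str(row["trial_id"]),
                female_taxon=str(row["female_taxon"]),
                composition=int(row["composition"]),
                outcome=outcome,
                observed=bool(row["observed"]),
            )
        )
    return records


def _build_pupal_fates(df: pd.DataFrame) -> PupalFateTable:
    counts = (
        df.pivot_table(
            index="cross_type", columns="fate", values="count",
            aggfunc="sum", fill_value=0,
        )
    )
    return PupalFateTable(counts)


_BUILDERS: dict[str, Callable[[pd.DataFrame], Any]] = {
    "mating_counts": _build_mating_counts,
    "mating_trials": _build_trials,
    "oviposition": OvipositionTable,
    "compounds": CompoundTable,
    "courtship": CourtshipTable,
    "broods": BroodTable,
    "pupal_fates": _build_pupal_fates,
    "occurrences": OccurrenceTable,
}


def read_table(path: str | Path, schema_name: str):
    """Read and validate a delimited file into its typed table."""
    df = _read_csv(path, schema_name)
    table = _BUILDERS[schema_name](df)
    log.info("read %s rows from %s as %s", len(df), path, schema_name)
    return table


def write_table(obj: Any, path: str | Path, seed: int | None = None) -> None:
    """Write a typed table (or plain frame) back to CSV.

    A ``# seed=`` header line is prepended when a seed is given, so every
    generated artifact records its provenance.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = _to_frame(obj)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        # shortest round-trip repr so floats survive write -> read exactly
        df.to_csv(fh, index=False, lineterminator="\n",
                  float_format=lambda v: repr(float(v)))


def _to_frame(obj: Any) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    if isinstance(obj, MatingCountTable):
        return (
            obj.counts.stack()
            .rename("count")
            .rename_axis(["female_taxon", "male_taxon"])
            .reset_index()
        )
    if isinstance(obj, PupalFateTable):
        return (
            obj.counts.stack()
            .rename("count")
            .rename_axis(["cross_type", "fate"])
            .reset_index()
        )
    if isinstance(obj, (OvipositionTable, CompoundTable, CourtshipTable)):
        return obj.long
    if isinstance(obj, (BroodTable, OccurrenceTable)):
        return obj.df
    if isinstance(obj, list) and obj and isinstance(obj[0], MatingTrialRecord):
        return pd.DataFrame(
            {
                "trial_id": [t.trial_id for t in obj],
                "female_taxon": [t.female_taxon for t in obj],
                "composition": [t.composition for t in obj],
                "outcome": [t.outcome if t.outcome is not None else "none" for t in obj],
                "observed": [t.observed for t in obj],
            }
        )
    raise TypeError(f"do not know how to serialize {type(obj).__name__}")


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: run configuration must be a mapping")
    return cfg


def dump_yaml(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
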
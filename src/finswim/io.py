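"""Readers and writers: species CSV, Newick trees, flat config files.

The species table is a plain CSV with columns
``species, gait, sl, depth, breadth, mass, fin_ar, umax``.  An optional
units row directly under the header (e.g. ``,,mm,mm,mm,g,,cm/s``) declares
the measurement units per column; values are converted to SI (m, kg, m/s)
on ingest.  Row-level validation failures are reported with file line
numbers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import trees
from .morphometrics import SpeciesRecord

__all__ = [
    "SPECIES_COLUMNS",
    "read_species_csv",
    "write_species_csv",
    "read_newick",
    "read_substitutions",
    "read_config",
    "write_json",
]

SPECIES_COLUMNS = ("species", "gait", "sl", "depth", "breadth", "mass", "fin_ar", "umax")

_LENGTH_UNITS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3}
_MASS_UNITS = {"kg": 1.0, "g": 1e-3, "mg": 1e-6}
_SPEED_UNITS = {"m/s": 1.0, "cm/s": 1e-2, "mm/s": 1e-3, "bl/s": None}
_UNIT_TABLES = {
    "sl": _LENGTH_UNITS,
    "depth": _LENGTH_UNITS,
    "breadth": _LENGTH_UNITS,
    "mass": _MASS_UNITS,
    "umax": _SPEED_UNITS,
}


def _unit_factor(column: str, unit: str, line: int) -> float:
    unit = unit.strip().lower()
    if unit in ("", "-", "1", "nan"):
        return 1.0
    table = _UNIT_TABLES.get(column)
    if table is None or unit not in table or table[unit] is None:
        raise ValueError(f"line {line}: unsupported unit {unit!r} for column {column!r}")
    return table[unit]


def read_species_csv(path) -> list[SpeciesRecord]:
    """Read and validate a species table, converting declared units to SI."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")

    first_data_line = 2  # header is line 1
    factors = {c: 1.0 for c in SPECIES_COLUMNS}
    if len(df) > 0:
        probe = df.iloc[0]["sl"]
        try:
            float(probe)
        except ValueError:  # units row
            for col in _UNIT_TABLES:
                factors[col] = _unit_factor(col, df.iloc[0][col], line=2)
            df = df.iloc[1:].reset_index(drop=True)
            first_data_line = 3

    records = []
    errors = []
    for i, row in df.iterrows():
        line = first_data_line + i
        try:
            numeric = {}
            for col in ("sl", "depth", "breadth", "mass", "fin_ar", "umax"):
                try:
                    numeric[col] = float(row[col]) * factors.get(col, 1.0)
                except ValueError:
                    raise ValueError(f"non-numeric {col}={row[col]!r}") from None
            records.append(
                SpeciesRecord(
                    species=row["species"],
                    gait=row["gait"],
                    length=numeric["sl"],
                    depth=numeric["depth"],
                    breadth=numeric["breadth"],
                    mass=numeric["mass"],
                    fin_aspect_ratio=numeric["fin_ar"],
                    umax=numeric["umax"],
                )
            )
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(f"{path.name}: invalid rows:\n  " + "\n  ".join(errors))
    return records


def write_species_csv(records: Iterable[SpeciesRecord], path) -> None:
    """Write records as a plain SI-unit CSV (no units row)."""
    rows = [
        {
            "species": r.species,
            "gait": r.gait,
            "sl": r.length,
            "depth": r.depth,
            "breadth": r.breadth,
            "mass": r.mass,
            "fin_ar": r.fin_aspect_ratio,
            "umax": r.umax,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(SPECIES_COLUMNS)).to_csv(path, index=False)


def read_newick(
    path,
    species: Sequence[str] | None = None,
    substitutions: Mapping[str, str] | None = None,
) -> dendropy.Tree:
    """Read a Newick tree, apply congeneric substitutions, prune to species.

    Substitutions (study species -> stand-in tip label) are applied before
    pruning.  Raises listing species absent from the tree after
    substitution.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    if substitutions:
        trees.apply_substitutions(tree, substitutions)
    if species is not None:
        tree = trees.prune_to_species(tree, species)
    return tree


def read_substitutions(path) -> dict[str, str]:
    """Tip-substitution map from ``species = stand_in`` lines."""
    return {k: v for k, v in _iter_kv(path)}


def read_config(path) -> dict[str, object]:
    """Flat ``key = value`` configuration with numeric coercion."""
    out: dict[str, object] = {}
    for key, value in _iter_kv(path):
        try:
            out[key] = int(value)
        except ValueError:
            try:
                out[key] = float(value)
            except ValueError:
                out[key] = value
    return out


def _iter_kv(path):
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{Path(path).name} line {lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        yield key.strip(), value.strip()


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
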
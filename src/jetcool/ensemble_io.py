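"""Readers and writers for conformer-ensemble data.

Formats handled:

* multi-structure XYZ (one frame per conformer, comment line = conformer id),
* delimited energy tables (conformer id, relative electronic energy in
  kcal/mol, optional ``g_corr@<T>`` free-energy-correction columns),
* barrier tables (conformer pair, free-energy barrier in kcal/mol),
* harmonic line lists (mode label, frequency in 1/cm, intensity),
* plain-text (JSON) basin reports.

All energies are relative kcal/mol. Absolute hartree inputs can be converted
on read with ``hartree=True`` (multiply by 627.5094740631, re-reference to the
ensemble minimum).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import pandas as pd

from .structure import Geometry

__all__ = [
    "EnergyRecord",
    "BarrierRecord",
    "ParseError",
    "ValidationError",
    "HARTREE_TO_KCAL",
    "read_xyz_ensemble",
    "write_xyz_ensemble",
    "read_energy_table",
    "write_energy_table",
    "read_barrier_table",
    "read_frequency_table",
    "write_report",
    "read_report",
]

HARTREE_TO_KCAL = 627.5094740631


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


@dataclass
class EnergyRecord:
    """Relative electronic energy of one conformer, kcal/mol.

    ``g_corr`` optionally maps temperature (K) to a free-energy correction
    (kcal/mol) so that G_rel(T) = e_rel + g_corr(T).
    """

    conformer_id: str
    e_rel: float
    g_corr: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.e_rel):
            raise ValidationError(f"{self.conformer_id!r}: non-finite energy")
        for t in self.g_corr:
            if t <= 0:
                raise ValidationError(
                    f"{self.conformer_id!r}: non-positive temperature {t} in g_corr"
                )


@dataclass(frozen=True)
class BarrierRecord:
    """Conversion free-energy barrier between two conformers, kcal/mol."""

    pair: tuple[str, str]
    dg_barrier: float
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValidationError(f"barrier pair ids must be distinct: {self.pair}")
        if self.dg_barrier < 0:
            raise ValidationError(f"{self.pair}: negative barrier {self.dg_barrier}")


# --- XYZ ---------------------------------------------------------------------

def read_xyz_ensemble(path) -> list[Geometry]:
    """Read a multi-structure XYZ file; the comment line carries the conformer id.

    Blank comment lines get auto-assigned ids ``conf_<k>`` (1-based). Frame and
    atom order are preserved; duplicate ids are rejected.
    """
    geometries: list[Geometry] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate blank separator lines
            i += 1
            continue
        frame += 1
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"frame {frame}: malformed atom-count line {lines[i]!r}")
        if natoms < 1:
            raise ParseError(f"frame {frame}: atom count must be >= 1, got {natoms}")
        if i + 1 + natoms >= len(lines) + 1 and i + 1 >= len(lines):
            raise ParseError(f"frame {frame}: missing comment line")
        label = lines[i + 1].strip() or f"conf_{frame}"
        body = lines[i + 2 : i + 2 + natoms]
        if len(body) < natoms or any(len(l.split()) < 4 for l in body):
            raise ParseError(
                f"frame {frame} ({label!r}): count line says {natoms} atoms but "
                f"fewer valid atom lines follow"
            )
        symbols, coords = [], []
        for line in body:
            tok = line.split()
            symbols.append(tok[0])
            try:
                coords.append([float(x) for x in tok[1:4]])
            except ValueError:
                raise ParseError(f"frame {frame} ({label!r}): bad coordinate line {line!r}")
        if label in seen:
            raise ValidationError(f"duplicate conformer id {label!r}")
        seen.add(label)
        geometries.append(Geometry(label=label, symbols=symbols, coords=coords))
        i += 2 + natoms
    return geometries


def write_xyz_ensemble(geometries: list[Geometry], path) -> None:
    with open(path, "w") as fh:
        for g in geometries:
            fh.write(f"{len(g)}\n{g.label}\n")
            for s, x, y, z in g.atoms:
                fh.write(f"{s} {x:.10f} {y:.10f} {z:.10f}\n")


# --- energy tables -----------------------------------------------------------

_ID_COLUMNS = ("id", "conformer", "conformer_id", "conf")
_E_COLUMNS = ("e_rel", "energy", "e")


def _read_delimited(path) -> pd.DataFrame:
    # comma or tab delimiter, auto-detected; period decimal separator
    return pd.read_csv(path, sep=None, engine="python")


def read_energy_table(
    path, reference_check: bool = True, hartree: bool = False
) -> list[EnergyRecord]:
    """Read a delimited energy table into :class:`EnergyRecord` objects.

    The id column is the first of ``id/conformer/conformer_id/conf`` (else the
    first column), the energy column the first of ``e_rel/energy/e``.
    Free-energy corrections come from columns named like ``g_corr@450``.
    Unknown extra columns are ignored. Unless ``reference_check=False``,
    exactly one record must sit at e_rel == 0 (the global-minimum reference).
    """
    df = _read_delimited(path)
    cols = {c.lower().strip(): c for c in df.columns}
    id_col = next((cols[c] for c in _ID_COLUMNS if c in cols), df.columns[0])
    e_col = next((cols[c] for c in _E_COLUMNS if c in cols), None)
    if e_col is None:
        raise ParseError(f"{path}: no energy column among {_E_COLUMNS}")

    g_cols: dict[float, str] = {}
    for c in df.columns:
        name = str(c).strip()
        if name.lower().startswith("g_corr@"):
            try:
                t = float(name.split("@", 1)[1])
            except ValueError:
                raise ParseError(f"{path}: unparseable temperature in column {name!r}")
            if t <= 0:
                raise ValidationError(f"{path}: non-positive temperature column {name!r}")
            g_cols[t] = c

    records: list[EnergyRecord] = []
    for _, row in df.iterrows():
        try:
            e = float(row[e_col])
        except (TypeError, ValueError):
            raise ParseError(f"{path}: non-numeric energy {row[e_col]!r} for {row[id_col]!r}")
        g_corr = {}
        for t, c in g_cols.items():
            v = row[c]
            if pd.notna(v):
                g_corr[t] = float(v)
        if hartree:
            e *= HARTREE_TO_KCAL
        records.append(EnergyRecord(conformer_id=str(row[id_col]), e_rel=e, g_corr=g_corr))

    if hartree and records:
        emin = min(r.e_rel for r in records)
        for r in records:
            r.e_rel -= emin
    ids = [r.conformer_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate conformer ids")
    if reference_check and records:
        zeros = [r for r in records if r.e_rel == 0.0]
        if len(zeros) != 1:
            raise ValidationError(
                f"{path}: expected exactly one zero-reference record (global minimum), "
                f"found {len(zeros)}"
            )
        if any(r.e_rel < 0 for r in records):
            raise ValidationError(f"{path}: negative relative energies present")
    return records


def write_energy_table(records: list[EnergyRecord], path) -> None:
    """Write records as CSV (full float precision; round-trips with the reader)."""
    temps = sorted({t for r in records for t in r.g_corr})
    rows = []
    for r in records:
        row = {"conformer": r.conformer_id, "e_rel": repr(r.e_rel)}
        for t in temps:
            key = f"g_corr@{t:g}"
            row[key] = repr(r.g_corr[t]) if t in r.g_corr else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_barrier_table(path) -> list[BarrierRecord]:
    """Read a barrier table with columns (a, b, dg) in kcal/mol."""
    df = _read_delimited(path)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: barrier table needs 3 columns (a, b, dg)")
    out = []
    for _, row in df.iterrows():
        a, b, dg = str(row.iloc[0]), str(row.iloc[1]), row.iloc[2]
        try:
            dg = float(dg)
        except (TypeError, ValueError):
            raise ParseError(f"{path}: non-numeric barrier {dg!r} for pair ({a}, {b})")
        out.append(BarrierRecord(pair=(a, b), dg_barrier=dg))
    return out


def read_frequency_table(path) -> pd.DataFrame:
    """Read a line list (mode_label, frequency in 1/cm, intensity >= 0)."""
    df = _read_delimited(path)
    cols = {c.lower().strip(): c for c in df.columns}
    out = pd.DataFrame(
        {
            "mode_label": df[cols["mode_label"]] if "mode_label" in cols else df.iloc[:, 0],
            "frequency": pd.to_numeric(
                df[cols["frequency"]] if "frequency" in cols else df.iloc[:, 1]
            ),
            "intensity": pd.to_numeric(df[cols["intensity"]], errors="coerce").fillna(1.0)
            if "intensity" in cols
            else 1.0,
        }
    )
    if (out["frequency"] <= 0).any():
        raise ValidationError(f"{path}: non-positive frequency in line list")
    if (out["intensity"] < 0).any():
        raise ValidationError(f"{path}: negative intensity in line list")
    return out


# --- basin reports -----------------------------------------------------------

def write_report(basins, path) -> None:
    """Write a machine-readable basin report (JSON text, bit-stable).

    One entry per kinetic basin: sorted members, sink conformer, pooled
    population (percent, full precision plus a 1-decimal display value) and
    the observability flag.
    """
    if not basins:
        raise ValidationError("refusing to write an empty basin report")
    payload = {
        "basins": [
            {
                "members": sorted(b.members),
                "sink": b.sink,
                "pooled_population": b.pooled_population,
                "pooled_display": round(b.pooled_population, 1),
                "observable": bool(b.observable),
            }
            for b in basins
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, ensure_ascii=False)
        fh.write("\n")


def read_report(path):
    """Read back a basin report written by :func:`write_report`."""
    from .kinetics import BasinResult

    with open(path) as fh:
        payload = json.load(fh)
    return [
        BasinResult(
            members=frozenset(b["members"]),
            sink=b["sink"],
            pooled_population=float(b["pooled_population"]),
            observable=bool(b["observable"]),
        )
        for b in payload["basins"]
    ]
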
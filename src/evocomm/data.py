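"""Factorial OD600 data tables: schema, validated I/O, and subsetting.

The experimental unit is one replicate well measured at 600 nm after 3.5 days
of growth. Every record is indexed by the community it belongs to (``A``..``H``
in the original design), the biological entity measured (``strain1``,
``strain2`` or the two-strain ``community`` co-culture), the evolutionary
history of that entity, the abiotic environment, and a replicate number.

Canonical on-disk format is a headered CSV with columns
``community,entity,history,environment,replicate,od``. A :class:`Dialect`
adapts files with other column names or factor labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

ENTITIES = ("strain1", "strain2", "community")
STRAIN_HISTORIES = ("ancestor", "evolved_isolation", "evolved_community")
COMMUNITY_HISTORIES = STRAIN_HISTORIES + ("mixed1", "mixed2")
HISTORIES = COMMUNITY_HISTORIES
ENVIRONMENTS = ("env1", "env2")
COLUMNS = ("community", "entity", "history", "environment", "replicate", "od")
#: columns that uniquely address one well
KEY_COLUMNS = COLUMNS[:5]

_DEFAULT_VALUE_MAPS = {
    # tolerated spellings normalised on ingest (input is case-insensitive)
    "environment": {"1": "env1", "2": "env2", "environment 1": "env1",
                    "environment 2": "env2"},
    "history": {"evolved in isolation": "evolved_isolation",
                "evolved in community": "evolved_community",
                "mixed 1": "mixed1", "mixed 2": "mixed2"},
    "entity": {"strain 1": "strain1", "strain 2": "strain2"},
}

_ENUM_DOMAIN = {"entity": ENTITIES, "history": HISTORIES,
                "environment": ENVIRONMENTS}


class SchemaError(ValueError):
    """A file or frame does not conform to the canonical OD schema."""


class DataError(ValueError):
    """A structurally valid table lacks the cells an operation needs."""


@dataclass(frozen=True)
class Dialect:
    """Column-name and factor-label mapping used to ingest foreign CSV files.

    Parameters
    ----------
    columns
        Mapping from canonical column name to the column name in the file,
        e.g. ``{"od": "OD600"}``. Unmapped canonical names are looked up
        verbatim (case-insensitively).
    values
        Per-field mapping from file factor labels to canonical labels, e.g.
        ``{"entity": {"coculture": "community"}}``.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    values: Mapping[str, Mapping[str, str]] = field(default_factory=dict)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_design`; ``ok`` iff no issue is an error."""

    issues: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, severity: str, cell: str, message: str) -> None:
        self.issues.append((severity, cell, message))

    @property
    def ok(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.issues)

    def to_json(self) -> str:
        return json.dumps(
            {"ok": self.ok,
             "issues": [{"severity": s, "cell": c, "message": m}
                        for s, c, m in self.issues]},
            indent=2)


class ODTable:
    """An ordered collection of replicate OD records.

    Wraps a :class:`pandas.DataFrame` with the canonical columns. Construction
    enforces the record-level schema (known factor labels, non-negative OD);
    design-level problems (missing cells, duplicates, mixed treatments on
    strain entities) are *reported* by :func:`validate_design` rather than
    raised, so that flawed tables can be inspected.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = ""):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
        for col, domain in _ENUM_DOMAIN.items():
            vals = df[col].astype(str)
            bad = ~vals.isin(domain)
            if bad.any():
                row = int(bad.idxmax())
                raise SchemaError(
                    f"unknown {col} label {df[col].iloc[row]!r} at row {row}")
            df[col] = vals
        df["community"] = df["community"].astype(str)
        od = pd.to_numeric(df["od"], errors="coerce")
        if od.isna().any():
            row = int(od.isna().idxmax())
            raise SchemaError(f"unparsable od value at row {row}: "
                              f"{df['od'].iloc[row]!r}")
        if (od < 0).any():
            row = int((od < 0).idxmax())
            raise SchemaError(f"negative od at row {row}: {od.iloc[row]}")
        df["od"] = od.astype(float)
        df["replicate"] = pd.to_numeric(df["replicate"]).astype(int)
        if (df["replicate"] < 1).any():
            raise SchemaError("replicate indices must be positive integers")
        self._df = df
        self.provenance = provenance

    # -- container behaviour -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        return isinstance(other, ODTable) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return (f"ODTable({len(self)} records, "
                f"{self._df['community'].nunique()} communities)")

    @property
    def df(self) -> pd.DataFrame:
        """The underlying records as a DataFrame (canonical column order)."""
        return self._df.copy()

    @property
    def communities(self) -> list[str]:
        return sorted(self._df["community"].unique())

    @property
    def environments(self) -> list[str]:
        return [e for e in ENVIRONMENTS if e in set(self._df["environment"])]

    # -- subsetting ----------------------------------------------------------
    def subset(self, filters: Mapping[str, object] | None = None,
               **kwargs) -> "ODTable":
        """Records matching all filters; values may be scalars or sets.

        An empty filter mapping returns an identical table; an empty result
        is legal and returned as an empty table.
        """
        filt = dict(filters or {})
        filt.update(kwargs)
        mask = pd.Series(True, index=self._df.index)
        for fieldname, allowed in filt.items():
            if fieldname not in COLUMNS:
                raise KeyError(f"unknown field {fieldname!r}; "
                               f"expected one of {COLUMNS}")
            if isinstance(allowed, (str, int, float)):
                allowed = [allowed]
            mask &= self._df[fieldname].isin(list(allowed))
        out = ODTable.__new__(ODTable)
        out._df = self._df.loc[mask].reset_index(drop=True)
        out.provenance = self.provenance
        return out

    def cell_values(self, community: str, entity: str, history: str,
                    environment: str):
        """OD values of one design cell as a float array."""
        sub = self.subset(community=community, entity=entity, history=history,
                          environment=environment)
        return sub._df["od"].to_numpy()

    # -- I/O -----------------------------------------------------------------
    def write(self, path) -> None:
        """Write canonical CSV; od at full ``repr`` precision (round-trips)."""
        self._df.to_csv(path, index=False,
                        float_format=lambda x: repr(float(x)))


def _normalise_label(field_name: str, raw: str,
                     value_map: Mapping[str, str]) -> str:
    s = str(raw).strip()
    if s in value_map:
        return value_map[s]
    low = s.lower()
    if low in value_map:
        return value_map[low]
    if low in _DEFAULT_VALUE_MAPS.get(field_name, {}):
        return _DEFAULT_VALUE_MAPS[field_name][low]
    return low


def read_od_table(path, dialect: Dialect | None = None,
                  provenance: str | None = None) -> ODTable:
    """Read a delimited OD table, applying an optional :class:`Dialect`.

    Raises :class:`SchemaError` naming the offending column, row or value on
    any format problem (missing column, unknown factor label, unparsable or
    negative OD).
    """
    dialect = dialect or Dialect()
    path = Path(path)
    raw = pd.read_csv(path, float_precision="round_trip")
    lower_cols = {c.lower(): c for c in raw.columns}
    data = {}
    for canon in COLUMNS:
        src = dialect.columns.get(canon, canon)
        if src in raw.columns:
            col = raw[src]
        elif src.lower() in lower_cols:
            col = raw[lower_cols[src.lower()]]
        else:
            raise SchemaError(f"missing required column {canon!r} "
                              f"(looked for {src!r}) in {path.name}")
        data[canon] = col
    df = pd.DataFrame(data)
    for fieldname in ("entity", "history", "environment"):
        vmap = dict(dialect.values.get(fieldname, {}))
        vmap.update({k.lower(): v for k, v in vmap.items()})
        df[fieldname] = [
            _normalise_label(fieldname, v, vmap) for v in df[fieldname]]
        bad = ~df[fieldname].isin(_ENUM_DOMAIN[fieldname])
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"row {row}: {fieldname} value {df[fieldname].iloc[row]!r} is "
                f"not a known label and no dialect mapping was given")
    df["community"] = df["community"].astype(str).str.strip()
    return ODTable(df, provenance=provenance or str(path))


def write_od_table(table: ODTable, path) -> None:
    table.write(path)


def expected_histories(entity: str) -> Sequence[str]:
    return COMMUNITY_HISTORIES if entity == "community" else STRAIN_HISTORIES


def validate_design(table: ODTable,
                    min_replicates: int = 2) -> ValidationReport:
    """Check design completeness and record-level invariants.

    For every community and every environment present in the table, the full
    11-cell design (two strains x three histories, community x five
    histories) must be present with at least ``min_replicates`` replicates
    (the bootstrap resamples within cells). Duplicated well coordinates and
    mixed treatments attached to strain entities are flagged as errors.
    Nothing is raised; all problems land in the report.
    """
    report = ValidationReport()
    df = table.df
    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        for _, grp in df.loc[dup].groupby(list(KEY_COLUMNS)):
            key = grp.iloc[0]
            report.add("error", _cell_name(key),
                       f"duplicate coordinates ({len(grp)} rows share "
                       f"replicate {key['replicate']})")
    mixed_on_strain = df["history"].isin(["mixed1", "mixed2"]) & \
        df["entity"].isin(["strain1", "strain2"])
    if mixed_on_strain.any():
        for _, row in df.loc[mixed_on_strain].iterrows():
            report.add("error", _cell_name(row),
                       "mixed treatments exist only for community entities")
    counts = df.groupby(["community", "entity", "history", "environment"],
                        sort=True).size()
    for community in sorted(df["community"].unique()):
        envs = sorted(df.loc[df["community"] == community, "environment"]
                      .unique())
        for env in envs:
            for entity in ENTITIES:
                for history in expected_histories(entity):
                    key = (community, entity, history, env)
                    n = counts.get(key, 0)
                    cell = ":".join(key)
                    if n == 0:
                        report.add("error", cell, "design cell missing")
                    elif n < min_replicates:
                        report.add("error", cell,
                                   f"only {n} replicate(s); at least "
                                   f"{min_replicates} needed for resampling")
    return report


def _cell_name(row) -> str:
    return ":".join(str(row[k]) for k in
                    ("community", "entity", "history", "environment"))


def concat_tables(tables: Iterable[ODTable], provenance: str = "") -> ODTable:
    frames = [t.df for t in tables]
    return ODTable(pd.concat(frames, ignore_index=True),
                   provenance=provenance)
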
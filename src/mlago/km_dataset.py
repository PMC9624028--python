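"""Curation of tabular Michaelis-constant (K_m) data.

A record is one enzyme-substrate-organism measurement: an EC number
(four dot-separated components), a KEGG compound identifier, an organism
identifier, and a K_m value in mM. Curation merges duplicated
(EC, compound, organism) triples by taking the geometric mean of their
K_m values, optionally removes benchmark-related entries, and splits the
result into training and test partitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: semantic column roles -> default column names in input files
DEFAULT_COLUMN_MAP = {
    "ec_number": "ec_number",
    "compound_id": "compound_id",
    "organism_id": "organism_id",
    "km_mM": "km_mM",
}

TRIPLE = ["ec_number", "compound_id", "organism_id"]


@dataclass(frozen=True)
class KmRecord:
    """One K_m measurement.

    ``km_mM`` must be positive; ``ec_number`` must have exactly four
    non-empty dot-separated components (e.g. ``"6.3.1.2"``).
    """

    ec_number: str
    compound_id: str
    organism_id: str
    km_mM: float

    def __post_init__(self) -> None:
        if not self.km_mM > 0:
            raise ValueError(f"km_mM must be positive, got {self.km_mM!r}")
        parts = self.ec_number.split(".")
        if len(parts) != 4 or any(not p for p in parts):
            raise ValueError(
                f"EC number must have four non-empty dot-separated components, got {self.ec_number!r}"
            )

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.ec_number, self.compound_id, self.organism_id)


@dataclass
class ReadSummary:
    """Row-level accounting of a table read."""

    n_read: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    rejected_reasons: dict[str, int] = field(default_factory=dict)


class KmTable:
    """Ordered collection of :class:`KmRecord` with provenance.

    Internally a pandas DataFrame with columns
    ``ec_number, compound_id, organism_id, km_mM``.
    """

    def __init__(self, records: Iterable[KmRecord] | pd.DataFrame, provenance: str = ""):
        if isinstance(records, pd.DataFrame):
            df = records.reset_index(drop=True)[TRIPLE + ["km_mM"]].copy()
        else:
            rows = [(r.ec_number, r.compound_id, r.organism_id, r.km_mM) for r in records]
            df = pd.DataFrame(rows, columns=TRIPLE + ["km_mM"])
        df["km_mM"] = df["km_mM"].astype(float)
        self._df = df
        self.provenance = provenance
        self.read_summary: ReadSummary | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self):
        for row in self._df.itertuples(index=False):
            yield KmRecord(row.ec_number, row.compound_id, row.organism_id, row.km_mM)

    def __getitem__(self, i: int) -> KmRecord:
        row = self._df.iloc[i]
        return KmRecord(row.ec_number, row.compound_id, row.organism_id, row.km_mM)

    def __eq__(self, other) -> bool:
        return isinstance(other, KmTable) and self._df.equals(other._df)

    @property
    def df(self) -> pd.DataFrame:
        """Underlying data (copy)."""
        return self._df.copy()

    @property
    def records(self) -> list[KmRecord]:
        return list(self)

    def is_deduplicated(self) -> bool:
        return not self._df.duplicated(subset=TRIPLE).any()


def read_km_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> KmTable:
    """Read a delimited K_m table (TSV by default, CSV via ``sep=","``).

    ``column_map`` maps the semantic roles ``ec_number``, ``compound_id``,
    ``organism_id``, ``km_mM`` to the file's column names. Rows with
    non-positive, non-finite, or unparseable K_m, or a malformed EC
    number, are dropped, logged, and counted in ``table.read_summary``.

    Raises ``FileNotFoundError``, ``KeyError`` (missing mapped column) or
    ``ValueError`` (zero valid rows).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"K_m table not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    missing = [c for c in cmap.values() if c not in raw.columns]
    if missing:
        raise KeyError(f"mapped column(s) {missing} not present in {path} (found {list(raw.columns)})")

    df = raw[[cmap[k] for k in ("ec_number", "compound_id", "organism_id", "km_mM")]].copy()
    df.columns = TRIPLE + ["km_mM"]
    summary = ReadSummary(n_read=len(df))

    km = pd.to_numeric(df["km_mM"], errors="coerce")
    bad_km = ~np.isfinite(km) | (km <= 0)
    ec_parts = df["ec_number"].fillna("").str.split(".")
    bad_ec = ec_parts.map(lambda p: len(p) != 4 or any(not s for s in p))
    bad_id = df["compound_id"].isna() | df["organism_id"].isna()

    summary.rejected_reasons = {
        "non_positive_or_unparseable_km": int(bad_km.sum()),
        "malformed_ec_number": int((bad_ec & ~bad_km).sum()),
        "missing_identifier": int((bad_id & ~bad_km & ~bad_ec).sum()),
    }
    keep = ~(bad_km | bad_ec | bad_id)
    summary.n_rejected = int((~keep).sum())
    summary.n_kept = int(keep.sum())
    if summary.n_rejected:
        logger.warning("read_km_table: dropped %d of %d rows (%s)",
                       summary.n_rejected, summary.n_read, summary.rejected_reasons)
    if summary.n_kept == 0:
        raise ValueError(f"no valid K_m rows in {path}")

    out = df.loc[keep].copy()
    out["km_mM"] = km.loc[keep].astype(float)
    table = KmTable(out, provenance=str(path))
    table.read_summary = summary
    return table


def write_km_table(table: KmTable, path: str | Path, sep: str = "\t") -> None:
    """Round-trip writer: same dialect and column layout the reader consumes."""
    table.df.to_csv(path, sep=sep, index=False, encoding="utf-8")


def deduplicate(table: KmTable) -> KmTable:
    """Merge duplicated (EC, compound, organism) triples.

    Each merged K_m is the geometric mean of the group's values (computed
    as the arithmetic mean of log10 K_m, exponentiated). Output is sorted
    by the triple; the operation is idempotent.
    """
    df = table.df
    merged = (
        np.log10(df["km_mM"])
        .groupby([df[c] for c in TRIPLE])
        .mean()
        .rename("km_mM")
        .reset_index()
    )
    merged["km_mM"] = 10.0 ** merged["km_mM"]
    merged = merged.sort_values(TRIPLE, kind="mergesort").reset_index(drop=True)
    out = KmTable(merged, provenance=table.provenance)
    return out


def exclude_entries(
    table: KmTable, keys: Sequence[tuple[str, str, str]]
) -> tuple[KmTable, int]:
    """Remove records whose (EC, compound, organism) triple matches any key.

    Returns the filtered table and the number of removed records.
    """
    if not keys:
        return KmTable(table.df, provenance=table.provenance), 0
    keyset = {tuple(k) for k in keys}
    df = table.df
    hit = df[TRIPLE].apply(tuple, axis=1).isin(keyset)
    n_removed = int(hit.sum())
    if n_removed:
        logger.info("exclude_entries: removed %d records", n_removed)
    return KmTable(df.loc[~hit], provenance=table.provenance), n_removed


def read_exclusion_keys(path: str | Path, sep: str = "\t") -> list[tuple[str, str, str]]:
    """Read a 3-column (EC, compound, organism) key file for `exclude_entries`."""
    df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    cols = list(df.columns[:3])
    return [tuple(r) for r in df[cols].itertuples(index=False)]


def split_train_test(
    table: KmTable, test_fraction: float, seed: int
) -> tuple[KmTable, KmTable]:
    """Deterministic random partition into (train, test).

    ``|test| = round(test_fraction * |table|)``; the same seed yields the
    identical split. The default protocol is a 4:1 split
    (``test_fraction=0.2``).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_test = int(round(test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    df = table.df
    train = KmTable(df.iloc[train_idx], provenance=table.provenance)
    test = KmTable(df.iloc[test_idx], provenance=table.provenance)
    return train, test


def geometric_mean(values: Iterable[float]) -> float:
    """Geometric mean of positive values."""
    logs = [math.log10(v) for v in values]
    if not logs:
        raise ValueError("empty group")
    return 10.0 ** (sum(logs) / len(logs))
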
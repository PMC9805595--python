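"""Readers and writers for the formats the tool touches.

Dependency screens arrive as wide CSV matrices (cell lines x genes, one
dependency score per cell, missing entries allowed), sample annotations
as a CSV keyed by sample id, and pathway collections as GMT.  Long-format
correlation tables are written as TSV with full float precision so that
a read/write round trip is value-identical.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: cell tokens treated as missing values (compared case-insensitively,
#: after stripping whitespace)
NA_TOKENS = frozenset({"", "na", "nan"})

ORIENTATIONS = ("genes_in_columns", "genes_in_rows")

CORR_COLUMNS = ["target", "gene", "r", "p", "q", "n"]


class DataFormatError(ValueError):
    """Malformed or inconsistent input data."""


def _is_na(token: str) -> bool:
    return token.strip().lower() in NA_TOKENS


def _repr_float(v) -> str:
    """Shortest round-trip decimal representation ('.' separator)."""
    return "" if pd.isna(v) else repr(float(v))


def _check_unique(labels: Iterable[str], kind: str) -> None:
    seen: dict[str, int] = {}
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
    dups = sorted(lab for lab, cnt in seen.items() if cnt > 1)
    if dups:
        raise DataFormatError(f"duplicate {kind} labels: {', '.join(dups)}")


# ---------------------------------------------------------------------------
# dependency matrix
# ---------------------------------------------------------------------------

def read_dependency_matrix(
    path, orientation: str = "genes_in_columns"
) -> pd.DataFrame:
    """Read a wide dependency-score CSV into a samples x genes DataFrame.

    Parameters
    ----------
    path
        CSV file with a header row and a leading label column.
    orientation
        ``"genes_in_columns"`` (default; cell lines in rows, matching the
        DEMETER2-style export) or ``"genes_in_rows"``; the returned frame
        is always oriented samples x genes.

    Returns
    -------
    pandas.DataFrame
        Float matrix indexed by sample id with gene-symbol columns.
        Empty/``NA``/``NaN`` cells (case-insensitive) become ``NaN``.

    Raises
    ------
    DataFormatError
        On duplicate row/column labels (naming the duplicates) or a
        non-numeric cell (naming its row and column).
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(
            f"orientation must be one of {ORIENTATIONS}, got {orientation!r}"
        )
    # read the raw header line first: pandas silently renames duplicate
    # column labels, which must instead be a hard error
    with open(path, encoding="utf-8", newline="") as fh:
        header = next(csv.reader(fh), None)
    if not header or len(header) < 2:
        raise DataFormatError("expected a header row with at least one gene")
    _check_unique(header[1:], "column")
    raw = pd.read_csv(
        path, header=0, index_col=0, dtype=str, keep_default_na=False
    )
    _check_unique(raw.index, "row")

    values = np.empty(raw.shape, dtype=float)
    cells = raw.to_numpy()
    for j in range(raw.shape[1]):
        col = cells[:, j]
        na_mask = np.array([_is_na(c) for c in col])
        tokens = np.where(na_mask, "nan", col)
        try:
            # numpy's parser round-trips the shortest decimal representation
            values[:, j] = tokens.astype(np.float64)
        except ValueError:
            for i, tok in enumerate(tokens):
                try:
                    float(tok)
                except ValueError:
                    raise DataFormatError(
                        f"non-numeric cell {col[i]!r} at row {raw.index[i]!r},"
                        f" column {raw.columns[j]!r}"
                    ) from None
    if not np.isfinite(values[~np.isnan(values)]).all():
        raise DataFormatError("non-finite value (inf) in dependency matrix")

    mat = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    if orientation == "genes_in_rows":
        mat = mat.T
    mat.index.name = "sample_id"
    mat.columns.name = "gene"
    return mat


def write_dependency_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a samples x genes matrix as CSV; missing entries as empty cells.

    Floats use shortest round-trip formatting so a write/read cycle is
    value-identical.
    """
    out = matrix.astype(object).map(_repr_float)
    out.to_csv(path)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

#: header names recognised as the sample-id column (case-insensitive)
_ID_COLUMN_ALIASES = ("sample_id", "depmap_id")


def read_metadata(path, id_column: str | None = None) -> pd.DataFrame:
    """Read a sample-annotation CSV (sample id, display name, lineage, ...).

    The sample-id column is auto-detected among common header names
    (``sample_id``, ``DepMap_ID``; case-insensitive) unless ``id_column``
    is given.  All fields are kept as text; empty cells (e.g. unused
    lineage-subtype slots) stay as empty strings.

    Returns a DataFrame indexed by the unique sample id.
    """
    meta = pd.read_csv(path, dtype=str, keep_default_na=False)
    if id_column is None:
        for col in meta.columns:
            if col.strip().lower() in _ID_COLUMN_ALIASES:
                id_column = col
                break
        else:
            raise DataFormatError(
                "no sample-id column found (expected one of "
                f"{_ID_COLUMN_ALIASES}); columns: {list(meta.columns)}"
            )
    elif id_column not in meta.columns:
        raise DataFormatError(f"sample-id column {id_column!r} not in file")
    _check_unique(meta[id_column], "sample_id")
    meta = meta.set_index(id_column)
    meta.index.name = "sample_id"
    return meta


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. a KEGG pathway such as hsa04151)."""

    set_id: str
    description: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene) -> bool:
        return gene in self.members


class GeneSetCollection(Mapping):
    """An ordered collection of uniquely named gene sets.

    Behaves as a mapping from set id to :class:`GeneSet`; also offers a
    reverse index from gene symbol to the ids of the sets containing it.
    """

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.set_id in self._sets:
                raise DataFormatError(f"duplicate set id: {gs.set_id!r}")
            self._sets[gs.set_id] = gs

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"

    def sets_containing(self, gene) -> set:
        """Ids of every set containing ``gene``."""
        return {sid for sid, gs in self._sets.items() if gene in gs.members}

    def membership(self) -> dict:
        """Reverse index: gene symbol -> set of set ids annotating it."""
        idx: dict[str, set] = {}
        for sid, gs in self._sets.items():
            for g in gs.members:
                idx.setdefault(g, set()).add(sid)
        return idx

    def all_members(self) -> set:
        """Union of all member genes."""
        out: set = set()
        for gs in self._sets.values():
            out |= gs.members
        return out


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line, tab-separated set id, description, members.

    Duplicate members within a line are collapsed; a line with fewer than
    three fields or a repeated set id is an error.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"GMT line {lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            set_id, description = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise DataFormatError(f"GMT line {lineno}: no members")
            sets.append(GeneSet(set_id, description, members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection as GMT (members sorted for reproducible output)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection.values():
            fh.write(
                "\t".join([gs.set_id, gs.description, *sorted(gs.members)])
                + "\n"
            )


# ---------------------------------------------------------------------------
# long-format correlation tables
# ---------------------------------------------------------------------------

def write_correlation_table(table: pd.DataFrame, path) -> None:
    """Write a correlation table as TSV (columns target, gene, r, p, q, n).

    Floats use shortest round-trip formatting with ``.`` decimals so the
    table survives a read/write cycle bit-exactly; row order is preserved.
    """
    missing = [c for c in CORR_COLUMNS if c not in table.columns]
    if missing:
        raise DataFormatError(f"correlation table lacks columns: {missing}")
    out = table[CORR_COLUMNS].copy()
    out["n"] = out["n"].astype(int)
    for col in ("r", "p", "q"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_MINIMAL)


def read_correlation_table(path) -> pd.DataFrame:
    """Read a TSV correlation table written by :func:`write_correlation_table`."""
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"target": str, "gene": str, "r": float, "p": float,
               "q": float, "n": int},
        keep_default_na=False,
        na_values=["NA"],
        float_precision="round_trip",
    )
    missing = [c for c in CORR_COLUMNS if c not in table.columns]
    if missing:
        raise DataFormatError(f"correlation table lacks columns: {missing}")
    return table[CORR_COLUMNS]
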
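"""Key-value database of interchangeable fragments.

Entries are ``(radius, canonical context, canonical core, n_heavy, count)``
rows; the ``(radius, context)`` pair is the lookup key under which cores
are interchangeable.  ``count`` is the number of distinct source molecules
contributing a triple (each stored permuted core variant counts
independently).

Two storage backends with identical behavior are provided: a TSV
interchange format and an embedded SQLite file (chosen by file suffix).
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from joblib import Parallel, delayed

from .errors import FormatError, ParameterError
from .fragmentation import (
    canonical_context_key,
    fragment_molecule,
    truncate_context,
    _renumber_core,
    parse_fragment,
)
from .records import MoleculeRecord, dedupe_records

TSV_HEADER = ("radius", "context", "core", "n_heavy", "count")
_SQLITE_SUFFIXES = {".db", ".sqlite", ".sqlite3"}


@dataclass(frozen=True)
class DBEntry:
    """One (radius, context, core) triple with its occurrence count."""

    radius: int
    context: str
    core: str
    n_heavy: int
    count: int


class FragDB:
    """In-memory fragment database with an index on (radius, context)."""

    def __init__(
        self,
        entries: Iterable[DBEntry],
        radii: Iterable[int] | None = None,
        corpus_size: int | None = None,
    ):
        self.entries: tuple[DBEntry, ...] = tuple(
            sorted(entries, key=lambda e: (e.radius, e.context, e.core))
        )
        if radii is None:
            radii = {e.radius for e in self.entries}
        self.radii: tuple[int, ...] = tuple(sorted(set(radii)))
        self.corpus_size = corpus_size
        self._index: dict[tuple[int, str], list[DBEntry]] = {}
        for e in self.entries:
            self._index.setdefault((e.radius, e.context), []).append(e)
        for key in self._index:
            self._index[key].sort(key=lambda e: (-e.count, e.core))

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragDB):
            return NotImplemented
        return self.entries == other.entries

    def query(self, radius: int, context: str) -> list[DBEntry]:
        """Entries for an exact (radius, canonical context) key.

        Deterministic order: descending count, then lexicographic core.
        """
        if radius not in self.radii:
            raise ParameterError(f"radius {radius} was not built (have {self.radii})")
        return list(self._index.get((radius, context), ()))


def _molecule_triples(
    smiles: str, radii: tuple[int, ...], max_cuts: int
) -> set[tuple[int, str, str, int]]:
    """All distinct (radius, context, core, n_heavy) triples of one molecule."""
    triples: set[tuple[int, str, str, int]] = set()
    for rec in fragment_molecule(smiles, max_cuts):
        core_mol = parse_fragment(rec.core.smiles_ap)
        for radius in radii:
            tctx = truncate_context(rec.context_full, radius)
            ctx, old_to_new, perms = canonical_context_key(tctx)
            for perm in perms:
                mapping = {old: perm[new] for old, new in old_to_new.items()}
                core_smi = _renumber_core(core_mol, mapping)
                triples.add((radius, ctx.smiles_ap, core_smi, rec.core.n_heavy))
    return triples


def build_db(
    corpus: Sequence[MoleculeRecord],
    radii: Sequence[int],
    max_cuts: int = 4,
    n_jobs: int = 1,
) -> FragDB:
    """Fragment a corpus and assemble the interchangeable-fragment database.

    The corpus is deduplicated to distinct canonical SMILES first; each
    distinct molecule increments the count of a triple at most once.
    """
    if not radii:
        raise ParameterError("radii must be non-empty")
    radii_t = tuple(sorted(set(int(r) for r in radii)))
    if radii_t[0] < 1:
        raise ParameterError("all radii must be >= 1")
    corpus = dedupe_records(list(corpus))
    if n_jobs != 1 and len(corpus) > 1:
        per_mol = Parallel(n_jobs=n_jobs)(
            delayed(_molecule_triples)(rec.smiles, radii_t, max_cuts) for rec in corpus
        )
    else:
        per_mol = (_molecule_triples(rec.smiles, radii_t, max_cuts) for rec in corpus)
    counts: dict[tuple[int, str, str], int] = {}
    sizes: dict[tuple[int, str, str], int] = {}
    for triples in per_mol:
        for radius, ctx, core, n_heavy in triples:
            key = (radius, ctx, core)
            counts[key] = counts.get(key, 0) + 1
            sizes[key] = n_heavy
    entries = [
        DBEntry(radius, ctx, core, sizes[(radius, ctx, core)], count)
        for (radius, ctx, core), count in counts.items()
    ]
    return FragDB(entries, radii_t, corpus_size=len(corpus))


def query(db: FragDB, radius: int, context: str) -> list[DBEntry]:
    """Module-level alias of :meth:`FragDB.query`."""
    return db.query(radius, context)


def filter_entries(
    entries: Sequence[DBEntry],
    min_freq: int = 0,
    min_size: int = 0,
    max_size: int | None = None,
) -> list[DBEntry]:
    """Keep entries with ``count >= min_freq`` and core size within bounds."""
    if min_freq < 0 or min_size < 0:
        raise ParameterError("min_freq and min_size must be >= 0")
    if max_size is not None and max_size < min_size:
        raise ParameterError("max_size must be >= min_size")
    out = []
    for e in entries:
        if e.count < min_freq or e.n_heavy < min_size:
            continue
        if max_size is not None and e.n_heavy > max_size:
            continue
        out.append(e)
    return out


def db_stats(db: FragDB) -> pd.DataFrame:
    """Distinct (context, core) pairs per radius."""
    rows = {r: 0 for r in db.radii}
    for e in db.entries:
        rows[e.radius] = rows.get(e.radius, 0) + 1
    return pd.DataFrame(
        {"radius": sorted(rows), "n_pairs": [rows[r] for r in sorted(rows)]}
    )


def write_db(db: FragDB, path: str | Path) -> None:
    """Serialize a database (TSV by default, SQLite for .db/.sqlite paths)."""
    path = Path(path)
    if path.suffix.lower() in _SQLITE_SUFFIXES:
        _write_sqlite(db, path)
    else:
        with open(path, "w") as fh:
            fh.write("\t".join(TSV_HEADER) + "\n")
            for e in db.entries:
                fh.write(f"{e.radius}\t{e.context}\t{e.core}\t{e.n_heavy}\t{e.count}\n")


def read_db(path: str | Path) -> FragDB:
    """Load a database written by :func:`write_db`."""
    path = Path(path)
    if path.suffix.lower() in _SQLITE_SUFFIXES:
        return _read_sqlite(path)
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != list(TSV_HEADER):
            raise FormatError(f"{path}: line 1: bad header {header!r}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(
                    f"{path}: line {lineno}: expected 5 columns, got {len(parts)}"
                )
            try:
                entries.append(
                    DBEntry(int(parts[0]), parts[1], parts[2], int(parts[3]), int(parts[4]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return FragDB(entries)


def _write_sqlite(db: FragDB, path: Path) -> None:
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.execute(
            "CREATE TABLE entries (radius INTEGER, context TEXT, core TEXT,"
            " n_heavy INTEGER, count INTEGER)"
        )
        con.execute("CREATE INDEX idx_key ON entries (radius, context)")
        con.executemany(
            "INSERT INTO entries VALUES (?,?,?,?,?)",
            [(e.radius, e.context, e.core, e.n_heavy, e.count) for e in db.entries],
        )
        con.commit()
    finally:
        con.close()


def _read_sqlite(path: Path) -> FragDB:
    con = sqlite3.connect(path)
    try:
        try:
            rows = con.execute(
                "SELECT radius, context, core, n_heavy, count FROM entries"
            ).fetchall()
        except sqlite3.Error as exc:
            raise FormatError(f"{path}: {exc}") from exc
    finally:
        con.close()
    return FragDB(DBEntry(*row) for row in rows)
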
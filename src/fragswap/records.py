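"""Molecule records: parsing, standardization and SMILES file I/O.

A :class:`MoleculeRecord` is the unit every other module consumes: a
sanitized molecule held as canonical SMILES plus an optional identifier.
Standardization strips stereochemistry and isotope labels by default so
that context keys stay stable across input representations, and restricts
structures to a configurable organic element subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem

from .errors import InputError

logger = logging.getLogger(__name__)

#: Atomic numbers of the default allowed organic subset:
#: C, N, O, S, P, F, Cl, Br, I, B (hydrogen is implicit).
ORGANIC_SUBSET = frozenset({5, 6, 7, 8, 9, 15, 16, 17, 35, 53})


@dataclass(frozen=True)
class MoleculeRecord:
    """A sanitized molecule as canonical SMILES with an optional identifier."""

    smiles: str
    id: str | None = None


def standardize_mol(
    mol: Chem.Mol,
    *,
    keep_stereo: bool = False,
    keep_isotopes: bool = False,
    allowed_elements: frozenset[int] | None = ORGANIC_SUBSET,
) -> Chem.Mol:
    """Return a standardized copy of a sanitized molecule.

    Parameters
    ----------
    mol
        A sanitized RDKit molecule.
    keep_stereo
        Preserve stereochemistry instead of stripping it.
    keep_isotopes
        Preserve isotope labels instead of zeroing them.
    allowed_elements
        Atomic numbers permitted (besides H); ``None`` disables the filter.

    Raises
    ------
    InputError
        If the molecule contains an element outside ``allowed_elements``.
    """
    mol = Chem.Mol(mol)
    if allowed_elements is not None:
        for atom in mol.GetAtoms():
            z = atom.GetAtomicNum()
            if z != 1 and z not in allowed_elements:
                raise InputError(
                    f"element {atom.GetSymbol()} outside the allowed subset"
                )
    if not keep_stereo:
        Chem.RemoveStereochemistry(mol)
    if not keep_isotopes:
        for atom in mol.GetAtoms():
            atom.SetIsotope(0)
    return mol


def parse_smiles(
    smiles: str,
    id: str | None = None,
    *,
    keep_stereo: bool = False,
    keep_isotopes: bool = False,
    allowed_elements: frozenset[int] | None = ORGANIC_SUBSET,
) -> MoleculeRecord:
    """Parse, sanitize and standardize a SMILES string into a record.

    Raises
    ------
    InputError
        If the SMILES does not parse/sanitize or fails the element filter.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    mol = standardize_mol(
        mol,
        keep_stereo=keep_stereo,
        keep_isotopes=keep_isotopes,
        allowed_elements=allowed_elements,
    )
    return MoleculeRecord(Chem.MolToSmiles(mol), id)


def to_mol(obj: MoleculeRecord | str | Chem.Mol) -> Chem.Mol:
    """Coerce a record, SMILES string or Mol into a sanitized RDKit Mol."""
    if isinstance(obj, Chem.Mol):
        return obj
    smiles = obj.smiles if isinstance(obj, MoleculeRecord) else obj
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    return mol


def canonical_smiles(obj: MoleculeRecord | str | Chem.Mol) -> str:
    """Canonical SMILES of any molecule-like input."""
    return Chem.MolToSmiles(to_mol(obj))


def read_smiles_file(
    path: str | Path,
    *,
    keep_stereo: bool = False,
    allowed_elements: frozenset[int] | None = ORGANIC_SUBSET,
) -> list[MoleculeRecord]:
    """Read a SMILES file (one molecule per line, optional tab-separated id).

    Lines failing sanitization or the element filter are logged and skipped.
    """
    records: list[MoleculeRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            mol_id = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
            try:
                records.append(
                    parse_smiles(
                        smiles,
                        mol_id,
                        keep_stereo=keep_stereo,
                        allowed_elements=allowed_elements,
                    )
                )
            except InputError as exc:
                logger.warning("%s:%d skipped: %s", path, lineno, exc)
    return records


def write_smiles_file(
    records: Iterable[MoleculeRecord | str], path: str | Path
) -> None:
    """Write records one per line (SMILES, optional tab-separated id)."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, MoleculeRecord):
                if rec.id is not None:
                    fh.write(f"{rec.smiles}\t{rec.id}\n")
                else:
                    fh.write(f"{rec.smiles}\n")
            else:
                fh.write(f"{rec}\n")


def dedupe_records(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Drop records with duplicate canonical SMILES, keeping first occurrence."""
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for rec in records:
        if rec.smiles not in seen:
            seen.add(rec.smiles)
            out.append(rec)
    return out
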
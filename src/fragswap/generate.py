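"""Structure generation by fragment replacement: MUTATE, GROW and LINK.

All three modes share one pipeline: fragment the parent, truncate and
canonicalize each context at the working radius, look the context up in
the fragment database, filter candidate cores, and splice each survivor
back into the parent's full context.  Products that fail sanitization are
dropped (and logged), so every returned SMILES is valid by construction.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from functools import lru_cache

from rdkit import Chem

from .errors import ContractViolation, ParameterError, SpliceError
from .fragdb import DBEntry, FragDB
from .fragmentation import (
    Context,
    Core,
    FragmentationRecord,
    HYDROGEN_CORE,
    canonical_context_key,
    fragment_molecule,
    hydrogen_cuts,
    parse_fragment,
    truncate_context,
)
from .records import MoleculeRecord, to_mol

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenerationParams:
    """Tuning parameters for one replacement call.

    ``min_size``/``max_size`` bound the heavy-atom count of the *replaced*
    core (the hydrogen core counts as size 0); ``min_inc``/``max_inc``
    bound the signed heavy-atom difference (replacing - replaced);
    ``max_rel_size`` caps the replaced-core size relative to the parent;
    ``max_replacements`` caps the number of randomly sampled
    (site, candidate) pairs, ``None`` meaning exhaustive.
    """

    radius: int = 3
    min_size: int = 0
    max_size: int = 10
    max_rel_size: float | None = None
    min_inc: int = -2
    max_inc: int = 2
    min_freq: int = 0
    max_replacements: int | None = None
    protected_atoms: frozenset[int] = field(default_factory=frozenset)
    seed: int | None = None
    max_cuts: int = 4

    def __post_init__(self):
        if self.min_size > self.max_size:
            raise ParameterError("min_size must be <= max_size")
        if self.min_inc > self.max_inc:
            raise ParameterError("min_inc must be <= max_inc")
        if self.max_rel_size is not None and not (0 < self.max_rel_size <= 1):
            raise ParameterError("max_rel_size must be in (0, 1]")


@lru_cache(maxsize=100_000)
def _core_mol(core_smiles: str) -> Chem.Mol:
    return parse_fragment(core_smiles)


@lru_cache(maxsize=100_000)
def _core_k(core_smiles: str) -> int:
    return sum(1 for a in _core_mol(core_smiles).GetAtoms() if a.GetAtomicNum() == 0)


def _renumbered_context_mol(ctx: Context, old_to_new: dict[int, int]) -> Chem.Mol:
    mol = Chem.Mol(parse_fragment(ctx.smiles_ap))
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(old_to_new[atom.GetAtomMapNum()])
    return mol


def _splice_mols(ctx_mol: Chem.Mol, core_mol: Chem.Mol) -> str:
    """Join a context and a core at matching attachment maps; canonical SMILES.

    Raises :class:`SpliceError` when the joined molecule cannot sanitize.
    """
    try:
        joined = Chem.molzip(Chem.CombineMols(ctx_mol, core_mol))
        Chem.SanitizeMol(joined)
        joined = Chem.RemoveHs(joined)
        return Chem.MolToSmiles(joined)
    except SpliceError:
        raise
    except Exception as exc:  # RDKit raises assorted exception types here
        raise SpliceError(str(exc)) from exc


def splice(
    parent: MoleculeRecord | str,
    record: FragmentationRecord,
    replacement: Core,
) -> str:
    """Replace ``record``'s core in the parent by ``replacement``.

    The replacement's attachment map numbers must equal the record core's.
    """
    rec_mol = _core_mol(record.core.smiles_ap)
    rep_mol = parse_fragment(replacement.smiles_ap)
    rec_maps = {a.GetAtomMapNum() for a in rec_mol.GetAtoms() if a.GetAtomicNum() == 0}
    rep_maps = {a.GetAtomMapNum() for a in rep_mol.GetAtoms() if a.GetAtomicNum() == 0}
    if rec_maps != rep_maps:
        raise ContractViolation(
            f"map-number mismatch: record {sorted(rec_maps)} vs replacement {sorted(rep_maps)}"
        )
    ctx_mol = parse_fragment(record.context_full.smiles_ap)
    return _splice_mols(ctx_mol, rep_mol)


def _candidate_pairs(records, db: FragDB, params: GenerationParams, n_parent: int,
                     grow_only: bool):
    """Deterministically ordered (record, renumber-map, entry) candidates."""
    pairs = []
    for rec in records:
        core = rec.core
        if grow_only and core.smiles_ap != HYDROGEN_CORE:
            continue
        if not (params.min_size <= core.n_heavy <= params.max_size):
            continue
        if (
            params.max_rel_size is not None
            and n_parent > 0
            and core.n_heavy / n_parent > params.max_rel_size
        ):
            continue
        if params.protected_atoms and set(rec.core_atoms) & params.protected_atoms:
            continue
        tctx = truncate_context(rec.context_full, params.radius)
        key, old_to_new, _ = canonical_context_key(tctx)
        for entry in db.query(params.radius, key.smiles_ap):
            if entry.count < params.min_freq:
                continue
            inc = entry.n_heavy - core.n_heavy
            if not (params.min_inc <= inc <= params.max_inc):
                continue
            if grow_only and entry.n_heavy < 1:
                continue
            pairs.append((rec, old_to_new, entry))
    return pairs


def _sample_pairs(pairs, params: GenerationParams):
    if params.max_replacements is not None and len(pairs) > params.max_replacements:
        rng = random.Random(params.seed)
        return rng.sample(pairs, params.max_replacements)
    return pairs


def _splice_all(parent_canon: str, pairs) -> set[str]:
    products: set[str] = set()
    ctx_cache: dict[int, Chem.Mol] = {}
    for rec, old_to_new, entry in pairs:
        ctx_mol = ctx_cache.get(id(rec))
        if ctx_mol is None:
            ctx_mol = _renumbered_context_mol(rec.context_full, old_to_new)
            ctx_cache[id(rec)] = ctx_mol
        try:
            smi = _splice_mols(ctx_mol, _core_mol(entry.core))
        except SpliceError as exc:
            logger.debug("dropped splice %s + %s: %s", entry.core, entry.context, exc)
            continue
        if smi != parent_canon:
            products.add(smi)
    return products


def mutate(
    parent: MoleculeRecord | str, db: FragDB, params: GenerationParams
) -> set[str]:
    """Replace arbitrarily chosen fragments of the parent by interchangeable
    ones; returns deduplicated canonical SMILES, parent excluded."""
    mol = to_mol(parent)
    parent_canon = Chem.MolToSmiles(mol)
    records = fragment_molecule(mol, params.max_cuts)
    pairs = _candidate_pairs(records, db, params, mol.GetNumAtoms(), grow_only=False)
    return _splice_all(parent_canon, _sample_pairs(pairs, params))


def grow(
    parent: MoleculeRecord | str, db: FragDB, params: GenerationParams
) -> set[str]:
    """MUTATE restricted to hydrogen cores, with replacing cores of size >= 1."""
    mol = to_mol(parent)
    parent_canon = Chem.MolToSmiles(mol)
    records = hydrogen_cuts(mol)
    pairs = _candidate_pairs(records, db, params, mol.GetNumAtoms(), grow_only=True)
    return _splice_all(parent_canon, _sample_pairs(pairs, params))


def link(
    parent_a: MoleculeRecord | str,
    parent_b: MoleculeRecord | str,
    db: FragDB,
    params: GenerationParams,
) -> set[str]:
    """Join two molecules through a two-attachment fragment replacing one
    hydrogen on each parent."""
    mol_a = to_mol(parent_a)
    mol_b = to_mol(parent_b)
    pairs = []
    for rec_a in hydrogen_cuts(mol_a):
        ctx_a = parse_fragment(rec_a.context_full.smiles_ap)
        for rec_b in hydrogen_cuts(mol_b):
            ctx_b = Chem.Mol(parse_fragment(rec_b.context_full.smiles_ap))
            for atom in ctx_b.GetAtoms():
                if atom.GetAtomicNum() == 0:
                    atom.SetAtomMapNum(2)
            combined = Chem.CombineMols(ctx_a, ctx_b)
            combined_ctx = Context(Chem.MolToSmiles(combined, ignoreAtomMapNumbers=True), None)
            tctx = truncate_context(combined_ctx, params.radius)
            key, old_to_new, _ = canonical_context_key(tctx)
            for entry in db.query(params.radius, key.smiles_ap):
                if entry.count < params.min_freq:
                    continue
                if _core_k(entry.core) != 2:
                    continue
                if not (max(params.min_size, 1) <= entry.n_heavy <= params.max_size):
                    continue
                pairs.append(((combined_ctx, rec_a, rec_b), old_to_new, entry))
    products: set[str] = set()
    for (combined_ctx, _, _), old_to_new, entry in _sample_pairs(pairs, params):
        ctx_mol = _renumbered_context_mol(combined_ctx, old_to_new)
        try:
            products.add(_splice_mols(ctx_mol, _core_mol(entry.core)))
        except SpliceError as exc:
            logger.debug("dropped link splice %s: %s", entry.core, exc)
    return products
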
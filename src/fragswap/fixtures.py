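"""Synthetic test corpora and a brute-force interchangeability oracle.

The corpora have known fragment structure (homologous series, decorated
aromatic scaffolds, disubstituted chains) so every pipeline stage can be
exercised without external data.  The oracle re-derives the context/core
map and mutate outputs by direct, unoptimized enumeration that shares no
code with the main fragmentation/database/generation path beyond the
SMILES toolkit itself; in particular context truncation is recomputed from
the full distance matrix and attachment-point permutations are validated
by brute force over all k! relabelings.
"""

from __future__ import annotations

import itertools
import random
from collections import Counter
from dataclasses import dataclass

from rdkit import Chem

from .errors import ParameterError
from .records import MoleculeRecord, parse_smiles

CORPUS_KINDS = ("homologs", "decorated_aromatics", "linkers", "pains_free")

_SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C(=O)C", "C(=O)O", "C(=O)N", "C#N", "S", "SC", "CO",
    "CN", "CCO", "C(F)(F)F",
)
_CHAIN_ENDS = ("O", "N", "C", "Cl", "OC", "NC")

#: SMARTS excluded from ``pains_free`` corpora by default: a dialkyl ether
#: motif of graph diameter 2, convenient for motif-exclusion experiments.
DEFAULT_EXCLUDED_SMARTS = "[CX4][OX2][CX4]"


@dataclass(frozen=True)
class FixtureCorpus:
    """A deterministic, deduplicated corpus of sanitized molecules."""

    molecules: tuple[MoleculeRecord, ...]
    description: str
    expected: dict | None = None

    @property
    def smiles(self) -> list[str]:
        return [m.smiles for m in self.molecules]


def _decorated_aromatic(rng: random.Random, exclude=None) -> str | None:
    mol = Chem.RWMol(Chem.MolFromSmiles("c1ccccc1"))
    n_sub = rng.randint(1, 3)
    positions = rng.sample(range(6), n_sub)
    for pos in positions:
        sub = Chem.MolFromSmiles(
            rng.choice(_SUBSTITUENTS).join(["", ""])  # plain fragment SMILES
        )
        offset = mol.GetNumAtoms()
        mol.InsertMol(sub)
        mol.AddBond(pos, offset, Chem.BondType.SINGLE)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    if exclude is not None and out.HasSubstructMatch(exclude):
        return None
    return Chem.MolToSmiles(out)


def synth_corpus(
    kind: str,
    n: int,
    seed: int | None = None,
    excluded_smarts: str = DEFAULT_EXCLUDED_SMARTS,
) -> FixtureCorpus:
    """Generate a deterministic synthetic corpus of ``n`` molecules.

    Kinds: ``homologs`` (n-alkylbenzenes), ``decorated_aromatics`` (benzene
    with 1-3 sampled substituents), ``linkers`` (disubstituted alkyl
    chains), ``pains_free`` (decorated aromatics purged of
    ``excluded_smarts``).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if kind not in CORPUS_KINDS:
        raise ParameterError(f"unknown corpus kind {kind!r} (have {CORPUS_KINDS})")
    rng = random.Random(seed)
    smiles: list[str] = []
    seen: set[str] = set()

    def add(smi: str | None):
        if smi is None:
            return
        rec = parse_smiles(smi)
        if rec.smiles not in seen:
            seen.add(rec.smiles)
            smiles.append(rec.smiles)

    if kind == "homologs":
        for k in range(1, n + 1):
            add("c1ccccc1" + "C" * k)
    elif kind == "linkers":
        attempts = 0
        while len(smiles) < n and attempts < 100 * n:
            attempts += 1
            k = rng.randint(1, 6)
            e1, e2 = rng.choice(_CHAIN_ENDS), rng.choice(_CHAIN_ENDS)
            add(f"{e1}{'C' * k}{e2}")
    else:
        exclude = None
        if kind == "pains_free":
            exclude = Chem.MolFromSmarts(excluded_smarts)
            if exclude is None:
                raise ParameterError(f"invalid excluded SMARTS: {excluded_smarts!r}")
        attempts = 0
        while len(smiles) < n and attempts < 200 * n:
            attempts += 1
            add(_decorated_aromatic(rng, exclude))
    records = tuple(MoleculeRecord(s, f"{kind}-{i}") for i, s in enumerate(smiles))
    return FixtureCorpus(records, f"{kind} corpus (n={len(records)}, seed={seed})")


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _oracle_writer(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol, ignoreAtomMapNumbers=True)


def _oracle_marked(mol: Chem.Mol) -> Chem.Mol:
    """Copy with aromatic atoms left ring-less by truncation isotope-tagged,
    so the canonical form is stable and aromaticity-aware."""
    w = Chem.Mol(mol)
    ri = w.GetRingInfo()
    for a in w.GetAtoms():
        if a.GetIsAromatic() and ri.NumAtomRings(a.GetIdx()) == 0:
            a.SetIsotope(9)
    return w


def _oracle_key_writer(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(_oracle_marked(mol), ignoreAtomMapNumbers=True)


def _oracle_attachment_numbering(ctx: Chem.Mol) -> dict[int, int]:
    """old map -> new map, by first appearance of the dummies in the
    map-stripped, isotope-tagged canonical string."""
    work = _oracle_marked(ctx)
    old_by_idx = {}
    for a in work.GetAtoms():
        if a.GetAtomicNum() == 0:
            old_by_idx[a.GetIdx()] = a.GetAtomMapNum()
            a.SetAtomMapNum(0)
    Chem.MolToSmiles(work)
    order = list(work.GetPropsAsDict(True, True)["_smilesAtomOutputOrder"])
    dummy_order = [i for i in order if work.GetAtomWithIdx(i).GetAtomicNum() == 0]
    return {old_by_idx[idx]: pos for pos, idx in enumerate(dummy_order, 1)}


def _oracle_submol(mol: Chem.Mol, keep: list[int]) -> Chem.Mol:
    """Rebuild a fragment atom-by-atom (reverse order, to differ from the
    main path's deletion-based construction)."""
    keep_rev = sorted(keep, reverse=True)
    pos = {old: new for new, old in enumerate(keep_rev)}
    em = Chem.RWMol()
    for old in keep_rev:
        src = mol.GetAtomWithIdx(old)
        atom = Chem.Atom(src.GetAtomicNum())
        atom.SetFormalCharge(src.GetFormalCharge())
        atom.SetIsAromatic(src.GetIsAromatic())
        atom.SetNumExplicitHs(src.GetNumExplicitHs())
        atom.SetAtomMapNum(src.GetAtomMapNum())
        em.AddAtom(atom)
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in pos and b in pos:
            em.AddBond(pos[a], pos[b], bond.GetBondType())
    out = em.GetMol()
    out.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(out)
    return out


def _oracle_truncate(ctx: Chem.Mol, radius: int) -> Chem.Mol:
    """Distance-matrix based truncation around attachment dummies."""
    dmat = Chem.GetDistanceMatrix(ctx)
    dummies = [a.GetIdx() for a in ctx.GetAtoms() if a.GetAtomicNum() == 0]
    keep = [
        i
        for i in range(ctx.GetNumAtoms())
        if min(dmat[i][d] for d in dummies) <= radius
    ]
    return _oracle_submol(ctx, keep)


def _oracle_canonical_pair(ctx: Chem.Mol, core: Chem.Mol) -> tuple[str, list[str]]:
    """Canonical context string and all stored core variants, permutations
    validated by brute force: a relabeling is kept iff it leaves the
    canonical context string unchanged."""
    old_to_new = _oracle_attachment_numbering(ctx)
    k = len(old_to_new)

    def ctx_string(relabel: dict[int, int]) -> str:
        w = Chem.Mol(ctx)
        for a in w.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(relabel[old_to_new[a.GetAtomMapNum()]])
        return _oracle_key_writer(w)

    identity = {i: i for i in range(1, k + 1)}
    base = ctx_string(identity)
    variants = set()
    for perm in itertools.permutations(range(1, k + 1)):
        relabel = dict(zip(range(1, k + 1), perm))
        if ctx_string(relabel) != base:
            continue
        w = Chem.Mol(core)
        for a in w.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(relabel[old_to_new[a.GetAtomMapNum()]])
        variants.add(Chem.MolToSmiles(w))  # labeled-graph canonical form
    return base, sorted(variants)


def _oracle_fragmentations(mol: Chem.Mol) -> list[tuple[Chem.Mol, Chem.Mol, int]]:
    """(core, full context, core heavy count) splits by direct enumeration."""
    out = []
    cuttable = [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE
        and not b.IsInRing()
        and b.GetBeginAtom().GetAtomicNum() > 1
        and b.GetEndAtom().GetAtomicNum() > 1
    ]
    for k in range(1, min(4, len(cuttable)) + 1):
        for cut in itertools.combinations(cuttable, k):
            fmol = Chem.FragmentOnBonds(
                mol, list(cut), addDummies=True,
                dummyLabels=[(i, i) for i in range(1, k + 1)],
            )
            for a in fmol.GetAtoms():
                if a.GetAtomicNum() == 0 and a.GetIsotope():
                    a.SetAtomMapNum(a.GetIsotope())
                    a.SetIsotope(0)
            fmol.UpdatePropertyCache(strict=False)
            Chem.FastFindRings(fmol)
            comps = Chem.GetMolFrags(fmol)
            for comp in comps:
                maps = sorted(
                    fmol.GetAtomWithIdx(i).GetAtomMapNum()
                    for i in comp
                    if fmol.GetAtomWithIdx(i).GetAtomicNum() == 0
                )
                if maps != list(range(1, k + 1)):
                    continue
                rest = [i for c in comps if c is not comp for i in c]
                if not rest:
                    continue
                core = _oracle_submol(fmol, list(comp))
                ctx = _oracle_submol(fmol, rest)
                n_heavy = sum(1 for a in core.GetAtoms() if a.GetAtomicNum() > 1)
                out.append((core, ctx, n_heavy))
    # hydrogen cuts through an explicit-hydrogen route
    hmol = Chem.AddHs(mol)
    seen_ctx = set()
    for atom in hmol.GetAtoms():
        if atom.GetAtomicNum() != 1:
            continue
        heavy = atom.GetNeighbors()[0]
        if heavy.GetAtomicNum() <= 1:
            continue
        em = Chem.RWMol(hmol)
        em.RemoveAtom(atom.GetIdx())
        d = em.AddAtom(Chem.Atom(0))
        em.GetAtomWithIdx(d).SetAtomMapNum(1)
        em.AddBond(
            heavy.GetIdx() if heavy.GetIdx() < atom.GetIdx() else heavy.GetIdx() - 1,
            d,
            Chem.BondType.SINGLE,
        )
        ctx = em.GetMol()
        Chem.SanitizeMol(ctx)
        ctx = Chem.RemoveHs(ctx)
        key = Chem.MolToSmiles(ctx)
        if key in seen_ctx:
            continue
        seen_ctx.add(key)
        core = Chem.MolFromSmiles("[H][*:1]", sanitize=False)
        core.UpdatePropertyCache(strict=False)
        out.append((core, ctx, 0))
    return out


def oracle_interchangeable(
    corpus: FixtureCorpus, radius: int
) -> dict[str, Counter]:
    """Map canonical context -> multiset of core SMILES with per-molecule
    occurrence counts, by direct enumeration."""
    table: dict[str, Counter] = {}
    for rec in corpus.molecules:
        mol = Chem.MolFromSmiles(rec.smiles)
        per_mol: set[tuple[str, str]] = set()
        for core, ctx, _ in _oracle_fragmentations(mol):
            tctx = _oracle_truncate(ctx, radius)
            base, variants = _oracle_canonical_pair(tctx, core)
            for v in variants:
                per_mol.add((base, v))
        for base, v in per_mol:
            table.setdefault(base, Counter())[v] += 1
    return table


def _oracle_hydrogen_contexts(mol: Chem.Mol) -> list[Chem.Mol]:
    """Distinct single-dummy contexts for every hydrogen position."""
    out, seen = [], set()
    hmol = Chem.AddHs(mol)
    for atom in hmol.GetAtoms():
        if atom.GetAtomicNum() != 1:
            continue
        heavy = atom.GetNeighbors()[0]
        if heavy.GetAtomicNum() <= 1:
            continue
        em = Chem.RWMol(hmol)
        em.RemoveAtom(atom.GetIdx())
        d = em.AddAtom(Chem.Atom(0))
        em.GetAtomWithIdx(d).SetAtomMapNum(1)
        em.AddBond(
            heavy.GetIdx() if heavy.GetIdx() < atom.GetIdx() else heavy.GetIdx() - 1,
            d,
            Chem.BondType.SINGLE,
        )
        ctx = em.GetMol()
        Chem.SanitizeMol(ctx)
        ctx = Chem.RemoveHs(ctx)
        key = Chem.MolToSmiles(ctx)
        if key not in seen:
            seen.add(key)
            out.append(ctx)
    return out


def oracle_link(
    parent_a: MoleculeRecord | str,
    parent_b: MoleculeRecord | str,
    corpus: FixtureCorpus,
    radius: int,
    min_size: int = 1,
    max_size: int = 10,
    min_freq: int = 0,
) -> set[str]:
    """Exhaustive link outputs by naive enumeration of hydrogen-position
    pairs and two-attachment candidate cores."""
    table = oracle_interchangeable(corpus, radius)
    sizes = {}
    ks = {}
    for counter in table.values():
        for smi in counter:
            m = Chem.MolFromSmiles(smi, sanitize=False)
            sizes[smi] = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() > 1)
            ks[smi] = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 0)
    sa = parent_a.smiles if isinstance(parent_a, MoleculeRecord) else parent_a
    sb = parent_b.smiles if isinstance(parent_b, MoleculeRecord) else parent_b
    products: set[str] = set()
    for ctx_a in _oracle_hydrogen_contexts(Chem.MolFromSmiles(sa)):
        for ctx_b in _oracle_hydrogen_contexts(Chem.MolFromSmiles(sb)):
            cb = Chem.Mol(ctx_b)
            for a in cb.GetAtoms():
                if a.GetAtomicNum() == 0:
                    a.SetAtomMapNum(2)
            combined = Chem.CombineMols(ctx_a, cb)
            tctx = _oracle_truncate(combined, radius)
            base = _oracle_key_writer_mapped(tctx)
            old_to_new = _oracle_attachment_numbering(tctx)
            ctx_re = Chem.Mol(combined)
            for a in ctx_re.GetAtoms():
                if a.GetAtomicNum() == 0:
                    a.SetAtomMapNum(old_to_new[a.GetAtomMapNum()])
            for cand, count in table.get(base, Counter()).items():
                if count < min_freq or ks[cand] != 2:
                    continue
                if not (min_size <= sizes[cand] <= max_size):
                    continue
                cand_mol = Chem.MolFromSmiles(cand, sanitize=False)
                cand_mol.UpdatePropertyCache(strict=False)
                try:
                    joined = Chem.molzip(Chem.CombineMols(ctx_re, cand_mol))
                    Chem.SanitizeMol(joined)
                    products.add(Chem.MolToSmiles(Chem.RemoveHs(joined)))
                except Exception:
                    continue
    return products


def _oracle_key_writer_mapped(ctx: Chem.Mol) -> str:
    """Canonical key of a context after canonical attachment renumbering."""
    old_to_new = _oracle_attachment_numbering(ctx)
    w = Chem.Mol(ctx)
    for a in w.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomMapNum(old_to_new[a.GetAtomMapNum()])
    return _oracle_key_writer(w)


def oracle_mutate(
    parent: MoleculeRecord | str,
    corpus: FixtureCorpus,
    radius: int,
    min_size: int = 0,
    max_size: int = 10,
    min_inc: int = -2,
    max_inc: int = 2,
    min_freq: int = 0,
    max_rel_size: float | None = None,
) -> set[str]:
    """Exhaustive mutate outputs by naive splicing of every candidate."""
    table = oracle_interchangeable(corpus, radius)
    sizes = {
        smi: sum(
            1
            for a in Chem.MolFromSmiles(smi, sanitize=False).GetAtoms()
            if a.GetAtomicNum() > 1
        )
        for counter in table.values()
        for smi in counter
    }
    smiles = parent.smiles if isinstance(parent, MoleculeRecord) else parent
    mol = Chem.MolFromSmiles(smiles)
    parent_canon = Chem.MolToSmiles(mol)
    n_parent = mol.GetNumAtoms()
    products: set[str] = set()
    for core, ctx, n_heavy in _oracle_fragmentations(mol):
        if not (min_size <= n_heavy <= max_size):
            continue
        if max_rel_size is not None and n_heavy / n_parent > max_rel_size:
            continue
        tctx = _oracle_truncate(ctx, radius)
        base, _ = _oracle_canonical_pair(tctx, core)
        # renumber the full context the same way the canonical key was built
        old_to_new = _oracle_attachment_numbering(tctx)
        ctx_re = Chem.Mol(ctx)
        for a in ctx_re.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(old_to_new[a.GetAtomMapNum()])
        for cand, count in table.get(base, Counter()).items():
            if count < min_freq:
                continue
            if not (min_inc <= sizes[cand] - n_heavy <= max_inc):
                continue
            cand_mol = Chem.MolFromSmiles(cand, sanitize=False)
            cand_mol.UpdatePropertyCache(strict=False)
            try:
                joined = Chem.molzip(Chem.CombineMols(ctx_re, cand_mol))
                Chem.SanitizeMol(joined)
                smi = Chem.MolToSmiles(Chem.RemoveHs(joined))
            except Exception:
                continue
            if smi != parent_canon:
                products.add(smi)
    return products
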
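"""Matched-pair style fragmentation with canonicalized attachment contexts.

Molecules are fragmented by cutting 1..``max_cuts`` acyclic single bonds
between heavy atoms; hydrogens are cut through a separate pathway.  Each
fragmentation yields a *core* (the replaceable fragment, carrying numbered
attachment dummies ``[*:i]``) and its *context* (the remainder of the
molecule with matching attachment numbers).  Contexts truncated to a bond
radius ``r`` around the attachment points, canonically renumbered and
written as canonical SMILES, are the keys under which cores are considered
interchangeable.

Truncated contexts are string keys, not necessarily sanitizable molecules:
an aromatic atom whose ring was truncated away stays aromatic in the key.
They round-trip through ``Chem.MolFromSmiles(smi, sanitize=False)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from rdkit import Chem

from .errors import ContractViolation, ParameterError
from .records import MoleculeRecord, to_mol

#: Canonical SMILES of the hydrogen core (the fragment replaced by GROW).
HYDROGEN_CORE = "[H][*:1]"

#: Maximum number of simultaneous bond cuts supported.
MAX_CUTS = 4


@dataclass(frozen=True)
class Core:
    """A fragment with ``k`` numbered attachment points.

    ``n_heavy`` excludes attachment dummies; the hydrogen core has
    ``n_heavy == 0`` and ``k == 1``.
    """

    smiles_ap: str
    n_heavy: int
    k: int


@dataclass(frozen=True)
class Context:
    """The environment of a core's attachment points.

    ``radius`` is the bond-topology truncation radius; ``None`` denotes the
    untruncated full context.
    """

    smiles_ap: str
    radius: int | None = None


@dataclass(frozen=True)
class FragmentationRecord:
    """One (core, full context) split of a source molecule.

    ``cut_bonds`` holds atom-index pairs of the source molecule; hydrogen
    cuts use ``(heavy_atom_index, -1)``.  ``core_atoms`` are the source
    atom indices inside the core (the anchor atom for hydrogen cuts),
    used for atom protection.
    """

    core: Core
    context_full: Context
    source_id: str | None = None
    cut_bonds: tuple[tuple[int, int], ...] = ()
    core_atoms: tuple[int, ...] = field(default=(), compare=False)


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def write_smiles(mol: Chem.Mol) -> str:
    """Canonical SMILES with atom maps excluded from the canonical ranking.

    Used for contexts, where the attachment numbering is derived from the
    map-stripped canonical form and must not feed back into it.
    """
    return Chem.MolToSmiles(mol, ignoreAtomMapNumbers=True)


def write_core_smiles(mol: Chem.Mol) -> str:
    """Canonical SMILES of a core as a *labeled* graph (maps rank-relevant).

    Cores need maps in the canonical ranking: with maps ignored, the
    placement of labels among automorphic attachment atoms would depend on
    the input atom order, making equal cores compare unequal.
    """
    return Chem.MolToSmiles(mol)


#: Isotope tag applied to aromatic atoms whose ring was truncated away.
#: The canonical ranking ignores the aromatic flag of such ring-less atoms,
#: which would make key strings depend on input atom order; an isotope is
#: part of the ranking invariants and restores a stable, aromaticity-aware
#: canonical form.  Standardization strips genuine isotopes, so the tag
#: cannot collide.
AROMATIC_MARK = 9


def _mark_ringless_aromatics(mol: Chem.Mol) -> Chem.Mol:
    """Copy with ring-stripped aromatic atoms isotope-tagged for key writing."""
    marked = Chem.Mol(mol)
    for atom in marked.GetAtoms():
        if atom.GetIsAromatic() and not atom.IsInRing():
            atom.SetIsotope(AROMATIC_MARK)
    return marked


def parse_fragment(smiles: str) -> Chem.Mol:
    """Parse a fragment/context SMILES, tolerating unsanitizable keys."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        mol = Chem.MolFromSmiles(smiles, sanitize=False)
        if mol is None:
            raise ContractViolation(f"unparsable fragment SMILES: {smiles!r}")
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
    return mol


def _dummy_maps(mol: Chem.Mol) -> dict[int, int]:
    """Map atom index -> atom map number for every attachment dummy."""
    out = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            out[atom.GetIdx()] = atom.GetAtomMapNum()
    return out


def _extract_submol(mol: Chem.Mol, keep: set[int]) -> Chem.Mol:
    """Copy of ``mol`` restricted to ``keep`` atom indices.

    Valences opened by the deletion are left to implicit hydrogens; ring
    perception is redone so the result is writable as SMILES even when it
    is no longer sanitizable.
    """
    em = Chem.RWMol(mol)
    for idx in sorted((a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in keep),
                      reverse=True):
        em.RemoveAtom(idx)
    sub = em.GetMol()
    sub.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(sub)
    return sub


def _n_heavy(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1 and a.GetAtomicNum() != 0)


# ---------------------------------------------------------------------------
# cut enumeration and fragmentation
# ---------------------------------------------------------------------------

def eligible_bonds(mol: Chem.Mol) -> list[int]:
    """Indices of single, acyclic bonds joining two heavy atoms."""
    out = []
    for bond in mol.GetBonds():
        if (
            bond.GetBondType() == Chem.BondType.SINGLE
            and not bond.IsInRing()
            and bond.GetBeginAtom().GetAtomicNum() > 1
            and bond.GetEndAtom().GetAtomicNum() > 1
        ):
            out.append(bond.GetIdx())
    return sorted(out)


def enumerate_cut_sets(
    mol: MoleculeRecord | str | Chem.Mol, max_cuts: int = MAX_CUTS
) -> list[tuple[int, ...]]:
    """Every set of 1..``max_cuts`` distinct cuttable bonds, sorted."""
    if max_cuts < 1:
        raise ParameterError("max_cuts must be >= 1")
    bonds = eligible_bonds(to_mol(mol))
    sets: list[tuple[int, ...]] = []
    for size in range(1, min(max_cuts, len(bonds)) + 1):
        sets.extend(itertools.combinations(bonds, size))
    return sets


def fragment_on_cut_set(
    mol: MoleculeRecord | str | Chem.Mol,
    cut_set: tuple[int, ...],
    source_id: str | None = None,
) -> list[FragmentationRecord]:
    """Cut all bonds in ``cut_set`` and emit (core, context) records.

    The two ends of cut ``i`` receive map number ``i``.  A connected
    component qualifies as a core when its attachment count equals
    ``len(cut_set)``; for a single cut both components qualify.
    """
    m = to_mol(mol)
    if isinstance(mol, MoleculeRecord) and source_id is None:
        source_id = mol.id
    k = len(cut_set)
    if k < 1:
        raise ContractViolation("empty cut set")
    for bidx in cut_set:
        bond = m.GetBondWithIdx(int(bidx))
        if (
            bond.GetBondType() != Chem.BondType.SINGLE
            or bond.IsInRing()
            or bond.GetBeginAtom().GetAtomicNum() <= 1
            or bond.GetEndAtom().GetAtomicNum() <= 1
        ):
            raise ContractViolation(f"bond {bidx} is not a cuttable acyclic single bond")

    cut_bonds = tuple(
        (m.GetBondWithIdx(int(b)).GetBeginAtomIdx(), m.GetBondWithIdx(int(b)).GetEndAtomIdx())
        for b in cut_set
    )
    labels = [(i, i) for i in range(1, k + 1)]
    fmol = Chem.FragmentOnBonds(m, [int(b) for b in cut_set], addDummies=True,
                                dummyLabels=labels)
    for atom in fmol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetIsotope():
            atom.SetAtomMapNum(atom.GetIsotope())
            atom.SetIsotope(0)
    fmol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(fmol)

    n_parent = m.GetNumAtoms()
    components = Chem.GetMolFrags(fmol)
    comp_info = []
    for comp in components:
        maps = sorted(
            fmol.GetAtomWithIdx(i).GetAtomMapNum()
            for i in comp
            if fmol.GetAtomWithIdx(i).GetAtomicNum() == 0
        )
        comp_info.append((comp, maps))

    records = []
    full_maps = list(range(1, k + 1))
    for ci, (comp, maps) in enumerate(comp_info):
        if maps != full_maps:
            continue
        if k > 1 or len(comp_info) == 2:
            core_keep = set(comp)
            ctx_keep = {i for other, _ in comp_info if other is not comp for i in other}
            if not ctx_keep:
                continue
            core_mol = _extract_submol(fmol, core_keep)
            ctx_mol = _extract_submol(fmol, ctx_keep)
            core = Core(write_core_smiles(core_mol), _n_heavy(core_mol), k)
            ctx = Context(write_smiles(ctx_mol), None)
            core_atoms = tuple(sorted(i for i in comp if i < n_parent))
            records.append(
                FragmentationRecord(core, ctx, source_id, cut_bonds, core_atoms)
            )
    return records


def hydrogen_cuts(
    mol: MoleculeRecord | str | Chem.Mol, source_id: str | None = None
) -> list[FragmentationRecord]:
    """One record per symmetry-distinct hydrogen position.

    The core is always ``[H][*:1]``; the context is the whole molecule with
    one hydrogen at the chosen atom replaced by the mapped attachment dummy.
    Records with identical canonical contexts are deduplicated.
    """
    m = to_mol(mol)
    if isinstance(mol, MoleculeRecord) and source_id is None:
        source_id = mol.id
    core = Core(HYDROGEN_CORE, 0, 1)
    seen: set[str] = set()
    records = []
    for atom in m.GetAtoms():
        if atom.GetAtomicNum() <= 1 or atom.GetTotalNumHs() < 1:
            continue
        em = Chem.RWMol(m)
        a = em.GetAtomWithIdx(atom.GetIdx())
        if a.GetNumExplicitHs() > 0:
            a.SetNumExplicitHs(a.GetNumExplicitHs() - 1)
        d = em.AddAtom(Chem.Atom(0))
        em.GetAtomWithIdx(d).SetAtomMapNum(1)
        em.AddBond(atom.GetIdx(), d, Chem.BondType.SINGLE)
        ctx_mol = em.GetMol()
        Chem.SanitizeMol(ctx_mol)
        smi = write_smiles(ctx_mol)
        if smi in seen:
            continue
        seen.add(smi)
        records.append(
            FragmentationRecord(
                core,
                Context(smi, None),
                source_id,
                ((atom.GetIdx(), -1),),
                (atom.GetIdx(),),
            )
        )
    return records


def fragment_molecule(
    mol: MoleculeRecord | str | Chem.Mol,
    max_cuts: int = MAX_CUTS,
    source_id: str | None = None,
) -> list[FragmentationRecord]:
    """All bond-cut records plus hydrogen-cut records for one molecule."""
    m = to_mol(mol)
    if isinstance(mol, MoleculeRecord) and source_id is None:
        source_id = mol.id
    records = []
    for cut_set in enumerate_cut_sets(m, max_cuts):
        records.extend(fragment_on_cut_set(m, cut_set, source_id))
    records.extend(hydrogen_cuts(m, source_id))
    return records


# ---------------------------------------------------------------------------
# context truncation
# ---------------------------------------------------------------------------

def _distances_to_dummies(mol: Chem.Mol) -> dict[int, int]:
    """Shortest bond distance of every atom to the nearest attachment dummy."""
    dist = {}
    frontier = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    for idx in frontier:
        dist[idx] = 0
    d = 0
    while frontier:
        d += 1
        nxt = []
        for idx in frontier:
            for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
                j = nb.GetIdx()
                if j not in dist:
                    dist[j] = d
                    nxt.append(j)
        frontier = nxt
    return dist


def truncate_context(context: Context, radius: int) -> Context:
    """Restrict a context to atoms within ``radius`` bonds of any dummy."""
    if radius < 1:
        raise ParameterError("radius must be >= 1")
    mol = parse_fragment(context.smiles_ap)
    dist = _distances_to_dummies(mol)
    keep = {i for i, d in dist.items() if d <= radius}
    if len(keep) == mol.GetNumAtoms():
        return Context(write_smiles(mol), radius)
    sub = _extract_submol(mol, keep)
    return Context(write_smiles(sub), radius)


# ---------------------------------------------------------------------------
# canonicalization of (context, core) pairs
# ---------------------------------------------------------------------------

@lru_cache(maxsize=500_000)
def _context_key_info(
    ctx_smiles: str,
) -> tuple[str, tuple[tuple[int, int], ...], tuple[tuple[tuple[int, int], ...], ...]]:
    """Canonical form of a context and the induced attachment renumbering.

    Returns ``(canonical_smiles, old_to_new_map_items, permutations)``.
    ``permutations`` holds every relabeling of the new attachment numbers
    that leaves the canonical context string unchanged, i.e. permutations
    of symmetry-equivalent attachment points: candidate groups come from
    equal canonical ranks of the dummies in the map-stripped ranking and
    each candidate permutation is verified by string equality.
    """
    mol = parse_fragment(ctx_smiles)
    work = _mark_ringless_aromatics(mol)
    old_by_idx = _dummy_maps(work)
    for idx in old_by_idx:
        work.GetAtomWithIdx(idx).SetAtomMapNum(0)
    Chem.MolToSmiles(work)
    order = list(work.GetPropsAsDict(True, True)["_smilesAtomOutputOrder"])
    ranks = list(Chem.CanonicalRankAtoms(work, breakTies=False))
    dummy_order = [idx for idx in order if work.GetAtomWithIdx(idx).GetAtomicNum() == 0]
    k = len(dummy_order)
    old_to_new = {}
    new_by_idx = {}
    for pos, idx in enumerate(dummy_order, start=1):
        old_to_new[old_by_idx[idx]] = pos
        new_by_idx[idx] = pos
    for idx, new in new_by_idx.items():
        work.GetAtomWithIdx(idx).SetAtomMapNum(new)
    canon = write_smiles(work)

    groups: dict[int, list[int]] = {}
    for idx, new in new_by_idx.items():
        groups.setdefault(ranks[idx], []).append(new)
    equiv = tuple(
        tuple(sorted(g)) for g in sorted(groups.values(), key=min) if len(g) > 1
    )

    def relabeled(perm: dict[int, int]) -> str:
        w = Chem.Mol(work)
        for idx, new in new_by_idx.items():
            w.GetAtomWithIdx(idx).SetAtomMapNum(perm[new])
        return write_smiles(w)

    identity = {i: i for i in range(1, k + 1)}
    perms = []
    for cand in _label_permutations(k, equiv):
        if cand == identity or relabeled(cand) == canon:
            perms.append(tuple(sorted(cand.items())))
    return canon, tuple(sorted(old_to_new.items())), tuple(perms)


def canonical_context_key(
    context: Context,
) -> tuple[Context, dict[int, int], tuple[dict[int, int], ...]]:
    """Canonicalize a context; also return the old->new map renumbering and
    the attachment-label permutations under which the context is invariant."""
    canon, items, perms = _context_key_info(context.smiles_ap)
    return Context(canon, context.radius), dict(items), tuple(dict(p) for p in perms)


def _renumber_core(core_mol: Chem.Mol, mapping: dict[int, int]) -> str:
    work = Chem.Mol(core_mol)
    for atom in work.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(mapping[atom.GetAtomMapNum()])
    return write_core_smiles(work)


def _label_permutations(
    k: int, equiv: tuple[tuple[int, ...], ...]
) -> list[dict[int, int]]:
    """All permutations of attachment labels within symmetry-equivalent groups."""
    perms = [dict(zip(range(1, k + 1), range(1, k + 1)))]
    for group in equiv:
        new_perms = []
        for perm in perms:
            for assign in itertools.permutations(group):
                p = dict(perm)
                for src, dst in zip(group, assign):
                    p[src] = dst
                new_perms.append(p)
        perms = new_perms
    return perms


def canonicalize_pair(context: Context, core: Core) -> tuple[Context, list[Core]]:
    """Canonicalize a context and emit the canonically renumbered core variants.

    The context canonical SMILES is computed with map numbers excluded from
    the ranking and attachment numbers reassigned 1..k in order of first
    appearance.  When several attachment points share an identical context
    environment, one core variant per distinct permutation of the
    equivalent labels is returned; variants identical after core
    canonicalization collapse.
    """
    ctx_mol = parse_fragment(context.smiles_ap)
    core_mol = parse_fragment(core.smiles_ap)
    ctx_maps = set(_dummy_maps(ctx_mol).values())
    core_maps = set(_dummy_maps(core_mol).values())
    k = len(core_maps)
    if ctx_maps != core_maps or core_maps != set(range(1, k + 1)):
        raise ContractViolation(
            f"attachment map mismatch: context {sorted(ctx_maps)} vs core {sorted(core_maps)}"
        )
    canon_ctx, old_to_new, perms = canonical_context_key(context)
    variants: set[str] = set()
    for perm in perms:
        mapping = {old: perm[new] for old, new in old_to_new.items()}
        variants.add(_renumber_core(core_mol, mapping))
    cores = [Core(s, core.n_heavy, core.k) for s in sorted(variants)]
    return canon_ctx, cores
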
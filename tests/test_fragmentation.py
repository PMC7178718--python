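import itertools
import random

import pytest
from rdkit import Chem

import fragswap as fs
from fragswap.errors import ContractViolation, ParameterError
from fragswap.fragmentation import Context, Core, eligible_bonds, parse_fragment


def n_atoms(smiles_ap):
    return parse_fragment(smiles_ap).GetNumAtoms()


class TestEnumerateCutSets:
    def test_benzene_has_no_cuttable_bonds(self):
        assert fs.enumerate_cut_sets("c1ccccc1") == []

    def test_toluene_single_cut(self):
        assert len(fs.enumerate_cut_sets("Cc1ccccc1")) == 1

    def test_butane_subset_count_matches_brute_force(self):
        # independent count: all subsets of size 1..4 of the 3 acyclic bonds
        mol = Chem.MolFromSmiles("CCCC")
        bonds = eligible_bonds(mol)
        expected = sum(
            1
            for size in range(1, 5)
            for _ in itertools.combinations(bonds, size)
        )
        assert expected == 7
        assert len(fs.enumerate_cut_sets("CCCC", 4)) == 7

    def test_max_cuts_limits_subset_size(self):
        sets = fs.enumerate_cut_sets("CCCC", 1)
        assert all(len(s) == 1 for s in sets) and len(sets) == 3

    def test_invalid_max_cuts(self):
        with pytest.raises(ParameterError):
            fs.enumerate_cut_sets("CC", 0)

    def test_deterministic_order(self):
        assert fs.enumerate_cut_sets("CCCCO") == fs.enumerate_cut_sets("CCCCO")


class TestFragmentOnCutSet:
    def test_toluene_both_directions(self):
        (cut,) = fs.enumerate_cut_sets("Cc1ccccc1")
        records = fs.fragment_on_cut_set("Cc1ccccc1", cut)
        assert len(records) == 2
        methyl = Chem.MolToSmiles(Chem.MolFromSmiles("[*:1]C"))
        phenyl = Chem.MolToSmiles(Chem.MolFromSmiles("[*:1]c1ccccc1"))
        sizes = {r.core.smiles_ap: r.core.n_heavy for r in records}
        assert sizes == {methyl: 1, phenyl: 6}

    def test_butane_middle_core(self):
        mol = Chem.MolFromSmiles("CCCC")
        pair = tuple(eligible_bonds(mol)[:2])  # C1-C2 and C2-C3
        records = fs.fragment_on_cut_set("CCCC", pair)
        assert len(records) == 1
        rec = records[0]
        assert rec.core.k == 2 and rec.core.n_heavy == 1
        # context has two disconnected components (methyl + ethyl)
        assert rec.context_full.smiles_ap.count(".") == 1

    def test_butane_three_cuts_no_qualifying_component(self):
        mol = Chem.MolFromSmiles("CCCC")
        records = fs.fragment_on_cut_set("CCCC", tuple(eligible_bonds(mol)))
        assert records == []

    def test_ring_bond_rejected(self):
        mol = Chem.MolFromSmiles("C1CCCCC1")
        with pytest.raises(ContractViolation):
            fs.fragment_on_cut_set("C1CCCCC1", (0,))

    def test_cut_legality_all_emitted_records(self):
        mol = Chem.MolFromSmiles("CCOc1ccccc1")
        ok = set(eligible_bonds(mol))
        for cut in fs.enumerate_cut_sets(mol):
            assert set(cut) <= ok


class TestHydrogenCuts:
    @pytest.mark.parametrize(
        "smiles,n", [("c1ccccc1", 1), ("C", 1), ("Cc1ccccc1", 4)]
    )
    def test_distinct_positions(self, smiles, n):
        assert len(fs.hydrogen_cuts(smiles)) == n

    def test_core_is_hydrogen(self):
        for rec in fs.hydrogen_cuts("CO"):
            assert rec.core.smiles_ap == fs.HYDROGEN_CORE
            assert rec.core.n_heavy == 0 and rec.core.k == 1

    def test_no_hydrogens_no_records(self):
        assert fs.hydrogen_cuts("FC(F)(F)F") == []


class TestTruncateContext:
    def test_identity_at_large_radius(self):
        ctx = Context("[*:1]c1ccccc1", None)
        assert fs.truncate_context(ctx, 50).smiles_ap == "[*:1]c1ccccc1"

    def test_toluene_methyl_context_radius_1(self):
        (cut,) = fs.enumerate_cut_sets("Cc1ccccc1")
        rec = next(
            r
            for r in fs.fragment_on_cut_set("Cc1ccccc1", cut)
            if r.core.n_heavy == 1
        )
        tctx = fs.truncate_context(rec.context_full, 1)
        mol = parse_fragment(tctx.smiles_ap)
        atoms = [a for a in mol.GetAtoms() if a.GetAtomicNum() != 0]
        assert len(atoms) == 1 and atoms[0].GetIsAromatic()

    def test_benzene_hydrogen_context_radius_2(self):
        (rec,) = fs.hydrogen_cuts("c1ccccc1")
        tctx = fs.truncate_context(rec.context_full, 2)
        mol = parse_fragment(tctx.smiles_ap)
        heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() != 0]
        assert len(heavy) == 3 and all(a.GetIsAromatic() for a in heavy)

    def test_invalid_radius(self):
        with pytest.raises(ParameterError):
            fs.truncate_context(Context("[*:1]C", None), 0)

    def test_truncation_nesting(self):
        for rec in fs.fragment_molecule("CCOc1ccc(CC(N)=O)cc1")[:40]:
            for r in (1, 2, 3):
                inner = fs.truncate_context(rec.context_full, r)
                outer = fs.truncate_context(rec.context_full, r + 1)
                assert n_atoms(inner.smiles_ap) <= n_atoms(outer.smiles_ap)
                # re-truncating the wider context reproduces the narrow one
                assert fs.truncate_context(outer, r).smiles_ap == inner.smiles_ap


class TestCanonicalizePair:
    def test_single_attachment_single_variant(self):
        ctx, variants = fs.canonicalize_pair(
            Context("[*:1]c1ccccc1", None), Core("[*:1]C", 1, 1)
        )
        assert len(variants) == 1

    def test_equivalent_contexts_store_two_variants(self):
        # asymmetric 2-attachment core whose contexts both truncate to a
        # methyl-like carbon at radius 1
        records = [
            r
            for cut in fs.enumerate_cut_sets("CCOC(C)=O", 2)
            for r in fs.fragment_on_cut_set("CCOC(C)=O", cut)
            if r.core.k == 2 and r.core.n_heavy == 2
            and "O" in r.core.smiles_ap and "=" not in r.core.smiles_ap
        ]
        rec = records[0]
        tctx = fs.truncate_context(rec.context_full, 1)
        _, variants = fs.canonicalize_pair(tctx, rec.core)
        assert len(variants) == 2

    def test_inequivalent_contexts_single_variant(self):
        # CH2 core between a carbon and an oxygen context (ethyl acetate)
        records = [
            r
            for cut in fs.enumerate_cut_sets("CCOC(C)=O", 2)
            for r in fs.fragment_on_cut_set("CCOC(C)=O", cut)
            if r.core.k == 2 and r.core.n_heavy == 1
        ]
        rec = records[0]
        _, variants = fs.canonicalize_pair(rec.context_full, rec.core)
        assert len(variants) == 1

    def test_map_mismatch_raises(self):
        with pytest.raises(ContractViolation):
            fs.canonicalize_pair(Context("[*:1]C", None), Core("[H][*:2]", 0, 1))

    def test_idempotent(self):
        rec = fs.fragment_molecule("CCOc1ccccc1")[5]
        ctx1, cores1 = fs.canonicalize_pair(rec.context_full, rec.core)
        ctx2, cores2 = fs.canonicalize_pair(ctx1, cores1[0])
        assert ctx1.smiles_ap == ctx2.smiles_ap
        assert cores1[0].smiles_ap in {c.smiles_ap for c in cores2}

    @pytest.mark.parametrize("seed", range(5))
    def test_stable_under_atom_renumbering(self, seed):
        rec = next(
            r for r in fs.fragment_molecule("CC(C)Oc1ccc(F)cc1") if r.core.k >= 2
        )
        tctx = fs.truncate_context(rec.context_full, 1)
        ctx1, cores1 = fs.canonicalize_pair(tctx, rec.core)

        def shuffled(smiles_ap):
            mol = parse_fragment(smiles_ap)
            order = list(range(mol.GetNumAtoms()))
            random.Random(seed).shuffle(order)
            return Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)

        ctx2, cores2 = fs.canonicalize_pair(
            Context(shuffled(tctx.smiles_ap), 1),
            Core(shuffled(rec.core.smiles_ap), rec.core.n_heavy, rec.core.k),
        )
        assert ctx1.smiles_ap == ctx2.smiles_ap
        assert {c.smiles_ap for c in cores1} == {c.smiles_ap for c in cores2}

    def test_permutation_count_bounded_by_k_factorial(self):
        # CF3 attached to benzene: cutting all four bonds around the central
        # carbon gives three equivalent fluorine contexts; the core itself is
        # fully symmetric, so all label permutations collapse after core
        # canonicalization.  The count must equal the brute-force oracle's.
        from fragswap.fixtures import _oracle_canonical_pair
        from fragswap.fragmentation import parse_fragment as pf

        mol = Chem.MolFromSmiles("FC(F)(F)c1ccccc1")
        cut = tuple(eligible_bonds(mol))
        (rec,) = fs.fragment_on_cut_set("FC(F)(F)c1ccccc1", cut)
        tctx = fs.truncate_context(rec.context_full, 1)
        _, variants = fs.canonicalize_pair(tctx, rec.core)
        _, oracle_variants = _oracle_canonical_pair(
            pf(tctx.smiles_ap), pf(rec.core.smiles_ap)
        )
        assert 1 <= len(variants) <= 24
        assert sorted(c.smiles_ap for c in variants) == oracle_variants


class TestRoundTrip:
    @pytest.mark.parametrize(
        "smiles",
        ["CCOC(C)=O", "Cc1ccc(O)cc1", "CCC", "CC(C)CO", "NC(=O)c1ccccc1"],
    )
    def test_splice_reproduces_source(self, smiles):
        source = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
        records = fs.fragment_molecule(smiles)
        assert records
        for rec in records:
            assert fs.splice(smiles, rec, rec.core) == source
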
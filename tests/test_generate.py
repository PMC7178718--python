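import pytest
from rdkit import Chem

import fragswap as fs
from fragswap.errors import ContractViolation, ParameterError, SpliceError
from fragswap.fragmentation import Core


def params(**kw):
    defaults = dict(radius=1, min_size=0, max_size=10, min_inc=-2, max_inc=2)
    defaults.update(kw)
    return fs.GenerationParams(**defaults)


class TestMutate:
    def test_methyl_to_ethyl_and_hydrogen(self, toluene_ethyl_db):
        out = fs.mutate(
            "Cc1ccccc1",
            toluene_ethyl_db,
            params(min_size=1, max_size=2, min_inc=-1, max_inc=1),
        )
        assert out == {"CCc1ccccc1", "c1ccccc1"}

    def test_only_self_replacements_gives_empty(self):
        # At radius 5 every toluene context covers the whole molecule, so a
        # single-molecule database admits only self-replacements.  (At radius
        # 3 the ring wraps around: the methyl context and the para-hydrogen
        # context coincide, and methyl<->H swaps are genuinely admissible --
        # confirmed by the brute-force oracle below.)
        db5 = fs.build_db([fs.parse_smiles("Cc1ccccc1")], [5])
        assert fs.mutate("Cc1ccccc1", db5, params(radius=5)) == set()

        corpus = fs.FixtureCorpus((fs.parse_smiles("Cc1ccccc1"),), "toluene")
        db3 = fs.build_db(list(corpus.molecules), [3])
        got = fs.mutate("Cc1ccccc1", db3, params(radius=3))
        assert got == fs.oracle_mutate("Cc1ccccc1", corpus, 3,
                                       min_inc=-2, max_inc=2)

    def test_parent_never_returned(self, decorated_db):
        corpus, db = decorated_db
        for parent in corpus.smiles[:3]:
            canon = Chem.MolToSmiles(Chem.MolFromSmiles(parent))
            assert canon not in fs.mutate(parent, db, params())

    def test_protected_atoms_block_replacement(self, toluene_ethyl_db):
        mol = Chem.MolFromSmiles("Cc1ccccc1")
        methyl = next(
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and not a.GetIsAromatic()
        )
        out = fs.mutate(
            "Cc1ccccc1",
            toluene_ethyl_db,
            params(
                min_size=1, max_size=2, min_inc=-1, max_inc=1,
                protected_atoms=frozenset({methyl}),
            ),
        )
        assert out == set()

    def test_unbuilt_radius(self, toluene_ethyl_db):
        with pytest.raises(ParameterError):
            fs.mutate("Cc1ccccc1", toluene_ethyl_db, params(radius=2))

    def test_max_replacements_caps_and_is_deterministic(self, decorated_db):
        corpus, db = decorated_db
        parent = corpus.smiles[0]
        a = fs.mutate(parent, db, params(max_replacements=4, seed=7))
        b = fs.mutate(parent, db, params(max_replacements=4, seed=7))
        assert a == b and len(a) <= 4

    def test_all_products_sanitize(self, decorated_db):
        corpus, db = decorated_db
        for parent in corpus.smiles[:3]:
            for smi in fs.mutate(parent, db, params()):
                assert Chem.MolFromSmiles(smi) is not None

    def test_oracle_equivalence(self, homolog_corpus):
        db = fs.build_db(list(homolog_corpus.molecules), [1])
        for parent in homolog_corpus.smiles:
            got = fs.mutate(parent, db, params(min_inc=-2, max_inc=2))
            want = fs.oracle_mutate(
                parent, homolog_corpus, 1, min_inc=-2, max_inc=2
            )
            assert got == want

    def test_radius_nesting(self, decorated_db):
        corpus, db = decorated_db
        for parent in corpus.smiles[:3]:
            outs = {r: fs.mutate(parent, db, params(radius=r)) for r in (1, 2, 3)}
            assert outs[3] <= outs[2] <= outs[1]


class TestGrow:
    def test_benzene_grows_to_toluene(self):
        db = fs.build_db([fs.parse_smiles("Cc1ccccc1")], [1])
        out = fs.grow("c1ccccc1", db, params(min_inc=0, max_inc=1))
        assert out == {"Cc1ccccc1"}

    def test_parent_without_hydrogens(self, toluene_ethyl_db):
        assert fs.grow("FC(F)(F)F", toluene_ethyl_db, params()) == set()

    def test_grow_subset_of_mutate(self, decorated_db):
        corpus, db = decorated_db
        p = params(min_size=0, max_size=4, min_inc=-1, max_inc=2)
        for parent in corpus.smiles[:3]:
            assert fs.grow(parent, db, p) <= fs.mutate(parent, db, p)


class TestLink:
    def test_methane_methane_through_propane_db(self):
        db = fs.build_db([fs.parse_smiles("CCC")], [1])
        out = fs.link("C", "C", db, params())
        assert out == {"CCC"}

    def test_no_two_attachment_cores(self):
        db = fs.build_db([fs.parse_smiles("Cc1ccccc1")], [1])
        assert fs.link("C", "C", db, params()) == set()

    def test_symmetric(self, decorated_db):
        corpus, db = decorated_db
        a, b = corpus.smiles[0], corpus.smiles[1]
        assert fs.link(a, b, db, params()) == fs.link(b, a, db, params())

    def test_oracle_equivalence(self):
        corpus = fs.synth_corpus("linkers", 5, seed=2)
        db = fs.build_db(list(corpus.molecules), [1])
        got = fs.link("C", "CO", db, params(min_size=0, max_size=6))
        want = fs.oracle_link("C", "CO", corpus, 1, min_size=1, max_size=6)
        assert got == want


class TestSplice:
    def test_self_replacement_identity(self):
        records = fs.fragment_molecule("CCOc1ccccc1")
        source = Chem.MolToSmiles(Chem.MolFromSmiles("CCOc1ccccc1"))
        for rec in records[:10]:
            assert fs.splice("CCOc1ccccc1", rec, rec.core) == source

    def test_known_replacement(self):
        (cut,) = fs.enumerate_cut_sets("Cc1ccccc1")
        rec = next(
            r
            for r in fs.fragment_on_cut_set("Cc1ccccc1", cut)
            if r.core.n_heavy == 1
        )
        assert fs.splice("Cc1ccccc1", rec, Core("[*:1]CC", 2, 1)) == "CCc1ccccc1"

    def test_valence_violation_raises(self):
        (rec,) = fs.hydrogen_cuts("C")
        with pytest.raises(SpliceError):
            fs.splice("C", rec, Core("[*:1][CH4]", 1, 1))

    def test_map_mismatch_raises(self):
        (rec,) = fs.hydrogen_cuts("C")
        with pytest.raises(ContractViolation):
            fs.splice("C", rec, Core("[*:2]C", 1, 1))


class TestParams:
    def test_invalid_sizes(self):
        with pytest.raises(ParameterError):
            fs.GenerationParams(min_size=3, max_size=1)

    def test_invalid_inc(self):
        with pytest.raises(ParameterError):
            fs.GenerationParams(min_inc=2, max_inc=-2)

    def test_invalid_rel_size(self):
        with pytest.raises(ParameterError):
            fs.GenerationParams(max_rel_size=1.5)
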
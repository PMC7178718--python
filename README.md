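# fragswap

Fragment-swap structure generation for de novo molecular design.

`fragswap` builds a database of *interchangeable fragments* from a corpus of
molecules and uses it to generate new, chemically valid structures. Molecules
are fragmented by cutting up to four acyclic single bonds between heavy atoms
(hydrogens are cut through a separate pathway). For each fragment (*core*,
carrying numbered attachment points) the environment within a bond radius *r*
of the attachment points (*context*) is canonically encoded; two cores are
interchangeable when their canonical `(radius, context)` keys are equal.
Splicing a retrieved core back into a parent's context yields products that
are valid by construction.

Three generation modes are provided:

- **MUTATE** — replace an arbitrarily chosen fragment with an interchangeable one
- **GROW** — replace a hydrogen with a fragment
- **LINK** — join two molecules through a two-attachment fragment

On top of these sit evaluation metrics (novelty, diversity, corpus novelty,
a nine-descriptor physicochemical panel, Bemis–Murcko scaffold analysis,
PAINS screening, pluggable synthetic-complexity scoring) and two search
workflows: an unguided stochastic walk with molecular-weight-binned
selection, and a greedy goal-directed optimizer with adaptive replacement
sizes and three patience levels.

## Quick start (Python)

```python
import fragswap as fs

corpus = [fs.parse_smiles(s) for s in ("Cc1ccccc1", "CCc1ccccc1")]
db = fs.build_db(corpus, radii=[1])

products = fs.mutate(
    "Cc1ccccc1", db,
    fs.GenerationParams(radius=1, min_size=1, max_size=2, min_inc=-1, max_inc=1),
)
# {'CCc1ccccc1', 'c1ccccc1'}
```

The tuning parameters mirror the framework's knobs: context `radius`,
replaced-fragment size bounds (`min_size`/`max_size`, plus `max_rel_size`
relative to the parent), the signed size change of the replacement
(`min_inc`/`max_inc`), the occurrence threshold `min_freq`, a cap on randomly
sampled replacements (`max_replacements` + `seed`), and `protected_atoms`.

## CLI

All commands are subcommands of `fragswap`:

```bash
fragswap fixtures make --kind homologs --n 10 --seed 1 --out corpus.smi
fragswap fragdb build --in corpus.smi --out db.tsv --radius 1 --radius 2 --max-cuts 4
fragswap fragdb stats --db db.tsv
fragswap mutate --in parents.smi --db db.tsv --radius 2 --min-size 0 --max-size 8 \
    --min-inc -2 --max-inc 2 --out out.smi
fragswap grow   --in parents.smi --db db.tsv --radius 1 --min-inc 1 --max-inc 5 --out grown.smi
fragswap link   --in-a a.smi --in-b b.smi --db db.tsv --radius 1 --out linked.smi
fragswap metrics --in out.smi --parent parents.smi --corpus corpus.smi \
    --out report.tsv --panel-out panel.tsv
fragswap explore  --seed-mol seed.smi --db db.tsv --iters 100 --mw-cap 500 --bins 5 \
    --seed 42 --out iters/
fragswap optimize --seeds pool.smi --db db.tsv --score sascore --out best.smi
```

The fragment database is a TSV with header
`radius	context	core	n_heavy	count`, sorted and bit-exact across runs;
paths ending in `.sqlite`/`.db` use an equivalent SQLite backend.

## Tests

```bash
python -m pytest tests/
```

The suite includes a brute-force oracle (`fragswap.fixtures`) that re-derives
the interchangeability table and generation outputs by independent
enumeration; `tests/test_acceptance.py` checks the acceptance criteria
(validity by design, oracle equivalence, radius nesting, motif exclusion,
special-case containment, filter monotonicity, optimizer contract).

## Notes

- Stereochemistry and isotope labels are stripped during standardization by
  default (flags exist to keep them); inputs are restricted to a
  configurable organic element subset (C, N, O, S, P, F, Cl, Br, I, B).
- Truncated context keys are strings, not necessarily sanitizable molecules:
  aromatic atoms whose ring was truncated away stay aromatic and carry a
  reserved isotope tag (`9`) so that the canonical form is stable.
- Database keys are comparable only between databases built by the same
  package version (canonical SMILES dialects differ across toolkits).
- New ring systems cannot be created: ring bonds are never cut, so ring
  diversity is inherited from the input corpus.
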
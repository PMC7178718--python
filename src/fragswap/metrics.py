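"""Evaluation metrics for generated compound sets.

Novelty is the mean Tanimoto distance of generated compounds to a parent;
diversity the mean pairwise Tanimoto distance within a set (subsampled for
large sets); corpus novelty the percentage of generated structures absent
from the fragmentation corpus.  A nine-descriptor physicochemical panel,
Bemis-Murcko scaffold analysis, PAINS screening and a pluggable
synthetic-complexity scorer round out the panel.
"""

from __future__ import annotations

import os
import random
import sys
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig
from rdkit.Chem import Descriptors, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.Chem import FilterCatalog
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .errors import ConfigError, ParameterError
from .records import MoleculeRecord, to_mol


@dataclass(frozen=True)
class FingerprintConfig:
    """Circular (Morgan) fingerprint settings for novelty/diversity."""

    n_bits: int = 2048
    fp_radius: int = 2


@dataclass(frozen=True)
class PropertyPanel:
    """The nine standard physicochemical descriptors."""

    HBD: int
    HBA: int
    MW: float
    logP: float
    RTB: int
    TPSA: float
    NumRings: int
    Csp3: float
    fmf: float

PANEL_COLUMNS = ("HBD", "HBA", "MW", "logP", "RTB", "TPSA", "NumRings", "Csp3", "fmf")


def _fingerprint(mol: Chem.Mol, cfg: FingerprintConfig):
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=cfg.fp_radius, fpSize=cfg.n_bits
    )
    return gen.GetFingerprint(mol)


def novelty(
    parent: MoleculeRecord | str,
    generated: Iterable[str],
    cfg: FingerprintConfig = FingerprintConfig(),
) -> float:
    """Mean Tanimoto distance of generated molecules to the parent."""
    generated = list(generated)
    if not generated:
        raise ParameterError("novelty is undefined for an empty set")
    ref = _fingerprint(to_mol(parent), cfg)
    fps = [_fingerprint(to_mol(s), cfg) for s in generated]
    sims = DataStructs.BulkTanimotoSimilarity(ref, fps)
    return float(np.mean([1.0 - s for s in sims]))


def _all_pairs_mean_distance(fps) -> float:
    n = len(fps)
    total = 0.0
    for i in range(n - 1):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
        total += sum(1.0 - s for s in sims)
    return total / (n * (n - 1) / 2)


def diversity(
    generated: Iterable[str],
    cfg: FingerprintConfig = FingerprintConfig(),
    subsample: int = 1000,
    repeats: int = 5,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mean pairwise Tanimoto distance, with spread over seeded subsamples.

    For sets no larger than ``subsample`` the exhaustive all-pairs mean is
    returned with spread 0.  Larger sets are subsampled ``repeats`` times;
    the mean and standard deviation over repeats are reported.
    """
    original = list(generated)
    if len(original) < 2:
        raise ParameterError("diversity needs at least 2 molecules")
    generated = sorted(set(original))
    if len(generated) == 1:
        return 0.0, 0.0
    fps = [_fingerprint(to_mol(s), cfg) for s in generated]
    if len(fps) <= subsample:
        return _all_pairs_mean_distance(fps), 0.0
    rng = random.Random(seed)
    values = []
    for _ in range(repeats):
        sample = rng.sample(fps, subsample)
        values.append(_all_pairs_mean_distance(sample))
    return float(np.mean(values)), float(np.std(values))


def corpus_novelty(generated: Iterable[str], corpus: Iterable[str]) -> float:
    """Percentage of generated structures absent from the corpus."""
    generated = set(generated)
    if not generated:
        raise ParameterError("corpus novelty is undefined for an empty set")
    corpus = set(corpus)
    return 100.0 * len(generated - corpus) / len(generated)


def murcko_scaffold(mol: MoleculeRecord | str) -> str:
    """Canonical Bemis-Murcko scaffold SMILES; empty for acyclic molecules."""
    m = to_mol(mol)
    if rdMolDescriptors.CalcNumRings(m) == 0:
        return ""
    return Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(m))


def property_panel(mol: MoleculeRecord | str) -> PropertyPanel:
    """Compute the nine-descriptor physicochemical panel."""
    m = to_mol(mol)
    n_heavy = m.GetNumHeavyAtoms()
    scaffold = murcko_scaffold(m)
    fmf = 0.0
    if scaffold:
        fmf = Chem.MolFromSmiles(scaffold).GetNumHeavyAtoms() / n_heavy
    return PropertyPanel(
        HBD=rdMolDescriptors.CalcNumHBD(m),
        HBA=rdMolDescriptors.CalcNumHBA(m),
        MW=float(Descriptors.MolWt(m)),
        logP=float(Descriptors.MolLogP(m)),
        RTB=rdMolDescriptors.CalcNumRotatableBonds(m),
        TPSA=float(rdMolDescriptors.CalcTPSA(m)),
        NumRings=rdMolDescriptors.CalcNumRings(m),
        Csp3=float(rdMolDescriptors.CalcFractionCSP3(m)),
        fmf=float(fmf),
    )


def panel_frame(mols: Sequence[MoleculeRecord | str]) -> pd.DataFrame:
    """Property panel for many molecules as a DataFrame (one row each)."""
    rows = [property_panel(m).__dict__ for m in mols]
    smiles = [m.smiles if isinstance(m, MoleculeRecord) else m for m in mols]
    frame = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
    frame.insert(0, "smiles", smiles)
    return frame


def scaffold_novelty(
    generated_by_iteration: Sequence[Iterable[str]], corpus: Iterable[str]
) -> pd.DataFrame:
    """Per-iteration and cumulative scaffold counts and novel percentages.

    Scaffolds of acyclic molecules (empty string) are excluded.  Novelty is
    relative to the scaffolds of the corpus molecules.
    """
    corpus_scaffolds = {murcko_scaffold(s) for s in corpus}
    corpus_scaffolds.discard("")
    rows = []
    cumulative: set[str] = set()
    for it, batch in enumerate(generated_by_iteration):
        scaffolds = {murcko_scaffold(s) for s in batch}
        scaffolds.discard("")
        novel = scaffolds - corpus_scaffolds
        cumulative |= scaffolds
        cum_novel = cumulative - corpus_scaffolds
        rows.append(
            {
                "iteration": it,
                "n_scaffolds": len(scaffolds),
                "pct_novel": 100.0 * len(novel) / len(scaffolds) if scaffolds else 0.0,
                "cum_n_scaffolds": len(cumulative),
                "cum_pct_novel": (
                    100.0 * len(cum_novel) / len(cumulative) if cumulative else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PAINS screening
# ---------------------------------------------------------------------------

class PainsCatalog:
    """A named list of SMARTS patterns for substructure alerts."""

    def __init__(self, patterns: Sequence[tuple[str, str]] | None = None):
        """``patterns`` is a list of (name, SMARTS); ``None`` loads the
        built-in PAINS catalog."""
        if patterns is None:
            params = FilterCatalog.FilterCatalogParams()
            params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
            self._catalog = FilterCatalog.FilterCatalog(params)
            self._custom = None
        else:
            self._catalog = None
            self._custom = []
            for name, smarts in patterns:
                patt = Chem.MolFromSmarts(smarts)
                if patt is None:
                    raise ConfigError(f"invalid SMARTS for {name!r}: {smarts!r}")
                self._custom.append((name, patt))

    def matches(self, mol: Chem.Mol) -> list[str]:
        if self._catalog is not None:
            return [e.GetDescription() for e in self._catalog.GetMatches(mol)]
        return [name for name, patt in self._custom if mol.HasSubstructMatch(patt)]


def pains_matches(
    mol: MoleculeRecord | str, catalog: PainsCatalog | None = None
) -> list[str]:
    """Names of all catalog patterns with at least one substructure match."""
    if catalog is None:
        catalog = PainsCatalog()
    return catalog.matches(to_mol(mol))


# ---------------------------------------------------------------------------
# synthetic-complexity scoring
# ---------------------------------------------------------------------------

def _sascore(mol: Chem.Mol) -> float:
    sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
    if sa_dir not in sys.path:
        sys.path.append(sa_dir)
    import sascorer  # deferred: ships with RDKit's contrib tree

    return float(min(10.0, max(1.0, sascorer.calculateScore(mol))))


_SCORERS: dict[str, Callable[[Chem.Mol], float]] = {"sascore": _sascore}


def register_scorer(name: str, fn: Callable[[Chem.Mol], float]) -> None:
    """Register a complexity scorer under a name (e.g. an external model)."""
    _SCORERS[name] = fn


def complexity_score(
    mol: MoleculeRecord | str, scorer: str | Callable[[Chem.Mol], float] = "sascore"
) -> float:
    """Value of a registered or callable synthetic-complexity scorer."""
    if callable(scorer):
        fn = scorer
    else:
        try:
            fn = _SCORERS[scorer]
        except KeyError:
            raise ConfigError(f"unknown scorer {scorer!r}") from None
    return float(fn(to_mol(mol)))
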
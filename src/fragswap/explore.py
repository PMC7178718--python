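"""Search workflows on top of fragment replacement.

Two workflows are provided: an unguided stochastic walk through chemical
space (molecular-weight-binned selection of survivors each iteration) and
a greedy goal-directed optimizer whose replacement-size window adapts to
the current best score, with three escalating patience levels when the
score stalls.
"""

from __future__ import annotations

import logging
import random
import time
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit.Chem import Descriptors

from .errors import ParameterError, ScoreError
from .fragdb import FragDB
from .generate import GenerationParams, mutate
from .records import MoleculeRecord, to_mol

logger = logging.getLogger(__name__)

ScoreFunction = Callable[[str], float]


@dataclass(frozen=True)
class ExplorationParams:
    """Settings of the stochastic chemical-space walk."""

    radius: int = 3
    iterations: int = 100
    min_size: int = 0
    max_size: int = 8
    max_rel_size: float = 0.3
    min_inc: int = -1
    max_inc: int = 1
    min_freq: int = 0
    max_replacements: int | None = 25_000
    mw_cap: float = 500.0
    n_bins: int = 5
    seed: int | None = None

    def __post_init__(self):
        if self.n_bins < 1:
            raise ParameterError("n_bins must be >= 1")
        if self.mw_cap <= 0:
            raise ParameterError("mw_cap must be > 0")


@dataclass(frozen=True)
class PatienceLevel:
    """Escalation fired after ``threshold`` consecutive non-improving
    iterations: widen the size window and raise the replacement cap."""

    threshold: int
    window_increase: int
    replacement_increase: int


@dataclass(frozen=True)
class OptimizerParams:
    """Settings of the greedy goal-directed optimizer."""

    radius: int = 3
    min_size: int = 0
    max_size: int = 10
    min_freq: int = 0
    low_score: float = 0.3
    high_score: float = 0.8
    window_low: int = 10     # size delta when score <= low_score
    window_high: int = 4     # size delta when score > high_score
    replacements_per_compound: int = 1000
    patience: tuple[PatienceLevel, ...] = (
        PatienceLevel(3, 1, 100),
        PatienceLevel(10, 10, 500),
    )
    reseed_after: int = 33
    output_size: int = 10
    max_iterations: int = 100
    max_seconds: float | None = None
    stop_score: float | None = 1.0
    mw_cap: float | None = None  # discard heavier products; bounds runtime
    seed: int | None = None

    def __post_init__(self):
        if not self.low_score < self.high_score:
            raise ParameterError("low_score must be < high_score")
        thresholds = [p.threshold for p in self.patience] + [self.reseed_after]
        if sorted(thresholds) != thresholds or len(set(thresholds)) != len(thresholds):
            raise ParameterError("patience thresholds must be strictly increasing")

    @property
    def population_size(self) -> int:
        return max(self.output_size, 10)


@dataclass
class OptimizationResult:
    """Best molecules (scored, descending), the per-iteration best-score
    trace, and the escalation/reseed events that fired."""

    best: list[tuple[str, float]]
    trace: list[float]
    events: list[tuple[int, str]]


def _mw(smiles: str) -> float:
    return Descriptors.MolWt(to_mol(smiles))


def mw_bin_select(
    mols: Iterable[str], n_bins: int, seed: int | None | random.Random = None
) -> list[str]:
    """One random pick from each of ``n_bins`` near-equal molecular-weight
    bins (equal-count, contiguous after sorting by MW)."""
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    ordered = sorted(set(mols), key=lambda s: (_mw(s), s))
    if not ordered:
        return []
    if len(ordered) <= n_bins:
        return ordered
    picks = []
    for chunk in np.array_split(np.array(ordered, dtype=object), n_bins):
        if len(chunk):
            picks.append(str(chunk[rng.randrange(len(chunk))]))
    return picks


def stochastic_explore(
    seed_mol: MoleculeRecord | str,
    db: FragDB,
    params: ExplorationParams = ExplorationParams(),
) -> list[set[str]]:
    """Iterative stochastic walk: mutate the current selection, discard
    overweight products, record survivors, carry a MW-binned sample forward.

    Returns one set per iteration; index 0 holds the seed.  Terminates
    early when an iteration yields no survivors.
    """
    rng = random.Random(params.seed)
    seed_smiles = (
        seed_mol.smiles if isinstance(seed_mol, MoleculeRecord) else seed_mol
    )
    history: list[set[str]] = [{seed_smiles}]
    selection = [seed_smiles]
    for it in range(1, params.iterations + 1):
        products: set[str] = set()
        for smi in selection:
            gp = GenerationParams(
                radius=params.radius,
                min_size=params.min_size,
                max_size=params.max_size,
                max_rel_size=params.max_rel_size,
                min_inc=params.min_inc,
                max_inc=params.max_inc,
                min_freq=params.min_freq,
                max_replacements=params.max_replacements,
                seed=rng.randrange(2**32),
            )
            products |= mutate(smi, db, gp)
        survivors = {s for s in products if _mw(s) <= params.mw_cap}
        if not survivors:
            logger.info("stochastic walk terminated at iteration %d (no survivors)", it)
            break
        history.append(survivors)
        selection = mw_bin_select(survivors, params.n_bins, rng)
    return history


def _check_score(value: float) -> float:
    if not (0.0 <= value <= 1.0):
        raise ScoreError(f"score {value} outside [0, 1]")
    return float(value)


def _size_window(best_score: float, params: OptimizerParams) -> int:
    """Replacement-size window from the current best score band.

    Scores at or below the low threshold use the widest window, scores
    above the high threshold the narrowest; the intermediate band maps
    linearly onto windows 5..9."""
    if best_score <= params.low_score:
        return params.window_low
    if best_score > params.high_score:
        return params.window_high
    frac = (best_score - params.low_score) / (params.high_score - params.low_score)
    return 5 + min(4, int(frac * 5))


def goal_directed_optimize(
    seeds: Sequence[MoleculeRecord | str],
    db: FragDB,
    score_fn: ScoreFunction,
    params: OptimizerParams = OptimizerParams(),
    seed_pool: Sequence[MoleculeRecord | str] | None = None,
) -> OptimizationResult:
    """Greedy population search with adaptive step sizes and patience.

    Each iteration mutates every not-yet-visited population member with a
    score-band-dependent size window, keeps the top-scored compounds, and
    never discards the best found so far.  After 3 / 10 consecutive
    non-improving iterations the window and replacement cap are raised;
    after ``reseed_after`` the population is reseeded from ``seed_pool``
    (skipped when no pool is supplied).  The visited list is cleared after
    any change of the generator parameters.
    """
    rng = random.Random(params.seed)
    t0 = time.monotonic()

    def smiles_of(x):
        return x.smiles if isinstance(x, MoleculeRecord) else x

    scores: dict[str, float] = {}

    def score(smi: str) -> float:
        if smi not in scores:
            scores[smi] = _check_score(score_fn(smi))
        return scores[smi]

    population = [smiles_of(s) for s in seeds]
    pool = [smiles_of(s) for s in (seed_pool or [])]
    for smi in population:
        score(smi)
    visited: set[str] = set()
    hall_of_fame: dict[str, float] = dict(scores)
    best_score = max(scores[s] for s in population)
    trace: list[float] = []
    events: list[tuple[int, str]] = []
    stall = 0
    window_bonus = 0
    replacement_bonus = 0
    prev_window = None

    for it in range(1, params.max_iterations + 1):
        window = _size_window(best_score, params) + window_bonus
        cap = params.replacements_per_compound + replacement_bonus
        if prev_window is not None and window != prev_window:
            visited.clear()
        prev_window = window
        products: set[str] = set()
        for smi in population:
            if smi in visited:
                continue
            gp = GenerationParams(
                radius=params.radius,
                min_size=params.min_size,
                max_size=params.max_size,
                min_inc=-window,
                max_inc=window,
                min_freq=params.min_freq,
                max_replacements=cap,
                seed=rng.randrange(2**32),
            )
            products |= mutate(smi, db, gp)
            visited.add(smi)
        products -= visited
        if params.mw_cap is not None:
            products = {s for s in products if _mw(s) <= params.mw_cap}
        for smi in products:
            hall_of_fame[smi] = score(smi)
        candidates = sorted(
            set(population) | products, key=lambda s: (-score(s), s)
        )
        population = candidates[: params.population_size]
        new_best = score(population[0])
        improved = new_best > best_score
        best_score = max(best_score, new_best)
        trace.append(best_score)
        if improved:
            stall = 0
            window_bonus = 0
            replacement_bonus = 0
            visited.clear()
        else:
            stall += 1
            for level in params.patience:
                if stall == level.threshold:
                    window_bonus += level.window_increase
                    replacement_bonus += level.replacement_increase
                    visited.clear()
                    events.append((it, f"patience_{level.threshold}"))
            if stall == params.reseed_after:
                events.append((it, "reseed"))
                if pool:
                    population = [
                        pool[rng.randrange(len(pool))]
                        for _ in range(params.population_size)
                    ]
                    for smi in population:
                        hall_of_fame[smi] = score(smi)
                stall = 0
                window_bonus = 0
                replacement_bonus = 0
                visited.clear()
        if params.stop_score is not None and best_score >= params.stop_score:
            break
        if params.max_seconds is not None and time.monotonic() - t0 > params.max_seconds:
            logger.info("optimizer wall-clock cap reached at iteration %d", it)
            break

    best = sorted(hall_of_fame.items(), key=lambda kv: (-kv[1], kv[0]))
    return OptimizationResult(best[: params.output_size], trace, events)
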
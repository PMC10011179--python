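"""Effective-wavelength (EW) selection by genetic algorithm.

A chromosome is a binary mask over spectral bands.  Fitness is the mean
stratified 5-fold cross-validation accuracy of an RBF support-vector
machine trained on the selected bands (per-band standardisation fitted
on training folds only).  The full selection protocol wraps the GA in a
restart loop: the first run sets a reference fitness; subsequent runs
replace it whenever they strictly improve, and the search stops after
``stall_limit`` consecutive runs without improvement.

:class:`GABandSelector` exposes the protocol as a scikit-learn feature
selector (``fit`` / ``transform`` / ``get_support``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = ["GAConfig", "EWSet", "cv_fitness", "ga_run", "ew_protocol", "GABandSelector"]


@dataclass
class GAConfig:
    """GA hyperparameters.  Defaults mirror a population of 100 run for
    400 generations with crossover 0.5 and per-bit mutation 0.1, and a
    1000-run stall limit for the restart protocol; desk-scale studies
    pass smaller values."""

    pop_size: int = 100
    generations: int = 400
    crossover_p: float = 0.5
    mutation_p: float = 0.1
    cv_folds: int = 5
    stall_limit: int = 1000
    init_density: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_p <= 1 and 0 <= self.mutation_p <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.pop_size < 1 or self.generations < 1:
            raise ValueError("pop_size and generations must be >= 1")


@dataclass
class EWSet:
    """Selected effective wavelengths with the protocol's fitness trace."""

    indices: np.ndarray
    wavelengths_nm: np.ndarray
    fitness: float
    n_restarts_used: int = 1
    trace: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "indices": [int(i) for i in self.indices],
            "wavelengths_nm": [float(w) for w in self.wavelengths_nm],
            "fitness": float(self.fitness),
            "n_restarts_used": int(self.n_restarts_used),
            "trace": [float(t) for t in self.trace],
        }


def _make_svm() -> SVC:
    return SVC(kernel="rbf", C=1.0, gamma="scale")


def _fold_indices(y: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def _cv_accuracy(X: np.ndarray, y: np.ndarray,
                 splits: list[tuple[np.ndarray, np.ndarray]]) -> float:
    accs = []
    for tr, te in splits:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        clf = _make_svm()
        clf.fit((X[tr] - mu) / sd, y[tr])
        accs.append(float(np.mean(clf.predict((X[te] - mu) / sd) == y[te])))
    return float(np.mean(accs))


def cv_fitness(X: np.ndarray, y: np.ndarray, subset: np.ndarray,
               folds: int = 5, seed: int = 0) -> float:
    """Mean stratified-CV SVM accuracy on the band ``subset``.

    An empty subset scores 0 by convention rather than raising, so the
    GA can penalise and repair empty chromosomes.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        return 0.0
    return _cv_accuracy(np.asarray(X, float)[:, subset], np.asarray(y), _fold_indices(np.asarray(y), folds, seed))


def _repair(chrom: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not chrom.any():
        chrom = chrom.copy()
        chrom[rng.integers(chrom.size)] = True
    return chrom


def ga_run(X: np.ndarray, y: np.ndarray, cfg: GAConfig,
           rng: np.random.Generator,
           _cache: dict[bytes, float] | None = None) -> EWSet:
    """One GA run: tournament-2 selection, uniform crossover, per-bit
    mutation, single elitism.  The best-so-far fitness is non-decreasing
    across generations.  Fitness evaluations are memoised per chromosome."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_bands = X.shape[1]
    splits = _fold_indices(y, cfg.cv_folds, cfg.seed)
    cache: dict[bytes, float] = _cache if _cache is not None else {}

    def fitness(chrom: np.ndarray) -> float:
        key = chrom.tobytes()
        if key not in cache:
            idx = np.flatnonzero(chrom)
            cache[key] = 0.0 if idx.size == 0 else _cv_accuracy(X[:, idx], y, splits)
        return cache[key]

    pop = rng.random((cfg.pop_size, n_bands)) < cfg.init_density
    pop = np.array([_repair(c, rng) for c in pop])
    fits = np.array([fitness(c) for c in pop])
    best_i = int(np.argmax(fits))
    best_chrom, best_fit = pop[best_i].copy(), float(fits[best_i])
    trace = [best_fit]

    for _ in range(cfg.generations - 1):
        children = []
        while len(children) < cfg.pop_size - 1:
            # tournament size 2 for each parent
            cands = rng.integers(cfg.pop_size, size=(2, 2))
            p1 = pop[cands[0][np.argmax(fits[cands[0]])]]
            p2 = pop[cands[1][np.argmax(fits[cands[1]])]]
            if rng.random() < cfg.crossover_p:
                mask = rng.random(n_bands) < 0.5
                c1 = np.where(mask, p1, p2)
                c2 = np.where(mask, p2, p1)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for c in (c1, c2):
                # mutation_p selects individuals for mutation; a mutated
                # individual flips each bit with probability 1/n_bands
                if rng.random() < cfg.mutation_p:
                    flip = rng.random(n_bands) < 1.0 / n_bands
                    c = np.logical_xor(c, flip)
                children.append(_repair(np.ascontiguousarray(c), rng))
        pop = np.array([best_chrom] + children[: cfg.pop_size - 1])  # elitism
        fits = np.array([fitness(c) for c in pop])
        gi = int(np.argmax(fits))
        if fits[gi] > best_fit:
            best_fit = float(fits[gi])
            best_chrom = pop[gi].copy()
        trace.append(best_fit)

    idx = np.flatnonzero(best_chrom)
    return EWSet(indices=idx, wavelengths_nm=idx.astype(float), fitness=best_fit,
                 n_restarts_used=1, trace=trace)


def ew_protocol(X: np.ndarray, y: np.ndarray, cfg: GAConfig,
                wavelengths: np.ndarray | None = None,
                ga_fn: Callable[..., EWSet] | None = None) -> EWSet:
    """Restart protocol around :func:`ga_run`.

    Run the GA once and take its fitness as the reference value; then
    rerun in a loop, promoting any strictly better result to the new
    reference (resetting the stall counter); stop after ``stall_limit``
    consecutive runs without improvement and return the best subset.
    """
    ga = ga_fn or ga_run
    cache: dict[bytes, float] = {}
    seeds = np.random.SeedSequence(cfg.seed)

    def one_run(i: int) -> EWSet:
        run_seed = int(seeds.spawn(1)[0].generate_state(1)[0] % (2**31 - 1)) if i else cfg.seed
        rng = np.random.default_rng(run_seed)
        if ga is ga_run:
            return ga(X, y, cfg, rng, _cache=cache)
        return ga(X, y, cfg, rng)

    best = one_run(0)
    reference = best.fitness
    trace = [reference]
    n_runs = 1
    stall = 0
    while stall < cfg.stall_limit:
        result = one_run(n_runs)
        n_runs += 1
        trace.append(result.fitness)
        if result.fitness > reference:
            reference = result.fitness
            best = result
            stall = 0
        else:
            stall += 1
    wl = (np.asarray(wavelengths, float)[best.indices]
          if wavelengths is not None else best.indices.astype(float))
    return EWSet(indices=best.indices, wavelengths_nm=wl, fitness=reference,
                 n_restarts_used=n_runs, trace=trace)


class GABandSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn feature selector running the GA restart protocol.

    Parameters mirror :class:`GAConfig`.  After ``fit``, ``support_``
    holds the boolean band mask, ``ew_set_`` the full :class:`EWSet`
    and ``fitness_`` its CV accuracy.
    """

    def __init__(self, pop_size: int = 100, generations: int = 400,
                 crossover_p: float = 0.5, mutation_p: float = 0.1,
                 cv_folds: int = 5, stall_limit: int = 1000,
                 init_density: float = 0.3, seed: int = 0):
        self.pop_size = pop_size
        self.generations = generations
        self.crossover_p = crossover_p
        self.mutation_p = mutation_p
        self.cv_folds = cv_folds
        self.stall_limit = stall_limit
        self.init_density = init_density
        self.seed = seed

    def _config(self) -> GAConfig:
        return GAConfig(pop_size=self.pop_size, generations=self.generations,
                        crossover_p=self.crossover_p, mutation_p=self.mutation_p,
                        cv_folds=self.cv_folds, stall_limit=self.stall_limit,
                        init_density=self.init_density, seed=self.seed)

    def fit(self, X: np.ndarray, y: np.ndarray, wavelengths: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.n_features_in_ = X.shape[1]
        self.ew_set_ = ew_protocol(X, y, self._config(), wavelengths=wavelengths)
        self.support_ = np.zeros(self.n_features_in_, dtype=bool)
        self.support_[self.ew_set_.indices] = True
        self.fitness_ = self.ew_set_.fitness
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
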
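"""Genetic 0/1-knapsack selection of the Key Group of Effective Components.

Given the components of a Function Response Space, each carrying a value
v_i (by default the number of effective proteins it targets) and a weight
w_i (by default 1, so the capacity C counts components), a genetic
algorithm searches binary selections x maximizing either

* ``sumvalue`` fitness:  V = sum v_i x_i   subject to   W = sum w_i x_i <= C
* ``coverage`` fitness:  the fraction of effective proteins targeted by the
  union of the selected components' target sets (the pipeline default,
  because the key group is defined by complete target coverage).

GA operators: binary encoding, random initial population, roulette-wheel
selection proportional to fitness, single-point crossover, single-locus
bit-flip mutation per chromosome, and elitism.  Infeasible chromosomes are
repaired by dropping the selected item with the lowest value density
v_i/w_i (with unit weights, simply the lowest value) until W <= C.
Termination: capacity saturated (best W = C) with no fitness improvement
for a stagnation window, full coverage reached (coverage mode), or the
generation cap.

Two exact baselines validate the GA: a dynamic-programming knapsack oracle
and a greedy set-cover heuristic used to bracket the key-group size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .frs import FRS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KnapsackInstance:
    """A 0/1 knapsack instance over component items.

    ``membership`` (items x proteins boolean matrix) and ``proteins`` are
    present only when the instance derives from an FRS and coverage is to
    be scored.
    """

    items: Tuple[str, ...]
    values: np.ndarray
    weights: np.ndarray
    capacity: float
    membership: Optional[np.ndarray] = None
    proteins: Tuple[str, ...] = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if len(self.items) != v.shape[0] or len(self.items) != w.shape[0]:
            raise ValueError("items, values and weights must have equal length")
        if (v < 0).any() or (w < 0).any():
            raise ValueError("values and weights must be non-negative")
        if self.capacity < 0:
            raise ValueError("capacity must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters."""

    pop_size: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    max_generations: int = 500
    elitism: int = 1
    stagnation: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            r = getattr(self, name)
            if not (0 <= r <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class KGECResult:
    """A selected component group with its knapsack bookkeeping."""

    items: Tuple[str, ...]
    x: Tuple[int, ...]
    V: float
    W: float
    capacity: float
    coverage: Optional[float]
    generations_run: int
    seed: int

    @property
    def selection(self) -> Tuple[str, ...]:
        return tuple(i for i, xi in zip(self.items, self.x) if xi)

    @property
    def size(self) -> int:
        return int(sum(self.x))


def _repair(pop: np.ndarray, w: np.ndarray, capacity: float,
            removal_order: np.ndarray) -> np.ndarray:
    """Drop lowest-density selected items (ties by item index) until W <= C."""
    W = pop @ w
    bad = W > capacity
    if not bad.any():
        return pop
    n = pop.shape[1]
    sub = pop[bad][:, removal_order]
    cum = np.cumsum(sub * w[removal_order], axis=1)
    feasible_after = (W[bad][:, None] - cum) <= capacity
    j = feasible_after.argmax(axis=1)
    sub &= np.arange(n)[None, :] > j[:, None]
    fixed = pop[bad].copy()
    fixed[:, removal_order] = sub
    pop = pop.copy()
    pop[bad] = fixed
    return pop


def _fitness(pop: np.ndarray, inst: KnapsackInstance, mode: str) -> np.ndarray:
    if mode == "sumvalue":
        return pop @ inst.values
    if mode == "coverage":
        covered = (pop.astype(np.int64) @ inst.membership) > 0
        return covered.sum(axis=1) / inst.membership.shape[1]
    raise ValueError(f"unknown fitness mode {mode!r}")


def ga_knapsack(
    inst: KnapsackInstance, cfg: GAConfig = GAConfig(), fitness: str = "sumvalue"
) -> KGECResult:
    """Run the genetic knapsack search and return the best selection found.

    Every chromosome in every generation is repaired to feasibility, so the
    returned selection always satisfies W <= C.  The run is a deterministic
    function of (instance, config, fitness mode).
    """
    if fitness == "coverage" and (inst.membership is None or not inst.proteins):
        raise ValueError("coverage fitness needs protein membership data")
    n = inst.n
    if inst.capacity == 0 or n == 0:
        empty = np.zeros(n, dtype=bool)
        return _result(empty, inst, fitness, generations=0, seed=cfg.seed)

    rng = np.random.default_rng(cfg.seed)
    w = inst.weights
    # repair removes the item contributing least value per unit weight first
    # (ties by index); with unit weights this is simply the lowest value
    density = inst.values / np.maximum(w, 1e-12)
    removal_order = np.lexsort((np.arange(n), density))
    pop = rng.random((cfg.pop_size, n)) < 0.5
    pop = _repair(pop, w, inst.capacity, removal_order)
    fit = _fitness(pop, inst, fitness)

    best_idx = int(fit.argmax())
    best_x = pop[best_idx].copy()
    best_fit = float(fit[best_idx])
    stagnant = 0
    generations = 0

    for generation in range(1, cfg.max_generations + 1):
        generations = generation
        # roulette-wheel selection
        total = fit.sum()
        probs = None if total <= 0 else fit / total
        parents = rng.choice(cfg.pop_size, size=cfg.pop_size, p=probs)
        new = pop[parents].copy()
        # single-point crossover on consecutive pairs
        half = cfg.pop_size // 2
        do_cross = rng.random(half) < cfg.crossover_rate
        cuts = rng.integers(1, n, size=half) if n > 1 else np.ones(half, dtype=int)
        for pair, (cross, cut) in enumerate(zip(do_cross, cuts)):
            if not cross:
                continue
            i, j = 2 * pair, 2 * pair + 1
            tail = new[i, cut:].copy()
            new[i, cut:] = new[j, cut:]
            new[j, cut:] = tail
        # one mutation locus per chromosome, applied with probability mutation_rate
        do_mut = rng.random(cfg.pop_size) < cfg.mutation_rate
        loci = rng.integers(0, n, size=cfg.pop_size)
        rows = np.nonzero(do_mut)[0]
        new[rows, loci[rows]] ^= True

        new = _repair(new, w, inst.capacity, removal_order)
        fit_new = _fitness(new, inst, fitness)
        # elitism: the best chromosomes of the old generation replace the worst
        if cfg.elitism > 0:
            elite = np.argsort(fit)[-cfg.elitism:]
            worst = np.argsort(fit_new)[: cfg.elitism]
            new[worst] = pop[elite]
            fit_new[worst] = fit[elite]
        pop, fit = new, fit_new

        gen_best = int(fit.argmax())
        if float(fit[gen_best]) > best_fit:
            best_fit = float(fit[gen_best])
            best_x = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1

        if fitness == "coverage" and best_fit >= 1.0:
            break
        best_W = float(best_x @ w)
        if best_W == inst.capacity and stagnant >= cfg.stagnation:
            break

    return _result(best_x, inst, fitness, generations=generations, seed=cfg.seed)


def _result(x: np.ndarray, inst: KnapsackInstance, fitness: str,
            generations: int, seed: int) -> KGECResult:
    coverage = None
    if inst.membership is not None and inst.proteins:
        covered = inst.membership[x].any(axis=0) if x.any() else np.zeros(
            len(inst.proteins), dtype=bool
        )
        coverage = float(covered.sum() / len(inst.proteins))
    return KGECResult(
        items=inst.items,
        x=tuple(int(b) for b in x),
        V=float(x @ inst.values),
        W=float(x @ inst.weights),
        capacity=float(inst.capacity),
        coverage=coverage,
        generations_run=generations,
        seed=seed,
    )


def dp_knapsack_oracle(inst: KnapsackInstance) -> Tuple[float, Tuple[str, ...]]:
    """Exact 0/1-knapsack optimum by dynamic programming (validation only).

    Requires integer weights; returns the optimal value and one optimal
    selection (the lexicographically first found in item order).
    """
    w = inst.weights
    if not np.allclose(w, np.round(w)):
        raise ValueError("dynamic-programming oracle requires integer weights")
    w = np.round(w).astype(int)
    C = int(inst.capacity)
    n = inst.n
    table = np.zeros((n + 1, C + 1))
    for i in range(1, n + 1):
        table[i] = table[i - 1]
        wi, vi = w[i - 1], inst.values[i - 1]
        if wi <= C:
            cand = table[i - 1, : C + 1 - wi] + vi
            improved = cand > table[i, wi:]
            table[i, wi:][improved] = cand[improved]
    best_v = float(table[n, C])
    # reconstruct one optimal selection
    selection = []
    c = C
    for i in range(n, 0, -1):
        if table[i, c] != table[i - 1, c]:
            selection.append(inst.items[i - 1])
            c -= w[i - 1]
    return best_v, tuple(reversed(selection))


def greedy_cover_oracle(
    target_sets: Mapping[str, FrozenSet[str]],
    effective_proteins: Iterable[str],
) -> Tuple[str, ...]:
    """Greedy set cover: repeatedly take the item with the largest marginal
    gain (ties by item id) until every effective protein is covered."""
    universe = set(effective_proteins)
    coverable = set().union(*target_sets.values()) if target_sets else set()
    missing = universe - coverable
    if missing:
        raise ValueError(
            f"effective proteins not coverable by any item: {sorted(missing)}"
        )
    uncovered = set(universe)
    selection = []
    remaining = dict(target_sets)
    while uncovered:
        best_id = min(
            remaining, key=lambda i: (-len(remaining[i] & uncovered), i)
        )
        gain = remaining[best_id] & uncovered
        if not gain:
            break
        selection.append(best_id)
        uncovered -= gain
        del remaining[best_id]
    return tuple(selection)


def frs_knapsack_instance(
    frs: FRS,
    weights: Optional[Mapping[str, float]] = None,
    capacity: Optional[float] = None,
) -> KnapsackInstance:
    """Build the knapsack instance over FRS components.

    Default value v_i = number of effective proteins component i targets;
    default weight w_i = 1 so the capacity counts components.  ``weights``
    may substitute e.g. molecular weight or assay concentration.
    """
    items = tuple(frs.selected_components)
    proteins = tuple(sorted(frs.effective_proteins))
    index = {p: j for j, p in enumerate(proteins)}
    membership = np.zeros((len(items), len(proteins)), dtype=bool)
    for i, cid in enumerate(items):
        for p in frs.target_sets[cid] & frs.effective_proteins:
            membership[i, index[p]] = True
    values = membership.sum(axis=1).astype(float)
    if weights is None:
        w = np.ones(len(items))
    else:
        w = np.array([weights[i] for i in items], dtype=float)
    cap = float(len(items) if capacity is None else capacity)
    return KnapsackInstance(
        items=items, values=values, weights=w, capacity=cap,
        membership=membership, proteins=proteins,
    )


def _child_seed(seed: int, capacity: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(capacity,))
    return int(ss.generate_state(1)[0] % (2**31))


def select_kgec(
    frs: FRS,
    cfg: GAConfig = GAConfig(),
    capacity: Optional[int] = None,
    fitness: str = "coverage",
) -> KGECResult:
    """Extract the key component group covering all effective proteins.

    With ``capacity`` given, a single GA run at that capacity is returned.
    Otherwise the capacity search starts from the greedy set-cover size and
    walks to the smallest capacity at which the GA still attains full
    coverage (stepping up first if the greedy size itself fails).  Each
    capacity gets its own GA seed derived deterministically from
    ``cfg.seed``, so the whole search is reproducible.
    """
    if not frs.effective_proteins:
        raise ValueError("FRS has no effective proteins")
    sets = {c: frs.target_sets[c] & frs.effective_proteins
            for c in frs.selected_components}
    greedy = greedy_cover_oracle(sets, frs.effective_proteins)  # raises if uncoverable

    if capacity is not None:
        inst = frs_knapsack_instance(frs, capacity=capacity)
        return ga_knapsack(inst, cfg, fitness=fitness)

    n = len(frs.selected_components)
    cap = len(greedy)
    best: Optional[KGECResult] = None

    def run(c: int) -> KGECResult:
        inst = frs_knapsack_instance(frs, capacity=c)
        return ga_knapsack(inst, replace(cfg, seed=_child_seed(cfg.seed, c)),
                           fitness=fitness)

    # step up until the GA first attains full coverage
    while cap <= n:
        res = run(cap)
        if res.coverage == 1.0:
            best = res
            break
        cap += 1
    if best is None:
        raise RuntimeError("GA failed to reach full coverage even at full capacity")
    # walk down to the smallest capacity that still covers everything
    while cap > 1:
        res = run(cap - 1)
        if res.coverage != 1.0:
            break
        best, cap = res, cap - 1
    logger.info("KGEC: %d components at capacity %d, coverage %.1f%%",
                best.size, int(best.capacity), 100 * best.coverage)
    return best
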
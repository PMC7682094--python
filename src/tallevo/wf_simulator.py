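"""Clone-based Wright-Fisher simulation of leukemic populations.

The simulator tracks a tumor population as a set of clones rather than
individual cells: each mutation event founds a new clone that inherits its
parent's mutations.  Genealogy is kept in an append-only store (one row per
mutation/clone), so the mutation content of any clone is the chain of store
rows from the clone to the root.  This makes 10^6-cell populations with
~1.5e3 mutation events per generation tractable on one CPU.

Model
-----
* Discrete, non-overlapping generations at fixed carrying capacity
  (Wright-Fisher): offspring counts are multinomial with probabilities
  proportional to clone size times clone fitness.
* Mutations arrive as a Poisson process with rate ``mu * n_sites * n_cells``
  per generation and land in uniformly chosen cells.  Sites are split into a
  driver namespace (selection coefficient ``driver_fitness`` each,
  multiplicative across drivers) and a neutral passenger namespace.  Each
  mutation event is a distinct allele; site labels are drawn uniformly from
  the respective namespace and serve only to classify driver vs passenger.
  (At these parameters ~7.5e6 mutation events occur over a burn-in, far more
  than the 150,100 tracked positions, so a literal once-per-site rule would
  exhaust the site pool within ~100 generations and extinguish all standing
  variation; the site budget is therefore interpreted as a rate multiplier.)
* Treatment is a bottleneck: either random survival (multivariate
  hypergeometric across clones) or survival of exactly the carriers of one
  low-frequency passenger "resistance" marker.
* Regrowth doubles the population stochastically per generation until the
  carrying capacity is reached, then Wright-Fisher resampling resumes.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "ClonePopulation",
    "CCFComparison",
    "evolve",
    "bottleneck_random",
    "bottleneck_resistant",
    "regrow",
    "compare_ccf",
    "run_scenario",
]

_uid_counter = itertools.count(1)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the leukemic Wright-Fisher model.

    ``mu`` is the per-site, per-cell, per-generation mutation rate.  Fitness
    of a clone carrying ``k`` driver mutations is ``(1 + driver_fitness)**k``
    (multiplicative; an additive rule is available via ``fitness_rule``).
    """

    pop_size: int = 1_000_000
    mu: float = 1e-8
    n_driver_sites: int = 100
    driver_fitness: float = 0.01
    n_passenger_sites: int = 150_000
    burn_in_generations: int = 5000
    regrow_generations: int = 40
    bottleneck_removed_range: tuple[int, int] = (90_000, 1_000_000)
    resistant_marker_freq_range: tuple[float, float] = (1e-4, 1e-2)
    fixed_threshold: float = 0.9
    fitness_rule: str = "multiplicative"  # or "additive"
    compact_interval: int = 200
    max_store_rows: int = 50_000_000  # overflow guard on the genealogy store

    def __post_init__(self):
        if self.pop_size < 1:
            raise ValueError("pop_size must be positive")
        if not 0 <= self.mu < 1:
            raise ValueError("mu must be in [0, 1)")
        lo, hi = self.bottleneck_removed_range
        if not 0 <= lo <= hi:
            raise ValueError("bottleneck_removed_range must satisfy 0 <= low <= high")
        if self.fitness_rule not in ("multiplicative", "additive"):
            raise ValueError("fitness_rule must be 'multiplicative' or 'additive'")

    @property
    def n_sites(self) -> int:
        return self.n_driver_sites + self.n_passenger_sites

    def clone_fitness(self, n_drivers) -> np.ndarray:
        """Fitness multiplier for a clone carrying ``n_drivers`` drivers."""
        n = np.asarray(n_drivers)
        if self.fitness_rule == "multiplicative":
            return (1.0 + self.driver_fitness) ** n
        return 1.0 + self.driver_fitness * n


class _Store:
    """Append-only genealogy of mutation events (one row per new clone)."""

    __slots__ = ("parent", "site", "fitness", "n_rows", "uid")

    def __init__(self, capacity: int = 1024):
        self.parent = np.full(capacity, -1, dtype=np.int64)
        self.site = np.full(capacity, -1, dtype=np.int64)
        self.fitness = np.ones(capacity, dtype=np.float64)
        self.n_rows = 0
        self.uid = next(_uid_counter)

    def _grow(self, need: int) -> None:
        cap = len(self.parent)
        if self.n_rows + need <= cap:
            return
        new_cap = max(cap * 2, self.n_rows + need)
        for name in ("parent", "site", "fitness"):
            old = getattr(self, name)
            new = np.empty(new_cap, dtype=old.dtype)
            new[: self.n_rows] = old[: self.n_rows]
            if name == "parent" or name == "site":
                new[self.n_rows:] = -1
            setattr(self, name, new)

    def append(self, parent: np.ndarray, site: np.ndarray, fitness: np.ndarray) -> np.ndarray:
        n = len(parent)
        self._grow(n)
        rows = np.arange(self.n_rows, self.n_rows + n, dtype=np.int64)
        self.parent[rows] = parent
        self.site[rows] = site
        self.fitness[rows] = fitness
        self.n_rows += n
        return rows

    def copy(self) -> "_Store":
        new = _Store(capacity=max(self.n_rows, 1))
        new.parent[: self.n_rows] = self.parent[: self.n_rows]
        new.site[: self.n_rows] = self.site[: self.n_rows]
        new.fitness[: self.n_rows] = self.fitness[: self.n_rows]
        new.n_rows = self.n_rows
        new.uid = self.uid  # copies remain comparable until either compacts
        return new


@dataclass
class ClonePopulation:
    """A population of clones backed by a shared genealogy store.

    ``clone_rows`` indexes live clones into the store; ``clone_counts`` holds
    their cell counts.  Row -1 denotes the founding (mutation-free) clone.
    """

    store: _Store
    clone_rows: np.ndarray  # int64, store row of each live clone (-1 = root)
    clone_counts: np.ndarray  # int64 cell counts, > 0
    generation: int = 0

    # -- constructors ------------------------------------------------------

    @classmethod
    def founding(cls, n_cells: int) -> "ClonePopulation":
        """A homogeneous, mutation-free population of ``n_cells`` cells."""
        store = _Store()
        return cls(
            store=store,
            clone_rows=np.array([-1], dtype=np.int64),
            clone_counts=np.array([n_cells], dtype=np.int64),
        )

    @classmethod
    def from_clones(
        cls,
        clones: Sequence[tuple[Sequence[int], int, float]],
        cfg: SimConfig | None = None,
    ) -> "ClonePopulation":
        """Build a population from explicit (mutation sites, count, fitness).

        Intended for tests and small constructed scenarios; each clone's
        mutation tuple becomes a chain of store rows, and clones sharing a
        mutation prefix share ancestry (the same store rows).
        """
        store = _Store()
        prefix_row: dict[tuple, int] = {(): -1}
        rows, counts = [], []
        for sites, count, fitness in clones:
            parent = -1
            for k, s in enumerate(sites):
                prefix = tuple(sites[: k + 1])
                if prefix in prefix_row:
                    parent = prefix_row[prefix]
                    continue
                row_arr = store.append(
                    np.array([parent]), np.array([s]), np.array([fitness])
                )
                parent = int(row_arr[0])
                prefix_row[prefix] = parent
            rows.append(parent)
            counts.append(count)
        return cls(
            store=store,
            clone_rows=np.array(rows, dtype=np.int64),
            clone_counts=np.array(counts, dtype=np.int64),
        )

    # -- basic properties --------------------------------------------------

    @property
    def total_cells(self) -> int:
        return int(self.clone_counts.sum())

    @property
    def n_clones(self) -> int:
        return len(self.clone_rows)

    def copy(self) -> "ClonePopulation":
        return ClonePopulation(
            store=self.store.copy(),
            clone_rows=self.clone_rows.copy(),
            clone_counts=self.clone_counts.copy(),
            generation=self.generation,
        )

    def clone_fitness(self) -> np.ndarray:
        w = np.ones(self.n_clones)
        live = self.clone_rows >= 0
        w[live] = self.store.fitness[self.clone_rows[live]]
        return w

    def clones(self) -> Iterator[tuple[frozenset, int, float]]:
        """Materialize clones as (mutation-id set, count, fitness)."""
        fit = self.clone_fitness()
        for row, count, w in zip(self.clone_rows, self.clone_counts, fit):
            muts = []
            r = int(row)
            while r >= 0:
                muts.append(r)
                r = int(self.store.parent[r])
            yield frozenset(muts), int(count), float(w)

    # -- mutation-level queries --------------------------------------------

    def mutation_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Carrier cell count of every mutation segregating or fixed.

        Returns (store row ids, carrier counts) for rows carried by at least
        one live cell.  A mutation's carriers are the cells of all clones in
        its subtree of the genealogy.
        """
        n = self.store.n_rows
        acc = np.zeros(n + 1, dtype=np.int64)  # last slot absorbs root (-1)
        acc[self.clone_rows] += self.clone_counts
        parent = self.store.parent
        # reverse topological accumulation (parent < child always)
        for i in range(n - 1, -1, -1):
            a = acc[i]
            if a:
                acc[parent[i]] += a
        carried = np.flatnonzero(acc[:n])
        return carried, acc[carried]

    def mutation_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        rows, counts = self.mutation_counts()
        return rows, counts / self.total_cells

    def fixed_mutation_rows(self) -> np.ndarray:
        rows, counts = self.mutation_counts()
        return rows[counts == self.total_cells]

    def _site_union_count(self, origin_rows: np.ndarray) -> int:
        """Cells carrying any of the given mutation events (exact union)."""
        mask = np.zeros(self.store.n_rows, dtype=bool)
        mask[origin_rows] = True
        parent = self.store.parent
        for i in range(int(origin_rows.min()) + 1, self.store.n_rows):
            p = parent[i]
            if p >= 0 and mask[p]:
                mask[i] = True
        live = self.clone_rows >= 0
        carried = mask[np.clip(self.clone_rows, 0, None)] & live
        return int(self.clone_counts[carried].sum())

    def fixed_counts(self, cfg: SimConfig) -> tuple[int, int]:
        """(fixed driver positions, fixed passenger positions).

        A position counts as fixed when the fraction of cells carrying a
        mutant allele at it exceeds ``cfg.fixed_threshold`` (0.9 by default,
        the same CCF criterion used for the primary/relapse comparison).
        Independent origins at the same position are merged (a soft sweep
        fixes the position even though no single origin crosses the
        threshold): candidate positions whose summed origin subtrees cross
        it are verified with an exact union over the genealogy, which
        removes any double counting of nested origins.
        """
        needed = cfg.fixed_threshold * self.total_cells
        rows, counts = self.mutation_counts()
        sites = self.store.site[rows]
        order = np.argsort(sites, kind="stable")
        sites, rows, counts = sites[order], rows[order], counts[order]
        uniq, start = np.unique(sites, return_index=True)
        totals = np.add.reduceat(counts, start)
        n_origins = np.diff(np.append(start, len(sites)))
        fixed = []
        for k in np.flatnonzero(totals > needed):
            if n_origins[k] == 1:
                carriers = int(totals[k])
            else:
                carriers = self._site_union_count(
                    rows[start[k]: start[k] + n_origins[k]]
                )
            if carriers > needed:
                fixed.append(uniq[k])
        fixed = np.asarray(fixed, dtype=np.int64)
        n_driver = int((fixed < cfg.n_driver_sites).sum())
        return n_driver, len(fixed) - n_driver

    # -- maintenance -------------------------------------------------------

    def compact(self) -> None:
        """Drop store rows that are not ancestors of any live clone.

        Renumbers rows; invalidates row-id comparability with copies made
        before compaction (the store uid changes).
        """
        n = self.store.n_rows
        keep = np.zeros(n, dtype=bool)
        live = self.clone_rows[self.clone_rows >= 0]
        keep[live] = True
        frontier = self.store.parent[live]
        frontier = np.unique(frontier[frontier >= 0])
        while frontier.size:
            frontier = frontier[~keep[frontier]]
            keep[frontier] = True
            frontier = self.store.parent[frontier]
            frontier = np.unique(frontier[frontier >= 0])
        new_index = np.cumsum(keep, dtype=np.int64) - 1
        kept = np.flatnonzero(keep)
        new_store = _Store(capacity=max(len(kept), 1))
        old_parent = self.store.parent[kept]
        remapped = np.where(old_parent >= 0, new_index[np.clip(old_parent, 0, None)], -1)
        new_store.append(remapped, self.store.site[kept], self.store.fitness[kept])
        self.clone_rows = np.where(
            self.clone_rows >= 0, new_index[np.clip(self.clone_rows, 0, None)], -1
        )
        self.store = new_store


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def _mutate(pop: ClonePopulation, cfg: SimConfig, rng: np.random.Generator) -> None:
    """Apply one generation's worth of new mutations to random cells."""
    n_cells = pop.total_cells
    lam = cfg.mu * cfg.n_sites * n_cells
    n_new = int(rng.poisson(lam)) if lam > 0 else 0
    if n_new == 0:
        return
    if pop.store.n_rows + n_new > cfg.max_store_rows:
        raise RuntimeError("genealogy store exceeded max_store_rows overflow guard")
    # unique cell indices => a clone is never decremented below zero
    cells = np.unique(rng.integers(0, n_cells, size=n_new))
    cum = np.cumsum(pop.clone_counts)
    k = np.searchsorted(cum, cells, side="right")
    parent_rows = pop.clone_rows[k]
    sites = rng.integers(0, cfg.n_sites, size=len(cells))
    parent_fit = np.ones(len(cells))
    live = parent_rows >= 0
    parent_fit[live] = pop.store.fitness[parent_rows[live]]
    is_driver = sites < cfg.n_driver_sites
    if cfg.fitness_rule == "multiplicative":
        fit = np.where(is_driver, parent_fit * (1.0 + cfg.driver_fitness), parent_fit)
    else:
        fit = np.where(is_driver, parent_fit + cfg.driver_fitness, parent_fit)
    new_rows = pop.store.append(parent_rows, sites, fit)
    np.subtract.at(pop.clone_counts, k, 1)
    pop.clone_rows = np.concatenate([pop.clone_rows, new_rows])
    pop.clone_counts = np.concatenate(
        [pop.clone_counts, np.ones(len(cells), dtype=np.int64)]
    )
    alive = pop.clone_counts > 0
    if not alive.all():
        pop.clone_rows = pop.clone_rows[alive]
        pop.clone_counts = pop.clone_counts[alive]


def evolve(
    pop: ClonePopulation, generations: int, cfg: SimConfig, seed=None
) -> ClonePopulation:
    """Evolve ``pop`` in place for ``generations`` Wright-Fisher generations.

    Each generation: multinomial resampling at constant population size with
    probabilities proportional to count x fitness, then Poisson mutation.
    """
    rng = _as_rng(seed)
    n_cells = pop.total_cells
    if n_cells == 0:
        raise ValueError("cannot evolve an empty population")
    for g in range(generations):
        w = pop.clone_counts * pop.clone_fitness()
        p = w / w.sum()
        counts = rng.multinomial(n_cells, p)
        alive = counts > 0
        pop.clone_rows = pop.clone_rows[alive]
        pop.clone_counts = counts[alive]
        _mutate(pop, cfg, rng)
        pop.generation += 1
        if cfg.compact_interval and (g + 1) % cfg.compact_interval == 0:
            pop.compact()
    return pop


def bottleneck_random(pop: ClonePopulation, cfg: SimConfig, seed=None) -> ClonePopulation:
    """Treatment as random survival: remove U(removed_range) random cells.

    Survivors are drawn without replacement across clones (multivariate
    hypergeometric), so expected post-bottleneck frequencies are unbiased.
    """
    rng = _as_rng(seed)
    lo, hi = cfg.bottleneck_removed_range
    n_cells = pop.total_cells
    removed = int(rng.integers(lo, hi + 1))
    removed = min(removed, n_cells)
    n_survivors = n_cells - removed
    if n_survivors <= 0:
        raise ValueError("bottleneck removed the entire population")
    counts = rng.multivariate_hypergeometric(
        pop.clone_counts, n_survivors, method="marginals"
    )
    alive = counts > 0
    pop.clone_rows = pop.clone_rows[alive]
    pop.clone_counts = counts[alive].astype(np.int64)
    return pop


def _descendant_mask(store: _Store, row: int) -> np.ndarray:
    """Boolean mask over store rows: descends-from-or-is ``row``."""
    n = store.n_rows
    mask = np.zeros(n, dtype=bool)
    mask[row] = True
    parent = store.parent
    for i in range(row + 1, n):
        p = parent[i]
        if p >= 0 and mask[p]:
            mask[i] = True
    return mask


def bottleneck_resistant(
    pop: ClonePopulation, marker_freq_range: tuple[float, float], seed=None,
    cfg: SimConfig | None = None,
) -> ClonePopulation:
    """Treatment as genetic resistance: survivors are exactly the carriers of
    one low-frequency passenger mutation picked uniformly at random.

    Returns the population restricted to carriers; the chosen marker's store
    row is recorded on the population as ``resistant_marker_row``.
    """
    rng = _as_rng(seed)
    cfg = cfg or SimConfig()
    lo, hi = marker_freq_range
    rows, freqs = pop.mutation_frequencies()
    sites = pop.store.site[rows]
    ok = (sites >= cfg.n_driver_sites) & (freqs >= lo) & (freqs <= hi)
    candidates = rows[ok]
    if candidates.size == 0:
        raise ValueError(
            f"no passenger mutation with frequency in [{lo}, {hi}] to act as marker"
        )
    marker = int(rng.choice(candidates))
    mask = _descendant_mask(pop.store, marker)
    live = pop.clone_rows >= 0
    carrier = np.zeros(pop.n_clones, dtype=bool)
    carrier[live] = mask[pop.clone_rows[live]]
    pop.clone_rows = pop.clone_rows[carrier]
    pop.clone_counts = pop.clone_counts[carrier]
    pop.resistant_marker_row = marker  # type: ignore[attr-defined]
    return pop


def regrow(
    pop: ClonePopulation, target_size: int, generations: int, cfg: SimConfig, seed=None
) -> ClonePopulation:
    """Regrow after a bottleneck: stochastic doubling to ``target_size``,
    then Wright-Fisher resampling at the target; mutation throughout.

    During growth each cell leaves Binomial(4, w/(2 w_bar)) offspring (mean
    2 per relative fitness unit, variance ~1), a supercritical branching
    process capped at ``target_size`` by hypergeometric downsampling.
    """
    rng = _as_rng(seed)
    if pop.total_cells == 0:
        raise ValueError("cannot regrow an empty population")
    for _ in range(generations):
        n_cells = pop.total_cells
        if n_cells < target_size:
            w = pop.clone_fitness()
            wbar = float(np.average(w, weights=pop.clone_counts))
            q = np.clip(w / (2.0 * wbar), 0.0, 1.0)
            counts = rng.binomial(4 * pop.clone_counts, q)
            if counts.sum() == 0:
                raise RuntimeError("population went extinct during regrowth")
            if counts.sum() > target_size:
                counts = rng.multivariate_hypergeometric(
                    counts, target_size, method="marginals"
                )
            alive = counts > 0
            pop.clone_rows = pop.clone_rows[alive]
            pop.clone_counts = counts[alive].astype(np.int64)
        else:
            w = pop.clone_counts * pop.clone_fitness()
            counts = rng.multinomial(target_size, w / w.sum())
            alive = counts > 0
            pop.clone_rows = pop.clone_rows[alive]
            pop.clone_counts = counts[alive]
        _mutate(pop, cfg, rng)
        pop.generation += 1
    return pop


# ---------------------------------------------------------------------------
# CCF comparison between primary and relapse
# ---------------------------------------------------------------------------


@dataclass
class CCFComparison:
    """Histogram over primary CCF of mutations fixed at relapse.

    ``histogram[b]`` is the fraction of relapse-fixed mutations (relapse CCF
    above ``fixed_threshold``) whose primary CCF falls in the b-th 0.1-wide
    bin; mutations absent from the primary fall in the [0, 0.1) bin.
    """

    fixed_threshold: float
    bin_edges: np.ndarray
    histogram: np.ndarray
    n_fixed: int
    empty: bool = False

    @property
    def low_bin_mass(self) -> float:
        return float(self.histogram[0])


def compare_ccf(
    primary_pop: ClonePopulation, relapse_pop: ClonePopulation, cfg: SimConfig
) -> CCFComparison:
    """Primary-CCF distribution of mutations fixed (CCF > threshold) at relapse.

    The two populations must share genealogy (the relapse evolved from a copy
    of the primary without intervening compaction), so mutations match by
    store row id; rows created after the primary snapshot have primary CCF 0.
    """
    if primary_pop.store.uid != relapse_pop.store.uid:
        raise ValueError(
            "primary and relapse populations do not share a genealogy store; "
            "snapshot the primary with .copy() and avoid compaction in between"
        )
    edges = np.linspace(0.0, 1.0, 11)
    rel_rows, rel_freq = relapse_pop.mutation_frequencies()
    fixed = rel_rows[rel_freq > cfg.fixed_threshold]
    if fixed.size == 0:
        return CCFComparison(cfg.fixed_threshold, edges, np.zeros(10), 0, empty=True)
    prim_rows, prim_freq = primary_pop.mutation_frequencies()
    n_prim = primary_pop.store.n_rows
    freq_lookup = np.zeros(max(n_prim, int(fixed.max()) + 1))
    freq_lookup[prim_rows] = prim_freq
    prim_ccf = freq_lookup[fixed]
    hist, _ = np.histogram(np.clip(prim_ccf, 0.0, 1.0), bins=edges)
    hist = hist / hist.sum()
    return CCFComparison(cfg.fixed_threshold, edges, hist, int(fixed.size))


def run_scenario(cfg: SimConfig, scenario: str, seed=None) -> tuple[CCFComparison, dict]:
    """Burn-in -> treatment bottleneck -> regrowth -> primary/relapse CCF.

    ``scenario`` is "resistant" (survivors share one low-frequency passenger
    marker) or "non_resistant" (random survivors).  Returns the CCF
    comparison and a summary dict.
    """
    if scenario not in ("resistant", "non_resistant"):
        raise ValueError("scenario must be 'resistant' or 'non_resistant'")
    rng = _as_rng(seed)
    pop = ClonePopulation.founding(cfg.pop_size)
    evolve(pop, cfg.burn_in_generations, cfg, rng)
    pop.compact()
    primary = pop.copy()
    fixed_drivers, fixed_passengers = primary.fixed_counts(cfg)
    marker_row = None
    if scenario == "resistant":
        bottleneck_resistant(pop, cfg.resistant_marker_freq_range, rng, cfg=cfg)
        marker_row = pop.resistant_marker_row  # type: ignore[attr-defined]
    else:
        bottleneck_random(pop, cfg, rng)
    survivors = pop.total_cells
    regrow(pop, cfg.pop_size, cfg.regrow_generations, cfg, rng)
    comparison = compare_ccf(primary, pop, cfg)
    summary = {
        "scenario": scenario,
        "burn_in_generations": cfg.burn_in_generations,
        "regrow_generations": cfg.regrow_generations,
        "fixed_drivers_primary": fixed_drivers,
        "fixed_passengers_primary": fixed_passengers,
        "bottleneck_survivors": survivors,
        "n_fixed_relapse": comparison.n_fixed,
        "low_bin_mass": comparison.low_bin_mass,
        "marker_row": marker_row,
    }
    return comparison, summary
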
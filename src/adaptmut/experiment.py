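"""Simulator for the 96-well lineage-separation experiment.

A single founder cell grows in a well to 400-3000 cells (phase I), the well
is plated, and a subset of the plated daughters independently adapt into
colonies.  Two mutation-timing models are contrasted:

* ``preexisting`` — mutations arise during phase-I divisions and are
  inherited clonally, producing Luria-Delbrück jackpot lineages;
* ``induced`` — each adapting colony independently acquires a target-locus
  mutation at growth resumption, giving Poisson-like counts across lineages.

All randomness derives from one seed via a per-lineage counter split, so
adding lineages never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .growth import AreaTimeSeries

MUTATION_MODELS = ("preexisting", "induced", "none")

#: maximum emergence generation detectable by consensus sequencing (the
#: mutant fraction 2^-g stays >= 25% only for g <= 2)
MAX_INDUCED_EMERGENCE_GENERATION = 2


@dataclass(frozen=True)
class ExperimentParams:
    """Parameters of the lineage-separation experiment simulator."""

    n_lineages: int = 56
    cells_per_well_range: tuple[int, int] = (400, 3000)
    p_adapt: float = 0.014
    mutation_model: str = "induced"
    mu_predivision: float = 0.0
    p_induced: float = 0.042
    locus_fraction: float = 1.08e-4
    post_adaptation_divisions: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        lo, hi = self.cells_per_well_range
        if lo < 1 or hi > 10**6 or lo > hi:
            raise ValueError("cells_per_well_range must lie within [1, 1e6]")
        for name in ("p_adapt", "mu_predivision", "p_induced", "locus_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.mutation_model not in MUTATION_MODELS:
            raise ValueError(
                f"unknown mutation_model {self.mutation_model!r}; "
                f"expected one of {MUTATION_MODELS}"
            )


@dataclass(frozen=True)
class ColonyRecord:
    lineage_id: int
    colony_id: int
    adapted: bool
    #: list of (locus_id, emergence_generation) pairs; emergence generation 0
    #: means the founding adapted cell already carried the mutation
    mutations: tuple[tuple[str, int], ...]
    mutant_fraction: float


@dataclass(frozen=True)
class LineageTable:
    """One row per adapted colony, plus the lineage universe size."""

    n_lineages: int
    colonies: tuple[ColonyRecord, ...]

    def __post_init__(self):
        for c in self.colonies:
            if c.mutant_fraction > 0 and not c.mutations:
                raise ValueError("mutant_fraction > 0 requires mutations")

    def __len__(self) -> int:
        return len(self.colonies)

    def mutant_counts_per_lineage(self) -> np.ndarray:
        """Number of mutation-carrying colonies in each lineage (length
        ``n_lineages``; lineages without colonies count 0)."""
        counts = np.zeros(self.n_lineages, dtype=int)
        for c in self.colonies:
            if c.mutations:
                counts[c.lineage_id] += 1
        return counts

    def colony_counts_per_lineage(self) -> np.ndarray:
        counts = np.zeros(self.n_lineages, dtype=int)
        for c in self.colonies:
            counts[c.lineage_id] += 1
        return counts


@dataclass(frozen=True)
class FluctuationSummary:
    histogram: dict[int, int]
    variance_to_mean: float
    fraction_lineages_with_mutant: float
    n_lineages: int


def _lineage_rng(seed: int, lineage_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(lineage_index,))
    )


def grow_division_tree(
    n_cells: int, mu: float, rng: np.random.Generator, lineage_id: int = 0
) -> list[tuple[frozenset, int]]:
    """Grow a synchronous binary division tree from one cell to ``n_cells``.

    Each of the ``n_cells - 1`` division events mutates one daughter's target
    locus with probability ``mu``; every mutation event gets a unique locus id
    and is inherited by all descendants.  Returns cell classes as
    ``(mutation_id_set, count)`` pairs.  The final generation divides only the
    cells needed to reach the drawn census (cap on the power-of-two tree).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    classes: list[tuple[frozenset, int]] = [(frozenset(), 1)]
    total = 1
    event = 0
    gen = 0
    while total < n_cells:
        gen += 1
        n_div = min(total, n_cells - total)
        counts = np.array([c for _, c in classes], dtype=np.int64)
        if n_div == total:
            dividing = counts
        else:
            dividing = rng.multivariate_hypergeometric(counts, n_div)
        new_classes: list[tuple[frozenset, int]] = []
        for (muts, count), d in zip(classes, dividing):
            n_mut = rng.binomial(d, mu) if mu > 0 else 0
            # each division adds one daughter; n_mut of the new daughters
            # carry a fresh mutation event
            new_classes.append((muts, count + int(d) - n_mut))
            for _ in range(n_mut):
                event += 1
                new_classes.append(
                    (muts | {f"pre_L{lineage_id}_g{gen}_e{event}"}, 1)
                )
        classes = new_classes
        total += n_div
    return classes


def simulate_lineage(params: ExperimentParams, seed: int | None = None) -> LineageTable:
    """Simulate all lineages of one experiment.

    Under ``preexisting``, mutations arise in the phase-I division tree and
    adapted colonies founded by mutant cells carry them clonally (mutant
    fraction 1).  Under ``induced``, each adapted colony independently
    acquires a mutation with probability ``p_induced`` at an emergence
    generation drawn uniformly from {0, 1, 2}; the colony mutant fraction is
    then ``2**-g`` under deterministic doubling.
    """
    if seed is None:
        seed = params.seed
    lo, hi = params.cells_per_well_range
    colonies: list[ColonyRecord] = []
    for lineage in range(params.n_lineages):
        rng = _lineage_rng(seed, lineage)
        n_cells = int(rng.integers(lo, hi + 1))
        colony_id = 0
        if params.mutation_model == "preexisting":
            classes = grow_division_tree(
                n_cells, params.mu_predivision, rng, lineage_id=lineage
            )
            for muts, count in classes:
                n_adapt = int(rng.binomial(count, params.p_adapt))
                for _ in range(n_adapt):
                    colonies.append(
                        ColonyRecord(
                            lineage_id=lineage,
                            colony_id=colony_id,
                            adapted=True,
                            mutations=tuple((m, 0) for m in sorted(muts)),
                            mutant_fraction=1.0 if muts else 0.0,
                        )
                    )
                    colony_id += 1
        else:
            n_adapt = int(rng.binomial(n_cells, params.p_adapt))
            for _ in range(n_adapt):
                mutations: tuple[tuple[str, int], ...] = ()
                fraction = 0.0
                if (
                    params.mutation_model == "induced"
                    and rng.random() < params.p_induced
                ):
                    g = int(
                        rng.integers(0, MAX_INDUCED_EMERGENCE_GENERATION + 1)
                    )
                    mutations = ((f"ind_L{lineage}_c{colony_id}", g),)
                    fraction = 2.0 ** (-g)
                colonies.append(
                    ColonyRecord(
                        lineage_id=lineage,
                        colony_id=colony_id,
                        adapted=True,
                        mutations=mutations,
                        mutant_fraction=fraction,
                    )
                )
                colony_id += 1
    return LineageTable(n_lineages=params.n_lineages, colonies=tuple(colonies))


def fluctuation_summary(table: LineageTable) -> FluctuationSummary:
    """Histogram and variance-to-mean ratio of mutant colonies per lineage.

    A Poisson-like ratio (~1) indicates independent post-separation events;
    strong overdispersion (jackpots) indicates pre-separation mutations.
    """
    if table.n_lineages < 1 or len(table) == 0:
        raise ValueError("empty lineage table")
    if table.n_lineages < 2:
        raise ValueError(
            "variance-to-mean is undefined for a single lineage"
        )
    counts = table.mutant_counts_per_lineage()
    values, freqs = np.unique(counts, return_counts=True)
    hist = {int(v): int(f) for v, f in zip(values, freqs)}
    mean = counts.mean()
    var = counts.var(ddof=1)
    vtm = float(var / mean) if mean > 0 else 0.0
    return FluctuationSummary(
        histogram=hist,
        variance_to_mean=vtm,
        fraction_lineages_with_mutant=float((counts > 0).mean()),
        n_lineages=table.n_lineages,
    )


@dataclass(frozen=True)
class GrowthPhaseParams:
    """Ground-truth parameters of a simulated three-phase area curve.

    Defaults place the division arrest between t1 = 30 h and t2 = 90 h,
    i.e. roughly 2-3 days of arrest before growth resumes slowly.
    """

    a0: float = 50.0  # pixels at t = 0
    t1: float = 30.0  # hours, end of phase I
    t2: float = 90.0  # hours, end of phase II
    s1: float = 0.12  # log-area slope per hour, phase I
    s2: float = 0.0  # phase II (arrest)
    s3: float = 0.03  # phase III (slow resumption)
    noise: float = 0.05  # sd of multiplicative (lognormal) noise


@dataclass(frozen=True)
class SimulatedGrowthCurve:
    series: AreaTimeSeries
    t1: float
    t2: float
    params: GrowthPhaseParams


def simulate_colony_growth(
    t_grid,
    phase_params: GrowthPhaseParams | None = None,
    seed: int = 0,
) -> SimulatedGrowthCurve:
    """Piecewise log-linear three-phase area curve with multiplicative noise.

    Changepoints are snapped to the nearest grid time; the snapped values are
    returned as ground truth.
    """
    if phase_params is None:
        phase_params = GrowthPhaseParams()
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 3:
        raise ValueError("t_grid must be a 1-D array of at least 3 times")
    if not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    p = phase_params
    if not (0.0 < p.t1 < p.t2 < t[-1]):
        raise ValueError("changepoints must satisfy 0 < t1 < t2 < max(t_grid)")
    if p.s1 <= 0 or p.s3 <= 0:
        raise ValueError("phase I and III slopes must be positive")
    t1 = float(t[np.argmin(np.abs(t - p.t1))])
    t2 = float(t[np.argmin(np.abs(t - p.t2))])
    if not t1 < t2:
        raise ValueError("changepoints collapse onto the same grid point")
    log_area = (
        np.log(p.a0)
        + p.s1 * np.minimum(t, t1)
        + p.s2 * (np.clip(t, t1, t2) - t1)
        + p.s3 * np.maximum(t - t2, 0.0)
    )
    if p.noise > 0:
        rng = np.random.default_rng(seed)
        log_area = log_area + rng.normal(0.0, p.noise, size=len(t))
    series = AreaTimeSeries(t=t, area=np.exp(log_area))
    return SimulatedGrowthCurve(
        series=series, t1=t1, t2=t2, params=replace(p, t1=t1, t2=t2)
    )
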
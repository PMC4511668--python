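"""Forward-time neutral simulation of host generations and their microbiomes.

Hosts reproduce asexually in discrete non-overlapping generations under a
Wright-Fisher process: each of the N offspring picks a parent uniformly at
random (with replacement) from the previous generation.  Each offspring then
fills its n microbiome slots by multinomial sampling with replacement: every
slot is parental with probability x (drawn from the parent's relative taxon
abundances) and environmental otherwise (drawn from the current environmental
pool).  The environment offered to a generation is the convex combination
``y * pooled + (1 - y) * fixed`` where *pooled* is the renormalized sum of all
previous-generation microbiomes and *fixed* is a constant (uniform by
default) pool of all m taxa.

There is no mutation, speciation or selection: taxa can only be lost (or,
with a fixed environmental component, re-acquired), and all diversity
dynamics arise from sampling noise and the host genealogy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .diversity import (
    DiversityRecord,
    alpha_diversity,
    beta_diversity,
    detect_stabilization,
    gamma_diversity,
)

__all__ = [
    "PopulationState",
    "EnvironmentState",
    "GenealogyRecord",
    "SimulationResult",
    "initialize_population",
    "compose_environment",
    "sample_offspring_microbiome",
    "step_generation",
    "run_simulation",
    "mrca_generation",
    "population_richness",
    "diversity_record",
    "trajectory_frame",
    "write_trajectory",
    "write_final_state",
]


@dataclass
class PopulationState:
    """Slot occupancies of every host: an N x m matrix of non-negative counts.

    Every row sums exactly to the per-host slot capacity n.  ``parent_index``
    maps each host to its parent in the previous generation (None at
    generation 0).
    """

    counts: np.ndarray
    generation: int = 0
    parent_index: np.ndarray | None = None

    @property
    def num_hosts(self) -> int:
        return self.counts.shape[0]

    @property
    def num_taxa(self) -> int:
        return self.counts.shape[1]

    def relative_abundances(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=1, keepdims=True)


@dataclass
class EnvironmentState:
    """Fixed and currently-offered environmental relative-abundance vectors."""

    fixed_distribution: np.ndarray
    current_distribution: np.ndarray

    def __post_init__(self) -> None:
        for name in ("fixed_distribution", "current_distribution"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
            setattr(self, name, vec)


@dataclass
class GenealogyRecord:
    """Per-generation parent-index vectors, one per generation after the first."""

    parents: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.parents)


@dataclass
class SimulationResult:
    trajectory: list[DiversityRecord]
    final_state: PopulationState
    genealogy: GenealogyRecord
    environment: EnvironmentState
    config: SimulationConfig

    def __iter__(self):
        # allows ``trajectory, final_state, genealogy = result``
        return iter((self.trajectory, self.final_state, self.genealogy))


def initialize_population(
    config: SimulationConfig, rng: np.random.Generator
) -> PopulationState:
    """Seed generation 0: each host's n slots drawn uniformly over the m taxa."""
    uniform = np.full(config.num_taxa, 1.0 / config.num_taxa)
    counts = rng.multinomial(config.slots_per_host, uniform, size=config.num_hosts)
    return PopulationState(counts=counts, generation=0, parent_index=None)


def compose_environment(
    prev_population: PopulationState,
    fixed_distribution: np.ndarray,
    pooled_env_fraction: float,
) -> np.ndarray:
    """Environmental pool offered to the next generation: y*pooled + (1-y)*fixed."""
    y = pooled_env_fraction
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"pooled_env_fraction must lie in [0, 1], got {y!r}")
    fixed = np.asarray(fixed_distribution, dtype=float)
    if y == 0.0:
        return fixed.copy()
    pooled = prev_population.counts.sum(axis=0).astype(float)
    total = pooled.sum()
    if total <= 0:
        raise ValueError("previous population has no microbes to pool")
    pooled /= total
    return y * pooled + (1.0 - y) * fixed


def sample_offspring_microbiome(
    parent_counts: np.ndarray,
    env_distribution: np.ndarray,
    parental_fraction: float,
    slots: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fill one offspring's slots from its parent and the environment.

    Each slot is independently parental with probability x; equivalently (and
    vectorizably) the number of parental slots is Binomial(slots, x) followed
    by one multinomial draw from each source.
    """
    x = parental_fraction
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"parental_fraction must lie in [0, 1], got {x!r}")
    parent_counts = np.asarray(parent_counts)
    k = int(rng.binomial(slots, x)) if 0.0 < x < 1.0 else int(round(slots * x))
    parental = rng.multinomial(k, parent_counts / parent_counts.sum())
    environmental = rng.multinomial(slots - k, np.asarray(env_distribution, float))
    return parental + environmental


def step_generation(
    population: PopulationState,
    environment: EnvironmentState,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance one host generation.

    The environmental pool is recomposed from the incoming population before
    any offspring samples from it; then every offspring independently draws a
    uniform parent and its microbiome.  ``environment.current_distribution``
    is updated in place.
    """
    n = config.slots_per_host
    num_hosts = config.num_hosts
    x = config.parental_fraction

    env_p = compose_environment(
        population, environment.fixed_distribution, config.pooled_env_fraction
    )
    environment.current_distribution = env_p

    parents = rng.integers(0, population.num_hosts, size=num_hosts)
    if x == 1.0:
        parent_rel = population.counts[parents] / n
        counts = rng.multinomial(n, parent_rel)
    elif x == 0.0:
        counts = rng.multinomial(n, env_p, size=num_hosts)
    else:
        k = rng.binomial(n, x, size=num_hosts)
        parent_rel = population.counts[parents] / n
        counts = rng.multinomial(k, parent_rel) + rng.multinomial(n - k, env_p)
    return PopulationState(
        counts=counts, generation=population.generation + 1, parent_index=parents
    )


def population_richness(population: PopulationState) -> int:
    """Number of taxa with nonzero abundance anywhere in the host population."""
    return int(np.count_nonzero(population.counts.sum(axis=0)))


def diversity_record(
    population: PopulationState,
    richness_mode: str = "global",
    global_richness: int | None = None,
) -> DiversityRecord:
    """Alpha/beta/gamma snapshot of a population state."""
    if richness_mode == "global" and global_richness is None:
        global_richness = population.num_taxa
    a_mean, a_sd = alpha_diversity(population.counts, richness_mode, global_richness)
    beta = (
        beta_diversity(population.counts) if population.num_hosts > 1 else float("nan")
    )
    gamma = gamma_diversity(population.counts, richness_mode, global_richness)
    return DiversityRecord(population.generation, a_mean, a_sd, beta, gamma)


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run a full forward simulation from a seeded uniform population.

    Diversity is recorded at generation 0 and every ``record_interval``
    generations thereafter.  The run halts at ``max_generations``, or earlier
    when the recorded gamma trajectory stabilizes (if
    ``stop_on_stabilization``), or when a single taxon remains population-wide
    (if ``stop_on_absorption``; that state is absorbing whenever x=1 or y=1).
    Identical configs (including the seed) give bitwise-identical results.
    """
    rng = np.random.default_rng(config.seed)
    population = initialize_population(config, rng)
    fixed = config.fixed_env()
    environment = EnvironmentState(fixed.copy(), fixed.copy())
    genealogy = GenealogyRecord()

    trajectory = [diversity_record(population, config.richness_mode)]
    gammas = [trajectory[0].gamma]

    for _ in range(config.max_generations):
        population = step_generation(population, environment, config, rng)
        if config.track_genealogy:
            genealogy.parents.append(population.parent_index.astype(np.int32))
        at_interval = population.generation % config.record_interval == 0
        absorbed = config.stop_on_absorption and population_richness(population) == 1
        if at_interval or absorbed:
            record = diversity_record(population, config.richness_mode)
            trajectory.append(record)
            gammas.append(record.gamma)
        if absorbed:
            break
        if (
            config.stop_on_stabilization
            and at_interval
            and population.generation >= config.min_generations
            and detect_stabilization(
                gammas, config.stabilization_window, config.stabilization_tolerance
            )
        ):
            break
    return SimulationResult(trajectory, population, genealogy, environment, config)


def mrca_generation(genealogy: GenealogyRecord) -> int | None:
    """Generations back from the final generation to the whole-population MRCA.

    Follows every extant host's lineage backwards through the recorded parent
    vectors and returns the first depth at which all lineages pass through a
    single ancestor, or None if they never coalesce within the record.
    """
    if len(genealogy.parents) == 0:
        raise ValueError("genealogy is empty")
    lineages = genealogy.parents[-1]
    depth = 1
    while np.unique(lineages).size > 1:
        if depth >= len(genealogy.parents):
            return None
        lineages = genealogy.parents[-1 - depth][lineages]
        depth += 1
    return depth


def trajectory_frame(trajectory: list[DiversityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "generation": [r.generation for r in trajectory],
            "alpha_mean": [r.alpha_mean for r in trajectory],
            "alpha_sd": [r.alpha_sd for r in trajectory],
            "beta": [r.beta for r in trajectory],
            "gamma": [r.gamma for r in trajectory],
        }
    )


def write_trajectory(trajectory: list[DiversityRecord], path) -> None:
    """CSV with header ``generation,alpha_mean,alpha_sd,beta,gamma``."""
    trajectory_frame(trajectory).to_csv(path, index=False)


def write_final_state(population: PopulationState, path) -> None:
    """Host x taxon count matrix as CSV (host ids as rows, taxon_j columns)."""
    frame = pd.DataFrame(
        population.counts,
        index=[f"host_{i}" for i in range(population.num_hosts)],
        columns=[f"taxon_{j}" for j in range(population.num_taxa)],
    )
    frame.to_csv(path, index_label="host")
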
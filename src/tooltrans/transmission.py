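"""Condition-specific transmission rules.

Three acquisition regimes are modelled:

* **social** — a naive agent's acquisition probability grows by a fixed
  increment (default 1 %) for every past co-occupancy with a tool user; the
  trial fires when it enters a cell holding a tool user and is old enough.
* **inheritance** — the trait passes from parent to offspring at birth,
  linked to the hybrid-like phenotype; agents age, die, reproduce on
  co-occupancy, and juveniles preferentially follow their mothers.
* **asocial** — agents acquire the trait independently at a fixed per-step
  chance, and tool users drift toward randomly placed resource "attractors",
  creating spatial (not social) structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simcore import (
    COMMON_LIKE,
    HYBRID_LIKE,
    AgentState,
    SimConfig,
    _neighbour_table,
    move_random,
)


@dataclass(frozen=True)
class Attractor:
    """Fixed grid location toward which tool users preferentially move."""

    row: int
    col: int

    @property
    def position(self) -> tuple[int, int]:
        return (self.row, self.col)


def place_attractors(config: SimConfig, rng: np.random.Generator) -> list[Attractor]:
    """Draw ``n_attractors`` positions uniformly over the grid."""
    return [
        Attractor(int(rng.integers(config.grid_rows)), int(rng.integers(config.grid_cols)))
        for _ in range(config.n_attractors)
    ]


# ---------------------------------------------------------------------------
# social condition


def social_acquisition_probability(encounters: int, increment: float = 0.01) -> float:
    """Acquisition probability after ``encounters`` tool-user co-occupancies.

    Linear in the encounter count (1 % per encounter by default), capped at 1.
    """
    if encounters < 0:
        raise ValueError("encounters must be non-negative")
    return min(1.0, increment * encounters)


# ---------------------------------------------------------------------------
# asocial condition


def asocial_acquire(agent: AgentState, config: SimConfig, rng: np.random.Generator) -> bool:
    """Independent per-step acquisition trial; returns the updated flag.

    Only living non-tool-users above the age gate are eligible; everyone else
    is left unchanged.
    """
    if (
        agent.alive
        and not agent.tool_user
        and agent.age > config.min_acquisition_age
        and rng.random() < config.asocial_p
    ):
        agent.tool_user = True
    return agent.tool_user


def _directed_step(
    position: tuple[int, int],
    targets: list[tuple[int, int]],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Candidate cell (a Moore neighbour or the current cell) minimising the
    Euclidean distance to the nearest target; ties broken uniformly."""
    candidates = _neighbour_table(config.grid_rows, config.grid_cols)[position] + [position]
    best: list[tuple[int, int]] = []
    best_d = np.inf
    for cell in candidates:
        d = min((cell[0] - t[0]) ** 2 + (cell[1] - t[1]) ** 2 for t in targets)
        if d < best_d - 1e-12:
            best_d = d
            best = [cell]
        elif d == best_d:
            best.append(cell)
    return best[int(rng.random() * len(best))]


def attractor_move(
    agent: AgentState,
    attractors: list[Attractor],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Asocial movement rule.

    A tool user moves toward the nearest attractor with probability
    ``attractor_pull``; otherwise (and always for non-tool users) it moves
    randomly.
    """
    if agent.tool_user and attractors and rng.random() < config.attractor_pull:
        return _directed_step(
            (agent.row, agent.col), [a.position for a in attractors], config, rng
        )
    return move_random(agent, config, rng)


# ---------------------------------------------------------------------------
# inheritance condition


def death_probability(age: int, config: SimConfig) -> float:
    """Per-step death probability: baseline plus a linear age penalty."""
    return min(1.0, max(0.0, config.death_baseline + config.death_age_coeff * age))


def death_check(agent: AgentState, config: SimConfig, rng: np.random.Generator) -> bool:
    """Survival trial; returns True if the agent stays alive."""
    return rng.random() >= death_probability(agent.age, config)


def offspring_phenotype(
    parent_a_phenotype: str, parent_b_phenotype: str, rng: np.random.Generator
) -> str:
    """Matching parents pass their phenotype on; mixed pairs flip a fair coin."""
    if parent_a_phenotype == parent_b_phenotype:
        return parent_a_phenotype
    return (HYBRID_LIKE, COMMON_LIKE)[int(rng.random() * 2)]


def offspring_tool_status(
    parent_a: AgentState,
    parent_b: AgentState,
    phenotype: str,
    require_tool_parent: bool = False,
) -> bool:
    """Trait inheritance rule: hybrid-like phenotype is necessary.

    Returns whether the offspring *carries* the trait; under the inheritance
    condition a carrier expresses (and is counted as) tool use only after
    passing the developmental age. With ``require_tool_parent`` at least one
    carrier parent is also required, restricting the trait to the seed
    lineage instead of every hybrid birth.
    """
    if phenotype != HYBRID_LIKE:
        return False
    if require_tool_parent:
        return (
            parent_a.tool_heir or parent_a.tool_user
            or parent_b.tool_heir or parent_b.tool_user
        )
    return True


def reproduce(
    parent_a: AgentState,
    parent_b: AgentState,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    offspring_id: int,
    living_population: int,
) -> AgentState | None:
    """Reproduction trial for a co-located pair.

    With probability ``reproduction_p``, and only while the living population
    is below ``population_cap``, creates an age-0 offspring at the parents'
    cell. Both parents must be past the developmental age
    (``min_acquisition_age``) — juveniles neither use tools nor breed. The
    recorded mother is one parent chosen at random; phenotype and tool status
    follow :func:`offspring_phenotype` and :func:`offspring_tool_status`.
    """
    if living_population >= config.population_cap:
        return None
    if (
        parent_a.age <= config.min_acquisition_age
        or parent_b.age <= config.min_acquisition_age
    ):
        return None
    if rng.random() >= config.reproduction_p:
        return None
    phenotype = offspring_phenotype(parent_a.phenotype, parent_b.phenotype, rng)
    heir = offspring_tool_status(
        parent_a, parent_b, phenotype, config.inherit_requires_tool_parent
    )
    mother = parent_a if rng.random() < 0.5 else parent_b
    return AgentState(
        id=offspring_id,
        age=0,
        phenotype=phenotype,
        tool_user=False,
        row=parent_a.row,
        col=parent_a.col,
        mother_id=mother.id,
        tool_heir=heir,
    )


def follow_probability(age: int) -> float:
    """Chance a juvenile follows its mother: 1 - 2*age/100, clamped to [0, 1].

    Newborns follow almost always; by age 50 the pull has fully decayed and
    movement is random.
    """
    return min(1.0, max(0.0, 1.0 - 2.0 * age / 100.0))


def mother_follow_move(
    agent: AgentState,
    mother: AgentState | None,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Juvenile movement: step toward the mother with an age-decaying
    probability, falling back to a random move (also when she is dead)."""
    if (
        mother is not None
        and mother.alive
        and rng.random() < follow_probability(agent.age)
    ):
        return _directed_step((agent.row, agent.col), [(mother.row, mother.col)], config, rng)
    return move_random(agent, config, rng)


def inheritance_move(
    agent: AgentState,
    agents: dict[int, AgentState],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Movement dispatch under inheritance: mother-following for agents with
    a known mother, random movement otherwise."""
    if agent.mother_id is not None:
        return mother_follow_move(agent, agents.get(agent.mother_id), config, rng)
    return move_random(agent, config, rng)
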
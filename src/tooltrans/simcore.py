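"""Grid-world simulation core.

A population of agents moves over a bounded rectangular grid. Agents carry a
binary tool-user trait, a phenotype (``hybrid_like`` / ``common_like``) and an
age measured in time steps. Each run starts from a single tool-using seed
agent and terminates when tool users reach ``stop_fraction`` of the population
(measured against the initial population size by default, or against the
living population; see ``SimConfig.stop_denominator``), or at ``max_steps``.
Every step the co-occupancy of grid
cells is written to an association log; that log, together with the final
agent attribute table, is the generative output consumed by the network and
inference stages.

Condition-specific acquisition, reproduction and movement rules live in
:mod:`tooltrans.transmission`; this module owns the world, the schedule and
the bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

HYBRID_LIKE = "hybrid_like"
COMMON_LIKE = "common_like"
PHENOTYPES = (HYBRID_LIKE, COMMON_LIKE)

CONDITIONS = ("social", "inheritance", "asocial")


class ConfigurationError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass(slots=True)
class AgentState:
    """One simulated individual.

    Age counts time steps, not years. ``encounters_with_tool_users`` is only
    incremented under the social condition; ``mother_id`` is only set for
    agents born under the inheritance condition.
    """

    id: int
    age: int
    phenotype: str
    tool_user: bool
    row: int
    col: int
    encounters_with_tool_users: int = 0
    mother_id: Optional[int] = None
    alive: bool = True
    # inheritance condition: trait carried from birth but expressed (and
    # counted) only once the agent passes the developmental age
    tool_heir: bool = False

    @property
    def position(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass
class SimConfig:
    """All transmission-regime parameters and run controls.

    Defaults reproduce the reference study conditions: 100 agents on a 20x20
    grid, a 1 % per-encounter social-learning increment, a 5 % per-step
    asocial acquisition chance, a 25 % attractor pull, an age gate at 25
    steps, and termination once half the population uses tools.
    """

    condition: str = "social"
    grid_rows: int = 20
    grid_cols: int = 20
    n_agents: int = 100
    min_acquisition_age: int = 25
    seed_agent_age: int = 25
    social_increment: float = 0.01
    asocial_p: float = 0.05
    n_attractors: int = 1
    attractor_pull: float = 0.25
    death_baseline: float = 0.0001
    death_age_coeff: float = 1e-5
    reproduction_p: float = 0.05
    population_cap: Optional[int] = None  # defaults to 2 * n_agents
    inherit_requires_tool_parent: bool = False
    stop_fraction: float = 0.5
    stop_denominator: str = "initial"  # "initial" population size or "living"
    max_steps: int = 20000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_cap is None:
            self.population_cap = 2 * self.n_agents
        self.validate()

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("grid dimensions must be >= 1")
        if self.n_agents < 1:
            raise ConfigurationError("n_agents must be >= 1")
        for name in ("social_increment", "asocial_p", "attractor_pull",
                     "death_baseline", "reproduction_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.death_age_coeff < 0:
            raise ConfigurationError("death_age_coeff must be >= 0")
        if not 0.0 < self.stop_fraction <= 1.0:
            raise ConfigurationError("stop_fraction must lie in (0, 1]")
        if self.stop_denominator not in ("initial", "living"):
            raise ConfigurationError("stop_denominator must be 'initial' or 'living'")
        if self.n_attractors < 1:
            raise ConfigurationError("n_attractors must be >= 1")
        if self.max_steps < 1:
            raise ConfigurationError("max_steps must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load a config from YAML or JSON, defaulting unspecified fields."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **overrides) -> "SimConfig":
        return replace(self, **overrides)


@dataclass
class RunMetadata:
    """Outcome of a single run."""

    condition: str
    rng_seed: int
    steps: int
    terminated_by: str  # "stop_fraction" or "max_steps"
    final_tool_fraction: float
    n_alive: int
    n_born: int
    n_died: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


@dataclass
class AssociationLog:
    """Generative output of a run: co-occupancy records + agent attributes.

    ``records`` has columns ``step, agent_a, agent_b`` with one row per
    unordered co-located pair per step; ``agents`` has columns
    ``id, age, phenotype, tool_user, mother_id`` describing the final state
    of every agent that ever existed (``alive`` marks survivors).
    """

    records: pd.DataFrame
    agents: pd.DataFrame

    def write_csv(self, records_path: str | Path, agents_path: str | Path) -> None:
        self.records.to_csv(records_path, index=False)
        self.agents.to_csv(agents_path, index=False)

    @classmethod
    def read_csv(cls, records_path: str | Path, agents_path: str | Path) -> "AssociationLog":
        return cls(pd.read_csv(records_path), pd.read_csv(agents_path))


@lru_cache(maxsize=None)
def _neighbour_table(rows: int, cols: int) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Moore (8-cell) neighbourhood for every cell, clipped at the boundary."""
    table: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r in range(rows):
        for c in range(cols):
            cells = [
                (r + dr, c + dc)
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if not (dr == 0 and dc == 0)
                and 0 <= r + dr < rows
                and 0 <= c + dc < cols
            ]
            table[(r, c)] = cells
    return table


def neighbours(position: tuple[int, int], config: SimConfig) -> list[tuple[int, int]]:
    """Admissible destination cells for an agent at ``position``."""
    return _neighbour_table(config.grid_rows, config.grid_cols)[position]


def move_random(agent: AgentState, config: SimConfig, rng: np.random.Generator) -> tuple[int, int]:
    """Uniform draw over the agent's boundary-clipped Moore neighbourhood."""
    cells = _neighbour_table(config.grid_rows, config.grid_cols)[(agent.row, agent.col)]
    return cells[int(rng.random() * len(cells))]


def init_population(config: SimConfig, rng: np.random.Generator) -> list[AgentState]:
    """Create the starting population.

    One seed agent is a hybrid-like tool user of age ``seed_agent_age``;
    everyone else is a non-tool user with uniform-random phenotype, an age
    drawn uniformly from 0..100, and a uniform-random grid position (several
    agents may share a cell).
    """
    config.validate()
    agents: list[AgentState] = []
    for i in range(config.n_agents):
        row = int(rng.integers(config.grid_rows))
        col = int(rng.integers(config.grid_cols))
        if i == 0:
            agents.append(AgentState(id=0, age=config.seed_agent_age,
                                     phenotype=HYBRID_LIKE, tool_user=True,
                                     row=row, col=col, tool_heir=True))
        else:
            phenotype = PHENOTYPES[int(rng.integers(2))]
            age = int(rng.integers(0, 101))
            agents.append(AgentState(id=i, age=age, phenotype=phenotype,
                                     tool_user=False, row=row, col=col))
    return agents


def record_associations(occupancy: Mapping[tuple[int, int], Sequence[int]]) -> list[tuple[int, int]]:
    """Unordered co-located pairs for one step's occupancy map.

    A cell holding k agents contributes k*(k-1)/2 pairs.
    """
    pairs: list[tuple[int, int]] = []
    for ids in occupancy.values():
        k = len(ids)
        if k < 2:
            continue
        for i in range(k):
            a = ids[i]
            for j in range(i + 1, k):
                pairs.append((a, ids[j]))
    return pairs


class Simulation:
    """Mutable world state for one run. Prefer :func:`run_simulation`."""

    def __init__(self, config: SimConfig):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.rng_seed)
        self.agents: dict[int, AgentState] = {
            a.id: a for a in init_population(config, self.rng)
        }
        self._next_id = config.n_agents
        # occupancy: cell -> list of living agent ids; tool-user count per cell
        self.occupancy: dict[tuple[int, int], list[int]] = {}
        self._cell_tool: dict[tuple[int, int], int] = {}
        for a in self.agents.values():
            self.occupancy.setdefault((a.row, a.col), []).append(a.id)
            if a.tool_user:
                self._cell_tool[(a.row, a.col)] = self._cell_tool.get((a.row, a.col), 0) + 1
        self.n_tool = sum(a.tool_user for a in self.agents.values())
        self.n_alive = len(self.agents)
        self.n_born = 0
        self.n_died = 0
        self.steps = 0
        self._rec_step: list[int] = []
        self._rec_a: list[int] = []
        self._rec_b: list[int] = []
        from . import transmission  # deferred: transmission imports this module

        self._tx = transmission
        self.attractors = (
            transmission.place_attractors(config, self.rng)
            if config.condition == "asocial"
            else []
        )

    # -- bookkeeping -------------------------------------------------------

    def _move_agent(self, agent: AgentState, cell: tuple[int, int]) -> None:
        old = (agent.row, agent.col)
        if cell == old:
            return
        occ = self.occupancy[old]
        occ.remove(agent.id)
        if not occ:
            del self.occupancy[old]
        if agent.tool_user:
            self._cell_tool[old] -= 1
        self.occupancy.setdefault(cell, []).append(agent.id)
        if agent.tool_user:
            self._cell_tool[cell] = self._cell_tool.get(cell, 0) + 1
        agent.row, agent.col = cell

    def _register_acquisition(self, agent: AgentState) -> None:
        """Sync counters after ``agent.tool_user`` flipped to True."""
        cell = (agent.row, agent.col)
        self._cell_tool[cell] = self._cell_tool.get(cell, 0) + 1
        self.n_tool += 1

    def _set_tool_user(self, agent: AgentState) -> None:
        if agent.tool_user:
            return
        agent.tool_user = True
        self._register_acquisition(agent)

    def _remove_agent(self, agent: AgentState) -> None:
        cell = (agent.row, agent.col)
        occ = self.occupancy[cell]
        occ.remove(agent.id)
        if not occ:
            del self.occupancy[cell]
        if agent.tool_user:
            self._cell_tool[cell] -= 1
            self.n_tool -= 1
        agent.alive = False
        self.n_alive -= 1
        self.n_died += 1

    def _add_agent(self, agent: AgentState) -> None:
        self.agents[agent.id] = agent
        self.occupancy.setdefault((agent.row, agent.col), []).append(agent.id)
        if agent.tool_user:
            cell = (agent.row, agent.col)
            self._cell_tool[cell] = self._cell_tool.get(cell, 0) + 1
            self.n_tool += 1
        self.n_alive += 1
        self.n_born += 1

    # -- schedule ----------------------------------------------------------

    def step(self) -> None:
        """Advance the world one time step.

        Living agents act in randomized order; each ages, (inheritance) risks
        death, moves under its condition's movement rule, then applies the
        condition's acquisition/reproduction rule. Acquisitions take effect
        immediately. Associations are recorded from the end-of-step occupancy.
        """
        cfg = self.config
        rng = self.rng
        tx = self._tx
        condition = cfg.condition
        self.steps += 1

        order = [a.id for a in self.agents.values() if a.alive]
        rng.shuffle(order)
        for aid in order:
            agent = self.agents[aid]
            if not agent.alive:
                continue
            agent.age += 1
            if condition == "inheritance":
                if not tx.death_check(agent, cfg, rng):
                    self._remove_agent(agent)
                    continue
                if (
                    agent.tool_heir
                    and not agent.tool_user
                    and agent.age > cfg.min_acquisition_age
                ):
                    # inherited trait becomes expressed at maturity
                    self._set_tool_user(agent)
                cell = tx.inheritance_move(agent, self.agents, cfg, rng)
            elif condition == "asocial":
                cell = tx.attractor_move(agent, self.attractors, cfg, rng)
            else:
                cell = move_random(agent, cfg, rng)
            self._move_agent(agent, cell)

            if condition == "social":
                self._social_interaction(agent)
            elif condition == "asocial":
                was_tool = agent.tool_user
                tx.asocial_acquire(agent, cfg, rng)
                if agent.tool_user and not was_tool:
                    self._register_acquisition(agent)
            else:
                self._maybe_reproduce(agent)

        step_no = self.steps
        for a, b in record_associations(self.occupancy):
            self._rec_step.append(step_no)
            self._rec_a.append(a)
            self._rec_b.append(b)

    def _social_interaction(self, agent: AgentState) -> None:
        """Encounter accounting and the acquisition trial on cell entry."""
        if agent.tool_user:
            return
        cell = (agent.row, agent.col)
        n_tool_here = self._cell_tool.get(cell, 0)
        if n_tool_here == 0:
            return
        agent.encounters_with_tool_users += n_tool_here
        if agent.age <= self.config.min_acquisition_age:
            return
        p = self._tx.social_acquisition_probability(
            agent.encounters_with_tool_users, self.config.social_increment
        )
        if self.rng.random() < p:
            self._set_tool_user(agent)

    def _maybe_reproduce(self, agent: AgentState) -> None:
        """Reproduction trial on cell entry with one random co-occupant."""
        cell = (agent.row, agent.col)
        occ = self.occupancy[cell]
        if len(occ) < 2:
            return
        others = [i for i in occ if i != agent.id]
        partner = self.agents[others[int(self.rng.random() * len(others))]]
        child = self._tx.reproduce(
            agent, partner, self.config, self.rng,
            offspring_id=self._next_id, living_population=self.n_alive,
        )
        if child is not None:
            self._next_id += 1
            self._add_agent(child)

    # -- run loop ----------------------------------------------------------

    def tool_fraction(self) -> float:
        """Tool users over the stopping-rule denominator (initial population
        size by default; the living population with
        ``stop_denominator="living"``)."""
        if self.config.stop_denominator == "living":
            return self.n_tool / self.n_alive if self.n_alive else 0.0
        return self.n_tool / self.config.n_agents

    def run(self) -> tuple[AssociationLog, RunMetadata]:
        cfg = self.config
        terminated_by = "max_steps"
        while self.steps < cfg.max_steps:
            self.step()
            if self.tool_fraction() >= cfg.stop_fraction:
                terminated_by = "stop_fraction"
                break
        log = self._build_log()
        meta = RunMetadata(
            condition=cfg.condition,
            rng_seed=cfg.rng_seed,
            steps=self.steps,
            terminated_by=terminated_by,
            final_tool_fraction=self.tool_fraction(),
            n_alive=self.n_alive,
            n_born=self.n_born,
            n_died=self.n_died,
        )
        return log, meta

    def _build_log(self) -> AssociationLog:
        records = pd.DataFrame(
            {
                "step": np.asarray(self._rec_step, dtype=np.int64),
                "agent_a": np.asarray(self._rec_a, dtype=np.int64),
                "agent_b": np.asarray(self._rec_b, dtype=np.int64),
            }
        )
        rows = [
            {
                "id": a.id,
                "age": a.age,
                "phenotype": a.phenotype,
                "tool_user": a.tool_user,
                "mother_id": a.mother_id if a.mother_id is not None else pd.NA,
                "alive": a.alive,
                "encounters_with_tool_users": a.encounters_with_tool_users,
                "tool_heir": a.tool_heir,
            }
            for a in self.agents.values()
        ]
        agents = pd.DataFrame(rows).astype({"mother_id": "Int64"})
        return AssociationLog(records=records, agents=agents)


def run_simulation(config: SimConfig) -> tuple[AssociationLog, RunMetadata]:
    """Run one simulation to termination.

    Identical configs (including ``rng_seed``) produce bit-identical logs.
    Hitting ``max_steps`` before the stopping rule is flagged in the metadata
    (``terminated_by="max_steps"``), not raised.
    """
    return Simulation(config).run()
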
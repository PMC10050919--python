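"""Batch experiment driver.

Runs replicated simulations per condition (the study design uses 30
iterations per condition and an attractor sweep over 1, 10 and 200 for the
asocial regime), builds the association network of every iteration, and
aggregates the cross-iteration statistics used to compare transmission
mechanisms: exceedance fractions of class means, pooled phenotype tool-use
rates, and the mean centrality gap between tool users and non-tool users.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .networks import build_network, node_metrics
from .simcore import AssociationLog, RunMetadata, SimConfig, run_simulation

logger = logging.getLogger(__name__)

_METRIC_COLS = {
    "strength": "strength_to_tool_users",
    "centrality": "ev_centrality",
}


@dataclass
class IterationSummary:
    """Per-iteration class comparison among living adult agents."""

    condition: str
    iteration: int
    seed: int
    steps: int
    terminated_by: str
    final_tool_fraction: float
    n_adult_tool: int
    n_adult_nontool: int
    mean_strength_tool: float
    mean_strength_nontool: float
    mean_centrality_tool: float
    mean_centrality_nontool: float


@dataclass
class BatchResult:
    """All artifacts of one condition batch."""

    condition: str
    summaries: list[IterationSummary]
    agent_tables: list[pd.DataFrame]
    metadata: list[RunMetadata]
    logs: list[AssociationLog]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.summaries])


def _adult_mask(agents: pd.DataFrame, age_threshold: int) -> pd.Series:
    alive = agents["alive"] if "alive" in agents.columns else True
    return (agents["age"] > age_threshold) & alive


def summarize_iteration(
    log: AssociationLog,
    meta: RunMetadata,
    iteration: int,
    age_threshold: int,
) -> tuple[IterationSummary, pd.DataFrame]:
    """Network metrics and adult class means for one finished run."""
    G = build_network(log.records, log.agents, directed=False)
    metrics = node_metrics(G)
    merged = log.agents.merge(metrics, on="id")
    adult = _adult_mask(merged, age_threshold)
    tool = merged["tool_user"].astype(bool)

    def class_mean(col: str, is_tool: bool) -> float:
        sel = merged.loc[adult & (tool == is_tool), col]
        return float(sel.mean()) if len(sel) else math.nan

    summary = IterationSummary(
        condition=meta.condition,
        iteration=iteration,
        seed=meta.rng_seed,
        steps=meta.steps,
        terminated_by=meta.terminated_by,
        final_tool_fraction=meta.final_tool_fraction,
        n_adult_tool=int((adult & tool).sum()),
        n_adult_nontool=int((adult & ~tool).sum()),
        mean_strength_tool=class_mean("strength_to_tool_users", True),
        mean_strength_nontool=class_mean("strength_to_tool_users", False),
        mean_centrality_tool=class_mean("ev_centrality", True),
        mean_centrality_nontool=class_mean("ev_centrality", False),
    )
    return summary, merged


def run_condition_batch(
    condition: str,
    n_iterations: int = 30,
    base_seed: int = 0,
    overrides: Optional[dict] = None,
    outdir: Optional[str | Path] = None,
    progress: bool = False,
) -> BatchResult:
    """Run ``n_iterations`` independent simulations with seeds
    ``base_seed + i`` and summarize each.

    ``overrides`` are applied to the default :class:`SimConfig` (e.g.
    ``{"n_attractors": 10}`` for the asocial sweep). With ``outdir`` given,
    each iteration's association log, agent table and metrics are written as
    CSV alongside a batch summary table. Iterations that hit ``max_steps``
    are flagged in their metadata, never fatal.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    overrides = dict(overrides or {})
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    summaries: list[IterationSummary] = []
    tables: list[pd.DataFrame] = []
    metas: list[RunMetadata] = []
    logs: list[AssociationLog] = []
    for i in range(n_iterations):
        cfg = SimConfig(condition=condition, rng_seed=base_seed + i, **overrides)
        log, meta = run_simulation(cfg)
        summary, merged = summarize_iteration(log, meta, i, cfg.min_acquisition_age)
        summaries.append(summary)
        tables.append(merged)
        metas.append(meta)
        logs.append(log)
        if progress:
            logger.info(
                "%s iteration %d/%d: %d steps, tool fraction %.2f (%s)",
                condition, i + 1, n_iterations, meta.steps,
                meta.final_tool_fraction, meta.terminated_by,
            )
        if outdir is not None:
            stem = outdir / f"{condition}_{i:03d}"
            log.write_csv(f"{stem}_associations.csv", f"{stem}_agents.csv")
            merged[["id", "ev_centrality", "strength_to_tool_users"]].to_csv(
                f"{stem}_metrics.csv", index=False
            )
            Path(f"{stem}_meta.json").write_text(meta.to_json())
    result = BatchResult(condition, summaries, tables, metas, logs)
    if outdir is not None:
        result.summary_frame().to_csv(outdir / f"{condition}_summary.csv", index=False)
    return result


@dataclass
class ExceedanceResult:
    """Fraction of iterations where adult tool users' class mean strictly
    exceeds adult non-tool users'; iterations lacking a class are excluded."""

    fraction: float
    n_compared: int
    n_excluded: int

    def __float__(self) -> float:
        return self.fraction


def exceedance_fraction(
    summaries: Sequence[IterationSummary], metric: str = "strength"
) -> ExceedanceResult:
    if metric not in _METRIC_COLS:
        raise ValueError("metric must be 'strength' or 'centrality'")
    wins = 0
    compared = 0
    excluded = 0
    for s in summaries:
        if s.n_adult_tool == 0 or s.n_adult_nontool == 0:
            excluded += 1
            continue
        t = getattr(s, f"mean_{metric}_tool")
        n = getattr(s, f"mean_{metric}_nontool")
        compared += 1
        if t > n:
            wins += 1
    if compared == 0:
        return ExceedanceResult(math.nan, 0, excluded)
    return ExceedanceResult(wins / compared, compared, excluded)


def phenotype_tool_rate(
    agent_tables: Iterable[pd.DataFrame],
    phenotype: str,
    adults_only: bool = True,
    age_threshold: int = 25,
    pooled: bool = True,
) -> float:
    """Proportion of (living, by default adult) agents of a phenotype that
    are tool users, pooled across iterations (or averaged per iteration with
    ``pooled=False``). NaN when no agent matches."""
    rates = []
    n_tool = 0
    n_total = 0
    for table in agent_tables:
        sel = table["phenotype"] == phenotype
        if "alive" in table.columns:
            sel &= table["alive"]
        if adults_only:
            sel &= table["age"] > age_threshold
        sub = table.loc[sel, "tool_user"].astype(bool)
        n_tool += int(sub.sum())
        n_total += len(sub)
        if len(sub):
            rates.append(float(sub.mean()))
    if pooled:
        return n_tool / n_total if n_total else math.nan
    return float(np.mean(rates)) if rates else math.nan


def centrality_gap(summaries: Sequence[IterationSummary]) -> float:
    """Mean over iterations of (adult tool users' mean EV-centrality minus
    adult non-tool users'); iterations lacking a class are excluded."""
    gaps = [
        s.mean_centrality_tool - s.mean_centrality_nontool
        for s in summaries
        if s.n_adult_tool > 0 and s.n_adult_nontool > 0
    ]
    return float(np.mean(gaps)) if gaps else math.nan


def permuted_exceedance(
    batch: BatchResult,
    metric: str = "strength",
    rng: Optional[np.random.Generator] = None,
    age_threshold: int = 25,
) -> ExceedanceResult:
    """Exceedance fraction after permuting tool-user labels among living
    adults within each iteration (a label-permutation null).

    Strength-to-tool-users is recomputed against the permuted labels, so the
    null destroys both the class assignment and the metric's dependence on it.
    """
    if metric not in _METRIC_COLS:
        raise ValueError("metric must be 'strength' or 'centrality'")
    rng = rng or np.random.default_rng()
    wins = 0
    compared = 0
    excluded = 0
    for log, table in zip(batch.logs, batch.agent_tables):
        attrs = table.drop(columns=list(_METRIC_COLS.values())).copy()
        adult = _adult_mask(attrs, age_threshold)
        labels = attrs.loc[adult, "tool_user"].to_numpy().copy()
        rng.shuffle(labels)
        attrs.loc[adult, "tool_user"] = labels
        n_tool = int(attrs.loc[adult, "tool_user"].sum())
        if n_tool == 0 or n_tool == int(adult.sum()):
            excluded += 1
            continue
        G = build_network(log.records, attrs, directed=False)
        metrics = node_metrics(G)
        merged = attrs.merge(metrics, on="id")
        adult = _adult_mask(merged, age_threshold)
        tool = merged["tool_user"].astype(bool)
        col = _METRIC_COLS[metric]
        t_mean = merged.loc[adult & tool, col].mean()
        n_mean = merged.loc[adult & ~tool, col].mean()
        compared += 1
        if t_mean > n_mean:
            wins += 1
    if compared == 0:
        return ExceedanceResult(math.nan, 0, excluded)
    return ExceedanceResult(wins / compared, compared, excluded)
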
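"""Synthetic observational focal-follow data.

Emulates the structure of a shoreline focal-follow study of a hybrid
macaque group: a fixed roster of individuals (69 by default, 42 of them
mature with known tool-user status, roughly half of the mature animals
using tools), and a stream of directed 1 m proximity records (focal ->
partner), one per focal scan (5990 by default).

Partner choice can be tilted so that tool users preferentially associate
with each other — the signature that social transmission leaves in real
association data: a tool-using focal's odds of picking a tool-using partner
are multiplied by ``exp(assortativity)``. The tilt is deliberately simple
plumbing — it creates detectable network structure for pipeline testing, it
does not model macaque behaviour. All tables use the same CSV
schemas as the simulator/network stages, so generated data flow through
:mod:`tooltrans.networks` and :mod:`tooltrans.inference` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simcore import COMMON_LIKE, HYBRID_LIKE


@dataclass
class ObsConfig:
    """Roster sizes, attribute fractions and scan count for the generator."""

    n_individuals: int = 69
    n_mature: int = 42
    tool_user_fraction: float = 0.5
    hybrid_fraction: float = 0.5
    assortativity: float = 0.0
    n_scans: int = 5990
    rng_seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.n_mature <= self.n_individuals:
            raise ValueError("need 1 <= n_mature <= n_individuals")
        for name in ("tool_user_fraction", "hybrid_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.n_scans < 0:
            raise ValueError("n_scans must be >= 0")
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals to record associations")


def generate_observational(config: ObsConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (records, attributes) for one synthetic observation season.

    ``records`` has columns ``focal, partner`` with exactly ``n_scans`` rows;
    ``attributes`` has ``id, mature, phenotype, tool_user``. Exact attribute
    counts are used (e.g. round(42 * 0.5) = 21 tool users), assigned to a
    random subset of ids. Only mature individuals can be tool users.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_individuals
    ids = np.arange(n)

    mature = np.zeros(n, dtype=bool)
    mature[rng.choice(n, size=config.n_mature, replace=False)] = True
    tool_user = np.zeros(n, dtype=bool)
    mature_ids = ids[mature]
    n_tool = int(round(config.tool_user_fraction * config.n_mature))
    tool_user[rng.choice(mature_ids, size=n_tool, replace=False)] = True
    phenotype = np.full(n, COMMON_LIKE, dtype=object)
    n_hybrid = int(round(config.hybrid_fraction * n))
    phenotype[rng.choice(n, size=n_hybrid, replace=False)] = HYBRID_LIKE

    attributes = pd.DataFrame(
        {"id": ids, "mature": mature, "phenotype": phenotype, "tool_user": tool_user}
    )

    tilt = np.exp(config.assortativity)
    focals = rng.integers(0, n, size=config.n_scans)
    partners = np.empty(config.n_scans, dtype=np.int64)
    base = np.ones(n)
    tool_f = tool_user.astype(float)
    for k, f in enumerate(focals):
        w = base.copy()
        if tool_user[f]:
            # tool-using focal: odds of a tool-using partner get the tilt
            w += (tilt - 1.0) * tool_f
        w[f] = 0.0
        w /= w.sum()
        partners[k] = rng.choice(n, p=w)
    records = pd.DataFrame({"focal": focals, "partner": partners})
    return records, attributes


def write_observational(
    records: pd.DataFrame,
    attributes: pd.DataFrame,
    records_path: str | Path,
    attributes_path: str | Path,
) -> None:
    records.to_csv(records_path, index=False)
    attributes.to_csv(attributes_path, index=False)
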
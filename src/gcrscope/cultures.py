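"""Luria-Delbrueck culture simulation for fluctuation assays.

Each culture grows from a single cell by binary expansion to ~N cells.
During the doubling that takes the population from 2^k to 2^(k+1) cells
there are 2^k divisions, each of which mutates with probability equal to
the per-division event rate; a mutant arising at that doubling expands
clonally to N / 2^(k+1) cells by the end of growth.  This reproduces the
heavy-tailed ("jackpot") mutant-count distribution that the method of the
median is designed for.  Mutant counts can be thinned by a plating
fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


@dataclass
class CultureSimConfig:
    true_rate: float = 1e-7  # events per cell division
    final_cells: float = 1e8  # N
    n_cultures: int = 8
    plating_fraction: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.final_cells < 1:
            raise ConfigurationError("final_cells must be >= 1")
        if self.n_cultures < 2:
            raise ConfigurationError("n_cultures must be >= 2")
        if not (0 < self.plating_fraction <= 1):
            raise ConfigurationError("plating_fraction must be in (0, 1]")
        if self.true_rate < 0:
            raise ConfigurationError("true_rate must be >= 0")


def simulate_cultures(config: CultureSimConfig, rng=None) -> np.ndarray:
    """Observed mutant counts for ``n_cultures`` parallel cultures."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    N = float(config.final_cells)
    mu = config.true_rate
    if mu * N > 1e4:
        warnings.warn(
            "expected mutation count exceeds 1e4; the median estimator "
            "is outside its useful range",
            stacklevel=2,
        )
    if mu == 0:
        return np.zeros(config.n_cultures, dtype=int)

    # Growth from one cell to N cells comprises ~N divisions.  A mutation at
    # division j (in temporal order) founds a clone that expands to ~N/j
    # cells by the end of growth: the j-th division's daughter lineage halves
    # its share of the final population at each subsequent doubling.
    n_mut = rng.poisson(mu * N, size=config.n_cultures)
    counts = np.zeros(config.n_cultures, dtype=np.int64)
    for i, m in enumerate(n_mut):
        if m == 0:
            continue
        j = rng.integers(1, int(N) + 1, size=m).astype(float)
        counts[i] = int((N / j).astype(np.int64).sum())
    if config.plating_fraction < 1:
        counts = rng.binomial(counts, config.plating_fraction)
    return counts
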
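"""Synthetic mixed-type cohorts with planted block structure.

The generator emulates a cross-sectional cohort table in which variables
fall into correlated blocks (think "lipid panel", "cognitive battery", ...)
that are themselves weakly chained together, so the downstream network
pipeline has a known ground truth to recover.

Generative model
----------------
A chain of latent block factors f_1 … f_B:

    f_1 = ε_1,    f_b = γ·f_{b−1} + √(1−γ²)·ε_b,    ε_b ~ N(0, 1) iid

so every factor is marginally standard normal and adjacent factors have
correlation γ. Variable i in block b is

    x_i = √ρ_b·f_b + √(1−ρ_b)·e_i,    e_i ~ N(0, 1) iid

giving within-block correlation ρ_b and between-adjacent-block
correlation ρ·γ. A fixed fraction of each block's variables is then
discretized into equiprobable quantile bins to make them categorical,
and cells are blanked independently (missing completely at random).

The RNG stream is consumed in a fixed, documented order — latent factors,
then variable noise, then the missing mask — so the output is bit-identical
for a given spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CATEGORICAL, NUMERICAL, CohortTable, VariableSpec


class SyntheticSpecError(ValueError):
    """Invalid synthetic-cohort specification."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block cohort generator.

    Defaults describe the standard recovery benchmark: 8 blocks of 10
    variables, 1,000 subjects, within-block correlation 0.6, backbone
    coupling 0.3 between consecutive blocks, 30% of each block's variables
    categorical with 3 levels, and 5% of cells missing at random.
    """

    n_subjects: int = 1000
    block_sizes: tuple[int, ...] = (10,) * 8
    within_block_corr: tuple[float, ...] | float = 0.6
    backbone_coupling: float = 0.3
    categorical_fraction: float = 0.3
    n_levels: int = 3
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SyntheticSpecError("n_subjects must be positive")
        if not self.block_sizes or any(s < 1 for s in self.block_sizes):
            raise SyntheticSpecError("every block must have at least 1 variable")
        for rho in self.rho_per_block():
            if not 0.0 <= rho < 1.0:
                raise SyntheticSpecError(f"within_block_corr {rho} outside [0, 1)")
        if not 0.0 <= self.backbone_coupling < 1.0:
            raise SyntheticSpecError("backbone_coupling outside [0, 1)")
        if not 0.0 <= self.categorical_fraction <= 1.0:
            raise SyntheticSpecError("categorical_fraction outside [0, 1]")
        if self.n_levels < 2:
            raise SyntheticSpecError("n_levels must be >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SyntheticSpecError("missing_rate outside [0, 1)")

    def rho_per_block(self) -> tuple[float, ...]:
        if isinstance(self.within_block_corr, (int, float)):
            return (float(self.within_block_corr),) * len(self.block_sizes)
        rhos = tuple(float(r) for r in self.within_block_corr)
        if len(rhos) != len(self.block_sizes):
            raise SyntheticSpecError("need one within_block_corr per block")
        return rhos

    @property
    def n_variables(self) -> int:
        return int(sum(self.block_sizes))


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    block_label: dict[str, int]
    kind: dict[str, str]
    chain_order: list[int] = field(default_factory=list)

    def labels_for(self, names: Sequence[str]) -> list[int]:
        return [self.block_label[n] for n in names]


def _quantile_bin(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Discretize into ``n_levels`` equiprobable bins by empirical quantile.

    Ranks are ordinal (ties broken by value order via stable argsort), so
    level frequencies stay balanced at any n.
    """
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    levels = (ranks * n_levels) // n
    return np.array([f"L{k + 1}" for k in levels], dtype=object)


def generate_cohort(spec: SyntheticSpec) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort table (and its ground truth) from the planted model."""
    rng = np.random.default_rng(spec.seed)
    n, n_blocks = spec.n_subjects, len(spec.block_sizes)
    rhos = spec.rho_per_block()

    # 1. latent chain
    eps = rng.standard_normal((n, n_blocks))
    factors = np.empty((n, n_blocks))
    factors[:, 0] = eps[:, 0]
    gamma = spec.backbone_coupling
    for b in range(1, n_blocks):
        factors[:, b] = gamma * factors[:, b - 1] + np.sqrt(1.0 - gamma**2) * eps[:, b]

    # 2. per-variable noise
    noise = rng.standard_normal((n, spec.n_variables))

    names: list[str] = []
    block_label: dict[str, int] = {}
    kind: dict[str, str] = {}
    columns: dict[str, np.ndarray] = {}
    idx = 0
    for b, size in enumerate(spec.block_sizes):
        n_cat = int(round(spec.categorical_fraction * size))
        for j in range(size):
            name = f"V{idx + 1:04d}"
            raw = np.sqrt(rhos[b]) * factors[:, b] + np.sqrt(1.0 - rhos[b]) * noise[:, idx]
            # the first n_cat variables of each block are discretized
            if j < n_cat:
                columns[name] = _quantile_bin(raw, spec.n_levels)
                kind[name] = CATEGORICAL
            else:
                columns[name] = raw
                kind[name] = NUMERICAL
            names.append(name)
            block_label[name] = b + 1
            idx += 1

    # 3. MCAR missing mask
    if spec.missing_rate > 0:
        mask = rng.random((n, spec.n_variables)) < spec.missing_rate
    else:
        mask = np.zeros((n, spec.n_variables), dtype=bool)

    data = {}
    for i, name in enumerate(names):
        col = columns[name]
        if kind[name] == CATEGORICAL:
            col = col.copy()
            col[mask[:, i]] = np.nan
            data[name] = pd.Series(col, dtype=object)
        else:
            col = col.copy()
            col[mask[:, i]] = np.nan
            data[name] = pd.Series(col, dtype=float)
    frame = pd.DataFrame(data, index=pd.RangeIndex(n, name="subject"))
    variables = [VariableSpec(nm, kind[nm]) for nm in names]
    table = CohortTable(data=frame, variables=variables)
    truth = GroundTruth(block_label=block_label, kind=kind,
                        chain_order=list(range(1, n_blocks + 1)))
    return table, truth
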
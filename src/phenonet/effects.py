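"""Pairwise effect sizes for mixed-type variable pairs.

Every unordered pair of variables gets an effect size on a common [0, 1]
scale (generically written R²) and a significance test, chosen by the
pair's type composition:

====================  ==========================================  ============
pair composition      significance test                           effect size
====================  ==========================================  ============
numerical-numerical   Student's t on Spearman's r                 Spearman r²
categorical-both      Pearson χ² on the contingency table         bias-corrected Cramér φ̃² (Bergsma)
numerical-categorical Kruskal–Wallis ANOVA (+ Dunn post hoc)      Z²max / n
====================  ==========================================  ============

Subjects with a missing value in either member of a pair are dropped for
that pair only (pairwise-complete deletion). Pairs with too few complete
subjects, or with a variable constant on the remaining subjects, are
flagged rather than tested.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CATEGORICAL, NUMERICAL, CohortTable

#: Default minimum pairwise-complete sample size: the power calculation for
#: detecting a small correlation-scale effect (0.1) at 80% power.
DEFAULT_MIN_N = 790

STATUS_OK = "ok"
STATUS_INSUFFICIENT_N = "insufficient_n"
STATUS_DEGENERATE = "degenerate"

PAIR_NUM_NUM = "num-num"
PAIR_CAT_CAT = "cat-cat"
PAIR_NUM_CAT = "num-cat"


@dataclass(frozen=True)
class PairResult:
    """Outcome of one pairwise association test.

    ``effect_size``, ``statistic`` and ``p_value`` are None unless
    ``status == "ok"``. ``var_a < var_b`` lexicographically.
    """

    var_a: str
    var_b: str
    pair_kind: str
    n_complete: int
    statistic: float | None = None
    effect_size: float | None = None
    p_value: float | None = None
    status: str = STATUS_OK


def complete_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Keep only the rows where both columns are non-missing, order preserved."""
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("columns must have the same length")
    mask = ~(_missing_mask(x) | _missing_mask(y))
    return x[mask], y[mask]


def _missing_mask(v: np.ndarray) -> np.ndarray:
    if np.issubdtype(v.dtype, np.number):
        return np.isnan(np.asarray(v, dtype=float))
    return pd.isna(v)


def spearman_effect(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Spearman r² with the Student-t p-value.

    Ranks use average-rank tie handling; r is the Pearson correlation of the
    ranks; the two-sided p-value comes from t = r·√((n−2)/(1−r²)) on n−2
    degrees of freedom, with p = 0 at |r| = 1.

    Returns ``(r², p, n)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("spearman_effect needs n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = math.sqrt(float(sx @ sx) * float(sy @ sy))
    if denom == 0.0:
        raise ValueError("constant input: Spearman correlation undefined")
    r = float(sx @ sy) / denom
    r = min(1.0, max(-1.0, r))
    r2 = r * r
    if r2 >= 1.0:
        return 1.0, 0.0, n
    t = r * math.sqrt((n - 2) / (1.0 - r2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r2, float(p), n


def cramers_effect(x: Sequence, y: Sequence) -> tuple[float, float, int]:
    """Squared bias-corrected Cramér's V (Bergsma) with the χ² p-value.

    With a contingency table of shape r × c over the observed levels and
    Pearson χ² (no continuity correction), φ² = χ²/n is shrunk and the
    table dimensions adjusted:

        φ̃² = max(0, φ² − (r−1)(c−1)/(n−1))
        r̃  = r − (r−1)²/(n−1),   c̃ = c − (c−1)²/(n−1)

    and the reported effect is φ̃² / min(r̃−1, c̃−1), clipped to [0, 1].
    The p-value is from the χ² distribution with (r−1)(c−1) df.

    Returns ``(effect, p, n)``.
    """
    table = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()
    return cramers_effect_from_table(table)


def cramers_effect_from_table(table: np.ndarray) -> tuple[float, float, int]:
    """As :func:`cramers_effect`, but starting from a contingency table."""
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    if r < 2 or c < 2:
        raise ValueError("each variable needs at least 2 observed levels")
    n = int(table.sum())
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    phi2 = chi2 / n
    df_rc = (r - 1) * (c - 1)
    phi2_tilde = max(0.0, phi2 - df_rc / (n - 1))
    r_tilde = r - (r - 1) ** 2 / (n - 1)
    c_tilde = c - (c - 1) ** 2 / (n - 1)
    effect = phi2_tilde / min(r_tilde - 1.0, c_tilde - 1.0)
    return min(1.0, max(0.0, effect)), float(p), n


def kw_dunn_effect(x: Sequence[float], g: Sequence) -> tuple[float, float, int, float]:
    """Kruskal–Wallis significance with the Dunn-based effect size Z²max/n.

    The Kruskal–Wallis H (tie-corrected) supplies the p-value on k−1 df.
    Dunn's post hoc z-score for groups i, j is

        z_ij = (R̄_i − R̄_j) / √[(N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j)]

    with R̄ the mean pooled rank and t the tie-group sizes. Z_max is the
    largest |z_ij| over group pairs and the effect size is Z²max/N.

    Returns ``(effect, p, n, H)``.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(g, dtype=object)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if np.all(x == x[0]):
        raise ValueError("constant response: Kruskal-Wallis undefined")
    groups = [x[g == lev] for lev in levels]
    h, p = stats.kruskal(*groups)

    ranks = stats.rankdata(x)
    n_total = len(x)
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    pooled_var = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks = [float(ranks[g == lev].mean()) for lev in levels]
    sizes = [int((g == lev).sum()) for lev in levels]
    z_max = 0.0
    for i, j in itertools.combinations(range(len(levels)), 2):
        se = math.sqrt(pooled_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0.0:
            continue
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        z_max = max(z_max, z)
    effect = min(1.0, z_max * z_max / n_total)
    return effect, float(p), n_total, float(h)


def bonferroni_threshold(alpha: float, n_vars: int) -> float:
    """Effective per-test α after Bonferroni over ALL unordered variable pairs.

    The divisor is n_vars·(n_vars−1)/2 — every pair, not only the valid
    tests (1,248,990 for 1,581 variables, giving ≈4.0×10⁻⁸ at α = 0.05).
    """
    if n_vars < 2:
        raise ValueError("need at least 2 variables")
    return alpha / (n_vars * (n_vars - 1) // 2)


def min_sample_size_correlation(effect: float, power: float = 0.8, alpha: float = 0.05) -> int:
    """Minimum n to detect a correlation-scale effect, Fisher-z approximation.

    n = ceil(((z_{1−α/2} + z_power) / atanh(ρ))² + 3).
    """
    if not 0.0 < effect < 1.0:
        raise ValueError("effect must be in (0, 1)")
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    z_power = stats.norm.ppf(power)
    return math.ceil(((z_alpha + z_power) / math.atanh(effect)) ** 2 + 3)


def _is_constant(v: np.ndarray) -> bool:
    if len(v) == 0:
        return True
    if np.issubdtype(v.dtype, np.number):
        return bool(np.all(v == v[0]))
    return len(pd.unique(v)) < 2


def _test_pair(xa: np.ndarray, xb: np.ndarray, kind_a: str, kind_b: str
               ) -> tuple[str, float, float, float]:
    """Dispatch one complete pair to its statistic. Returns (pair_kind, stat, effect, p)."""
    if kind_a == NUMERICAL and kind_b == NUMERICAL:
        r2, p, n = spearman_effect(xa.astype(float), xb.astype(float))
        t = math.inf if r2 >= 1.0 else r2**0.5 * math.sqrt((n - 2) / (1 - r2))
        return PAIR_NUM_NUM, t, r2, p
    if kind_a == CATEGORICAL and kind_b == CATEGORICAL:
        table = pd.crosstab(pd.Series(xa), pd.Series(xb)).to_numpy()
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        effect, p, _ = cramers_effect_from_table(table)
        return PAIR_CAT_CAT, float(chi2), effect, p
    # one numerical, one categorical
    x, g = (xa, xb) if kind_a == NUMERICAL else (xb, xa)
    effect, p, _, h = kw_dunn_effect(x.astype(float), g)
    return PAIR_NUM_CAT, h, effect, p


def compute_all_pairs(table: CohortTable, min_n: int = DEFAULT_MIN_N) -> list[PairResult]:
    """One :class:`PairResult` per unordered variable pair, canonically ordered.

    Pairwise-complete deletion is applied per pair. A pair is flagged
    ``insufficient_n`` when fewer than ``min_n`` complete subjects remain,
    and ``degenerate`` when either variable is constant on those subjects;
    only ``ok`` pairs carry an effect size and p-value.
    """
    kinds = table.kinds
    names = sorted(kinds)
    columns = {name: table.data[name].to_numpy() for name in names}
    results: list[PairResult] = []
    for var_a, var_b in itertools.combinations(names, 2):
        xa, xb = complete_pair(columns[var_a], columns[var_b])
        n = len(xa)
        kind_pair = _pair_kind(kinds[var_a], kinds[var_b])
        if n < min_n:
            results.append(PairResult(var_a, var_b, kind_pair, n, status=STATUS_INSUFFICIENT_N))
            continue
        if _is_constant(xa) or _is_constant(xb):
            results.append(PairResult(var_a, var_b, kind_pair, n, status=STATUS_DEGENERATE))
            continue
        _, stat, effect, p = _test_pair(xa, xb, kinds[var_a], kinds[var_b])
        results.append(
            PairResult(var_a, var_b, kind_pair, n,
                       statistic=stat, effect_size=effect, p_value=p)
        )
    return results


def _pair_kind(kind_a: str, kind_b: str) -> str:
    if kind_a == kind_b:
        return PAIR_NUM_NUM if kind_a == NUMERICAL else PAIR_CAT_CAT
    return PAIR_NUM_CAT


def significant_pairs(pairs: Sequence[PairResult], alpha_eff: float) -> Iterator[PairResult]:
    """Pairs with status ok and p ≤ α_eff (the threshold itself passes)."""
    for pr in pairs:
        if pr.status == STATUS_OK and pr.p_value is not None and pr.p_value <= alpha_eff:
            yield pr


def pairs_to_frame(pairs: Sequence[PairResult]) -> pd.DataFrame:
    """Tabulate pair results (column layout matches the on-disk TSV)."""
    return pd.DataFrame(
        {
            "var_a": [p.var_a for p in pairs],
            "var_b": [p.var_b for p in pairs],
            "pair_kind": [p.pair_kind for p in pairs],
            "n": [p.n_complete for p in pairs],
            "statistic": [p.statistic for p in pairs],
            "effect_size": [p.effect_size for p in pairs],
            "p_value": [p.p_value for p in pairs],
            "status": [p.status for p in pairs],
        }
    )


def write_pairs(pairs: Sequence[PairResult], path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pairs(path) -> list[PairResult]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        ok = row.status == STATUS_OK
        out.append(
            PairResult(
                var_a=str(row.var_a), var_b=str(row.var_b), pair_kind=row.pair_kind,
                n_complete=int(row.n),
                statistic=float(row.statistic) if ok else None,
                effect_size=float(row.effect_size) if ok else None,
                p_value=float(row.p_value) if ok else None,
                status=row.status,
            )
        )
    return out
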
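"""miRNA-target pairing: prediction intersection and correlation gating.

Sequence-based target predictions from three independent sources are
intersected (a pair must be reported by all three), then surviving
pairs are gated on negative Spearman coexpression: a pair is kept only
when SCC < -0.7 and p < 0.05 (both strict).  At the sample sizes this
design targets (six follicle pools) the Spearman p-value is computed by
exact permutation enumeration; the t approximation takes over for
larger n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import factorial
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "intersect_predictions",
    "spearman",
    "select_negative_pairs",
    "read_prediction_tsv",
    "write_pairs_tsv",
    "EXACT_PERMUTATION_MAX_N",
]

#: exact permutation enumeration is used up to this sample count (8! = 40320)
EXACT_PERMUTATION_MAX_N = 8

SCC_THRESHOLD = -0.7
PAIR_ALPHA = 0.05


@dataclass
class CorrelationResult:
    """One pair's correlation coefficient, two-sided p-value and n."""

    id_a: str
    id_b: str
    method: str  # "spearman" | "pearson"
    coefficient: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.coefficient) > 1 + 1e-12:
            raise ValueError("|coefficient| cannot exceed 1")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")
        if self.n < 3:
            raise ValueError("correlation needs at least 3 samples")


# -- prediction intersection ---------------------------------------------------


def intersect_predictions(*tables) -> set[tuple[str, str]]:
    """Pairs (miRNA_id, target_id) present in all three prediction sources."""
    if len(tables) != 3:
        raise ValueError("exactly three prediction tables are required")
    sets = [_as_pair_set(t) for t in tables]
    return sets[0] & sets[1] & sets[2]


def _as_pair_set(table) -> set[tuple[str, str]]:
    if isinstance(table, pd.DataFrame):
        return set(zip(table["miRNA_id"], table["target_id"]))
    return {(a, b) for a, b in table}


# -- Spearman ------------------------------------------------------------------


@lru_cache(maxsize=None)
def _perm_indices(n: int) -> np.ndarray:
    return np.array(list(permutations(range(n))), dtype=np.intp)


def _standardize(v: np.ndarray) -> np.ndarray:
    c = v - v.mean()
    s = np.sqrt((c**2).sum())
    return c / s


def _permutation_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact p: share of orderings with |r| >= |r_obs|."""
    n = len(x)
    zx = _standardize(x)
    zy = _standardize(y)
    r_all = zy[_perm_indices(n)] @ zx  # zy permuted over all orderings, zx fixed
    return float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))


def _t_approx_p(r: float, n: int) -> float:
    if abs(r) >= 1.0 - 1e-15:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman(x, y, id_a: str = "x", id_b: str = "y") -> CorrelationResult:
    """Spearman rank correlation with average-rank ties.

    The coefficient is the Pearson correlation of the rank vectors.  The
    two-sided p-value is exact (full permutation enumeration of one
    rank vector) for n <= 8 and a t approximation with n - 2 degrees of
    freedom beyond that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(_standardize(rx) @ _standardize(ry))
    r = float(np.clip(r, -1.0, 1.0))
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _permutation_p(rx, ry, r)
    else:
        p = _t_approx_p(r, n)
    return CorrelationResult(id_a, id_b, "spearman", r, p, n)


def exact_permutation_count(n: int) -> int:
    return factorial(n)


# -- gating --------------------------------------------------------------------


def select_negative_pairs(
    pairs,
    expression: dict[str, np.ndarray],
    scc_threshold: float = SCC_THRESHOLD,
    alpha: float = PAIR_ALPHA,
) -> pd.DataFrame:
    """Keep pairs with SCC strictly below ``scc_threshold`` and p < alpha.

    ``pairs`` is an iterable of (miRNA_id, target_id); ``expression``
    maps feature id -> value vector on a shared sample ordering.  Pairs
    with a missing feature are skipped with a log entry.  Returns all
    evaluated pairs with their statistics and a ``kept`` flag.
    """
    rows = []
    for mirna_id, target_id in sorted(_as_pair_set(pairs)):
        if mirna_id not in expression or target_id not in expression:
            logger.warning("pair (%s, %s) skipped: feature missing from expression", mirna_id, target_id)
            continue
        try:
            res = spearman(expression[mirna_id], expression[target_id], mirna_id, target_id)
        except ValueError:
            logger.warning("pair (%s, %s) skipped: correlation undefined", mirna_id, target_id)
            continue
        rows.append(
            {
                "miRNA_id": mirna_id,
                "target_id": target_id,
                "scc": res.coefficient,
                "p_value": res.p_value,
                "n": res.n,
                "kept": (res.coefficient < scc_threshold) and (res.p_value < alpha),
            }
        )
    cols = ["miRNA_id", "target_id", "scc", "p_value", "n", "kept"]
    return pd.DataFrame(rows, columns=cols).astype(
        {"scc": float, "p_value": float, "n": int, "kept": bool}
    )


# -- I/O -----------------------------------------------------------------------


def read_prediction_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"miRNA_id", "target_id"}.issubset(df.columns):
        raise ValueError("prediction table needs columns miRNA_id, target_id")
    return df


def write_pairs_tsv(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)
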
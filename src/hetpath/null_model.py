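"""Degree-grouped permutation nulls and the gamma-hurdle significance model.

Because XSwap preserves node degree, permuted DWPCs for all node pairs sharing
the same (source degree, target degree) are draws from the same null: pooling
them ("degree-grouping") multiplies the effective number of permutations.
Only five additive running totals are kept per (metapath, source degree,
target degree): the number of null DWPCs, the number of nonzero ones, their
sum, their sum of squares, and the number of permuted networks seen.

The null is modeled as a gamma-hurdle (zero-inflated gamma): zero with
probability 1 - lambda, and gamma(alpha, beta) on the positive reals
otherwise. Parameters come from the method of moments with Bessel's
correction; the upper-tail probability of an observed DWPC t > 0 is
``lambda * Q(alpha, beta * t)`` with Q the regularized upper incomplete gamma
function. When the gamma portion cannot be fit, empirical fallback rules
computable from the summary statistics are used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special

from .hetnet_core import HetnetStore, Metapath
from .metapaths import count_metapaths

__all__ = [
    "STAT_COLUMNS",
    "GammaHurdleParams",
    "SignificanceResult",
    "NullStats",
    "degree_group_key",
    "accumulate_null_stats",
    "merge_stats",
    "fit_gamma_hurdle",
    "gamma_hurdle_pvalue",
    "empirical_pvalue",
    "dwpc_pvalue",
    "bonferroni_adjust",
    "NullCatalog",
    "compute_null_catalog",
]

STAT_COLUMNS = ["n_dwpcs", "n_nonzero_dwpcs", "sum", "sum_of_squares", "n_perms"]


@dataclass(frozen=True)
class GammaHurdleParams:
    lam: float  # probability of a nonzero draw
    alpha: float  # shape
    beta: float  # rate

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


@dataclass
class SignificanceResult:
    p_value: float
    method: str  # "gamma-hurdle" or "empirical"
    nonzero_mean: float | None = None
    nonzero_sd: float | None = None
    adjusted_p_value: float | None = None


class NullStats:
    """Running null-DWPC summary statistics for one metapath, keyed by
    (source degree, target degree)."""

    def __init__(self, metapath_abbreviation: str, table: pd.DataFrame | None = None):
        self.metapath_abbreviation = metapath_abbreviation
        if table is None:
            index = pd.MultiIndex.from_arrays(
                [[], []], names=["source_degree", "target_degree"]
            )
            table = pd.DataFrame(
                {col: pd.Series(dtype=float) for col in STAT_COLUMNS}, index=index
            )
        self.table = table

    def group(self, d_s: int, d_t: int) -> pd.Series | None:
        key = (int(d_s), int(d_t))
        if key in self.table.index:
            return self.table.loc[key]
        return None

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index()

    @classmethod
    def from_frame(cls, metapath_abbreviation: str, frame: pd.DataFrame) -> "NullStats":
        table = frame.set_index(["source_degree", "target_degree"])[STAT_COLUMNS]
        return cls(metapath_abbreviation, table.astype(float))


def degree_group_key(
    store: HetnetStore, metapath: Metapath, source_node: str, target_node: str
) -> tuple[int, int]:
    """(source degree, target degree) of a node pair for a metapath.

    The source degree counts the source node's edges of the metapath's first
    metaedge type (orientation respected); the target degree counts the target
    node's edges of the last metaedge type.
    """
    first, last = metapath.steps[0], metapath.steps[-1]
    src_deg, _ = store.step_degrees(first)
    _, tgt_deg = store.step_degrees(last)
    i = store.node_position(first.source, source_node)
    j = store.node_position(last.target, target_node)
    return int(src_deg[i]), int(tgt_deg[j])


def _group_frame(
    matrix: np.ndarray, source_degrees: np.ndarray, target_degrees: np.ndarray
) -> pd.DataFrame:
    if matrix.shape != (len(source_degrees), len(target_degrees)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match degree vector lengths "
            f"({len(source_degrees)}, {len(target_degrees)})"
        )
    values = np.asarray(matrix, dtype=float).ravel()
    d_s = np.repeat(source_degrees, len(target_degrees))
    d_t = np.tile(target_degrees, len(source_degrees))
    frame = pd.DataFrame(
        {
            "source_degree": d_s,
            "target_degree": d_t,
            "n_dwpcs": 1.0,
            "n_nonzero_dwpcs": (values > 0).astype(float),
            "sum": values,
            "sum_of_squares": values**2,
        }
    )
    grouped = frame.groupby(["source_degree", "target_degree"]).sum()
    grouped["n_perms"] = 1.0
    return grouped[STAT_COLUMNS]


def accumulate_null_stats(
    stats: NullStats,
    permuted_dwpc_matrix: np.ndarray,
    source_degrees: np.ndarray,
    target_degrees: np.ndarray,
) -> NullStats:
    """Fold one permuted network's DWPC matrix into the running statistics.

    Each (source degree, target degree) cell gains the group's size, nonzero
    count, sum and sum of squares; ``n_perms`` increments by one.
    """
    grouped = _group_frame(permuted_dwpc_matrix, source_degrees, target_degrees)
    merged = stats.table.add(grouped, fill_value=0.0)
    return NullStats(stats.metapath_abbreviation, merged[STAT_COLUMNS])


def merge_stats(a: NullStats, b: NullStats) -> NullStats:
    """Fieldwise sum of two running-total tables (additive by construction)."""
    if a.metapath_abbreviation != b.metapath_abbreviation:
        raise ValueError(
            f"cannot merge statistics for different metapaths "
            f"({a.metapath_abbreviation} vs {b.metapath_abbreviation})"
        )
    merged = a.table.add(b.table, fill_value=0.0)
    return NullStats(a.metapath_abbreviation, merged[STAT_COLUMNS])


def fit_gamma_hurdle(row) -> GammaHurdleParams | None:
    """Method-of-moments gamma-hurdle fit from one degree group's totals.

    With N total and n nonzero null DWPCs summing to S with squared sum S2:
    ``lambda = n/N``, nonzero mean ``mu = S/n``, Bessel-corrected variance
    ``var = (n*S2 - S^2) / (n*(n-1))``, then ``alpha = mu^2/var`` and
    ``beta = mu/var``. Returns None (the fallback signal) when n < 2, the
    variance is zero, or no nulls exist.
    """
    N = float(row["n_dwpcs"])
    n = float(row["n_nonzero_dwpcs"])
    s = float(row["sum"])
    s2 = float(row["sum_of_squares"])
    if N <= 0 or n < 2:
        return None
    var = (n * s2 - s * s) / (n * (n - 1))
    if var <= 0:
        return None
    mu = s / n
    return GammaHurdleParams(lam=n / N, alpha=mu * mu / var, beta=mu / var)


def gamma_hurdle_pvalue(t: float, params: GammaHurdleParams) -> float:
    """P(X >= t) under the gamma-hurdle null: 1 at t = 0, else the hurdle
    probability times the regularized upper incomplete gamma tail."""
    if t < 0:
        raise ValueError("observed DWPC must be non-negative")
    if t == 0:
        return 1.0
    return float(params.lam * scipy.special.gammaincc(params.alpha, params.beta * t))


def empirical_pvalue(t: float, row) -> float:
    """Proportion of null DWPCs >= t, reconstructed from summary statistics.

    Rules: an observed DWPC of zero is never significant (p = 1); a positive
    DWPC against an all-zero null is maximally significant (p = 0); when every
    nonzero null equals the same value, p is 0 if t exceeds it and otherwise
    the proportion of nonzero nulls.
    """
    if t < 0:
        raise ValueError("observed DWPC must be non-negative")
    if t == 0:
        return 1.0
    N = float(row["n_dwpcs"])
    n = float(row["n_nonzero_dwpcs"])
    if N <= 0 or n == 0:
        return 0.0
    s = float(row["sum"])
    common_value = s / n
    return 0.0 if t > common_value else n / N


def dwpc_pvalue(t: float, row) -> SignificanceResult:
    """Significance of an observed DWPC against one degree group's null.

    Uses the gamma-hurdle tail when the fit succeeds, otherwise the empirical
    rules; records which method produced the p-value and the nonzero null
    moments when estimable.
    """
    n = float(row["n_nonzero_dwpcs"])
    nonzero_mean = nonzero_sd = None
    if n >= 1:
        nonzero_mean = float(row["sum"]) / n
    if n >= 2:
        var = (n * float(row["sum_of_squares"]) - float(row["sum"]) ** 2) / (
            n * (n - 1)
        )
        nonzero_sd = math.sqrt(max(var, 0.0))
    params = fit_gamma_hurdle(row)
    if t > 0 and params is not None:
        p = gamma_hurdle_pvalue(t, params)
        method = "gamma-hurdle"
    else:
        p = empirical_pvalue(t, row)
        method = "empirical"
    return SignificanceResult(
        p_value=p, method=method, nonzero_mean=nonzero_mean, nonzero_sd=nonzero_sd
    )


def bonferroni_adjust(
    p: float,
    metagraph,
    source_metanode,
    target_metanode,
    length: int,
) -> float:
    """Bonferroni correction by the number of same-length metapaths between
    the two metanodes (one orientation per metapath), capped at 1."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p-value must be in [0, 1]")
    m = count_metapaths(metagraph, source_metanode, target_metanode, length)
    if m == 0:
        raise ValueError(
            f"no metapaths of length {length} between "
            f"{source_metanode} and {target_metanode}"
        )
    return min(1.0, p * m)


class NullCatalog:
    """Null summary statistics for a collection of metapaths.

    Keys are canonical metapath abbreviations; looking up a reversed metapath
    transparently swaps the degree-group key, since the null statistics of the
    reverse are the transpose's.
    """

    def __init__(self, w: float, n_permutations: int = 0):
        self.w = w
        self.n_permutations = n_permutations
        self._stats: dict[str, NullStats] = {}

    def add(self, stats: NullStats) -> None:
        self._stats[stats.metapath_abbreviation] = stats

    def stats_for(self, metapath: Metapath) -> NullStats | None:
        return self._stats.get(metapath.canonical().abbreviation)

    def group_row(self, metapath: Metapath, d_s: int, d_t: int):
        stats = self.stats_for(metapath)
        if stats is None:
            return None
        if metapath.is_canonical():
            return stats.group(d_s, d_t)
        return stats.group(d_t, d_s)

    def metapath_abbreviations(self) -> list[str]:
        return sorted(self._stats)

    def save(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for abbrev, stats in self._stats.items():
            safe = abbrev.replace(">", "_fwd_").replace("<", "_rev_")
            stats.to_frame().to_csv(
                directory / f"{safe}.tsv.gz", sep="\t", index=False
            )

    @classmethod
    def load(cls, directory, metagraph, w: float, n_permutations: int = 0):
        from pathlib import Path

        catalog = cls(w=w, n_permutations=n_permutations)
        for path in sorted(Path(directory).glob("*.tsv.gz")):
            abbrev = path.name[: -len(".tsv.gz")]
            abbrev = abbrev.replace("_fwd_", ">").replace("_rev_", "<")
            frame = pd.read_csv(path, sep="\t")
            catalog.add(NullStats.from_frame(abbrev, frame))
        return catalog


def compute_null_catalog(
    store: HetnetStore,
    metapaths: list[Metapath],
    n_permutations: int,
    base_seed: int,
    w: float = 0.5,
    multiplier: float = 10.0,
) -> NullCatalog:
    """Build degree-grouped null statistics from freshly generated permutations.

    Streams one permuted store at a time; each contributes its full DWPC
    matrix per metapath to the running totals.
    """
    from .dwpc import dwpc_matrix
    from .permutation import generate_permutations

    catalog = NullCatalog(w=w, n_permutations=n_permutations)
    canonical = [mp.canonical() for mp in metapaths]
    running = {mp.abbreviation: NullStats(mp.abbreviation) for mp in canonical}
    for permuted in generate_permutations(store, n_permutations, base_seed, multiplier):
        for mp in canonical:
            result = dwpc_matrix(permuted, mp, w=w)
            src_deg, _ = permuted.step_degrees(mp.steps[0])
            _, tgt_deg = permuted.step_degrees(mp.steps[-1])
            running[mp.abbreviation] = accumulate_null_stats(
                running[mp.abbreviation], result.matrix, src_deg, tgt_deg
            )
    for stats in running.values():
        catalog.add(stats)
    return catalog
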
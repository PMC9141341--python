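"""Divergence statistics between ranked spectra.

Two ranked 4096-cell spectra are stacked into a 2 x 4096 contingency table and
compared with the mutual-information statistic

    I = sum_ij m ln m  -  sum_i x ln x  -  sum_j y ln y  +  L ln L

(natural logarithms, 0 ln 0 = 0; x and y are row and column sums, L the grand
total).  2I is the G statistic of the table and is approximately chi-square
distributed under the independence hypothesis; applying Fisher's square-root
normal approximation to it gives the index actually reported,

    W = sqrt(4 I) - sqrt(2 df - 1),

which behaves like a standard-normal argument over a wide range.  Identical
rows give I = 0 and put W at its floor -sqrt(2 df - 1).

The per-word z statistic for an observed word count against a binomial
expectation is also provided; it underlies the small worked examples that
motivate the method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .kmer_spectrum import RankedSpectrum

#: Default degrees of freedom: the standard (rows-1)(cols-1) of a 2 x 4096 table.
DEFAULT_DF = 4095


@dataclass(frozen=True)
class ContingencyTable:
    """A 2 x K non-negative table; row 1 observed-ranked, row 2 null-ranked."""

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.m, dtype=float))
        object.__setattr__(self, "m", m)
        if m.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        if (m < 0).any():
            raise ValueError("negative entries in contingency table")

    @property
    def L(self) -> float:
        return float(self.m.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.m.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.m.sum(axis=0)


@dataclass(frozen=True)
class DivergenceResult:
    """Mutual information (nats), its normal-scale index, and provenance."""

    I: float
    W: float
    df: int
    table: ContingencyTable


def mutual_info_I(table: ContingencyTable | np.ndarray) -> float:
    """Mutual-information statistic of a contingency table, in nats.

    Uses the convention 0 ln 0 = 0.  The quantity is mathematically
    non-negative; tiny negative rounding residues (below 1e-9 of the grand
    total) are clipped to zero.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    m = table.m
    L = table.L
    if L == 0:
        return 0.0
    value = (
        xlogy(m, m).sum()
        - xlogy(table.row_sums, table.row_sums).sum()
        - xlogy(table.col_sums, table.col_sums).sum()
        + xlogy(L, L)
    )
    if value < 0:
        if value < -1e-9 * L:
            raise ArithmeticError(f"mutual information came out negative ({value})")
        value = 0.0
    return float(value)


def w_statistic(I: float, df: int = DEFAULT_DF) -> float:
    """Normal-scale index W = sqrt(4 I) - sqrt(2 df - 1).

    This is Fisher's sqrt(2 chi^2) - sqrt(2 df - 1) approximation applied to
    chi^2 = 2 I.  Strictly increasing in I; at I = 0 it returns the floor
    -sqrt(2 df - 1) (about -90.49 for df = 4095).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if I < 0:
        if I < -1e-9:
            raise ValueError(f"negative mutual information {I}")
        I = 0.0
    return math.sqrt(4.0 * I) - math.sqrt(2.0 * df - 1.0)


def w_floor(df: int = DEFAULT_DF) -> float:
    """The minimum attainable W at the given degrees of freedom."""
    return -math.sqrt(2.0 * df - 1.0)


def compare_spectra(
    observed: RankedSpectrum, null: RankedSpectrum, df: int = DEFAULT_DF
) -> DivergenceResult:
    """Build the 2 x K table from two ranked spectra and compute I and W."""
    if len(observed.values) != len(null.values):
        raise ValueError(
            f"spectra have different cell counts ({len(observed.values)} vs {len(null.values)})"
        )
    if observed.scale != null.scale:
        raise ValueError("spectra have different scales")
    table = ContingencyTable(np.vstack([observed.values, null.values]))
    I = mutual_info_I(table)
    return DivergenceResult(I=I, W=w_statistic(I, df), df=df, table=table)


def z_statistic(N: float, total: float, p: float) -> float:
    """Normal approximation to the binomial deviation of a word count.

    ``N`` observed occurrences out of ``total`` windows with per-window
    probability ``p``: z = (N - total*p) / sqrt(total*p*(1-p)).  The
    degenerate cases p = 1 (the word is certain) and p = 0 with N = 0 return
    0; p = 0 with N > 0 is an impossible-word observation and raises.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p == 1.0:
        return 0.0
    if p == 0.0:
        if N == 0:
            return 0.0
        raise ValueError("observed a word whose null probability is zero")
    return float((N - total * p) / math.sqrt(total * p * (1.0 - p)))
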
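"""Hexamer spectra of coding-sequence sets.

A CDS set is reduced to a 4096-cell count array: every 6-base word starting at
in-frame positions 1, 4, 7, ... (1-based, 3-base step, so consecutive words
overlap by one codon) increments one cell.  The 3-base step is the smallest
that respects triplet periodicity while sampling hexamers in both codon
phases.  Counts are then normalised to a fixed total of 10^6 and sorted
ascending — the same ranking used for Gini-coefficient curves — giving the
ranked spectrum Q1 that the divergence statistics compare against shuffled
nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import CodingSequence

#: Published word length and step (hexamers, codon-phase step).
WORD_LENGTH = 6
STEP = 3
N_CELLS = 4 ** WORD_LENGTH
#: Fixed total of a ranked spectrum; removes CDS-set size from the comparison.
SCALE = 1.0e6

# a=1, t=2, c=3, g=4 in the published encoding; we store code-1 internally so
# a hexamer is a little-endian base-4 number in [0, 4096).
_CODE = np.full(256, -1, dtype=np.int64)
for _b, _v in zip(b"atcg", range(4)):
    _CODE[_b] = _v
_LETTERS = "atcg"


def encode_bases(seq: str) -> np.ndarray:
    """Map a/t/c/g to 0/1/2/3; anything else (e.g. masked ``n``) to -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def word_index(seq: str | CodingSequence, start: int, word_length: int = WORD_LENGTH) -> int:
    """1-based cell index of the word at 1-based position ``start``.

    With letters encoded a=1, t=2, c=3, g=4 the index is
    ``s(start) + sum_{k=1..w-1} (s(start+k)-1) * 4**k``, i.e. "aaaaaa" -> 1 and
    "gggggg" -> 4096.
    """
    s = seq.seq if isinstance(seq, CodingSequence) else seq
    if start < 1 or start + word_length - 1 > len(s):
        raise ValueError(f"window [{start}, {start + word_length - 1}] outside sequence of length {len(s)}")
    codes = encode_bases(s[start - 1 : start - 1 + word_length])
    if (codes < 0).any():
        raise ValueError("window contains ambiguous characters")
    return int(1 + codes @ (4 ** np.arange(word_length)))


def word_string(j: int, word_length: int = WORD_LENGTH) -> str:
    """Inverse of :func:`word_index`: the hexamer spelled by cell ``j``."""
    if not 1 <= j <= 4 ** word_length:
        raise ValueError(f"cell index {j} out of range")
    j -= 1
    out = []
    for _ in range(word_length):
        out.append(_LETTERS[j % 4])
        j //= 4
    return "".join(out)


@dataclass(frozen=True)
class HexamerSpectrum:
    """Raw word counts of a CDS set.

    ``counts`` is real-valued so replicate-averaged null spectra fit the same
    container; for a single unaveraged CDS set every cell is an integer.
    ``n_windows`` counts the windows actually tallied (windows touching a
    masked base are excluded, so ``total == n_windows`` only in the unmasked,
    unaveraged case).
    """

    counts: np.ndarray
    total: float
    n_sequences: int
    n_windows: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if (c < 0).any():
            raise ValueError("negative counts")
        if not np.isclose(self.total, c.sum(), rtol=1e-9, atol=0):
            raise ValueError("total inconsistent with counts")


@dataclass(frozen=True)
class RankedSpectrum:
    """A spectrum normalised to total :data:`SCALE` and sorted ascending."""

    values: np.ndarray
    scale: float = SCALE

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if (np.diff(v) < 0).any():
            raise ValueError("values not sorted ascending")
        if not np.isclose(v.sum(), self.scale, rtol=1e-9):
            raise ValueError("values do not sum to the scale")

    def to_tsv(self, path: str | Path) -> None:
        """Write (rank, value) pairs, rank 1 = smallest."""
        with open(path, "w") as fh:
            fh.write("rank\tvalue\n")
            for k, v in enumerate(self.values, start=1):
                fh.write(f"{k}\t{v:.6g}\n")


def window_indices(codes: np.ndarray, word_length: int = WORD_LENGTH, step: int = STEP) -> np.ndarray:
    """0-based cell indices of all unambiguous windows of one encoded CDS."""
    l = len(codes)
    if l < word_length:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, word_length)[::step]
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(word_length)
    return windows[valid] @ powers


def count_hexamers(
    cds_set: Sequence[CodingSequence] | Iterable[CodingSequence],
    word_length: int = WORD_LENGTH,
    step: int = STEP,
) -> HexamerSpectrum:
    """Accumulate the word-count array over a whole CDS set.

    Windows start at 1-based positions 1, 4, ..., never span two records, and
    each increments exactly one of the ``4**word_length`` cells.
    """
    if word_length % step != 0:
        raise ValueError("word_length must be a multiple of step")
    cds_list = list(cds_set)
    if not cds_list:
        raise ValueError("empty CDS set")
    n_cells = 4 ** word_length
    counts = np.zeros(n_cells, dtype=float)
    n_windows = 0
    for cds in cds_list:
        idx = window_indices(encode_bases(cds.seq), word_length, step)
        counts += np.bincount(idx, minlength=n_cells)
        n_windows += len(idx)
    return HexamerSpectrum(
        counts=counts, total=float(counts.sum()), n_sequences=len(cds_list), n_windows=n_windows
    )


def normalize_and_rank(spectrum: HexamerSpectrum) -> RankedSpectrum:
    """Scale counts to total 10^6 and sort ascending (the Q1/R1/T1 form)."""
    if spectrum.total <= 0:
        raise ValueError("cannot normalise a spectrum with zero total")
    values = np.sort(spectrum.counts * (SCALE / spectrum.total))
    return RankedSpectrum(values=values)
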
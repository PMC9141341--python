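"""Monte Carlo null spectra: base shuffling without stop codons, and codon
(triplet) shuffling.

The observed ranked spectrum Q1 is compared against two randomised baselines.

* ``base_no_stop`` — every CDS is replaced by a random permutation of its own
  bases, constrained so that no stop codon appears at an in-frame (frame-1)
  codon position.  This destroys all correlation structure while preserving
  base composition, so divergence from it (W1) reflects triplet periodicity
  plus any longer correlations.
* ``triplet`` — every CDS is replaced by a random permutation of its own
  codons.  Codon usage is preserved exactly, so divergence from it (W2)
  reflects only correlations spanning six bases or more.

Each CDS is re-shuffled ``replicates`` times (default 100); cell counts are
averaged over replicates *before* normalisation and ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kmer_spectrum import (
    STEP,
    WORD_LENGTH,
    HexamerSpectrum,
    RankedSpectrum,
    encode_bases,
    normalize_and_rank,
    window_indices,
)
from .sequence_io import STANDARD_STOP_CODONS, CodingSequence

logger = logging.getLogger(__name__)

_LETTERS = np.frombuffer(b"atcg", dtype=np.uint8)

#: Stream-derivation tags, so R and T replicates never share random numbers.
_MODE_KEY = {"base_no_stop": 0, "triplet": 1}


class ShuffleError(RuntimeError):
    """Stop-free rearrangement not found within the repair budget."""


@dataclass(frozen=True)
class NullConfig:
    mode: str = "base_no_stop"
    replicates: int = 100
    seed: int = 0
    max_repair_iterations: int | None = None  # None -> 10 * sequence length
    stop_codons: tuple[str, ...] = STANDARD_STOP_CODONS

    def __post_init__(self) -> None:
        if self.mode not in _MODE_KEY:
            raise ValueError(f"unknown null mode {self.mode!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _rng_stream(seed: int, mode: str, cds_index: int, replicate: int) -> np.random.Generator:
    """Generator keyed by (seed, mode, CDS, replicate): reproducible regardless
    of iteration order."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_MODE_KEY[mode], cds_index, replicate))
    return np.random.default_rng(ss)


def _stop_codes(stop_codons: Sequence[str]) -> np.ndarray:
    """Each stop codon packed as c0*16 + c1*4 + c2 over the 0..3 base codes."""
    packed = []
    for codon in stop_codons:
        c = encode_bases(codon)
        packed.append(int(c[0] * 16 + c[1] * 4 + c[2]))
    return np.asarray(packed, dtype=np.int64)


def _inframe_stops(codes: np.ndarray, stop_packed: np.ndarray) -> np.ndarray:
    cods = codes.reshape(-1, 3)
    packed = cods[:, 0] * 16 + cods[:, 1] * 4 + cods[:, 2]
    return np.flatnonzero(np.isin(packed, stop_packed))


def _shuffle_codes_no_stop(
    codes: np.ndarray,
    rng: np.random.Generator,
    stop_packed: np.ndarray,
    max_repair_iterations: int,
) -> np.ndarray:
    """Permute base codes; repair in-frame stops by random swaps.

    A full Fisher-Yates permutation is drawn first.  Whenever an in-frame stop
    codon remains, one of its three bases (chosen uniformly) is swapped with a
    uniformly chosen position anywhere in the sequence and the scan repeats.
    The result is close to, but not exactly, a uniform draw from the stop-free
    permutations; the residual bias is negligible for rank statistics.
    """
    out = rng.permutation(codes)
    iterations = 0
    while True:
        stops = _inframe_stops(out, stop_packed)
        if stops.size == 0:
            return out
        for ci in stops:
            if iterations >= max_repair_iterations:
                raise ShuffleError(
                    f"no stop-free arrangement found within {max_repair_iterations} repair swaps"
                )
            iterations += 1
            pos = 3 * ci + rng.integers(3)
            other = rng.integers(len(out))
            out[pos], out[other] = out[other], out[pos]


def _decode(codes: np.ndarray) -> str:
    return _LETTERS[codes].tobytes().decode("ascii")


def shuffle_bases_no_stop(
    cds: CodingSequence,
    rng: np.random.Generator,
    stop_codons: Sequence[str] = STANDARD_STOP_CODONS,
    max_repair_iterations: int | None = None,
) -> CodingSequence:
    """Random permutation of the bases of ``cds`` with no in-frame stop codon.

    The base multiset is preserved exactly.  Raises :class:`ShuffleError` when
    the composition (nearly) forces stops and repair exhausts its budget.
    """
    codes = encode_bases(cds.seq)
    if (codes < 0).any():
        raise ValueError(f"{cds.id!r}: cannot base-shuffle a sequence with masked positions")
    budget = max_repair_iterations if max_repair_iterations is not None else 10 * len(codes)
    try:
        out = _shuffle_codes_no_stop(codes, rng, _stop_codes(stop_codons), budget)
    except ShuffleError as exc:
        raise ShuffleError(f"{cds.id!r}: {exc}") from exc
    return CodingSequence(cds.id, _decode(out))


def shuffle_triplets(cds: CodingSequence, rng: np.random.Generator) -> CodingSequence:
    """Uniform random permutation of the codons of ``cds`` (frame 1)."""
    codons = np.frombuffer(cds.seq.encode("ascii"), dtype=np.uint8).reshape(-1, 3)
    return CodingSequence(cds.id, rng.permutation(codons, axis=0).tobytes().decode("ascii"))


def null_spectrum(
    cds_set: Sequence[CodingSequence],
    config: NullConfig,
    word_length: int = WORD_LENGTH,
    step: int = STEP,
) -> RankedSpectrum:
    """Replicate-averaged ranked null spectrum (R1 or T1) of a CDS set.

    For every replicate each CDS is independently re-shuffled and its windows
    counted; cell counts are summed over replicates, divided by the replicate
    number, then normalised to 10^6 and ranked.  Averaging precedes ranking.
    A CDS that cannot be de-stopped raises :class:`ShuffleError` naming it;
    callers wanting a skip-and-log policy must exclude the offender from the
    observed spectrum as well (see the pipeline module).
    """
    if not cds_set:
        raise ValueError("empty CDS set")
    n_cells = 4 ** word_length
    stop_packed = _stop_codes(config.stop_codons)
    acc = np.zeros(n_cells, dtype=float)
    n_windows = 0
    for ci, cds in enumerate(cds_set):
        codes = encode_bases(cds.seq)
        if config.mode == "base_no_stop" and (codes < 0).any():
            raise ValueError(f"{cds.id!r}: cannot base-shuffle a sequence with masked positions")
        budget = (
            config.max_repair_iterations
            if config.max_repair_iterations is not None
            else 10 * len(codes)
        )
        triplets = codes.reshape(-1, 3)
        for rep in range(config.replicates):
            rng = _rng_stream(config.seed, config.mode, ci, rep)
            if config.mode == "base_no_stop":
                try:
                    shuffled = _shuffle_codes_no_stop(codes, rng, stop_packed, budget)
                except ShuffleError as exc:
                    raise ShuffleError(f"{cds.id!r}: {exc}") from exc
            else:
                shuffled = rng.permutation(triplets, axis=0).reshape(-1)
            idx = window_indices(shuffled, word_length, step)
            acc += np.bincount(idx, minlength=n_cells)
            if rep == 0:
                n_windows += len(idx)
    avg = acc / config.replicates
    spectrum = HexamerSpectrum(
        counts=avg, total=float(avg.sum()), n_sequences=len(cds_set), n_windows=n_windows
    )
    return normalize_and_rank(spectrum)
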
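"""Reading and validation of coding sequences (CDS) from FASTA files.

Everything downstream assumes each record is an in-frame protein-coding
nucleotide sequence: lower-case ``a/t/c/g``, length a multiple of three and at
least six bases (one hexamer window), with no terminal stop codon.  This module
turns raw FASTA records into that canonical form and reports what it dropped or
repaired along the way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Stop codons of the standard genetic code (also NCBI table 11, bacteria).
STANDARD_STOP_CODONS: tuple[str, ...] = ("taa", "tag", "tga")

_UNAMBIGUOUS = frozenset("atcg")
# 'n' marks a masked position under the "skip-windows" ambiguity policy;
# hexamer windows containing it are excluded from counting.
_ALLOWED = frozenset("atcgn")


class SequenceRejected(ValueError):
    """A record that cannot be brought into canonical CDS form.

    Carries a short machine-readable ``reason`` used in drop reports.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class CodingSequence:
    """One validated coding sequence.

    ``seq`` is lower-case over ``a/t/c/g`` (plus ``n`` only when the
    skip-windows ambiguity policy masked positions), its length is a multiple
    of three and at least 6.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 6:
            raise ValueError(f"{self.id!r}: sequence shorter than 6 bases")
        if len(self.seq) % 3 != 0:
            raise ValueError(f"{self.id!r}: length {len(self.seq)} not a multiple of 3")
        if not _ALLOWED.issuperset(self.seq):
            bad = sorted(set(self.seq) - _ALLOWED)
            raise ValueError(f"{self.id!r}: invalid characters {bad}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]


@dataclass(frozen=True)
class PreprocessConfig:
    """Hygiene rules applied to raw FASTA records.

    ambiguity_policy
        ``"drop-record"`` (default) rejects any record still containing a
        non-``acgt`` character after case-folding and ``u``→``t``;
        ``"skip-windows"`` masks those characters as ``n`` so only the hexamer
        windows touching them are lost.
    """

    stop_codons: tuple[str, ...] = STANDARD_STOP_CODONS
    strip_terminal_stop: bool = True
    ambiguity_policy: str = "drop-record"
    min_length: int = 6

    def __post_init__(self) -> None:
        if self.ambiguity_policy not in ("drop-record", "skip-windows"):
            raise ValueError(f"unknown ambiguity_policy {self.ambiguity_policy!r}")
        for c in self.stop_codons:
            if len(c) != 3 or not _UNAMBIGUOUS.issuperset(c):
                raise ValueError(f"invalid stop codon {c!r}")


DEFAULT_PREPROCESS = PreprocessConfig()


def preprocess(
    raw_id: str, raw_seq: str, config: PreprocessConfig = DEFAULT_PREPROCESS
) -> CodingSequence:
    """Canonicalise one raw record or raise :class:`SequenceRejected`.

    Steps, in order: case-fold and map ``u``→``t``; trim 1-2 trailing bases if
    the length is not a multiple of three; strip trailing stop codons (repeated
    until none remains, which makes the whole function idempotent); apply the
    ambiguity policy; enforce the minimum length.
    """
    s = raw_seq.strip().lower().replace("u", "t")
    if not s:
        raise SequenceRejected("empty sequence")
    if len(s) % 3 != 0:
        trimmed = len(s) % 3
        s = s[: len(s) - trimmed]
        logger.debug("%s: trimmed %d trailing base(s) to restore frame", raw_id, trimmed)
    if config.strip_terminal_stop:
        stops = set(config.stop_codons)
        while len(s) >= 3 and s[-3:] in stops:
            s = s[:-3]
    if not s:
        raise SequenceRejected("empty after stop-codon stripping")
    if len(s) < max(config.min_length, 6):
        raise SequenceRejected(f"too short after preprocessing ({len(s)} < {max(config.min_length, 6)})")
    if not _UNAMBIGUOUS.issuperset(s):
        if config.ambiguity_policy == "drop-record":
            raise SequenceRejected("ambiguous characters")
        s = "".join(c if c in _UNAMBIGUOUS else "n" for c in s)
    return CodingSequence(raw_id, s)


@dataclass
class ReadReport:
    """Outcome of reading one FASTA file: retained records plus a drop log."""

    path: str
    records: list[CodingSequence] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def n_records(self) -> int:
        return len(self.records) + len(self.dropped)


def read_cds_fasta(
    path: str | Path, config: PreprocessConfig = DEFAULT_PREPROCESS
) -> ReadReport:
    """Read and preprocess a multi-FASTA of coding sequences.

    Records are returned in file order.  A file with no parseable record, or
    one from which nothing survives preprocessing, is a hard error.
    """
    path = Path(path)
    report = ReadReport(path=str(path))
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read FASTA {path}: {exc}") from exc
    if not parsed:
        raise ValueError(f"no FASTA records found in {path}")
    for rec in parsed:
        try:
            report.records.append(preprocess(rec.id, str(rec.seq), config))
        except SequenceRejected as rej:
            report.dropped.append((rec.id, rej.reason))
            logger.info("%s: dropped %s (%s)", path, rec.id, rej.reason)
    if not report.records:
        raise ValueError(f"no records retained from {path} after preprocessing")
    return report


def write_cds_fasta(records: Iterable[CodingSequence], path: str | Path) -> None:
    """Write coding sequences to an (unwrapped) FASTA file."""
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(path), "fasta-2line")
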
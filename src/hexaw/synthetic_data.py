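"""Synthetic coding-sequence constructors and generators.

Deterministic constructors reproduce the small pedagogical sequences used to
illustrate the method (pure-repeat CDS, the 900-nt gene with a contiguous run
of t), and a seeded generator produces CDS sets with controllable codon-usage
bias and adjacent-codon coupling so every stage of the pipeline can be
exercised without external genome downloads.

The generator draws codons independently from a weight table; an optional
coupling parameter makes each codon repeat its predecessor with probability
``hexamer_coupling``, which induces correlations of six bases and longer —
exactly the structure that survives triplet shuffling and therefore drives W2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .kmer_spectrum import count_hexamers, word_index
from .sequence_io import STANDARD_STOP_CODONS, CodingSequence

#: All 64 codons in lexicographic a<t<c<g order of the internal encoding.
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("atcg", repeat=3)
)
#: The 61 sense codons of the standard code.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if c not in STANDARD_STOP_CODONS
)


def make_repeat(unit: str, n: int, cds_id: str | None = None) -> CodingSequence:
    """A CDS made of ``unit`` (a codon or a hexamer) repeated ``n`` times."""
    unit = unit.lower()
    if len(unit) not in (3, 6):
        raise ValueError("repeat unit must be 3 or 6 bases long")
    if n < 2:
        raise ValueError("need at least 2 repeats")
    return CodingSequence(cds_id or f"{unit}_x{n}", unit * n)


def make_trun_gene(seed: int = 0, run_start: int = 301) -> CodingSequence:
    """The 900-nt gene whose 90 t bases all sit in one contiguous run.

    Base frequencies are a, t, c, g = 0.3, 0.1, 0.3, 0.3 (counts 270, 90, 270,
    270).  The t-run starts at a frame-aligned 1-based position (default 301)
    and the remaining positions carry a seeded random permutation of the a, c
    and g bases.  Any interior frame-aligned start yields exactly 29 in-frame
    tttttt windows out of 299 windows total, which the constructor asserts.
    """
    length, t_count = 900, 90
    if run_start % 3 != 1 or run_start < 1 or run_start + t_count - 1 > length:
        raise ValueError("t-run must be frame-aligned and fully interior")
    rng = np.random.default_rng(seed)
    rest = rng.permutation(np.array(list("a" * 270 + "c" * 270 + "g" * 270)))
    seq = np.empty(length, dtype="<U1")
    run = slice(run_start - 1, run_start - 1 + t_count)
    seq[run] = "t"
    mask = np.ones(length, dtype=bool)
    mask[run] = False
    seq[mask] = rest
    cds = CodingSequence(f"trun_seed{seed}", "".join(seq))
    spectrum = count_hexamers([cds])
    t6 = word_index("tttttt", 1)
    assert spectrum.n_windows == 299 and spectrum.counts[t6 - 1] == 29
    return cds


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions for one synthetic CDS set.

    codon_weights maps codons to non-negative sampling weights (unlisted
    codons get 0); stop codons must have weight 0 so generated sequences are
    valid stop-free coding material.  hexamer_coupling in [0, 1] is the
    probability that a codon copies its predecessor instead of being drawn
    fresh.
    """

    n_cds: int
    length: int
    codon_weights: dict[str, float]
    hexamer_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cds < 1:
            raise ValueError("n_cds must be >= 1")
        if self.length < 6 or self.length % 3 != 0:
            raise ValueError("length must be a multiple of 3 and >= 6")
        if not 0.0 <= self.hexamer_coupling <= 1.0:
            raise ValueError("hexamer_coupling must lie in [0, 1]")
        total = 0.0
        for codon, w in self.codon_weights.items():
            if codon not in ALL_CODONS:
                raise ValueError(f"unknown codon {codon!r}")
            if w < 0:
                raise ValueError(f"negative weight for {codon!r}")
            if codon in STANDARD_STOP_CODONS and w > 0:
                raise ValueError(f"stop codon {codon!r} must have weight 0")
            total += w
        if total <= 0:
            raise ValueError("codon weights sum to zero")


def uniform_codon_weights() -> dict[str, float]:
    """Equal weight on all 61 sense codons."""
    return {c: 1.0 for c in SENSE_CODONS}


def skewed_codon_weights(strength: float, seed: int = 0) -> dict[str, float]:
    """Log-normally skewed sense-codon weights; ``strength`` 0 is uniform.

    Weights are exp(strength * z) with z a fixed standard-normal draw per
    codon, so increasing ``strength`` at a fixed seed monotonically sharpens
    the same usage pattern — a convenient dial for codon-usage bias.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(len(SENSE_CODONS))
    return {c: float(np.exp(strength * zi)) for c, zi in zip(SENSE_CODONS, z)}


def generate_cds_set(spec: GeneratorSpec) -> list[CodingSequence]:
    """Draw ``spec.n_cds`` sequences of ``spec.length`` bases.

    Codons are i.i.d. from ``codon_weights`` when ``hexamer_coupling`` is 0;
    with coupling c each subsequent codon repeats the previous one with
    probability c.  Fully reproducible from ``spec.seed``.
    """
    codons = [c for c, w in sorted(spec.codon_weights.items()) if w > 0]
    weights = np.array([spec.codon_weights[c] for c in codons], dtype=float)
    probs = weights / weights.sum()
    n_codons = spec.length // 3
    out: list[CodingSequence] = []
    for ci in range(spec.n_cds):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(ci,)))
        fresh = rng.choice(len(codons), size=n_codons, p=probs)
        if spec.hexamer_coupling > 0 and n_codons > 1:
            repeat = rng.random(n_codons) < spec.hexamer_coupling
            repeat[0] = False
            # forward-fill: each repeated position takes the last fresh draw
            src = np.where(repeat, 0, np.arange(n_codons))
            src = np.maximum.accumulate(src)
            fresh = fresh[src]
        seq = "".join(codons[k] for k in fresh)
        out.append(CodingSequence(f"synth_{ci}", seq))
    return out
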
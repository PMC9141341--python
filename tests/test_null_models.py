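"""Conservation laws and determinism of the shuffling null models."""

import itertools
from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare

from hexaw import (
    CodingSequence,
    NullConfig,
    count_hexamers,
    make_repeat,
    normalize_and_rank,
    null_spectrum,
    shuffle_bases_no_stop,
    shuffle_triplets,
)

from conftest import random_cds_seqs

STOPS = {"taa", "tag", "tga"}


def inframe_codons(seq):
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def test_base_shuffle_conserves_bases_and_avoids_stops(rng):
    for i, s in enumerate(random_cds_seqs(rng, 100)):
        cds = CodingSequence(f"r{i}", s)
        out = shuffle_bases_no_stop(cds, rng)
        assert Counter(out.seq) == Counter(cds.seq)
        assert not STOPS & set(inframe_codons(out.seq))


def test_base_shuffle_single_arrangement_is_identity(rng):
    cds = CodingSequence("mono", "aaaaaa")
    assert shuffle_bases_no_stop(cds, rng).seq == "aaaaaa"


def test_base_shuffle_outputs_lie_in_enumerated_stop_free_set(rng):
    # brute-force oracle: of the 6!/(2!2!2!) = 90 distinct arrangements of
    # t,a,g,t,a,g, keep those with no in-frame stop; every shuffle must land
    # in that set
    bases = "tagtag"
    stop_free = {
        "".join(p)
        for p in itertools.permutations(bases)
        if not STOPS & set(inframe_codons("".join(p)))
    }
    assert 0 < len(stop_free) < 90
    cds = CodingSequence("x", "gatgat")  # same base multiset, itself stop-free
    for _ in range(200):
        out = shuffle_bases_no_stop(cds, rng)
        assert out.seq in stop_free
        assert Counter(out.seq) == Counter(bases)


def test_triplet_shuffle_conserves_codons(rng):
    for i, s in enumerate(random_cds_seqs(rng, 50)):
        cds = CodingSequence(f"r{i}", s)
        out = shuffle_triplets(cds, rng)
        assert Counter(inframe_codons(out.seq)) == Counter(inframe_codons(cds.seq))


def test_triplet_shuffle_of_single_codon_repeat_is_identity(rng, s1):
    assert shuffle_triplets(s1, rng).seq == s1.seq


def test_triplet_shuffle_two_codon_distribution(rng):
    # "atgccc" has exactly two codon orders; both should appear ~equally
    cds = CodingSequence("x", "atgccc")
    counts = Counter(shuffle_triplets(cds, rng).seq for _ in range(10_000))
    assert set(counts) == {"atgccc", "cccatg"}
    stat, p = chisquare(list(counts.values()))
    assert p > 1e-4


def test_null_spectrum_triplet_identity_for_single_codon_set(s1):
    q1 = normalize_and_rank(count_hexamers([s1]))
    t1 = null_spectrum([s1], NullConfig(mode="triplet", replicates=5, seed=3))
    assert np.allclose(q1.values, t1.values)


def test_null_spectrum_deterministic_under_seed(rng):
    cds_set = [CodingSequence(f"r{i}", s) for i, s in enumerate(random_cds_seqs(rng, 5))]
    cfg = NullConfig(mode="base_no_stop", replicates=4, seed=17)
    a = null_spectrum(cds_set, cfg)
    b = null_spectrum(cds_set, cfg)
    assert np.array_equal(a.values, b.values)
    c = null_spectrum(cds_set, NullConfig(mode="base_no_stop", replicates=4, seed=18))
    assert not np.array_equal(a.values, c.values)


def test_null_spectrum_averaged_total_matches_window_count(rng):
    cds_set = [CodingSequence(f"r{i}", s) for i, s in enumerate(random_cds_seqs(rng, 8))]
    observed = count_hexamers(cds_set)
    for mode in ("base_no_stop", "triplet"):
        ranked = null_spectrum(cds_set, NullConfig(mode=mode, replicates=7, seed=2))
        # normalisation to the common scale only works because every replicate
        # has the same window count as the original set
        assert ranked.values.sum() == pytest.approx(1e6, rel=1e-9)
        assert observed.n_windows == count_hexamers(cds_set).n_windows


def test_base_shuffle_disperses_a_point_mass(s1):
    # the 99-fold atcatc point mass must spread out under base shuffling
    q1 = normalize_and_rank(count_hexamers([s1]))
    r1 = null_spectrum([s1], NullConfig(mode="base_no_stop", replicates=20, seed=9))
    assert r1.values[-1] < q1.values[-1]


def test_base_shuffle_null_avoids_stop_containing_cells():
    # hexamer cells whose word contains an in-frame stop codon can never be
    # populated by the constrained shuffle
    from hexaw import word_string

    rng = np.random.default_rng(0)
    sense = [c for c in map("".join, itertools.product("atcg", repeat=3)) if c not in STOPS]
    seqs = [
        CodingSequence(f"u{i}", "".join(rng.choice(sense, size=100))) for i in range(10)
    ]
    shuffled = [shuffle_bases_no_stop(c, rng) for c in seqs]
    counts = count_hexamers(shuffled).counts
    stop_cells = [
        j
        for j in range(1, 4097)
        if word_string(j)[:3] in STOPS or word_string(j)[3:] in STOPS
    ]
    assert counts[np.array(stop_cells) - 1].sum() == 0


def test_replicate_streams_do_not_depend_on_iteration_order(rng):
    seqs = random_cds_seqs(rng, 4)
    cds_set = [CodingSequence(f"r{i}", s) for i, s in enumerate(seqs)]
    cfg = NullConfig(mode="triplet", replicates=3, seed=5)
    full = null_spectrum(cds_set, cfg)
    # analysing a subset reuses the same per-CDS streams for shared indices;
    # here we just re-run to confirm bitwise stability of the whole pipeline
    assert np.array_equal(full.values, null_spectrum(cds_set, cfg).values)


def test_empty_set_and_bad_config_rejected():
    with pytest.raises(ValueError):
        null_spectrum([], NullConfig(mode="triplet"))
    with pytest.raises(ValueError):
        NullConfig(mode="bogus")
    with pytest.raises(ValueError):
        NullConfig(replicates=0)
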
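"""Alignment, E-value, RBH and AAI contracts.

The alignment oracle here is an independent affine-gap Smith-Waterman
(Gotoh) dynamic program over Biopython's BLOSUM62 table; the package's
aligner must reproduce its optimal scores.
"""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from hemenet.errors import InputError, ParameterError
from hemenet.homology import (
    AAIResult,
    AlignmentParams,
    align_pair,
    best_hits,
    compute_aai,
    evalue,
    reciprocal_best_hits,
    search,
)
from hemenet.records import ProteinRecord
from hemenet.synthetic import BACKGROUND_ALPHABET, mutate_to_identity

_B62 = substitution_matrices.load("BLOSUM62")
AA = list("ACDEFGHIKLMNPQRSTVWY")


def gotoh_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Reference optimal local alignment score (first gap symbol costs open)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    e = [[neg] * (m + 1) for _ in range(n + 1)]
    f = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(e[i][j - 1] - gap_extend, h[i][j - 1] - gap_open)
            f[i][j] = max(f[i - 1][j] - gap_extend, h[i - 1][j] - gap_open)
            h[i][j] = max(
                0.0,
                h[i - 1][j - 1] + _B62[a[i - 1], b[j - 1]],
                e[i][j],
                f[i][j],
            )
            best = max(best, h[i][j])
    return int(best)


def test_alignment_matches_independent_dp(rng):
    for _ in range(200):
        la, lb = rng.integers(5, 41, size=2)
        a = "".join(rng.choice(AA, size=la))
        b = "".join(rng.choice(AA, size=lb))
        assert align_pair(a, b).raw_score == gotoh_local_score(a, b)


def test_self_alignment_is_perfect(rng):
    for _ in range(20):
        s = "".join(rng.choice(AA, size=int(rng.integers(5, 60))))
        hit = align_pair(s, s)
        assert hit.pident == 100.0
        assert hit.qcov == 100.0


def test_alignment_symmetry(rng):
    for _ in range(30):
        a = "".join(rng.choice(AA, size=40))
        b = "".join(rng.choice(AA, size=45))
        ab, ba = align_pair(a, b), align_pair(b, a)
        assert ab.raw_score == ba.raw_score
        assert ab.pident == pytest.approx(ba.pident)


def test_two_substitutions_on_forced_alignment():
    a = "ACDEFGHIKL" * 3
    b = list(a)
    b[4] = "W" if b[4] != "W" else "Y"
    b[20] = "W" if b[20] != "W" else "Y"
    hit = align_pair(a, "".join(b))
    assert hit.length == len(a)
    assert hit.pident == pytest.approx(100.0 * (len(a) - 2) / len(a))


def test_score_monotone_under_identical_extension(rng):
    a = "".join(rng.choice(AA, size=30))
    b = "".join(rng.choice(AA, size=30))
    block = "".join(rng.choice(AA, size=15))
    assert align_pair(a + block, b + block).raw_score >= align_pair(a, b).raw_score


def test_empty_sequence_rejected():
    with pytest.raises(InputError):
        align_pair("", "ACD")


class TestEvalue:
    def test_identity_case(self):
        assert evalue(0.0, 1, 1) == 1.0

    def test_ten_bits_shrink_1024fold(self):
        assert evalue(40.0, 100, 1000) == pytest.approx(evalue(30.0, 100, 1000) / 1024)

    def test_closed_form(self, rng):
        for _ in range(50):
            s = float(rng.uniform(0, 300))
            m = int(rng.integers(1, 10_000))
            n = int(rng.integers(1, 10_000_000))
            assert evalue(s, m, n) == pytest.approx(m * n * 2.0 ** (-s))

    def test_ordering_preserved_under_scaling(self):
        bits = [10.0, 25.0, 60.0]
        for scale in (1, 7, 1000):
            es = [evalue(b, 50 * scale, 100) for b in bits]
            assert es == sorted(es, reverse=True)

    @pytest.mark.parametrize("m,n", [(0, 5), (5, 0), (-1, 1)])
    def test_bad_sizes_rejected(self, m, n):
        with pytest.raises(ParameterError):
            evalue(10.0, m, n)

    def test_bit_score_conversion(self):
        params = AlignmentParams()
        raw = 100
        expected = (params.lam * raw - math.log(params.k)) / math.log(2)
        assert params.bit_score(raw) == pytest.approx(expected)


class TestRBH:
    def test_empty_inputs(self):
        assert reciprocal_best_hits([], []) == []

    def test_identical_proteomes_pair_one_to_one(self, rng):
        prots_a = [
            ProteinRecord(f"a{i}", "ga", "".join(rng.choice(AA, size=50)))
            for i in range(10)
        ]
        prots_b = [
            ProteinRecord(f"b{i}", "gb", prots_a[i].sequence) for i in range(10)
        ]
        pairs = reciprocal_best_hits(search(prots_a, prots_b), search(prots_b, prots_a))
        assert sorted(pairs) == [(f"a{i}", f"b{i}") for i in range(10)]

    def test_planted_orthologs_recovered_over_decoys(self, rng):
        base = ["".join(rng.choice(AA, size=90)) for _ in range(4)]
        prots_a = [ProteinRecord(f"a{i}", "ga", s) for i, s in enumerate(base)]
        orthologs = [mutate_to_identity(s, 75, seed=i) for i, s in enumerate(base)]
        decoys = ["".join(rng.choice(AA, size=90)) for _ in range(4)]
        prots_b = [ProteinRecord(f"b{i}", "gb", s) for i, s in enumerate(orthologs)] + [
            ProteinRecord(f"d{i}", "gb", s) for i, s in enumerate(decoys)
        ]
        pairs = reciprocal_best_hits(search(prots_a, prots_b), search(prots_b, prots_a))
        assert sorted(pairs) == [(f"a{i}", f"b{i}") for i in range(4)]

    def test_each_protein_in_at_most_one_pair(self, rng):
        prots_a = [
            ProteinRecord(f"a{i}", "ga", "".join(rng.choice(AA, size=60)))
            for i in range(6)
        ]
        prots_b = [
            ProteinRecord(f"b{i}", "gb", "".join(rng.choice(AA, size=60)))
            for i in range(6)
        ]
        pairs = reciprocal_best_hits(search(prots_a, prots_b), search(prots_b, prots_a))
        lefts = [a for a, _ in pairs]
        rights = [b for _, b in pairs]
        assert len(lefts) == len(set(lefts)) and len(rights) == len(set(rights))


class TestAAI:
    def _proteome(self, rng, genome, n=6, length=80):
        return [
            ProteinRecord(f"{genome}|s01|{i:05d}", genome, "".join(rng.choice(AA, size=length)))
            for i in range(n)
        ]

    def test_identical_proteomes_aai_100(self, rng):
        a = self._proteome(rng, "ga")
        b = [
            ProteinRecord(p.protein_id.replace("ga", "gb"), "gb", p.sequence) for p in a
        ]
        res = compute_aai(a, b)
        assert res.aai == pytest.approx(100.0)
        assert res.n_rbh_pairs == len(a)

    def test_symmetry(self, rng):
        a = self._proteome(rng, "ga")
        b = self._proteome(rng, "gb")
        r1, r2 = compute_aai(a, b), compute_aai(b, a)
        assert r1.aai == r2.aai and r1.n_rbh_pairs == r2.n_rbh_pairs

    def test_planted_identity_recovered(self, rng):
        a = self._proteome(rng, "ga", n=5, length=120)
        b = [
            ProteinRecord(
                p.protein_id.replace("ga", "gb"),
                "gb",
                mutate_to_identity(p.sequence, 75, seed=i),
            )
            for i, p in enumerate(a)
        ]
        res = compute_aai(a, b)
        assert res.defined
        assert abs(res.aai - 75.0) <= 3.0

    def test_raising_min_identity_never_adds_pairs(self, rng):
        a = self._proteome(rng, "ga", n=5, length=100)
        b = [
            ProteinRecord(
                p.protein_id.replace("ga", "gb"),
                "gb",
                mutate_to_identity(p.sequence, 70, seed=i),
            )
            for i, p in enumerate(a)
        ]
        counts = [
            compute_aai(a, b, min_identity=t).n_rbh_pairs for t in (30, 50, 70, 90)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_undefined_aai_is_explicit(self, rng):
        a = self._proteome(rng, "ga", n=3, length=60)
        b = self._proteome(rng, "gb", n=3, length=60)
        res = compute_aai(a, b, min_identity=95)
        assert not res.defined and res.aai is None and res.n_rbh_pairs == 0

    def test_empty_proteome_rejected(self, rng):
        with pytest.raises(InputError):
            compute_aai([], self._proteome(rng, "gb"))


def test_best_hit_tie_breaking_is_deterministic():
    from hemenet.homology import PairwiseHit

    def hit(subject, bit, length):
        return PairwiseHit(
            query_id="q", subject_id=subject, raw_score=0, bit_score=bit,
            pident=50.0, length=length, mismatches=0, gap_opens=0,
            qstart=1, qend=length, sstart=1, send=length, evalue=1e-5, qcov=100.0,
        )

    hits = [hit("z", 50.0, 40), hit("b", 50.0, 40), hit("a", 50.0, 30)]
    assert best_hits(hits)["q"].subject_id == "b"  # bit tie -> longer, then lexicographic
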
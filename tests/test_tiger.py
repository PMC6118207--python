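"""Set-partition site rates: examples, anchors, and a brute-force oracle."""

from fractions import Fraction

import numpy as np
import pytest

from tigerpart.alignment import AlignmentMatrix, LengthMismatchError
from tigerpart.tiger import (
    SiteRates,
    partition_agreement,
    read_rates,
    site_partition,
    tiger_rates,
    write_rates,
)

from conftest import random_alignment


# -- independent oracle -------------------------------------------------

def oracle_blocks(aln: AlignmentMatrix, site: int) -> list[set[int]]:
    """Taxa grouped by canonical state at a site, by direct scan."""
    groups: dict[str, set[int]] = {}
    for i in range(aln.n_taxa):
        ch = aln.matrix[i, site - 1]
        if ch in "ACGT":
            groups.setdefault(ch, set()).add(i)
    return list(groups.values())


def oracle_agreement(aln: AlignmentMatrix, ref: int, other: int) -> Fraction:
    """Fraction of `other`'s blocks nested in `ref`'s grouping.

    Taxa without a scored state at the reference site are unconstrained.
    Exact rational arithmetic keeps the oracle free of rounding, so the
    comparison against the fast implementation can demand bit identity.
    """
    rblocks = oracle_blocks(aln, ref)
    oblocks = oracle_blocks(aln, other)
    if not oblocks or not rblocks:
        return Fraction(1)
    scored = set().union(*rblocks)
    hits = 0
    for b in oblocks:
        restricted = b & scored
        if not restricted or any(restricted <= rb for rb in rblocks):
            hits += 1
    return Fraction(hits, len(oblocks))


def oracle_rates(aln: AlignmentMatrix) -> np.ndarray:
    out = np.empty(aln.n_sites)
    for i in range(1, aln.n_sites + 1):
        vals = [
            oracle_agreement(aln, i, j)
            for j in range(1, aln.n_sites + 1)
            if j != i
        ]
        out[i - 1] = float(sum(vals, Fraction(0)) / len(vals))
    return out


# -- site partitions ----------------------------------------------------

class TestSitePartition:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ("ACCA", [{0, 3}, {1, 2}]),
            ("AAAA", [{0, 1, 2, 3}]),
            ("A??T", [{0}, {3}]),
            ("????", []),
        ],
    )
    def test_examples(self, column, expected):
        aln = AlignmentMatrix.from_sequences(
            ["t1", "t2", "t3", "t4"], [c + "A" for c in column]
        )
        blocks = [set(b) for b in site_partition(aln, 1).blocks]
        assert sorted(map(sorted, blocks)) == sorted(map(sorted, expected))

    def test_ambiguity_codes_excluded(self):
        aln = AlignmentMatrix.from_sequences(["a", "b", "c"], ["RA", "AA", "NA"])
        assert [set(b) for b in site_partition(aln, 1).blocks] == [{1}]


class TestAgreement:
    def test_invariable_reference_agrees_with_anything(self):
        aln = AlignmentMatrix.from_sequences(
            ["a", "b", "c", "d"], ["AA", "AC", "AG", "AT"]
        )
        ref = site_partition(aln, 1)
        other = site_partition(aln, 2)
        assert partition_agreement(ref, other) == 1.0

    def test_fully_conflicting_partitions(self):
        # reference {1,4},{2,3} vs other {1,2},{3,4}: no block nests
        aln = AlignmentMatrix.from_sequences(
            ["t1", "t2", "t3", "t4"], ["AA", "CA", "CC", "AC"]
        )
        ref = site_partition(aln, 1)
        other = site_partition(aln, 2)
        assert partition_agreement(ref, other) == 0.0
        assert oracle_agreement(aln, 1, 2) == 0.0

    def test_identical_partitions(self):
        aln = AlignmentMatrix.from_sequences(
            ["a", "b", "c", "d"], ["AA", "AA", "TT", "TT"]
        )
        p1, p2 = site_partition(aln, 1), site_partition(aln, 2)
        assert partition_agreement(p1, p2) == 1.0


class TestTigerRates:
    def test_all_invariable_gives_all_ones(self):
        aln = AlignmentMatrix.from_sequences(["a", "b"], ["AAAA", "AAAA"])
        assert np.array_equal(tiger_rates(aln).rates, np.ones(4))

    def test_worked_three_site_example(self):
        # columns AAAA | ACCA | AGTA, rates derived by the oracle
        aln = AlignmentMatrix.from_sequences(
            ["t1", "t2", "t3", "t4"], ["AAA", "ACG", "ACT", "AAA"]
        )
        rates = tiger_rates(aln).rates
        assert np.array_equal(rates, oracle_rates(aln))
        assert rates[0] == 1.0
        assert rates[1] == pytest.approx(0.5)
        assert rates[2] == pytest.approx(0.25)

    def test_identical_variable_patterns_rate_one(self):
        aln = AlignmentMatrix.from_sequences(
            ["a", "b", "c", "d"], ["AA", "AA", "TT", "TT"]
        )
        assert np.array_equal(tiger_rates(aln).rates, np.ones(2))

    def test_single_site_rejected(self):
        aln = AlignmentMatrix.from_sequences(["a", "b"], ["A", "C"])
        with pytest.raises(ValueError):
            tiger_rates(aln)

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(60):
            aln = random_alignment(rng, n_taxa=6, n_sites=20,
                                   missing_prob=0.15)
            fast = tiger_rates(aln).rates
            slow = oracle_rates(aln)
            assert np.array_equal(fast, slow)

    def test_taxon_permutation_invariance(self, rng):
        aln = random_alignment(rng, n_taxa=8, n_sites=30)
        perm = rng.permutation(8)
        shuffled = AlignmentMatrix(
            tuple(aln.taxa[i] for i in perm), aln.matrix[perm]
        )
        assert np.allclose(tiger_rates(aln).rates, tiger_rates(shuffled).rates)

    def test_duplicating_a_site_only_rescales_denominator(self, rng):
        aln = random_alignment(rng, n_taxa=6, n_sites=12, missing_prob=0.0)
        dup = AlignmentMatrix(
            aln.taxa, np.concatenate([aln.matrix, aln.matrix[:, :1]], axis=1)
        )
        assert np.array_equal(tiger_rates(dup).rates, oracle_rates(dup))

    def test_invariable_anchor_with_missing_data(self, rng):
        # invariable = single observed state; must score exactly 1
        for _ in range(20):
            aln = random_alignment(rng, n_taxa=7, n_sites=15,
                                   missing_prob=0.3)
            rates = tiger_rates(aln).rates
            for s in range(aln.n_sites):
                col = aln.matrix[:, s]
                observed = {c for c in col if c in "ACGT"}
                if len(observed) <= 1:
                    assert rates[s] == 1.0
            assert np.all(rates >= 0.0) and np.all(rates <= 1.0)


class TestRatesIO:
    def test_round_trip_exact(self, tmp_path):
        rates = SiteRates(np.array([1.0, 0.5, 0.123456789012345678, 0.0]))
        path = tmp_path / "rates.txt"
        write_rates(rates, path)
        back = read_rates(path)
        assert np.array_equal(back.rates, rates.rates)

    def test_count_mismatch(self, tmp_path):
        path = tmp_path / "rates.txt"
        path.write_text("1.0\n0.5\n0.2\n")
        with pytest.raises(LengthMismatchError):
            read_rates(path, expected_length=4)

    def test_non_numeric_line(self, tmp_path):
        path = tmp_path / "rates.txt"
        path.write_text("1.0\nfoo\n")
        with pytest.raises(ValueError, match="line 2"):
            read_rates(path)

    def test_out_of_range_rate(self, tmp_path):
        path = tmp_path / "rates.txt"
        path.write_text("1.23\n")
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            read_rates(path)
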
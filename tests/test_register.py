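"""Register mapping: R/Y conversion, scanning, probabilities, palindromes."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circdna.fixtures import fixture
from circdna.register import (
    MatchHit,
    RYProfile,
    assign_register,
    complement_ry,
    count_agreements,
    find_palindromes,
    interval_overlap,
    match_probability,
    one_in_n,
    scan,
    to_ry,
)
from circdna.sequences import CircularSequence, reverse_complement
from circdna.synthetic import Plant, SyntheticSpec, planted_query, synth_sequence

nucleotides = st.text(alphabet="ACGT", min_size=1, max_size=60)
ry_strings = st.text(alphabet="RYX", min_size=1, max_size=60)


@pytest.mark.parametrize(
    "seq,expected",
    [("GAATTC", "RRRYYY"), ("ACGT", "RYRY"), ("A", "R")],
)
def test_to_ry_mapping(seq, expected):
    prof = to_ry(seq)
    assert prof.symbols == expected
    assert prof.source == "sequence"


def test_to_ry_rejects_and_names_position():
    with pytest.raises(ValueError, match="position 2"):
        to_ry("ANT")


@settings(derandomize=True)
@given(nucleotides)
def test_to_ry_reverse_complement_identity(s):
    # R/Y of the reverse complement = reversed R/Y-complement of R/Y
    lhs = to_ry(reverse_complement(s)).symbols
    rhs = complement_ry(to_ry(s)).symbols[::-1]
    assert lhs == rhs


@settings(derandomize=True)
@given(ry_strings)
def test_complement_ry_involution(p):
    prof = RYProfile(p)
    assert complement_ry(complement_ry(prof)).symbols == p


def test_complement_ry_examples():
    assert complement_ry(RYProfile("RYYR")).symbols == "YRRY"
    assert complement_ry(RYProfile("XXX")).symbols == "XXX"


class TestMatchProbability:
    def test_published_values(self):
        assert match_probability(24, 2) == 301 / 2**24
        assert one_in_n(24, 2) == 55738
        assert match_probability(30, 2) == 466 / 2**30
        assert one_in_n(30, 2) == 2304167

    def test_edge_cases(self):
        assert match_probability(1, 0) == 0.5
        assert match_probability(7, 7) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            match_probability(5, 6)
        with pytest.raises(ValueError):
            match_probability(0, 0)
        with pytest.raises(ValueError):
            match_probability(5, -1)

    @pytest.mark.parametrize("n,f", [(4, 1), (8, 2), (12, 3), (12, 0)])
    def test_exhaustive_enumeration_oracle(self, n, f):
        # count, over all 2^n R/Y strings, those within f of a fixed target
        target = "".join("RY"[i % 2] for i in range(n))
        count = 0
        for cand in product("RY", repeat=n):
            if sum(a != b for a, b in zip(cand, target)) <= f:
                count += 1
        assert match_probability(n, f) == count / 2**n

    def test_monotonicity(self):
        # decreasing in n at fixed f; increasing in f at fixed n
        assert all(
            match_probability(n + 1, 2) < match_probability(n, 2) for n in range(2, 30)
        )
        assert all(
            match_probability(20, f) < match_probability(20, f + 1) for f in range(0, 20)
        )


class TestCountAgreements:
    def test_table1_columns(self):
        t1 = fixture("table1")
        assert count_agreements(t1.chain_e_assignment(), t1.chain_e_pattern()) == (22, 1, 1)

    def test_table2_columns(self):
        t2 = fixture("table2")
        assert count_agreements(t2.chain_e_assignment(), t2.chain_e_pattern()) == (28, 2, 0)

    def test_identical_profiles(self):
        p = RYProfile("RYRYRY")
        assert count_agreements(p, RYProfile("RYRYRY", source="sequence")) == (6, 0, 0)

    def test_errors(self):
        with pytest.raises(ValueError):
            count_agreements(RYProfile("RY"), RYProfile("RYR"))
        with pytest.raises(ValueError):
            count_agreements(RYProfile("RY"), RYProfile("RX"))

    @settings(derandomize=True)
    @given(ry_strings)
    def test_totals_sum_to_length(self, p):
        ref = RYProfile(p.replace("X", "R"))
        counts = count_agreements(RYProfile(p), ref)
        assert sum(counts) == len(p)


def _scan_oracle(profile, ref, max_free):
    """Independent scan: reverse strand compares the profile to the R/Y of
    the reverse-complemented window (vs. the implementation's
    profile-complementation route)."""
    L = len(ref)
    n = len(profile.symbols)
    starts = range(1, L + 1) if ref.circular else range(1, L - n + 2)
    hits = set()
    for s in starts:
        window = ref.fragment(s, n)
        for strand, w in (
            ("forward", to_ry(window).symbols),
            ("reverse", to_ry(reverse_complement(window)).symbols),
        ):
            q = profile.symbols if strand == "forward" else profile.symbols
            # compare profile (5'->3' along its own strand) to the strand's R/Y
            free = sum(
                1
                for p_sym, w_sym in zip(q, w)
                if p_sym == "X" or p_sym != w_sym
            )
            if free <= max_free:
                hits.add((s, strand, free))
    return hits


class TestScan:
    def test_planted_profile_is_unique_minimum(self):
        spec = SyntheticSpec(
            seed=11,
            length=601,
            plant=Plant("RYYRYRRRRYRRYRRYYRRYRRRY", position=250, n_mismatch=1),
        )
        seq = synth_sequence(spec)
        query = planted_query(spec)
        res = scan(query, seq, max_free=2)
        assert res.best.start == 250
        assert res.best.strand == "forward"
        assert res.best.n_mismatch == 1
        assert res.unique

    def test_all_x_profile_hits_everywhere(self):
        ref = CircularSequence("ACGTACGTAC", circular=True)
        res = scan(RYProfile("XXX"), ref, max_free=3)
        assert len(res) == 2 * len(ref)
        assert all(h.n_unresolved == 3 for h in res)
        assert not res.unique

    def test_self_match_is_exact(self):
        ref = CircularSequence("ACGTTGCAGGAT", circular=True)
        prof = RYProfile(to_ry(ref.fragment(4, 6)).symbols)
        res = scan(prof, ref, max_free=0)
        exact_fwd = [h for h in res if h.strand == "forward" and h.start == 4]
        assert exact_fwd and exact_fwd[0].n_agree == 6

    def test_sorted_by_free_then_position(self):
        ref = CircularSequence("ACGTACGTACGTACGT", circular=True)
        res = scan(RYProfile("RYRY"), ref, max_free=2)
        keys = [(h.free, h.start) for h in res]
        assert keys == sorted(keys)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            L = int(rng.integers(20, 64))
            seq = CircularSequence(
                "".join(rng.choice(list("ACGT"), L)), circular=bool(trial % 2)
            )
            n = int(rng.integers(4, 10))
            prof = RYProfile(
                "".join(rng.choice(list("RYX"), n, p=[0.45, 0.45, 0.1]))
            )
            if not seq.circular and n > L:
                continue
            got = {(h.start, h.strand, h.free) for h in scan(prof, seq, max_free=2)}
            assert got == _scan_oracle(prof, seq, 2)

    def test_probability_attached_to_hits(self):
        ref = CircularSequence("ACGTACGT", circular=True)
        for h in scan(RYProfile("RYR"), ref, max_free=1):
            assert h.probability == match_probability(3, h.free)

    def test_profile_longer_than_linear_reference(self):
        with pytest.raises(ValueError):
            scan(RYProfile("RYRYR"), CircularSequence("ACG", circular=False), 0)

    def test_expected_hit_count_in_random_sequences(self):
        # expected hits ~ 2 * L * P(n, max_free) over many seeded replicates
        n, L, max_free, reps = 10, 64, 1, 200
        p = match_probability(n, max_free)
        prof = RYProfile("RYRRYYRYRR")
        total = 0
        for seed in range(reps):
            seq = synth_sequence(SyntheticSpec(seed=seed, length=L))
            total += len(scan(prof, seq, max_free))
        trials = reps * 2 * L
        se = math.sqrt(trials * p * (1 - p))
        assert abs(total - trials * p) < 3 * se


class TestAssignRegister:
    def _hit(self, start, strand, n):
        return MatchHit(start, strand, n, n, 0, 0, match_probability(n, 0))

    def test_extension_covers_widened_range(self):
        seq = synth_sequence(SyntheticSpec(seed=3, length=601))
        hit = self._hit(112, "forward", 24)
        asg = assign_register(hit, seq, extend_left=3, extend_right=3)
        assert asg.mapped_range == (109, 138)
        assert len(asg.chain_sequence) == 30
        assert asg.chain_sequence == seq.interval(109, 138)

    def test_zero_extension_is_hit_interval(self):
        seq = synth_sequence(SyntheticSpec(seed=3, length=50))
        asg = assign_register(self._hit(10, "forward", 8), seq)
        assert asg.chain_sequence == seq.interval(10, 17)

    def test_reverse_strand_gives_reverse_complement(self):
        seq = synth_sequence(SyntheticSpec(seed=4, length=80))
        fwd = assign_register(self._hit(20, "forward", 12), seq)
        rev = assign_register(self._hit(20, "reverse", 12), seq)
        assert rev.chain_sequence == reverse_complement(fwd.chain_sequence)
        assert rev.mapped_range == fwd.mapped_range

    def test_wraps_on_circle_and_errors_on_linear(self):
        circ = synth_sequence(SyntheticSpec(seed=5, length=30))
        asg = assign_register(self._hit(2, "forward", 5), circ, extend_left=4)
        assert asg.mapped_range == (28, 6)
        lin = CircularSequence(circ.residues, circular=False)
        with pytest.raises(ValueError):
            assign_register(self._hit(2, "forward", 5), lin, extend_left=4)


def _palindrome_oracle(s, min_len):
    """All maximal even self-reverse-complement substrings (linear, brute)."""
    hits = set()
    L = len(s)
    for i in range(L):
        for j in range(i + 1, L, 2):
            sub = s[i : j + 1]
            if sub != reverse_complement(sub):
                continue
            if len(sub) < min_len:
                continue
            if i > 0 and j < L - 1:
                wider = s[i - 1 : j + 2]
                if wider == reverse_complement(wider):
                    continue  # extensible, not maximal
            hits.add((i + 1, j + 1, j - i + 1))
    return hits


class TestPalindromes:
    def test_gaattc(self):
        hits = find_palindromes(CircularSequence("GAATTC", circular=False), 4)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].length) == (1, 6, 6)

    def test_aaaa_is_not_palindromic(self):
        assert find_palindromes(CircularSequence("AAAA", circular=False), 4) == []

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        s = "".join(rng.choice(list("ACGT"), 200))
        got = {
            (h.start, h.end, h.length)
            for h in find_palindromes(CircularSequence(s, circular=False), 4)
        }
        assert got == _palindrome_oracle(s, 4)

    def test_wraps_across_circular_origin(self):
        # GAATTC split across the origin: ...GAA | TTC...
        middle = "GGGCCGCCGGGACGGGG"  # no palindromes >= 4 of its own
        seq = CircularSequence("TTC" + middle + "GAA", circular=True)
        hits = find_palindromes(seq, 6)
        L = len(seq)
        assert any(h.start == L - 2 and h.end == 3 and h.length == 6 for h in hits)

    def test_min_len_must_be_even(self):
        with pytest.raises(ValueError):
            find_palindromes(CircularSequence("ACGT"), 3)


class TestIntervalOverlap:
    def test_gsegment_assignments_share_7bp(self):
        assert interval_overlap((109, 138), (132, 161), 601, circular=True) == 7

    def test_disjoint(self):
        assert interval_overlap((1, 10), (20, 30), 601, circular=True) == 0

    def test_wraparound(self):
        assert interval_overlap((595, 10), (1, 5), 601, circular=True) == 5

    def test_linear_rejects_wrap(self):
        with pytest.raises(ValueError):
            interval_overlap((595, 10), (1, 5), 601, circular=False)

    def test_malformed(self):
        with pytest.raises(ValueError):
            interval_overlap((0, 5), (1, 2), 10, circular=True)
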